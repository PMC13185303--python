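# Methods

This note documents the models and procedures `drugsig` implements, the
choices made where a definition was genuinely open, and the limits of what
the synthetic studies demonstrate.

## Interaction scoring

A compound–protein score is a docking surrogate built from binding-site
predictions (site confidence in [0, 1] plus a template-ligand fingerprint)
and chemical similarity between the query compound and the templates:

    score(c, p) = Dice(q_c, t*) × conf(t*)

with `t*` the template maximising the Sorenson-Dice coefficient to the query.
Two readings of this rule are possible — select the most similar template and
multiply by its confidence, or maximise the product directly — and they can
disagree when a slightly less similar template has much higher confidence.
The default is `argmax_dice` (template selection first), with
`mode="max_product"` available; Dice ties across sites resolve to the higher
confidence, then site id, so scoring is invariant to site order. Proteins
without predicted sites score 0 and are logged once. Fingerprints are
unfolded sparse ECFP4 feature sets (RDKit Morgan radius 2); folded bit
vectors on input are converted to sets of set-bit indices. Two empty
fingerprints have similarity 0, not 1 — a featureless parse must not look
like a perfect match.

## Similarity lists and ties

Signature rows are compared with cosine distance without centering or
scaling. Zero-signature edge cases: one all-zero vector is at distance 1
from any non-zero vector, two all-zero vectors are at distance 0. Distances
below 1e-12 are snapped to exactly 0 so that duplicate signatures form exact
tie blocks. Every ordering in the package is a total order: ascending
distance (or fused key), then ascending compound id. Rank-fusion pipelines
store the fused key normalised by its operator-specific ceiling (L for
min/max/mean, 2L for sum, L² for rank product; the distance product is
already in [0, 1]) so fused lists satisfy the same distance-in-[0,1]
contract as native ones.

The uniqueness filter zeroes the similarity of the top `ceil(f·L)` neighbors
per list (default f = 0.02) — `ceil` so the filter is never a no-op on short
lists — keeping the pairs in place at distance 1 rather than deleting them,
which leaves list lengths and cutoff arithmetic unchanged while removing the
pairs' influence on top-N metrics. The percentile rule is primary; an
absolute-threshold variant (`apply_absolute_similarity_filter`) exists for
sensitivity checks.

## Benchmarking metrics

IA for an indication with approved set A (|A| ≥ 2): the percentage of drugs
in A whose top-N list contains another member of A; AIA is the unweighted
mean across indications. NDCG uses the standard information-retrieval form:
binary relevance, 1/log₂(j+1) discount, ideal DCG truncated at
min(|A|−1, N), averaged over approved queries.

Consensus lists order compounds by (descending vote count, ascending mean
rank over voting lists, ascending id). The average score is the mean rank
over only the lists in which the compound appeared within the voting cutoff.
**A vote requires positive similarity**: a neighbor at distance exactly 1
(zero similarity — either never similar or zeroed by the uniqueness filter)
does not contribute, even if it falls inside the voting cutoff by tie-break
order. This is what makes the degenerate perfect-duplicate limit behave
correctly: when everything outside an indication sits at distance exactly 1,
the id-ordered tie block would otherwise collect one more vote than any
approved drug can (the block is identical across all voters' lists, while
each approved drug is absent from its own), inverting the consensus head on
a technicality of tie-filling rather than any similarity signal. The
per-list voting cutoff defaults to the evaluation cutoff N and is
configurable. nIA is the percentage of approved drugs inside the consensus
top-N; nNDCG applies the DCG construction once to the consensus ordering
with ideal DCG over min(|A|, N).

Controls: the IA chance baseline is the closed-form hypergeometric
probability 1 − C(M−K, N)/C(M−1, N) of drawing at least one of the K−1 other
approved drugs in N of M−1 slots. The NDCG baseline is exact under position
exchangeability: E[NDCG@N] = ((K−1)/(M−1)) Σ 1/log₂(j+1) / IDCG. No closed
form is used for the consensus metrics; `control="monte_carlo"` estimates
nIA/nNDCG baselines from seeded permutation nulls (default 100 replicates
per indication) via a vectorised null-consensus path.

## Candidate prediction

Candidates are the consensus list truncated to `top_k` (default 100) with
voting depth `per_list_cutoff` (default 100). The binomial null takes
n = number of voters and p = per_list_cutoff/(M−1), i.e. each voter's list
is an independent uniform ranking; both parameters are logged with every
run since other parameterisations are defensible. Approved drugs are
retained and flagged rather than removed — rediscovered approved drugs are a
positive control, and novel-only filtering is presentation, not modelling.

## Target overlap

Per-compound target rankings sort proteins by descending score, ties by id.
Group-level overlap pools a candidate group by **best rank** (the minimum
predicted rank of each gold protein over the group's candidates), feeding
rank-bin frequencies (bins of 20 up to rank 100), cumulative percentage
overlap (cutoffs 10..100), and the Jaccard coefficient of the pooled
rank ≤ 10 target set against the gold standard. Bin proportions are
normalised within the group (counts are also reported, so across-group
normalisation can be recomputed). Control groups: a seeded uniform random
draw, and a bottom-of-list group pre-filtered to ≥ 5 heavy atoms so trivial
fragments do not masquerade as low-scoring but complex candidates.

## Synthetic studies

`generate_study` plants the structure the analysis assumes. Indication i
gets K dedicated approved drugs and G dedicated driver proteins; each
approved drug's entries on its drivers are `clip(background + signal +
N(0, noise_sd), 0, 1)` — an *additive elevation*, so `signal=0, noise_sd=0`
yields an exact null with no indication structure. The background is
`Bernoulli(density) × Beta(2, 5)` (right-skewed, as expected for products of
a similarity and a confidence), with a uniform option for null calibration.
Fingerprints are random sparse feature sets; analog pairs share exactly
`ceil(2Ft/(1+t))` features to guarantee Tanimoto ≥ t (default 0.9), and are
planted between approved drugs of *different* indications so the uniqueness
filter demonstrably removes cross-indication analog crowding. Gold standard
for indication i is its driver set. Heavy-atom counts are uniform on 1..40.
One master seed is split into named substreams (background, signal,
fingerprints, analogs, sites, atoms), so each component is independently
reproducible. The generated site library exercises the scoring stage; the
planted matrix is generated directly and is deliberately *not* derived from
those sites.

What the synthetic studies do **not** emulate: real score distributions
beyond their qualitative shape, chemical-series structure in fingerprints
(only the planted analog pairs carry fingerprint signal, so fingerprint
pipelines benchmark near chance on synthetic data — by construction, not as
a statement about real libraries), correlated indications sharing drugs or
targets, and realistic library sizes. Passing tests demonstrate the
correctness and calibration of the machinery, not performance on real data.

## Problem sizes and numerical choices

Default study scale is M = 500 compounds × P = 300 proteins with 50
indications of 4 drugs — large enough for stable calibration statistics,
small enough that the full four-pipeline comparison runs in well under two
minutes on one CPU. Calibration checks use 200 replicate indications at
M = 500 and compare mean IA to the hypergeometric control within three
Monte-Carlo standard errors. The planted-recovery/overlap analyses use
M = 300 × P = 2000 — a proteome much larger than the pooled top-target sets,
mirroring the regime the overlap statistics are designed for — over 20
replicate studies. Hypergeometric and binomial tails are computed via
`scipy.stats` survival functions (numerically stable sums), asserted in
tests against exhaustive enumeration and direct summation.

## Known limitations

- The binomial null for consensus votes assumes voters' lists are
  independent uniform rankings; correlated voters (the norm in real data)
  make it anti-conservative. It is a ranking heuristic, not a p-value.
- The consensus vote gate (positive similarity) means a pipeline whose
  distances saturate at 1 produces empty consensus lists — intended, but it
  makes nIA sensitive to how a distance reaches 1 exactly.
- Monotonicity of the scoring rule holds for confidences, but adding a site
  can lower the `argmax_dice` score if the new site wins the Dice argmax
  with lower confidence; only site-order invariance is guaranteed (and
  property-tested).
- Exact tie blocks rely on bitwise-equal floating point distances; this is
  guaranteed for construction-identical signatures but not for signatures
  that are merely mathematically equal via different arithmetic paths.
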