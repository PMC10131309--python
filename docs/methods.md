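# Methods

## The resampling procedure

Given a binary dataset with minority count m and majority count n (m < n),
the resampler augments the minority class until the minority/majority
ratio reaches a target ρ (default 0.5). Each run:

1. **Neighborhoods.** For every minority point x, the k nearest minority
   neighbors KNN(x) are computed under Euclidean distance, with
   k = max(1, round_half_up(k_frac · m)) clamped to m − 1. Neighbors are
   drawn from the minority class only: interpolating toward majority
   points would manufacture samples of the wrong class by construction.
2. **Visibility filter** (on in the full method). y ∈ KNN(x) is kept iff
   ⟨x − z, y − z⟩ ≥ 0 for all z ∈ KNN(x). The geometric reading: z
   *separates* x and y when it lies strictly inside the sphere with
   diameter xy; a neighbor with no separator is visible. Three
   consequences shape the implementation:
   - the test at z = y is an inner product with the zero vector, so it
     never disqualifies;
   - the nearest neighbor is always visible (a separator z of the nearest
     neighbor would satisfy |xz| < |xy| by the obtuse-angle inequality,
     contradicting minimality), so visible sets are non-empty and the
     sampler never stalls;
   - visibility depends only on inner products of difference vectors, so
     it is invariant under rigid motions and positive scaling.
3. **Generation.** Each minority point contributes n_per_point candidates
   per round; each candidate picks a neighbor uniformly (with
   replacement) from the eligible set and a factor u uniform on the unit
   interval, giving parent + u · (neighbor − parent). Every candidate is
   a convex combination of two minority points and carries provenance
   (parent row, neighbor row, u, round).
4. **Inspection** (on in the full method). Before round 1 the majority
   rows are randomly partitioned into M = max(1, round_half_up(n/m))
   batches with sizes differing by at most one; each batch plus the full
   minority class trains one inspector (default: 100-tree random forest)
   on roughly 1:1 data. A candidate's uncertainty score is the fraction
   of inspectors whose hard prediction is the majority class — always a
   multiple of 1/M — and candidates scoring strictly above the threshold
   T are dropped. Inspectors are trained once, on original rows only;
   training them on synthetic points would let the generator grade its
   own output.
5. **Accumulation.** Rounds repeat until ceil(ρ·n) − m candidates are
   accepted or max_rounds is exhausted. The final round's surplus is
   removed by seeded uniform subsampling, so the target count is hit
   exactly whenever the budget allows; a shortfall is reported on the
   result (achieved ratio below target) with a warning rather than an
   error, because a strict threshold on heavily overlapping classes can
   legitimately reject nearly everything.

The round structure is a reconciliation device: a single fixed-N pass
cannot guarantee the target ratio once the filter removes an
unpredictable fraction, and iterating with surplus truncation restores
the exact-count contract without biasing toward any parent.

## Parameters

| name | default | meaning |
|---|---|---|
| `k_frac` | 0.75 | neighborhood size as a fraction of the minority count (dimensionless) |
| `n_per_point` | 5 | candidates per minority point per round |
| `threshold` | 0.5 | uncertainty cutoff T; candidates with S > T are dropped |
| `target_ratio` | 0.5 | desired minority/majority count ratio |
| `max_rounds` | 20 | round budget before accepting a shortfall |
| `seed` | 0 | master seed; the whole run is bit-reproducible from it |

The defaults are the headline operating point of the method; the
sensitivity sweep in the evaluation module varies K over
{5, 10, 25, 50, 75}% of the minority count, N over 1–5 and T over
{25, 50, 60, 75, 90}% one at a time with the others held at these
defaults.

Features are used as-is — no automatic standardization. Euclidean
distance (and hence the visibility test) is scale-sensitive, so callers
with heterogeneous units should scale before resampling; the package
deliberately does not guess.

## Inspectors and final classifier

Inspectors are pluggable through a `classifier_factory(seed)` hook; the
default random forest with 100 trees is the conventional ensemble size,
and each inspector receives a child seed derived from the master seed.
Hard class predictions feed the score (matching its indicator
definition); probabilities are never consulted. The evaluation harness
fits the same family (100-tree random forest, independently seeded) as
the final classifier on the augmented training split of each stratified
fold, and reports minority precision/recall/F1 per fold with mean and
sample (n − 1) standard deviation. Zero-denominator precision or recall
is reported as 0 with a logged warning — the conservative convention for
a minority-focused comparison. Folds are stratified because at 5–15%
minority prevalence unstratified splits risk minority-free test folds.

## Synthetic scenarios: what they emulate, and what they don't

`nonconvex_crescent` places the minority on a half-annulus (radius band
3 ± 0.5, upper half-plane) wrapped around a central majority Gaussian
(sd one third of the inner radius). It realizes, with a known membership
oracle, the geometry that motivates visibility filtering: segments
between far-apart minority points cut through the majority blob, so
plain-KNN interpolation leaks out of the class while visible-mode
interpolation stays in the band. The nonconvexity is certified per
dataset (some minority midpoint lies in the majority region).

`gaussian_blobs` (mean separation 8 × noise_sd) is the
nothing-should-go-wrong control; `overlap_blobs` (separation
1.5 × noise_sd) produces heavy class overlap calibrated so that an
unresampled random-forest at ~10% imbalance shows the hallmark of the
problem the method addresses: minority recall far below precision.
Feature dimensions beyond the first two are isotropic noise, keeping the
geometry planar while exercising d > 2 code paths. `noise_sd` (default
0.25) sets the blob scale and the noise-dimension scale; crescent
minority points are drawn uniformly in the band, so the oracle is exact
on its own samples.

What passing on these scenarios does **not** show: the generators make
no attempt to match real cohorts' dimensionality, marginals or feature
correlations, and the two ingredients do not pay off uniformly across
geometries. On *convex* overlapping blobs the visibility filter is pure
conservatism — it shortens interpolation reach without any nonconvexity
to protect against, and can cost recall relative to plain SMOTE even
while inspection helps; the visible-neighbor advantage is a nonconvexity
story, demonstrated on the crescent. Conclusions about any real dataset
require running the evaluation harness on that dataset.

## Numerical choices

- Visibility uses the exact comparison ≥ 0, no tolerance. The boundary
  (right angle) counts as visible — the defining inequality is taken
  over the prose intuition of "acute angles" — and exact duplicates
  (zero difference vectors) are visible, since dropping them would
  silently discard valid minority mass. The vectorized implementation
  evaluates, per anchor, G[a,a] − G[a,b] from one Gram matrix of
  neighbor offsets; duplicate rows make the difference exactly zero in
  floating point, so the convention is stable.
- Distance ties in KNN break by ascending row index (stable argsort),
  making neighbor lists deterministic.
- Rounding is half-up for both M and k; "round to the ratio" needs a
  rule at .5 and half-up keeps each inspector batch closest to 1:1.
- u is drawn by a uniform generator on [0, 1); the closed-endpoint case
  u = 1 has measure zero and endpoints are harmless anyway (they
  reproduce an existing minority point).
- Generation and inspector-training randomness come from two independent
  streams spawned from the master seed, so disabling inspection — or
  making its filter vacuous with T = 1 — leaves the generated candidate
  stream untouched; the ablations then coincide bit-for-bit with classic
  SMOTE under the same seed.
- Rows are never reordered anywhere; all provenance indices refer to
  original row positions, and augmented datasets are original rows (byte
  identical, in order) followed by synthetic rows.

## Test problem sizes

The test suite runs the geometric property checks on 1,000 random
instances (n ≤ 50 points, k ≤ 20, d ∈ {2, 5, 20}), the crescent quality
comparison and the end-to-end CV comparison on 20 seeds each, with the
CV study at 40 minority / 400 majority and 5 folds — sizes chosen so the
full Monte-Carlo suite completes in minutes on a single core while
keeping every per-fold minority count comfortably above the stratified
CV minimum.

## Known limitations

- Binary labels and purely numeric features only; no categorical
  handling and no missing values (validation rejects them — imputation
  interacts with interpolation geometry in ways this package does not
  model).
- KNN is exact and O(m²) in the minority count; fine for the intended
  regime (minority classes in the hundreds), wasteful beyond it.
- The uncertainty score is a vote fraction on the 1/M grid; with small M
  the threshold granularity is coarse (at M = 2, T anywhere in [0.5, 1)
  behaves identically).
- T is a tuning parameter; the package does not calibrate it
  automatically.
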