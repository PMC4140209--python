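# Methods

This note records the models implemented in `hrventropy`, the conventions
that had to be fixed where the literature leaves room, and what the
synthetic study presets do and do not demonstrate.

## Estimators and conventions

All four estimators share the template/Chebyshev-distance machinery
described in the README.  The following conventions are fixed package-wide:

* **Strict match inequality.** A match is `d < r`.  For real-valued signals
  ties occur with probability zero; the convention only matters for exactly
  quantised data.
* **ApEn counts self-matches** (`j = i` included), so every count is at
  least 1 and the logarithms are always finite.  Its `φ^m` averages over all
  `N−m+1` templates with the same count normaliser; `φ^{m+1}` over `N−m`.
  This is the classical form and is the source of ApEn's bias toward
  regularity.
* **SampEn excludes self-matches** and uses only the first `N−m` templates
  at both lengths with denominator `N−m−1`, so an `(m+1)`-match is always
  also an `m`-match and SampEn ≥ 0 whenever defined.  When either match
  average is zero, SampEn is undefined; the package raises a typed
  `UndefinedEntropyError` carrying both `φ` values rather than returning an
  infinity, and the sweep layer records the record as missing.  Silent
  infinities would corrupt group statistics downstream.
* **Fuzzy variants.** The membership function is `exp(−(x/r)^n)` —
  continuous (similarity degrades gradually) and convex with its maximum at
  self-similarity; as `n → ∞` it converges to the hard indicator.  Local
  (baseline-removed) templates subtract each template's own mean; the mean
  of an `(m+1)`-template is recomputed over its `m+1` elements.  Sums run
  over `i, j = 1..N−m`, `j ≠ i`, with denominator `N−m−1`.  Memberships are
  strictly positive, so the fuzzy entropies are defined for every input and
  are continuous in `r` — the property that removes the abrupt threshold
  sensitivity of ApEn/SampEn.
* **FuzzyMEn global term.** Subtracting the whole-signal mean from every
  template shifts all templates by the same constant, so the global pairwise
  distances equal the raw template distances.  The implementation exploits
  this identity; the oracle tests verify it against a literal transcription
  that subtracts the mean explicitly.

The estimators are vectorised (`O(N²m)` time); a per-record
`EntropyEngine` caches the distance matrices, which makes threshold and
weight sweeps cheap because only the counting/membership step depends on
`(r, n)`.  A record of N ≈ 1100 takes well under a second per estimator.

## Threshold selection

`r = k·σ` uses the sample (n−1) standard deviation of the **cropped segment
actually analysed**, never the full original recording: the threshold must
describe the data the estimator sees.  The `r_Chon` empirical formula

    r_Chon = (−0.036 + 0.26·√(σ₁/σ₂)) / (N/1000)^(1/4)

is implemented for `m = 2` from precomputed `σ₁` (successive differences)
and `σ₂` (full segment).  The formula's published renderings are often
typographically mangled; this reconstruction follows the original source and
satisfies the checkable anchors: `0.224` at `σ₁ = σ₂`, `N = 1000`; halved at
`N = 16000`; scale-invariant (ratio only); and `σ₁/σ₂ → √2` for iid data.
For extremely smooth signals (`√(σ₁/σ₂) < 0.1385`) the formula goes
non-positive; this raises a degenerate-threshold error and the sweep layer
records the row as missing.

## Preprocessing

RR intervals strictly greater than 2.5 s are deleted (not interpolated) as
artifacts; no low-side rule is applied.  Records are then center-cropped to
a common length `N`, removing `floor((L−N)/2)` samples from the start and
the remainder from the end — on an odd surplus the extra sample comes off
the end (a tie-break that had to be fixed somewhere; the choice is
arbitrary but frozen and tested).  Filtering precedes cropping to maximise
usable length.  `prepare_cohorts` is idempotent and reports rejected
records rather than failing, unless strict mode is requested.

## Statistical procedure

Each group sample is screened with Lilliefors' composite normality test.
P-values come from Monte-Carlo null tables (10 000 simulated standard-normal
samples per sample size, cached; p = (1 + exceedances)/(1 + replicates)),
which avoids interpolating small printed tables.  If neither group rejects
at α = 0.05, groups are compared with Student's pooled two-sample t-test
(Welch available behind a flag); otherwise with the two-sided Wilcoxon
rank-sum test — exact enumeration when the smaller group has fewer than 10
values and there are no ties, else the normal approximation with tie and
continuity corrections.  α = 0.05 is used for both the gate and the
comparison.  Groups too small or too degenerate to screen (fewer than 4
clean values, or constant) cannot be certified normal and are routed to the
rank-sum branch.  Undefined entropies are dropped per group with the counts
recorded.

Within one sweep subset — one cohort pair and one threshold mode of a test
case — the same test is enforced for every grid point: if any comparison
fell back to the rank-sum test, all are recomputed with it.  Mixed tests
across a grid would make the p-value curves incomparable.  No
multiple-testing correction is applied anywhere: the comparisons share the
null hypothesis, subjects and endpoint, and the aim is to compare the
methods' sensitivity, not to confirm a group difference.

## The sweep test cases

1. `r = r_L = r_F = k·σ`, `k ∈ [0.1, 0.25]` (default 7-point grid), fixed
   `m = 2`, `n = n_L = 3`, `n_F = 2`, `N = 1126` — entropy-value curves,
   group comparisons and crossover detection.
2. `N = 110·x`, `x ∈ 1..10`, under `r = r_Chon` and `r = 0.2σ` — p-value
   versus data length.  Thresholds are recomputed on each cropped segment
   (r_Chon depends on `N` explicitly).
3. FuzzyEn weight `n ∈ [1, 6]` at `N = 1000`, both threshold modes.
4. FuzzyMEn weights `(n_L, n_F) ∈ [1, 6]²` at `N = 1000`, both modes.
5. FuzzyMEn thresholds `(r_L, r_F)` over `[0.25, 6]·r_Chon` with
   `n_L = 2, n_F = 1`, and over `[0.1, 0.25]·σ` with `n_L = 1, n_F = 3` —
   the weight pairs that perform best per threshold family in case 4.

Grid defaults are the study conditions above; every grid is overridable in
the plan config.  Rows are independent and emitted in plan order;
per-group curves use means (medians are also emitted) and tests use the
full samples.

**Crossover convention.**  A crossover is a strict sign change of the
group-mean difference between adjacent grid points.  A grid point where the
difference is exactly zero is a touch point; when flanked by opposite signs
it counts as one crossing at that point.  Exact zeros essentially only
arise for identical cohorts, but the rule must be total to be testable.

## Synthetic study presets

The generators are pure functions of (parameters, seed); per-record streams
derive from the global seed by a fixed (cohort, record) counter, so records
are stable under reordering and subsetting.

* **RRI model** — mean interval 0.8 s modulated by a respiratory sine
  (0.25 Hz), a low-frequency sine (0.1 Hz, random phase per record) and
  Gaussian beat noise, with beat times accumulating the generated
  intervals.  Defaults give per-record σ in the physiological 0.02–0.05 s
  range.
* **`separated`** — healthy-like (resp 0.03 s, LF 0.02 s, noise 0.03 s;
  noise ≈ 58 % of variance) versus pathological-like (resp 0.025 s, LF
  0.015 s, noise 0.01 s; noise ≈ 19 %).  Because thresholds are σ-relative,
  cohorts must differ in their noise-to-modulation *ratio* to differ in
  entropy — a pure amplitude rescaling is invisible to every estimator.
  The group-σ ratio is ≈ 2:1 (0.039 vs 0.023 s) and all four estimators
  separate the groups decisively at `N = 1000`, 30 records/group.
* **`null`** — both cohorts from the healthy-like parameters; downstream
  significance rates calibrate to α.
* **`flipflop`** — MIX(p) signals (unit-variance sine with a fraction `p`
  of samples replaced by iid uniform noise) mapped to the RRI range as
  `0.8 + 0.04·x`.  Within the standard threshold window the mean ApEn of
  MIX(p) is monotone in `p` at every grid point, so no pure-`p` pair
  crosses there; cohorts with different sine *periods* do cross.  The
  frozen preset is MIX(0.1, period 12) versus MIX(0.1, period 100): the
  fast sine's quantised template-distance spectrum makes its ApEn jump near
  `r ≈ 0.19σ`, reversing the cohort ordering between 0.175σ and 0.2σ,
  robustly across seeds, while FuzzyEn's curves move smoothly (adjacent-
  point jumps ≤ 0.1 on the 0.025σ grid).

What these presets do **not** show: real RR series are nonstationary, have
ectopic beats and spikes, autonomic trends, and age/sex structure.  Passing
the synthetic suite demonstrates the estimators, thresholds, statistics and
sweep machinery are correct and calibrated — not that any particular
clinical separation will hold on recorded data.

## Numerical choices

* Distances and memberships in double precision; memberships are strictly
  positive so no flooring of `φ` is needed for the fuzzy variants.
* Numerically constant signals (rounding noise only: spread below
  10⁻¹² of scale) are treated as zero-variance for threshold purposes.
* Lilliefors null tables are seeded deterministically per sample size;
  p-values use the +1/(n+1) guard so p > 0.
* Result CSVs are written with `%.12g` floats and sorted provenance
  headers, making seeded runs byte-identical.

## Problem sizes in the test suite

The suite exercises the stated study conditions where they are cheap
(N = 1126/1000 for power and flip-flop checks, 2000 null replicates for
type-I calibration) and reduced sizes where the full design adds nothing to
the property under test (shape/determinism contracts run on 6–8 records of
N = 300; null-preset calibration uses 200 seeds of 10 records at N = 200).
Oracle-equivalence checks use 50 random signals of N ∈ [30, 200] against
literal double-loop transcriptions of the defining formulas.

## Known limitations

* `r_Chon` is implemented for `m = 2` only (the formula is specific to it);
  other `m` are supported everywhere else but not studied.
* Multiscale and cross-entropy variants, alternative membership functions,
  and the entropy-maximising `r` search are out of scope.
* The Wilcoxon exact branch refuses ties by falling back to the asymptotic
  approximation; for tiny heavily-tied samples this is a compromise.
* Sweep rows are computed sequentially; the row structure is
  embarrassingly parallel if a future need arises.
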