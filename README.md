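# hrventropy

Entropy-based regularity analysis for heart rate variability (HRV) data.

Heart rate variability — the beat-to-beat variation of RR intervals — is
routinely summarised by entropy statistics that quantify how *regular* a
recording is: a failing regulatory system tends to produce a more regular
(lower-entropy) heart rhythm.  In practice these statistics are controlled by
several interacting parameters (template length `m`, similarity threshold
`r`, fuzzy weights `n`), and conclusions can reverse when the parameters
change.  `hrventropy` is a toolkit for studying exactly that: it implements
the four standard estimators, the common threshold-selection rules, the
preprocessing conventions for RR-interval records, a normality-gated
two-group significance procedure, and a sweep engine that maps out how group
separation depends on each parameter — including detection of the
*flip-flop effect*, where the ordering of two cohorts' entropies reverses as
the threshold `r` varies.

Intended users: researchers analysing RR-interval cohorts (e.g. healthy vs
cardiac-disease groups) who need reproducible, parameter-transparent entropy
pipelines, and methodologists studying the estimators themselves.

## The estimators

For a sequence `{u_1, ..., u_N}`, templates `X_i^m = {u_i, ..., u_{i+m-1}}`
are compared under the Chebyshev distance `d(X_i, X_j) = max_k |u_{i+k} - u_{j+k}|`.

* **ApEn(m, r, N) = φ^m − φ^{m+1}**, where
  `φ^m = (N−m+1)^{-1} Σ_i ln(C_i^m / (N−m+1))` and `C_i^m` counts templates
  with `d < r` (self-matches included).
* **SampEn(m, r, N) = ln φ^m − ln φ^{m+1}**, counting without self-matches
  over the first `N−m` templates at both lengths (denominator `N−m−1`);
  undefined (typed error) when no matches exist.
* **FuzzyEn(m, r, n, N)**: the same log-ratio with the hard indicator
  replaced by the membership `μ(d, n, r) = exp(−(d/r)^n)` applied to
  baseline-removed templates (each template minus its own mean).
* **FuzzyMEn(m, r_L, r_F, n_L, n_F, N)**: FuzzyEn's local term plus a global
  term computed on templates with the whole-signal mean removed, graded by a
  second `(r_F, n_F)` pair.

Thresholds are resolved per record: `r = k·σ` (sample standard deviation of
the analysed segment, conventional range `k ∈ [0.1, 0.25]`) or the empirical
entropy-maximising approximation
`r_Chon = (−0.036 + 0.26·√(σ₁/σ₂)) / (N/1000)^{1/4}` for `m = 2`, with `σ₁`
the standard deviation of successive differences and `σ₂` that of the
sequence.

Group comparisons screen each sample with Lilliefors' normality test
(Monte-Carlo null tables); unanimously normal subsets use a two-sample
t-test, anything else the Wilcoxon rank-sum test, with one test enforced
per sweep subset.  No multiple-testing correction is applied (the endpoints
are deliberately correlated variations of one method).

## Worked example

Two synthetic cohorts (10 records each, cropped to N = 1000): a noisy,
strongly modulated "healthy-like" group `a` and a more regular
"pathological-like" group `b`.  Sweep the threshold `r = k·σ` and compare
groups at each point:

```python
from hrventropy import make_study_fixture, run_test_case_1

a, b = make_study_fixture("separated", seed=1, n_records=10, record_length=1200)
result, reports = run_test_case_1(
    a, b, r_coeffs=(0.10, 0.15, 0.20, 0.25), n_length=1000,
    estimators=("sampen", "fuzzyen"), seed=1,
)
print(result.rows[["estimator", "r_coeff", "mean_a", "mean_b", "test_used", "p_value"]])
```

```
estimator  r_coeff   mean_a   mean_b test_used      p_value
   sampen     0.10 2.909781 2.584905    t_test 3.710595e-07
   sampen     0.15 2.454972 2.188487    t_test 1.744949e-10
   sampen     0.20 2.173666 1.900959    t_test 4.160246e-14
   sampen     0.25 1.946718 1.694800    t_test 1.266852e-14
  fuzzyen     0.10 2.965879 2.873516    t_test 4.372157e-07
  fuzzyen     0.15 2.557700 2.475263    t_test 5.406966e-08
  fuzzyen     0.20 2.269833 2.191400    t_test 1.070525e-08
  fuzzyen     0.25 2.047685 1.972473    t_test 4.431314e-09
```

The noisier cohort has the higher entropy at every threshold (no flip-flop
here: `reports["sampen"].crossings` is empty), both samples pass the
normality screen (`t_test`), and the separation is significant at every grid
point.  On the `"flipflop"` preset the same sweep shows the ApEn group-mean
curves crossing near `r ≈ 0.19σ` while the fuzzy estimators vary smoothly.

The same pipeline is available from the shell:

```bash
hrventropy synth --preset separated --seed 1 --out fixture/
hrventropy sweep --plan plan.yaml --manifest fixture/manifest.yaml --out results/ --seed 1
hrventropy entropy fixture/np-like-000.txt --estimators sampen,fuzzyen --threshold chon
```

where `plan.yaml` contains, e.g., `test_case: 1` plus optional grid
overrides.  Output CSVs carry seed, plan hash and version as comment
headers and are byte-identical across reruns.

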