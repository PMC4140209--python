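"""Two-group significance procedure with a normality gate.

Per-record entropy values for two cohorts are compared as follows: each
group's sample is first screened with Lilliefors' composite goodness-of-fit
test for normality (a Kolmogorov–Smirnov test against a normal law with
estimated mean and variance).  If neither group rejects normality the groups
are compared with a two-sample t-test; otherwise with a two-sided Wilcoxon
rank-sum (Mann–Whitney) test.  No multiple-testing correction is applied
anywhere: the comparisons in a sweep share the null hypothesis, the subjects
and the endpoint, so Bonferroni-style adjustments assuming independent
endpoints would be inappropriate — the goal is to compare the *methods'*
ability to detect a difference, not to confirm the difference itself.

Within one declared subset of a sweep (one cohort pair and one threshold
mode) the *same* test must be used for every comparison so that p-values are
comparable across the parameter grid; :func:`enforce_uniform_test` recomputes
a subset with the rank-sum test unless every comparison was unanimously
normal.

Lilliefors p-values come from a Monte-Carlo table of the null distribution
of the statistic (simulated standard-normal samples, 10 000 replicates by
default, cached per sample size), which avoids interpolation in small
printed tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSampleError, InsufficientSampleError, InvalidInputError

__all__ = [
    "GroupSample",
    "LillieforsResult",
    "ComparisonResult",
    "lilliefors_statistic",
    "lilliefors",
    "compare_groups",
    "enforce_uniform_test",
]

#: Replicates used to build each cached Monte-Carlo null table.
DEFAULT_NULL_REPLICATES = 10_000

# null tables keyed by (sample size, replicates): sorted statistics
_NULL_TABLES: dict[tuple[int, int], np.ndarray] = {}


@dataclass(frozen=True)
class GroupSample:
    """One cohort's entropy values; NaN marks records whose entropy was undefined."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise InvalidInputError("group values must be one-dimensional")
        object.__setattr__(self, "values", arr)

    @property
    def clean(self) -> np.ndarray:
        """Values with missing entries dropped."""
        return self.values[np.isfinite(self.values)]


@dataclass(frozen=True)
class LillieforsResult:
    statistic: float
    p_value: float
    rejected: bool


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-group comparison."""

    p_value: float
    test_used: str                      # "t_test" | "wilcoxon"
    normality: dict                     # label -> LillieforsResult | None
    n_used: dict                        # label -> count after dropping missing
    significant: bool
    alpha: float
    a: GroupSample
    b: GroupSample
    subset_id: str | None = None


def lilliefors_statistic(values) -> float:
    """Kolmogorov–Smirnov statistic against N(mean, s^2) estimated from the data."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise InsufficientSampleError(f"need at least 4 values for Lilliefors, got {n}")
    s = x.std(ddof=1)
    if x[-1] == x[0] or s == 0:        # sorted, so a constant sample is flat
        raise DegenerateSampleError("constant sample: normality test undefined")
    z = (x - x.mean()) / s
    cdf = sps.norm.cdf(z)
    steps = np.arange(1, n + 1) / n
    d_plus = np.max(steps - cdf)
    d_minus = np.max(cdf - (steps - 1.0 / n))
    return float(max(d_plus, d_minus))


def _null_table(n: int, n_sim: int) -> np.ndarray:
    key = (n, n_sim)
    if key not in _NULL_TABLES:
        # fixed seed per (n, n_sim): the table is a deterministic object
        rng = np.random.default_rng(np.random.SeedSequence(entropy=1851936, spawn_key=(n, n_sim)))
        samples = rng.standard_normal((n_sim, n))
        samples.sort(axis=1)
        means = samples.mean(axis=1, keepdims=True)
        sds = samples.std(axis=1, ddof=1, keepdims=True)
        cdf = sps.norm.cdf((samples - means) / sds)
        steps = np.arange(1, n + 1) / n
        d_plus = np.max(steps - cdf, axis=1)
        d_minus = np.max(cdf - (steps - 1.0 / n), axis=1)
        _NULL_TABLES[key] = np.sort(np.maximum(d_plus, d_minus))
    return _NULL_TABLES[key]


def lilliefors(
    values,
    alpha: float = 0.05,
    n_sim: int = DEFAULT_NULL_REPLICATES,
) -> LillieforsResult:
    """Lilliefors normality test with Monte-Carlo p-values.

    The p-value is ``(1 + #{null >= observed}) / (1 + n_sim)`` against a
    cached simulated null for this sample size; the +1 guard keeps p > 0.
    """
    stat = lilliefors_statistic(values)
    n = np.asarray(values).size
    null = _null_table(n, n_sim)
    exceed = null.size - int(np.searchsorted(null, stat, side="left"))
    p = (1 + exceed) / (1 + null.size)
    return LillieforsResult(statistic=stat, p_value=float(p), rejected=bool(p < alpha))


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small groups without ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    small = min(x.size, y.size) < 10
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True, method=method)
    return float(res.pvalue)


def compare_groups(
    a: GroupSample,
    b: GroupSample,
    alpha: float = 0.05,
    welch: bool = False,
    force_test: str | None = None,
    subset_id: str | None = None,
) -> ComparisonResult:
    """Compare two groups of entropy values with the normality-gated procedure.

    Missing values (undefined entropies) are dropped per group and the counts
    recorded.  Groups of fewer than 4 clean values cannot be screened for
    normality and are routed to the rank-sum branch.  ``force_test`` bypasses
    the gate (used to keep one test across a sweep subset).
    """
    xa, xb = a.clean, b.clean
    if xa.size < 3 or xb.size < 3:
        raise InsufficientSampleError(
            f"need >= 3 non-missing values per group, got {xa.size} and {xb.size}"
        )
    normality: dict = {a.label: None, b.label: None}
    if force_test is None:
        any_reject = False
        for label, x in ((a.label, xa), (b.label, xb)):
            try:
                res = lilliefors(x, alpha=alpha)
            except (InsufficientSampleError, DegenerateSampleError):
                res = None
                any_reject = True          # cannot certify normality
            normality[label] = res
            if res is not None and res.rejected:
                any_reject = True
        test_used = "wilcoxon" if any_reject else "t_test"
    else:
        if force_test not in ("t_test", "wilcoxon"):
            raise InvalidInputError(f"unknown test {force_test!r}")
        test_used = force_test
    if test_used == "t_test":
        p = float(sps.ttest_ind(xa, xb, equal_var=not welch).pvalue)
    else:
        p = _rank_sum_test(xa, xb)
    return ComparisonResult(
        p_value=p,
        test_used=test_used,
        normality=normality,
        n_used={a.label: int(xa.size), b.label: int(xb.size)},
        significant=bool(p < alpha),
        alpha=alpha,
        a=a,
        b=b,
        subset_id=subset_id,
    )


def enforce_uniform_test(
    results: list[ComparisonResult], subset_id: str | None = None
) -> list[ComparisonResult]:
    """Make one subset of comparisons use a single statistical test.

    If any comparison in the subset fell back to the rank-sum test, every
    comparison is recomputed with it; the t-test is kept only when the subset
    was unanimously normal.
    """
    if not results:
        return []
    if all(r.test_used == "t_test" for r in results):
        return list(results)
    out = []
    for r in results:
        if r.test_used == "wilcoxon":
            out.append(r if subset_id is None else dataclasses.replace(r, subset_id=subset_id))
        else:
            redone = compare_groups(
                r.a, r.b, alpha=r.alpha, force_test="wilcoxon",
                subset_id=subset_id if subset_id is not None else r.subset_id,
            )
            # keep the original normality diagnostics for the record
            out.append(dataclasses.replace(redone, normality=r.normality))
    return out
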