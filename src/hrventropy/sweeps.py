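"""Parameter-sweep study engine for two-cohort entropy comparisons.

Five canonical test cases probe how the entropy estimators' ability to
separate two cohorts depends on their parameters:

1. threshold ``r = r_L = r_F`` swept over the standard interval
   [0.1*sigma, 0.25*sigma] at fixed ``m = 2``, ``n = n_L = 3``, ``n_F = 2``,
   record length 1126 — including detection of group-mean *crossovers* (the
   flip-flop effect: which cohort has the higher entropy reverses with r);
2. record length ``N = 110 * x``, x in 1..10, under ``r = r_chon`` and
   ``r = 0.2*sigma``;
3. FuzzyEn weight ``n`` in [1, 6] at ``N = 1000``;
4. FuzzyMEn weights ``(n_L, n_F)`` in [1, 6]^2 at ``N = 1000``;
5. FuzzyMEn thresholds ``(r_L, r_F)`` over [0.25, 6] multiples of r_chon
   (with ``n_L = 2, n_F = 1``) and over [0.1*sigma, 0.25*sigma] (with
   ``n_L = 1, n_F = 3``), at ``N = 1000``.

Thresholds are resolved *per record* on the cropped segment entering the
entropy computation.  Within each subset (one cohort pair and one threshold
mode of one test case) the normality-gated comparison is forced to a single
statistical test via :func:`hrventropy.stats.enforce_uniform_test`.

Results are tidy tables (one row per estimator x grid point x pair) carrying
provenance (plan hash, seed, package version) as CSV comment headers, so a
seeded run is byte-for-byte reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .entropy import ESTIMATORS, EntropyEngine
from .errors import (
    DegenerateThresholdError,
    InvalidInputError,
    PlanError,
    UndefinedEntropyError,
)
from .preprocessing import Cohort, crop_center, prepare_cohorts
from .stats import GroupSample, compare_groups, enforce_uniform_test
from .thresholds import ThresholdSpec, resolve

__all__ = [
    "SweepResult",
    "Crossing",
    "CrossoverReport",
    "SweepPlan",
    "detect_crossovers",
    "run_test_case_1",
    "run_test_case_2",
    "run_test_case_3",
    "run_test_case_4",
    "run_test_case_5",
    "run_plan",
]

_CSV_FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class SweepResult:
    """Tidy sweep table plus provenance (plan, seed, version)."""

    rows: pd.DataFrame
    provenance: dict

    def to_csv(self, path) -> None:
        """Write the table with provenance comment lines; byte-reproducible."""
        with open(path, "w", newline="") as fh:
            for key in sorted(self.provenance):
                fh.write(f"# {key}: {self.provenance[key]}\n")
            self.rows.to_csv(fh, index=False, float_format=_CSV_FLOAT_FORMAT, lineterminator="\n")


@dataclass(frozen=True)
class Crossing:
    """One sign change of the group-mean difference curve.

    ``kind`` is ``"interval"`` for a change between adjacent grid points with
    strictly opposite signs, or ``"zero"`` when the change passes through a
    grid point where the difference is exactly zero.
    """

    left_r: float
    right_r: float
    kind: str


@dataclass(frozen=True)
class CrossoverReport:
    """Crossovers of two group-mean entropy curves over a threshold grid."""

    estimator: str
    r_values: np.ndarray
    diff: np.ndarray                 # mean_a - mean_b per grid point
    crossings: tuple[Crossing, ...]
    touch_points: tuple[float, ...]  # r values where the difference is exactly 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"estimator": self.estimator, "kind": c.kind, "left_r": c.left_r, "right_r": c.right_r}
                for c in self.crossings
            ],
            columns=["estimator", "kind", "left_r", "right_r"],
        )


def detect_crossovers(r_values, mean_a, mean_b, estimator: str = "") -> CrossoverReport:
    """Locate sign changes of ``mean_a - mean_b`` along a common grid.

    A crossing is reported for each pair of adjacent grid points with
    strictly opposite signs, and for each zero of the difference flanked by
    opposite signs (counted once, at that grid point).  Zeros not flanked by
    opposite signs are touch points, not crossings.
    """
    r = np.asarray(r_values, dtype=float)
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if r.shape != a.shape or r.shape != b.shape:
        raise InvalidInputError("curves and grid must have identical shapes")
    if r.size < 2:
        return CrossoverReport(estimator, r, a - b, (), tuple(r[(a - b) == 0]))
    diff = a - b
    signs = np.sign(diff)
    touch = tuple(float(rv) for rv in r[signs == 0])
    crossings: list[Crossing] = []
    nz = np.flatnonzero(signs)
    for p, q in zip(nz[:-1], nz[1:]):
        if signs[p] * signs[q] < 0:
            if q == p + 1:
                crossings.append(Crossing(float(r[p]), float(r[q]), "interval"))
            else:
                # opposite signs separated by an exact-zero run: one crossing
                # attributed to the zero grid point(s)
                crossings.append(Crossing(float(r[p + 1]), float(r[q - 1]), "zero"))
    return CrossoverReport(estimator, r, diff, tuple(crossings), touch)


# ---------------------------------------------------------------------------
# shared machinery


def _build_engines(cohort: Cohort, m: int) -> dict[str, EntropyEngine]:
    return {rec.id: EntropyEngine(rec.intervals, m) for rec in cohort.records}


def _cohort_values(
    cohort: Cohort,
    engines: dict[str, EntropyEngine],
    estimator: str,
    spec_L: ThresholdSpec,
    spec_F: ThresholdSpec | None = None,
    n: float = 3.0,
    n_L: float = 3.0,
    n_F: float = 2.0,
) -> np.ndarray:
    """Per-record entropies; NaN where the threshold degenerates or SampEn is undefined."""
    if estimator not in ESTIMATORS:
        raise InvalidInputError(f"unknown estimator {estimator!r}")
    out = np.full(len(cohort), np.nan)
    for idx, rec in enumerate(cohort.records):
        eng = engines[rec.id]
        try:
            r_l = resolve(spec_L, rec.intervals)
            if estimator == "apen":
                out[idx] = eng.apen(r_l)
            elif estimator == "sampen":
                out[idx] = eng.sampen(r_l)
            elif estimator == "fuzzyen":
                out[idx] = eng.fuzzyen(r_l, n)
            else:
                r_f = resolve(spec_F if spec_F is not None else spec_L, rec.intervals)
                out[idx] = eng.fuzzymen(r_l, r_f, n_L, n_F)
        except (DegenerateThresholdError, UndefinedEntropyError):
            out[idx] = np.nan
    return out


def _prepare_pair(cohort_a: Cohort, cohort_b: Cohort, n: int):
    prepared, rejections = prepare_cohorts([cohort_a, cohort_b], n)
    if len(prepared) != 2:
        raise InvalidInputError("a cohort lost all records during preparation")
    return prepared[0], prepared[1], rejections


def _summary_columns(label_a, vals_a, label_b, vals_b, comparison):
    return {
        "pair": f"{label_a}|{label_b}",
        "mean_a": float(np.nanmean(vals_a)) if np.any(np.isfinite(vals_a)) else np.nan,
        "mean_b": float(np.nanmean(vals_b)) if np.any(np.isfinite(vals_b)) else np.nan,
        "median_a": float(np.nanmedian(vals_a)) if np.any(np.isfinite(vals_a)) else np.nan,
        "median_b": float(np.nanmedian(vals_b)) if np.any(np.isfinite(vals_b)) else np.nan,
        "n_a": comparison.n_used[label_a],
        "n_b": comparison.n_used[label_b],
        "n_missing_a": int(np.count_nonzero(~np.isfinite(vals_a))),
        "n_missing_b": int(np.count_nonzero(~np.isfinite(vals_b))),
        "test_used": comparison.test_used,
        "p_value": comparison.p_value,
        "significant": comparison.significant,
    }


def _apply_uniform_test(entries: list[dict], alpha: float) -> list[dict]:
    """Group row entries by subset and force one statistical test per subset.

    ``entries`` pair a mutable row dict with the ComparisonResult that
    produced it; rows are updated in place and returned in original order.
    """
    by_subset: dict[str, list[dict]] = {}
    for e in entries:
        by_subset.setdefault(e["row"]["subset_id"], []).append(e)
    for subset_id, members in by_subset.items():
        uniform = enforce_uniform_test([m["comparison"] for m in members], subset_id)
        for member, comp in zip(members, uniform):
            member["row"]["test_used"] = comp.test_used
            member["row"]["p_value"] = comp.p_value
            member["row"]["significant"] = comp.significant
    return [e["row"] for e in entries]


def _result(rows: list[dict], provenance: dict) -> SweepResult:
    return SweepResult(rows=pd.DataFrame(rows), provenance=provenance)


def _provenance(test_case: int, seed: int | None, extra: dict | None = None) -> dict:
    prov = {"test_case": test_case, "seed": seed, "version": __version__}
    if extra:
        prov.update(extra)
    return prov


# ---------------------------------------------------------------------------
# test cases


def run_test_case_1(
    cohort_a: Cohort,
    cohort_b: Cohort,
    r_coeffs=(0.10, 0.125, 0.15, 0.175, 0.20, 0.225, 0.25),
    n_length: int = 1126,
    m: int = 2,
    n: float = 3.0,
    n_L: float = 3.0,
    n_F: float = 2.0,
    alpha: float = 0.05,
    estimators=ESTIMATORS,
    seed: int | None = None,
) -> tuple[SweepResult, dict[str, CrossoverReport]]:
    """Threshold sweep ``r = r_L = r_F = k * sigma`` over the standard interval.

    Returns the sweep table and, per estimator, a crossover report of the
    two group-mean entropy curves (the flip-flop diagnostic).
    """
    r_coeffs = [float(k) for k in r_coeffs]
    if not r_coeffs or any(k <= 0 for k in r_coeffs):
        raise PlanError("r_coeffs must be non-empty and positive")
    a, b, rejections = _prepare_pair(cohort_a, cohort_b, n_length)
    eng_a, eng_b = _build_engines(a, m), _build_engines(b, m)
    entries: list[dict] = []
    curves: dict[str, dict[str, list[float]]] = {
        est: {"a": [], "b": []} for est in estimators
    }
    for est in estimators:
        for k in r_coeffs:
            spec = ThresholdSpec("sigma_multiple", k)
            vals_a = _cohort_values(a, eng_a, est, spec, n=n, n_L=n_L, n_F=n_F)
            vals_b = _cohort_values(b, eng_b, est, spec, n=n, n_L=n_L, n_F=n_F)
            subset_id = f"tc1|{a.label}|{b.label}|sigma"
            comp = compare_groups(
                GroupSample(a.label, vals_a), GroupSample(b.label, vals_b),
                alpha=alpha, subset_id=subset_id,
            )
            row = {
                "test_case": 1, "estimator": est, "r_mode": "sigma",
                "r_coeff": k, "N": n_length, "subset_id": subset_id,
                **_summary_columns(a.label, vals_a, b.label, vals_b, comp),
            }
            entries.append({"row": row, "comparison": comp})
            curves[est]["a"].append(float(np.nanmean(vals_a)))
            curves[est]["b"].append(float(np.nanmean(vals_b)))
    rows = _apply_uniform_test(entries, alpha)
    reports = {
        est: detect_crossovers(r_coeffs, curves[est]["a"], curves[est]["b"], est)
        for est in estimators
    }
    prov = _provenance(1, seed, {"n_rejections": len(rejections)})
    return _result(rows, prov), reports


def run_test_case_2(
    cohort_a: Cohort,
    cohort_b: Cohort,
    n_grid=tuple(110 * x for x in range(1, 11)),
    r_modes=(ThresholdSpec("chon"), ThresholdSpec("sigma_multiple", 0.2)),
    m: int = 2,
    n: float = 3.0,
    n_L: float = 3.0,
    n_F: float = 2.0,
    alpha: float = 0.05,
    estimators=ESTIMATORS,
    seed: int | None = None,
) -> SweepResult:
    """Data-length sweep: recrop records to each N, recompute thresholds per
    cropped segment, and track the p-value versus N for each threshold mode."""
    n_grid = sorted(int(x) for x in n_grid)
    if not n_grid or n_grid[0] < m + 2:
        raise PlanError(f"n_grid must contain lengths >= m + 2, got {n_grid}")
    a0, b0, rejections = _prepare_pair(cohort_a, cohort_b, max(n_grid))
    entries: list[dict] = []
    for n_len in n_grid:
        a = Cohort(a0.label, tuple(crop_center(r, n_len) for r in a0.records))
        b = Cohort(b0.label, tuple(crop_center(r, n_len) for r in b0.records))
        eng_a, eng_b = _build_engines(a, m), _build_engines(b, m)
        for spec in r_modes:
            for est in estimators:
                vals_a = _cohort_values(a, eng_a, est, spec, n=n, n_L=n_L, n_F=n_F)
                vals_b = _cohort_values(b, eng_b, est, spec, n=n, n_L=n_L, n_F=n_F)
                subset_id = f"tc2|{a.label}|{b.label}|{spec.label()}"
                comp = compare_groups(
                    GroupSample(a.label, vals_a), GroupSample(b.label, vals_b),
                    alpha=alpha, subset_id=subset_id,
                )
                row = {
                    "test_case": 2, "estimator": est, "r_mode": spec.label(),
                    "N": n_len, "subset_id": subset_id,
                    **_summary_columns(a.label, vals_a, b.label, vals_b, comp),
                }
                entries.append({"row": row, "comparison": comp})
    rows = _apply_uniform_test(entries, alpha)
    return _result(rows, _provenance(2, seed, {"n_rejections": len(rejections)}))


def run_test_case_3(
    cohort_a: Cohort,
    cohort_b: Cohort,
    n_grid=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    r_modes=(ThresholdSpec("chon"), ThresholdSpec("sigma_multiple", 0.2)),
    n_length: int = 1000,
    m: int = 2,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SweepResult:
    """FuzzyEn weight sweep: p-value versus the membership exponent ``n``."""
    n_grid = [float(v) for v in n_grid]
    if not n_grid or any(v <= 0 for v in n_grid):
        raise PlanError("weight grid must be non-empty and positive")
    a, b, rejections = _prepare_pair(cohort_a, cohort_b, n_length)
    eng_a, eng_b = _build_engines(a, m), _build_engines(b, m)
    entries: list[dict] = []
    for spec in r_modes:
        for n_val in n_grid:
            vals_a = _cohort_values(a, eng_a, "fuzzyen", spec, n=n_val)
            vals_b = _cohort_values(b, eng_b, "fuzzyen", spec, n=n_val)
            subset_id = f"tc3|{a.label}|{b.label}|{spec.label()}"
            comp = compare_groups(
                GroupSample(a.label, vals_a), GroupSample(b.label, vals_b),
                alpha=alpha, subset_id=subset_id,
            )
            row = {
                "test_case": 3, "estimator": "fuzzyen", "r_mode": spec.label(),
                "n": n_val, "N": n_length, "subset_id": subset_id,
                **_summary_columns(a.label, vals_a, b.label, vals_b, comp),
            }
            entries.append({"row": row, "comparison": comp})
    rows = _apply_uniform_test(entries, alpha)
    return _result(rows, _provenance(3, seed, {"n_rejections": len(rejections)}))


def run_test_case_4(
    cohort_a: Cohort,
    cohort_b: Cohort,
    nl_grid=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    nf_grid=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    r_modes=(ThresholdSpec("chon"), ThresholdSpec("sigma_multiple", 0.2)),
    n_length: int = 1000,
    m: int = 2,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SweepResult:
    """FuzzyMEn weight sweep: p-value surface over the ``(n_L, n_F)`` grid."""
    nl_grid = [float(v) for v in nl_grid]
    nf_grid = [float(v) for v in nf_grid]
    if not nl_grid or not nf_grid or any(v <= 0 for v in nl_grid + nf_grid):
        raise PlanError("weight grids must be non-empty and positive")
    a, b, rejections = _prepare_pair(cohort_a, cohort_b, n_length)
    eng_a, eng_b = _build_engines(a, m), _build_engines(b, m)
    entries: list[dict] = []
    for spec in r_modes:
        for n_l in nl_grid:
            for n_f in nf_grid:
                vals_a = _cohort_values(a, eng_a, "fuzzymen", spec, n_L=n_l, n_F=n_f)
                vals_b = _cohort_values(b, eng_b, "fuzzymen", spec, n_L=n_l, n_F=n_f)
                subset_id = f"tc4|{a.label}|{b.label}|{spec.label()}"
                comp = compare_groups(
                    GroupSample(a.label, vals_a), GroupSample(b.label, vals_b),
                    alpha=alpha, subset_id=subset_id,
                )
                row = {
                    "test_case": 4, "estimator": "fuzzymen", "r_mode": spec.label(),
                    "n_L": n_l, "n_F": n_f, "N": n_length, "subset_id": subset_id,
                    **_summary_columns(a.label, vals_a, b.label, vals_b, comp),
                }
                entries.append({"row": row, "comparison": comp})
    rows = _apply_uniform_test(entries, alpha)
    return _result(rows, _provenance(4, seed, {"n_rejections": len(rejections)}))


def run_test_case_5(
    cohort_a: Cohort,
    cohort_b: Cohort,
    chon_multiples=tuple(np.round(np.linspace(0.25, 6.0, 8), 6)),
    sigma_multiples=tuple(np.round(np.linspace(0.10, 0.25, 8), 6)),
    chon_weights=(2.0, 1.0),
    sigma_weights=(1.0, 3.0),
    n_length: int = 1000,
    m: int = 2,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SweepResult:
    """FuzzyMEn threshold sweep: p-value surface over ``(r_L, r_F)`` grids.

    Two grids are run: multiples of r_chon (weights ``n_L = 2, n_F = 1``) and
    multiples of sigma (weights ``n_L = 1, n_F = 3``), the weight choices that
    perform best for each threshold family in the weight sweep.
    """
    grids = [
        ("chon", [float(v) for v in chon_multiples], "chon_multiple", chon_weights),
        ("sigma", [float(v) for v in sigma_multiples], "sigma_multiple", sigma_weights),
    ]
    for name, vals, _, weights in grids:
        if not vals or any(v <= 0 for v in vals):
            raise PlanError(f"{name} grid must be non-empty and positive")
        if len(weights) != 2 or any(w <= 0 for w in weights):
            raise PlanError(f"{name} weights must be a positive (n_L, n_F) pair")
    a, b, rejections = _prepare_pair(cohort_a, cohort_b, n_length)
    eng_a, eng_b = _build_engines(a, m), _build_engines(b, m)
    entries: list[dict] = []
    for mode_label, vals, spec_mode, (n_l, n_f) in grids:
        for c_l in vals:
            for c_f in vals:
                spec_l = ThresholdSpec(spec_mode, c_l)
                spec_f = ThresholdSpec(spec_mode, c_f)
                vals_a = _cohort_values(a, eng_a, "fuzzymen", spec_l, spec_F=spec_f, n_L=n_l, n_F=n_f)
                vals_b = _cohort_values(b, eng_b, "fuzzymen", spec_l, spec_F=spec_f, n_L=n_l, n_F=n_f)
                subset_id = f"tc5|{a.label}|{b.label}|{mode_label}"
                comp = compare_groups(
                    GroupSample(a.label, vals_a), GroupSample(b.label, vals_b),
                    alpha=alpha, subset_id=subset_id,
                )
                row = {
                    "test_case": 5, "estimator": "fuzzymen", "r_mode": mode_label,
                    "rL_coeff": c_l, "rF_coeff": c_f, "n_L": n_l, "n_F": n_f,
                    "N": n_length, "subset_id": subset_id,
                    **_summary_columns(a.label, vals_a, b.label, vals_b, comp),
                }
                entries.append({"row": row, "comparison": comp})
    rows = _apply_uniform_test(entries, alpha)
    return _result(rows, _provenance(5, seed, {"n_rejections": len(rejections)}))


# ---------------------------------------------------------------------------
# plan plumbing (config-file driven runs)

_PLAN_KEYS = {
    1: {"r_coeffs", "n_length", "m", "n", "n_L", "n_F", "estimators"},
    2: {"n_grid", "r_modes", "m", "n", "n_L", "n_F", "estimators"},
    3: {"n_grid", "r_modes", "n_length", "m"},
    4: {"nl_grid", "nf_grid", "r_modes", "n_length", "m"},
    5: {"chon_multiples", "sigma_multiples", "chon_weights", "sigma_weights", "n_length", "m"},
}


@dataclass(frozen=True)
class SweepPlan:
    """Validated description of one sweep run, loadable from YAML/JSON."""

    test_case: int
    options: dict = field(default_factory=dict)
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, raw: dict) -> "SweepPlan":
        errors = []
        if not isinstance(raw, dict):
            raise PlanError("plan must be a mapping")
        tc = raw.get("test_case")
        if tc not in (1, 2, 3, 4, 5):
            errors.append(f"test_case must be 1..5, got {tc!r}")
        alpha = raw.get("alpha", 0.05)
        if not (0 < alpha < 1):
            errors.append(f"alpha must be in (0, 1), got {alpha!r}")
        options = {k: v for k, v in raw.items() if k not in ("test_case", "alpha")}
        if tc in _PLAN_KEYS:
            unknown = set(options) - _PLAN_KEYS[tc]
            if unknown:
                errors.append(f"unknown plan keys for test case {tc}: {sorted(unknown)}")
        if errors:
            raise PlanError("; ".join(errors))
        if "r_modes" in options:
            options = dict(options)
            options["r_modes"] = tuple(ThresholdSpec.parse(s) for s in options["r_modes"])
        return cls(test_case=tc, options=options, alpha=float(alpha))

    def hash(self) -> str:
        canon = {"test_case": self.test_case, "alpha": self.alpha,
                 "options": {k: str(v) for k, v in sorted(self.options.items())}}
        return hashlib.sha256(json.dumps(canon, sort_keys=True).encode()).hexdigest()[:16]


_RUNNERS = {
    1: run_test_case_1,
    2: run_test_case_2,
    3: run_test_case_3,
    4: run_test_case_4,
    5: run_test_case_5,
}


def run_plan(
    plan: SweepPlan,
    cohort_a: Cohort,
    cohort_b: Cohort,
    seed: int | None = None,
) -> tuple[SweepResult, dict[str, CrossoverReport] | None]:
    """Execute a validated plan; returns the sweep result and, for test case
    1, the per-estimator crossover reports."""
    runner = _RUNNERS[plan.test_case]
    out = runner(cohort_a, cohort_b, alpha=plan.alpha, seed=seed, **plan.options)
    if plan.test_case == 1:
        result, reports = out
    else:
        result, reports = out, None
    result.provenance["plan_hash"] = plan.hash()
    return result, reports
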