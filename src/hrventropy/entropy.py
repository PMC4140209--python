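"""Template-matching entropy estimators for physiological time series.

Implements the four regularity statistics most used in heart-rate-complexity
work: approximate entropy (ApEn), sample entropy (SampEn), fuzzy entropy
(FuzzyEn) and fuzzy measure entropy (FuzzyMEn).  All four share the same
machinery: a signal ``{u_1, ..., u_N}`` is split into overlapping templates
of length ``m``, templates are compared under the Chebyshev (maximum
coordinate) distance, and the entropy is the log-decrease of the match rate
when the template length grows from ``m`` to ``m + 1``.

Conventions, fixed once for the whole package:

* a "match" is a *strict* inequality ``d < r``;
* ApEn counts self-matches (``j = i``), so its counts are never zero and its
  logarithms always finite;
* SampEn excludes self-matches and uses only the first ``N - m`` templates at
  both lengths, with denominator ``N - m - 1``; when no matches survive at
  either length the value is undefined and a typed
  :class:`~hrventropy.errors.UndefinedEntropyError` is raised rather than
  returning an infinity;
* the fuzzy variants replace the hard match indicator with the membership
  function ``mu(x, n, r) = exp(-(x/r)**n)``, applied to mean-removed
  templates; their averages are strictly positive by construction so they are
  defined for every input;
* FuzzyMEn adds a *global* similarity term: templates with the whole-signal
  mean removed, graded by a second ``(r_F, n_F)`` pair, on top of the *local*
  (per-template mean removed) term with ``(r_L, n_L)``.

The pairwise-distance layer is vectorised (``O(N^2 m)`` time, ``O(N^2)``
transient space for the distance matrix).  :class:`EntropyEngine` caches the
distance matrices of one record so parameter sweeps that vary only ``r`` or
the fuzzy weights do not recompute them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, UndefinedEntropyError

__all__ = [
    "TemplateSet",
    "EntropyParams",
    "EntropyEngine",
    "embed",
    "cheb_dist",
    "fuzzy_membership",
    "apen",
    "sampen",
    "fuzzyen",
    "fuzzymen",
    "ESTIMATORS",
]

#: Names of the four estimators, in canonical order.
ESTIMATORS = ("apen", "sampen", "fuzzyen", "fuzzymen")


def _as_signal(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError(f"signal must be one-dimensional, got shape {x.shape}")
    if x.size == 0:
        raise InvalidInputError("signal is empty")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("signal contains non-finite values")
    return x


def _check_m(m: int) -> int:
    if int(m) != m or m < 1:
        raise InvalidInputError(f"template length m must be a positive integer, got {m!r}")
    return int(m)


def _check_positive(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise InvalidInputError(f"{name} must be positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class TemplateSet:
    """Overlapping length-``m`` windows of a signal and their mean-removed forms.

    ``templates[i] = {u_i, ..., u_{i+m-1}}`` for ``i = 0 .. N - m``;
    ``baseline_removed`` subtracts each template's own mean (the *local*
    sequences of FuzzyEn/FuzzyMEn), ``global_removed`` subtracts the mean of
    the whole signal (the *global* sequences of FuzzyMEn).
    """

    m: int
    templates: np.ndarray          # (N - m + 1, m)
    local_means: np.ndarray        # (N - m + 1,)
    global_mean: float
    baseline_removed: np.ndarray   # templates - local_means[:, None]
    global_removed: np.ndarray     # templates - global_mean


@dataclass(frozen=True)
class EntropyParams:
    """Parameter bundle covering all four estimators.

    ``m`` is the template length; ``r`` the similarity threshold in signal
    units; ``n`` the fuzzy weighting exponent; ``r_L, n_L`` and ``r_F, n_F``
    the local/global pairs of FuzzyMEn.
    """

    m: int = 2
    r: float | None = None
    n: float = 3.0
    r_L: float | None = None
    r_F: float | None = None
    n_L: float = 3.0
    n_F: float = 2.0

    def __post_init__(self):
        _check_m(self.m)
        for name in ("r", "r_L", "r_F"):
            v = getattr(self, name)
            if v is not None:
                _check_positive(v, name)
        for name in ("n", "n_L", "n_F"):
            _check_positive(getattr(self, name), name)


def embed(signal, m: int) -> TemplateSet:
    """Split ``signal`` into the ``N - m + 1`` overlapping length-``m`` templates.

    For example ``{1, 2, 3, 4, 5}`` with ``m = 3`` yields
    ``{{1,2,3}, {2,3,4}, {3,4,5}}``.  Requires ``N >= m + 1`` so that at least
    two templates exist.
    """
    x = _as_signal(signal)
    m = _check_m(m)
    if x.size < m + 1:
        raise InvalidInputError(f"signal of length {x.size} too short for m={m} (need N >= m + 1)")
    # stride trick view, copied so downstream arithmetic owns its memory
    templates = np.lib.stride_tricks.sliding_window_view(x, m).copy()
    local_means = templates.mean(axis=1)
    global_mean = float(x.mean())
    return TemplateSet(
        m=m,
        templates=templates,
        local_means=local_means,
        global_mean=global_mean,
        baseline_removed=templates - local_means[:, None],
        global_removed=templates - global_mean,
    )


def cheb_dist(a, b) -> float:
    """Chebyshev distance: the maximum absolute coordinate difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError(f"templates have different shapes: {a.shape} vs {b.shape}")
    return float(np.max(np.abs(a - b)))


def fuzzy_membership(x, n: float, r: float):
    """Exponential fuzzy membership ``mu(x, n, r) = exp(-(x/r)**n)``.

    Continuous and non-increasing in the distance ``x``; equal to 1 at
    ``x = 0`` (self-similarity is the maximum) and ``1/e`` at ``x = r``.  As
    ``n`` grows it converges to the Heaviside indicator of ``x < r``.
    """
    n = _check_positive(n, "n")
    r = _check_positive(r, "r")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise InvalidInputError("distance x must be non-negative")
    out = np.exp(-((x_arr / r) ** n))
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def _pairwise_cheb(templates: np.ndarray) -> np.ndarray:
    """Full pairwise Chebyshev distance matrix, one coordinate at a time."""
    k, m = templates.shape
    out = np.abs(templates[:, 0, None] - templates[None, :, 0])
    for d in range(1, m):
        np.maximum(out, np.abs(templates[:, d, None] - templates[None, :, d]), out=out)
    return out


class EntropyEngine:
    """All four entropies of one record, with cached distance matrices.

    The Chebyshev distance matrices at template lengths ``m`` and ``m + 1``
    are the expensive part of every estimator and do not depend on the
    threshold ``r`` or the fuzzy weights.  The engine computes them lazily
    (raw templates for ApEn/SampEn, mean-removed for the fuzzy variants) and
    reuses them across calls, which makes threshold and weight sweeps cheap.

    Because the global sequences of FuzzyMEn subtract the *same* constant
    from every template, their pairwise distances coincide with the raw
    template distances; the engine exploits that identity.
    """

    def __init__(self, signal, m: int = 2):
        self.x = _as_signal(signal)
        self.m = _check_m(m)
        self.N = self.x.size
        if self.N < self.m + 2:
            raise InvalidInputError(
                f"signal of length {self.N} too short for m={self.m} (need N >= m + 2)"
            )
        self._raw: dict[int, np.ndarray] = {}
        self._local: dict[int, np.ndarray] = {}

    # -- distance-matrix caches ------------------------------------------

    def _raw_dists(self, mm: int) -> np.ndarray:
        if mm not in self._raw:
            t = np.lib.stride_tricks.sliding_window_view(self.x, mm)
            self._raw[mm] = _pairwise_cheb(t)
        return self._raw[mm]

    def _local_dists(self, mm: int) -> np.ndarray:
        if mm not in self._local:
            t = np.lib.stride_tricks.sliding_window_view(self.x, mm)
            t = t - t.mean(axis=1, keepdims=True)
            self._local[mm] = _pairwise_cheb(t)
        return self._local[mm]

    # -- estimators -------------------------------------------------------

    def apen(self, r: float) -> float:
        r = _check_positive(r, "r")
        m, N = self.m, self.N
        c_m = np.count_nonzero(self._raw_dists(m) < r, axis=1)          # self-match included
        c_m1 = np.count_nonzero(self._raw_dists(m + 1) < r, axis=1)
        phi_m = float(np.mean(np.log(c_m / (N - m + 1))))
        phi_m1 = float(np.mean(np.log(c_m1 / (N - m))))
        return phi_m - phi_m1

    def sampen(self, r: float) -> float:
        r = _check_positive(r, "r")
        m, N = self.m, self.N
        k = N - m                                                       # templates used at both lengths
        d_m = self._raw_dists(m)[:k, :k]
        c_m = np.count_nonzero(d_m < r, axis=1) - 1                     # drop the self-match
        c_m1 = np.count_nonzero(self._raw_dists(m + 1) < r, axis=1) - 1
        phi_m = float(np.mean(c_m / (k - 1)))
        phi_m1 = float(np.mean(c_m1 / (k - 1)))
        if phi_m == 0.0 or phi_m1 == 0.0:
            raise UndefinedEntropyError(phi_m, phi_m1)
        return float(np.log(phi_m) - np.log(phi_m1))

    def _fuzzy_phi(self, dists: np.ndarray, k: int, r: float, n: float) -> float:
        # mean over i of (sum_{j != i} mu(d_ij)) / (k - 1); the diagonal
        # contributes membership exactly 1 at distance 0, subtracted off.
        mu = np.exp(-((dists[:k, :k] / r) ** n))
        return float(np.mean((mu.sum(axis=1) - 1.0) / (k - 1)))

    def fuzzyen(self, r: float, n: float) -> float:
        r = _check_positive(r, "r")
        n = _check_positive(n, "n")
        m, N = self.m, self.N
        k = N - m
        phi_m = self._fuzzy_phi(self._local_dists(m), k, r, n)
        phi_m1 = self._fuzzy_phi(self._local_dists(m + 1), k, r, n)
        return float(np.log(phi_m) - np.log(phi_m1))

    def fuzzymen(self, r_L: float, r_F: float, n_L: float, n_F: float) -> float:
        r_L = _check_positive(r_L, "r_L")
        r_F = _check_positive(r_F, "r_F")
        n_L = _check_positive(n_L, "n_L")
        n_F = _check_positive(n_F, "n_F")
        m, N = self.m, self.N
        k = N - m
        # local term: per-template mean removed
        phi_l_m = self._fuzzy_phi(self._local_dists(m), k, r_L, n_L)
        phi_l_m1 = self._fuzzy_phi(self._local_dists(m + 1), k, r_L, n_L)
        # global term: whole-signal mean removed; subtracting one constant
        # from all templates leaves pairwise distances equal to the raw ones
        phi_f_m = self._fuzzy_phi(self._raw_dists(m), k, r_F, n_F)
        phi_f_m1 = self._fuzzy_phi(self._raw_dists(m + 1), k, r_F, n_F)
        return float(
            np.log(phi_l_m) - np.log(phi_l_m1) + np.log(phi_f_m) - np.log(phi_f_m1)
        )


def apen(signal, m: int, r: float) -> float:
    """Approximate entropy ``ApEn(m, r, N) = phi^m - phi^(m+1)``.

    ``phi^m`` averages ``ln(C_i^m / (N - m + 1))`` over all ``N - m + 1``
    templates, where ``C_i^m`` counts templates within distance ``r`` of
    template ``i`` (itself included); ``phi^(m+1)`` does the same over the
    ``N - m`` longer templates.
    """
    return EntropyEngine(signal, m).apen(r)


def sampen(signal, m: int, r: float) -> float:
    """Sample entropy ``SampEn(m, r, N) = ln(phi^m) - ln(phi^(m+1))``.

    Self-matches are excluded and only the first ``N - m`` templates enter at
    both lengths, removing the regularity bias of ApEn.  Raises
    :class:`~hrventropy.errors.UndefinedEntropyError` when no matches exist
    at either length.
    """
    return EntropyEngine(signal, m).sampen(r)


def fuzzyen(signal, m: int, r: float, n: float) -> float:
    """Fuzzy entropy: SampEn-style statistic on mean-removed templates with
    the hard match indicator replaced by ``exp(-(d/r)**n)``."""
    return EntropyEngine(signal, m).fuzzyen(r, n)


def fuzzymen(signal, m: int, r_L: float, r_F: float, n_L: float, n_F: float) -> float:
    """Fuzzy measure entropy: sum of a local fuzzy term (per-template mean
    removed, graded by ``r_L, n_L``) and a global term (whole-signal mean
    removed, graded by ``r_F, n_F``)."""
    return EntropyEngine(signal, m).fuzzymen(r_L, r_F, n_L, n_F)
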