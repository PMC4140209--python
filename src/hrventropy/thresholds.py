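"""Similarity-threshold selection for template-matching entropies.

Two families of thresholds are supported:

* fixed multiples of the sample standard deviation of the analysed segment,
  ``r = k * sigma`` (the conventional range is ``k`` in [0.1, 0.25], most
  commonly 0.2);
* the empirical formula of Chon and co-workers approximating the
  entropy-maximising threshold for ``m = 2``::

      r_chon = (-0.036 + 0.26 * sqrt(sigma_1 / sigma_2)) / (N / 1000) ** 0.25

  where ``sigma_1`` is the sample standard deviation of the successive
  differences ``{u_1 - u_2, ..., u_{N-1} - u_N}`` and ``sigma_2`` that of the
  sequence itself.  The published rendering of the formula is typographically
  ambiguous; the form above follows the original source (square root over the
  ratio, fourth root of N/1000) and reproduces its stated values (0.224 at
  ``sigma_1 = sigma_2``, ``N = 1000``).

All statistics use the n-1 (sample) denominator and are computed on the
cropped segment actually fed to the entropy estimator, never on the full
original recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateThresholdError, InvalidInputError

__all__ = ["ThresholdSpec", "r_sigma", "r_chon", "chon_value", "resolve"]

_MODES = ("sigma_multiple", "chon", "chon_multiple", "absolute")


@dataclass(frozen=True)
class ThresholdSpec:
    """Declarative threshold rule, resolvable against any signal.

    ``mode`` is one of ``sigma_multiple`` (r = coefficient * sigma), ``chon``
    (r = r_chon), ``chon_multiple`` (r = coefficient * r_chon) or
    ``absolute`` (r = coefficient, in signal units).
    """

    mode: str
    coefficient: float = 1.0

    def __post_init__(self):
        if self.mode not in _MODES:
            raise InvalidInputError(f"unknown threshold mode {self.mode!r}; expected one of {_MODES}")
        if not np.isfinite(self.coefficient) or self.coefficient <= 0:
            raise InvalidInputError(f"threshold coefficient must be positive, got {self.coefficient!r}")

    @classmethod
    def parse(cls, text: str) -> "ThresholdSpec":
        """Parse compact CLI syntax: ``"0.2sigma"``, ``"chon"``, ``"1.5chon"``, ``"abs:0.05"``."""
        s = text.strip().lower()
        if s == "chon":
            return cls("chon")
        if s.startswith("abs:"):
            return cls("absolute", float(s[4:]))
        if s.endswith("sigma"):
            return cls("sigma_multiple", float(s[: -len("sigma")]))
        if s.endswith("chon"):
            return cls("chon_multiple", float(s[: -len("chon")]))
        raise InvalidInputError(f"cannot parse threshold spec {text!r}")

    def label(self) -> str:
        if self.mode == "chon":
            return "chon"
        if self.mode == "chon_multiple":
            return f"{self.coefficient:g}chon"
        if self.mode == "sigma_multiple":
            return f"{self.coefficient:g}sigma"
        return f"abs:{self.coefficient:g}"


def _as_signal(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError("signal must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("signal contains non-finite values")
    return x


def r_sigma(signal, k: float) -> float:
    """``k`` times the sample standard deviation of the analysed segment."""
    x = _as_signal(signal)
    if x.size < 2:
        raise InvalidInputError("need at least 2 samples for a standard deviation")
    if k <= 0:
        raise InvalidInputError(f"multiplier k must be positive, got {k!r}")
    sigma = float(np.std(x, ddof=1))
    # a numerically constant signal (rounding noise only) is degenerate too
    if np.ptp(x) == 0.0 or sigma < 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        raise DegenerateThresholdError("zero-variance signal: r = k * sigma would be 0")
    return k * sigma


def chon_value(sigma1: float, sigma2: float, n: int) -> float:
    """Evaluate the Chon formula from precomputed statistics (m = 2 only)."""
    if sigma2 <= 0:
        raise DegenerateThresholdError("sigma_2 must be positive")
    r = (-0.036 + 0.26 * np.sqrt(sigma1 / sigma2)) / (n / 1000.0) ** 0.25
    if r <= 0:
        raise DegenerateThresholdError(
            f"r_chon = {r:g} <= 0 (signal too smooth: sqrt(sigma1/sigma2) < 0.1385)"
        )
    return float(r)


def r_chon(signal) -> float:
    """Empirical approximation of the entropy-maximising threshold for ``m = 2``.

    Depends only on the ratio of the successive-difference standard deviation
    to the overall one (hence invariant under rescaling of the signal) and
    decays with the segment length as ``N**-0.25``.
    """
    x = _as_signal(signal)
    if x.size < 3:
        raise InvalidInputError("need at least 3 samples for r_chon")
    sigma1 = float(np.std(np.diff(x), ddof=1))
    sigma2 = float(np.std(x, ddof=1))
    if np.ptp(x) == 0.0 or sigma2 < 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        raise DegenerateThresholdError("zero-variance signal: r_chon undefined")
    return chon_value(sigma1, sigma2, x.size)


def resolve(spec: ThresholdSpec, signal) -> float:
    """Resolve a :class:`ThresholdSpec` against a concrete signal segment."""
    if spec.mode == "sigma_multiple":
        return r_sigma(signal, spec.coefficient)
    if spec.mode == "chon":
        return r_chon(signal)
    if spec.mode == "chon_multiple":
        return spec.coefficient * r_chon(signal)
    return float(spec.coefficient)
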