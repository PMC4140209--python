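"""Independent oracles for the entropy estimators.

Literal, unoptimised transcriptions of the defining formulas: explicit
double loops over templates, scalar Chebyshev distances, no shared machinery
with the package implementation.  Deliberately slow and simple — these exist
so the vectorised estimators can be checked against an implementation whose
correctness is readable at a glance.
"""

from __future__ import annotations

import math

from scipy.stats import norm


def _templates(u, mm):
    n = len(u)
    return [list(u[i : i + mm]) for i in range(n - mm + 1)]


def _cheb(a, b):
    return max(abs(x - y) for x, y in zip(a, b))


def apen_oracle(u, m, r):
    """phi^m - phi^(m+1); counts include the self-match."""
    n = len(u)
    x_m = _templates(u, m)
    b_m = n - m + 1
    phi_m = 0.0
    for i in range(b_m):
        c = sum(1 for j in range(b_m) if _cheb(x_m[i], x_m[j]) < r)
        phi_m += math.log(c / b_m)
    phi_m /= b_m
    x_m1 = _templates(u, m + 1)
    b_m1 = n - m
    phi_m1 = 0.0
    for i in range(b_m1):
        c = sum(1 for j in range(b_m1) if _cheb(x_m1[i], x_m1[j]) < r)
        phi_m1 += math.log(c / b_m1)
    phi_m1 /= b_m1
    return phi_m - phi_m1


def sampen_phis(u, m, r):
    """(phi^m, phi^(m+1)) without self-matches, first n-m templates, denominator n-m-1."""
    n = len(u)
    k = n - m
    x_m = _templates(u, m)[:k]
    x_m1 = _templates(u, m + 1)
    phi = [0.0, 0.0]
    for idx, tpls in enumerate((x_m, x_m1)):
        for i in range(k):
            c = sum(1 for j in range(k) if j != i and _cheb(tpls[i], tpls[j]) < r)
            phi[idx] += c / (k - 1)
        phi[idx] /= k
    return phi[0], phi[1]


def sampen_oracle(u, m, r):
    """ln phi^m - ln phi^(m+1); None when either phi is zero (undefined)."""
    phi_m, phi_m1 = sampen_phis(u, m, r)
    if phi_m == 0.0 or phi_m1 == 0.0:
        return None
    return math.log(phi_m) - math.log(phi_m1)


def _baseline_removed(u, mm):
    out = []
    for t in _templates(u, mm):
        mu = sum(t) / len(t)
        out.append([v - mu for v in t])
    return out


def _fuzzy_phi(tpls, k, r, n):
    total = 0.0
    for i in range(k):
        s = 0.0
        for j in range(k):
            if j != i:
                s += math.exp(-((_cheb(tpls[i], tpls[j]) / r) ** n))
        total += s / (k - 1)
    return total / k


def fuzzyen_oracle(u, m, r, n):
    k = len(u) - m
    phi_m = _fuzzy_phi(_baseline_removed(u, m), k, r, n)
    phi_m1 = _fuzzy_phi(_baseline_removed(u, m + 1), k, r, n)
    return math.log(phi_m) - math.log(phi_m1)


def fuzzymen_oracle(u, m, r_l, r_f, n_l, n_f):
    k = len(u) - m
    u_mean = sum(u) / len(u)
    local_m = _baseline_removed(u, m)
    local_m1 = _baseline_removed(u, m + 1)
    global_m = [[v - u_mean for v in t] for t in _templates(u, m)]
    global_m1 = [[v - u_mean for v in t] for t in _templates(u, m + 1)]
    phi_l_m = _fuzzy_phi(local_m, k, r_l, n_l)
    phi_l_m1 = _fuzzy_phi(local_m1, k, r_l, n_l)
    phi_f_m = _fuzzy_phi(global_m, k, r_f, n_f)
    phi_f_m1 = _fuzzy_phi(global_m1, k, r_f, n_f)
    return (
        math.log(phi_l_m) - math.log(phi_l_m1) + math.log(phi_f_m) - math.log(phi_f_m1)
    )


def fuzzymen_local_term_oracle(u, m, r, n):
    """Just the local half of the fuzzy measure entropy."""
    k = len(u) - m
    phi_m = _fuzzy_phi(_baseline_removed(u, m), k, r, n)
    phi_m1 = _fuzzy_phi(_baseline_removed(u, m + 1), k, r, n)
    return math.log(phi_m) - math.log(phi_m1)


def hard_threshold_fuzzy_oracle(u, m, r):
    """SampEn-style hard counting applied to baseline-removed templates.

    The Heaviside limit of FuzzyEn as the weight n grows: membership becomes
    the indicator of distance < r between mean-removed templates.
    """
    k = len(u) - m
    local_m = _baseline_removed(u, m)
    local_m1 = _baseline_removed(u, m + 1)
    phi = [0.0, 0.0]
    for idx, tpls in enumerate((local_m, local_m1)):
        for i in range(k):
            c = sum(1 for j in range(k) if j != i and _cheb(tpls[i], tpls[j]) < r)
            phi[idx] += c / (k - 1)
        phi[idx] /= k
    if phi[0] == 0.0 or phi[1] == 0.0:
        return None
    return math.log(phi[0]) - math.log(phi[1])


def sampen_iid_gaussian_limit(k: float = 0.2) -> float:
    """Closed-form SampEn limit for iid Gaussian data at r = k * sigma.

    For iid data the templates' coordinates match independently, so the
    conditional probability that an (m+1)-th coordinate also matches is
    p = P(|X - Y| < r) with X, Y iid N(0, sigma^2), i.e.
    ``2 * Phi(k / sqrt(2)) - 1``; SampEn converges to ``-ln p``.
    """
    return -math.log(2.0 * norm.cdf(k / math.sqrt(2.0)) - 1.0)
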