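"""Unit and property tests for the entropy estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrventropy.entropy import (
    EntropyEngine,
    apen,
    cheb_dist,
    embed,
    fuzzy_membership,
    fuzzyen,
    fuzzymen,
    sampen,
)
from hrventropy.errors import InvalidInputError, UndefinedEntropyError

import _oracles as oracle


class TestEmbed:
    def test_overlapping_templates(self):
        ts = embed([1, 2, 3, 4, 5], 3)
        assert ts.templates.tolist() == [[1, 2, 3], [2, 3, 4], [3, 4, 5]]

    def test_local_means(self):
        ts = embed([1, 2, 3, 4], 2)
        assert ts.local_means.tolist() == [1.5, 2.5, 3.5]

    def test_constant_signal_baseline_removed_all_zero(self):
        ts = embed(np.full(10, 3.7), 4)
        assert np.all(ts.baseline_removed == 0.0)

    def test_template_count_and_global_mean(self, rng):
        x = rng.normal(size=50)
        ts = embed(x, 5)
        assert ts.templates.shape == (46, 5)
        assert ts.global_mean == pytest.approx(x.mean())

    def test_too_short_signal_rejected(self):
        with pytest.raises(InvalidInputError):
            embed([1.0, 2.0], 2)


class TestChebDist:
    @pytest.mark.parametrize(
        "a, b, expected",
        [([1, 2, 3], [1, 2, 3], 0.0), ([1, 5], [2, 3], 2.0), ([0.0], [-1.5], 1.5)],
    )
    def test_examples(self, a, b, expected):
        assert cheb_dist(a, b) == expected

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 4))
            assert cheb_dist(a, b) == cheb_dist(b, a)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            cheb_dist([1, 2], [1, 2, 3])


class TestFuzzyMembership:
    def test_zero_distance_is_one(self):
        assert fuzzy_membership(0.0, 3.0, 0.2) == 1.0

    @pytest.mark.parametrize("n", [0.5, 1.0, 3.0, 10.0])
    def test_at_threshold_equals_inv_e(self, n):
        assert fuzzy_membership(0.2, n, 0.2) == pytest.approx(np.exp(-1.0))

    def test_heaviside_limit(self):
        assert fuzzy_membership(0.5 * 0.2, 100.0, 0.2) == pytest.approx(1.0, abs=1e-12)
        assert fuzzy_membership(2.0 * 0.2, 100.0, 0.2) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_x_and_n(self):
        xs = np.linspace(0.0, 0.5, 40)
        mu = fuzzy_membership(xs, 2.0, 0.2)
        assert np.all(np.diff(mu) <= 0)
        # below the threshold, larger n weights close pairs more strongly
        for x in np.linspace(0.01, 0.19, 10):
            vals = [fuzzy_membership(x, n, 0.2) for n in (0.5, 1, 2, 4, 8)]
            assert np.all(np.diff(vals) >= 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(InvalidInputError):
            fuzzy_membership(-0.1, 2.0, 0.2)


class TestConstantSignals:
    """A constant sequence is perfectly regular: every entropy is exactly 0."""

    def test_all_four_zero(self):
        c = np.full(60, 0.8)
        assert apen(c, 2, 0.1) == 0.0
        assert sampen(c, 2, 0.1) == 0.0
        assert fuzzyen(c, 2, 0.1, 3.0) == 0.0
        assert fuzzymen(c, 2, 0.1, 0.1, 3.0, 2.0) == 0.0


class TestAgainstOracles:
    """Vectorised estimators must match the literal double-loop transcriptions."""

    def test_random_signals_match_all_estimators(self, rng):
        for _ in range(8):
            n = int(rng.integers(30, 120))
            u = rng.normal(size=n)
            r = 0.2 * np.std(u, ddof=1)
            assert apen(u, 2, r) == pytest.approx(oracle.apen_oracle(u, 2, r), abs=1e-10)
            expected = oracle.sampen_oracle(u, 2, r)
            if expected is not None:
                assert sampen(u, 2, r) == pytest.approx(expected, abs=1e-10)
            assert fuzzyen(u, 2, r, 3.0) == pytest.approx(
                oracle.fuzzyen_oracle(u, 2, r, 3.0), abs=1e-10
            )
            assert fuzzymen(u, 2, r, r, 3.0, 2.0) == pytest.approx(
                oracle.fuzzymen_oracle(u, 2, r, r, 3.0, 2.0), abs=1e-10
            )

    @pytest.mark.parametrize("m", [1, 3])
    def test_other_template_lengths(self, rng, m):
        u = rng.normal(size=80)
        r = 0.25 * np.std(u, ddof=1)
        assert apen(u, m, r) == pytest.approx(oracle.apen_oracle(u, m, r), abs=1e-10)
        assert fuzzymen(u, m, r, 1.5 * r, 2.0, 1.0) == pytest.approx(
            oracle.fuzzymen_oracle(u, m, r, 1.5 * r, 2.0, 1.0), abs=1e-10
        )

    def test_periodic_signal_apen_near_zero(self):
        # two alternating templates with deterministic extensions: ApEn is
        # zero up to the finite-N edge terms (uneven template counts)
        u = np.tile([1.0, 2.0], 50)
        expected = oracle.apen_oracle(u, 2, 0.05)
        assert expected == pytest.approx(0.0, abs=1e-3)
        assert apen(u, 2, 0.05) == pytest.approx(expected, abs=1e-10)


class TestSampEnDegeneracy:
    def test_no_matches_raises_typed_error(self, rng):
        u = rng.normal(size=50)
        # r below the smallest inter-template gap: the oracle finds no matches
        phis = oracle.sampen_phis(u, 2, 1e-9)
        assert phis == (0.0, 0.0)
        with pytest.raises(UndefinedEntropyError) as exc_info:
            sampen(u, 2, 1e-9)
        assert exc_info.value.phi_m == 0.0
        assert exc_info.value.phi_m1 == 0.0

    def test_short_signal_rejected(self):
        with pytest.raises(InvalidInputError):
            sampen([1.0, 2.0, 3.0], 2, 0.1)


class TestFuzzyMEnStructure:
    def test_local_term_equals_fuzzyen(self, rng):
        """With r_L = r_F, n_L = n_F the local half of FuzzyMEn is FuzzyEn."""
        u = rng.normal(size=90)
        r, n = 0.2 * np.std(u, ddof=1), 3.0
        eng = EntropyEngine(u, 2)
        k = eng.N - eng.m
        local_term = np.log(eng._fuzzy_phi(eng._local_dists(2), k, r, n)) - np.log(
            eng._fuzzy_phi(eng._local_dists(3), k, r, n)
        )
        assert local_term == pytest.approx(fuzzyen(u, 2, r, n), abs=1e-12)
        assert local_term == pytest.approx(
            oracle.fuzzymen_local_term_oracle(list(u), 2, r, n), abs=1e-10
        )


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    data=st.lists(st.floats(-5, 5), min_size=20, max_size=60),
    shift=st.floats(-100, 100),
)
def test_translation_invariance(data, shift):
    """Adding a constant changes no distances, hence no entropy."""
    u = np.asarray(data)
    if np.std(u, ddof=1) < 1e-6:
        return
    r = 0.3 * np.std(u, ddof=1)
    v = u + shift
    assert apen(v, 2, r) == pytest.approx(apen(u, 2, r), abs=1e-9)
    assert fuzzyen(v, 2, r, 2.0) == pytest.approx(fuzzyen(u, 2, r, 2.0), abs=1e-9)
    assert fuzzymen(v, 2, r, r, 2.0, 1.0) == pytest.approx(
        fuzzymen(u, 2, r, r, 2.0, 1.0), abs=1e-9
    )


@settings(max_examples=25, derandomize=True, deadline=None)
@given(scale=st.floats(0.01, 100.0))
def test_scale_equivariance(scale):
    """Scaling the signal and the thresholds together leaves entropies unchanged."""
    rng = np.random.default_rng(5)
    u = rng.normal(size=60)
    r = 0.2 * np.std(u, ddof=1)
    assert apen(scale * u, 2, scale * r) == pytest.approx(apen(u, 2, r), abs=1e-9)
    assert sampen(scale * u, 2, scale * r) == pytest.approx(sampen(u, 2, r), abs=1e-9)
    assert fuzzyen(scale * u, 2, scale * r, 3.0) == pytest.approx(
        fuzzyen(u, 2, r, 3.0), abs=1e-9
    )
    assert fuzzymen(scale * u, 2, scale * r, scale * r, 3.0, 2.0) == pytest.approx(
        fuzzymen(u, 2, r, r, 3.0, 2.0), abs=1e-9
    )


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_sampen_nonnegative_when_defined(seed):
    """Every (m+1)-match is an m-match, so phi^m >= phi^(m+1) and SampEn >= 0."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=40)
    r = 0.25 * np.std(u, ddof=1)
    try:
        assert sampen(u, 2, r) >= 0.0
    except UndefinedEntropyError:
        pass


def test_fuzzy_entropies_continuous_in_r(rng):
    """Small threshold perturbations move FuzzyEn/FuzzyMEn only slightly."""
    u = rng.normal(size=100)
    r = 0.2 * np.std(u, ddof=1)
    for delta in (1e-3 * r, 1e-5 * r):
        assert abs(fuzzyen(u, 2, r + delta, 3.0) - fuzzyen(u, 2, r, 3.0)) < 50 * delta / r
        assert abs(
            fuzzymen(u, 2, r + delta, r, 3.0, 2.0) - fuzzymen(u, 2, r, r, 3.0, 2.0)
        ) < 50 * delta / r


def test_engine_reuse_matches_fresh_computation(rng):
    u = rng.normal(size=120)
    eng = EntropyEngine(u, 2)
    for k in (0.1, 0.2, 0.3):
        r = k * np.std(u, ddof=1)
        assert eng.apen(r) == apen(u, 2, r)
        assert eng.sampen(r) == sampen(u, 2, r)
        assert eng.fuzzyen(r, 3.0) == fuzzyen(u, 2, r, 3.0)
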