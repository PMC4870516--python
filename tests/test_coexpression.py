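"""Unit and property tests for the co-expression statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isocoex.coexpression import (CoexpressionTrendModel, bh_adjust,
                                  classify_trends, coexpression_index,
                                  dip_statistic, dip_test, kde_density,
                                  kendall_tau, nu_from_psi, shannon_entropy)

from _oracles import kendall_exact_p_enumeration, kendall_tau_b_bruteforce


class TestEntropyAndNu:
    @pytest.mark.parametrize("p, expected_h", [
        ((1.0, 0.0), 0.0),
        ((0.5, 0.5), math.log(2)),
        ((0.9, 0.1), 0.325083),
    ])
    def test_entropy_closed_form(self, p, expected_h):
        assert shannon_entropy(p) == pytest.approx(expected_h, abs=1e-6)

    def test_nu_boundaries(self):
        assert coexpression_index([0.5, 0.5]).nu == pytest.approx(2.0)
        assert coexpression_index([1.0, 0.0]).nu == pytest.approx(1.0)
        assert coexpression_index([0.25] * 4).nu == pytest.approx(4.0)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([0.6, 0.6])
        with pytest.raises(ValueError):
            shannon_entropy([1.2, -0.2])

    @given(st.floats(min_value=0.0, max_value=100.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nu_psi_complement_symmetry(self, psi):
        assert nu_from_psi(psi) == pytest.approx(nu_from_psi(100 - psi))

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                    min_size=2, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nu_bounds_and_permutation_invariance(self, weights):
        p = np.array(weights) / np.sum(weights)
        nu = coexpression_index(p).nu
        assert 1.0 - 1e-9 <= nu <= len(p) + 1e-9
        shuffled = np.roll(p, 1)
        assert coexpression_index(shuffled).nu == pytest.approx(nu)

    def test_nu_monotone_in_evenness(self):
        psis = np.linspace(0, 50, 101)
        nus = [nu_from_psi(p) for p in psis]
        assert np.all(np.diff(nus) >= -1e-12)


class TestKendall:
    def test_perfect_trends(self):
        x = np.arange(5.0)
        assert kendall_tau(x, x)[0] == pytest.approx(1.0)
        assert kendall_tau(x, -x)[0] == pytest.approx(-1.0)

    def test_small_exact_example(self):
        tau, p, defined = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert defined
        assert tau == pytest.approx(2 / 3)
        assert p == pytest.approx(1 / 3)

    def test_constant_y_flagged(self):
        tau, p, defined = kendall_tau([1, 2, 3, 4], [5, 5, 5, 5])
        assert (tau, p, defined) == (0.0, 1.0, False)

    def test_matches_bruteforce_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 31))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            tau, _, _ = kendall_tau(x, y)
            assert tau == pytest.approx(kendall_tau_b_bruteforce(x, y), abs=1e-12)

    def test_exact_p_matches_enumeration(self, rng):
        for n in (3, 4, 5, 6):
            for _ in range(3):
                x = np.arange(n, dtype=float)
                y = rng.permutation(n).astype(float)
                if np.all(np.diff(y) > 0) or np.all(np.diff(y) < 0):
                    continue
                _, p, _ = kendall_tau(x, y)
                assert p == pytest.approx(kendall_exact_p_enumeration(x, y),
                                          abs=1e-12)


class TestBHAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1 + 1e-12)


class TestTrendClassification:
    @pytest.mark.parametrize("tau, p_adj, expected", [
        (0.5, 0.001, "increasing"),
        (0.5, 0.01, "none"),
        (-0.45, 0.004, "decreasing"),
        (0.3, 0.001, "none"),
    ])
    def test_thresholds(self, tau, p_adj, expected):
        assert classify_trends([tau], [p_adj])[0] == expected


class TestDip:
    def test_two_point_sample(self):
        assert dip_statistic([0.0, 1.0]) == pytest.approx(0.25)
        assert dip_statistic([3.0, -7.0]) == pytest.approx(0.25)

    def test_identical_values_perfectly_unimodal(self):
        assert dip_statistic([2.0] * 10) == 0.0

    def test_separated_clusters_have_large_dip(self, rng):
        x = np.concatenate([rng.normal(-1, 0.01, 50), rng.normal(1, 0.01, 50)])
        assert dip_statistic(x) >= 0.1

    def test_uniform_sample_near_floor(self, rng):
        n = 2000
        d = dip_statistic(rng.uniform(size=n))
        assert 1 / (2 * n) <= d < 0.02

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6,
                              allow_nan=False), min_size=2, max_size=40))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_bounds_and_affine_invariance(self, xs):
        xs = [round(v, 3) for v in xs]  # keep spacings representable
        d = dip_statistic(xs)
        if len(set(xs)) == 1:
            assert d == 0.0
            return
        assert 1 / (2 * len(xs)) - 1e-12 <= d <= 0.25 + 1e-12
        scaled = [2.5 * v - 3.0 for v in xs]
        assert dip_statistic(scaled) == pytest.approx(d, abs=1e-9)

    def test_dip_test_bimodal_vs_normal(self, rng):
        mix = np.concatenate([rng.normal(-0.5, 0.1, 200),
                              rng.normal(0.5, 0.1, 200)])
        assert dip_test(mix, seed=5).p < 0.01
        hits = sum(dip_test(np.random.default_rng(s).normal(size=400),
                            seed=5).p > 0.05 for s in range(10))
        assert hits >= 9

    def test_dip_test_identical_values(self):
        assert dip_test([1.0] * 10, seed=0).p == pytest.approx(1.0)

    def test_dip_test_deterministic(self, rng):
        x = rng.normal(size=50)
        assert dip_test(x, seed=3) == dip_test(x, seed=3)


class TestKDE:
    def test_integrates_to_one(self, rng):
        est = kde_density(rng.normal(size=200))
        area = np.trapezoid(est.density, est.grid)
        assert area == pytest.approx(1.0, abs=1e-3)
        assert np.all(est.density >= 0)

    def test_two_points(self):
        est = kde_density([0.0, 1.0])
        area = np.trapezoid(est.density, est.grid)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_normal_peak_height(self, rng):
        est = kde_density(rng.normal(size=1000))
        peak = est.density.max()
        assert abs(peak - 1 / math.sqrt(2 * math.pi)) / peak < 0.2

    def test_zero_variance_flagged(self):
        est = kde_density([1.0, 1.0, 1.0])
        assert est.degenerate


class TestTrendModel:
    def test_fit_on_tiny_table(self):
        samples = pd.DataFrame({
            "sample_id": [f"s{i}{r}" for i in range(4) for r in range(2)],
            "stage": pd.Categorical(
                [f"t{i}" for i in range(4) for r in range(2)],
                categories=[f"t{i}" for i in range(4)], ordered=True),
            "replicate": [r for i in range(4) for r in range(2)],
        })
        psi = pd.DataFrame({
            "event_id": ["e1"] * 8 + ["e2"] * 8,
            "sample_id": list(samples["sample_id"]) * 2,
            "psi": [5, 6, 15, 16, 30, 31, 48, 49] + [50.0] * 8,
        })
        res = CoexpressionTrendModel(psi, samples).fit(alpha=0.05)
        t = res.trends.set_index("event_id")
        assert t.loc["e1", "tau"] > 0.9
        assert t.loc["e1", "trend_class"] == "increasing"
        assert t.loc["e2", "trend_class"] == "none"
        assert not t.loc["e2", "tau_defined"]
        assert res.counts["increasing"] == 1

    def test_summary_mentions_thresholds(self):
        samples = pd.DataFrame({"sample_id": ["a", "b", "c"],
                                "stage": ["s1", "s2", "s3"],
                                "replicate": [1, 1, 1]})
        psi = pd.DataFrame({"event_id": ["e"] * 3,
                            "sample_id": ["a", "b", "c"],
                            "psi": [10.0, 20.0, 30.0]})
        res = CoexpressionTrendModel(psi, samples).fit()
        assert "0.4" in res.summary() and "0.005" in res.summary()
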