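"""psi computation, detectability, regulation calling, overlap testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isocoex.quant import (JunctionCountTable, KnockdownRegulationModel,
                           TimecourseRegulationModel, compute_psi,
                           estimate_overdispersion, fisher_exact_2x2,
                           flag_detectable, overlap_enrichment, psi_matrix)
from isocoex.simulate import SimulationConfig, simulate_timecourse_counts

from _oracles import fisher_enumeration_oracle


def make_table(rows, samples):
    return JunctionCountTable(
        pd.DataFrame(rows, columns=["event_id", "sample_id",
                                    "inclusion", "exclusion"]),
        pd.DataFrame(samples, columns=["sample_id", "stage", "replicate"]))


class TestPsi:
    @pytest.mark.parametrize("inc, exc, expected", [
        (50, 50, 50.0), (0, 37, 0.0), (3, 7, 30.0), (12, 0, 100.0),
    ])
    def test_values(self, inc, exc, expected):
        assert compute_psi(inc, exc) == pytest.approx(expected)

    def test_undefined_when_uncovered(self):
        assert np.isnan(compute_psi(0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(-1, 5)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_complement_symmetry(self, a, b):
        if a + b == 0:
            return
        assert compute_psi(a, b) + compute_psi(b, a) == pytest.approx(100.0)

    def test_matrix_shape(self):
        table = make_table(
            [("e1", "s1", 3, 7), ("e1", "s2", 0, 0), ("e2", "s1", 5, 5),
             ("e2", "s2", 1, 3)],
            [("s1", "t1", 1), ("s2", "t2", 1)])
        m = psi_matrix(table)
        assert m.loc["e1", "s1"] == pytest.approx(30.0)
        assert np.isnan(m.loc["e1", "s2"])


class TestDetectability:
    def test_all_zero_not_detectable(self):
        table = make_table([("e", "s1", 0, 0), ("e", "s2", 0, 0)],
                           [("s1", "t1", 1), ("s2", "t2", 1)])
        assert not flag_detectable(table)["e"]

    def test_single_supported_stage_suffices(self):
        table = make_table([("e", "s1", 20, 5), ("e", "s2", 0, 0)],
                           [("s1", "t1", 1), ("s2", "t2", 1)])
        assert flag_detectable(table, min_total_per_sample=20, min_stages=1)["e"]

    def test_threshold_sweep_monotone(self, rng):
        rows, samples = [], []
        for s in range(3):
            for r in range(2):
                sid = f"t{s}_r{r}"
                samples.append((sid, f"t{s}", r))
                for e in range(30):
                    tot = int(rng.integers(0, 60))
                    inc = int(rng.integers(0, tot + 1))
                    rows.append((f"e{e}", sid, inc, tot - inc))
        table = make_table(rows, samples)
        counts = [int(flag_detectable(table, thr).sum())
                  for thr in range(0, 70, 5)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFisher:
    def test_matches_enumeration_small_tables(self, rng):
        for _ in range(150):
            cells = rng.integers(0, 11, size=4)
            if cells.sum() == 0 or cells.sum() > 40:
                continue
            a, b, c, d = (int(v) for v in cells)
            for alt in ("two-sided", "greater"):
                _, p = fisher_exact_2x2(a, b, c, d, alternative=alt)
                assert p == pytest.approx(
                    fisher_enumeration_oracle(a, b, c, d, alt), abs=1e-9)

    def test_odds_ratio_conventions(self):
        orr, _ = fisher_exact_2x2(5, 0, 0, 5)
        assert orr == np.inf
        orr, _ = fisher_exact_2x2(0, 5, 0, 5)
        assert np.isnan(orr)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestOverlap:
    def test_exhaustive_oracle(self):
        universe = [f"e{i}" for i in range(20)]
        a = set(universe[:8])
        b = set(universe[3:8])
        enr = overlap_enrichment(a, b, universe)
        assert enr.a_and_b == 5
        assert enr.p == pytest.approx(
            fisher_enumeration_oracle(5, 3, 0, 12), abs=1e-9)

    def test_identical_half_split(self):
        universe = [f"e{i}" for i in range(10)]
        half = set(universe[:5])
        enr = overlap_enrichment(half, half, universe)
        assert enr.odds_ratio == np.inf
        assert enr.p == pytest.approx(fisher_enumeration_oracle(5, 0, 0, 5))

    def test_uniform_p_under_independence(self, rng):
        """Independent random sets give roughly uniform p values."""
        from scipy.stats import kstest

        universe = list(range(60))
        ps = []
        for _ in range(300):
            a = set(rng.choice(universe, size=20, replace=False))
            b = set(rng.choice(universe, size=20, replace=False))
            ps.append(overlap_enrichment(a, b, universe).p)
        # discrete + conservative: the CDF may only sit above uniform
        assert kstest(ps, "uniform", alternative="greater").pvalue > 0.01

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(set(), set(), set())


def _switch_table(depth=200, lo=5.0, hi=45.0, stages=4, reps=3, seed=0):
    rng = np.random.default_rng(seed)
    rows, samples = [], []
    for s in range(stages):
        psi = lo if s < stages // 2 else hi
        for r in range(reps):
            sid = f"t{s}_r{r}"
            samples.append((sid, f"t{s}", r))
            inc = rng.binomial(depth, psi / 100)
            rows.append(("switch", sid, int(inc), int(depth - inc)))
            rows.append(("flat", sid, depth // 2, depth - depth // 2))
    s = pd.DataFrame(samples, columns=["sample_id", "stage", "replicate"])
    s["stage"] = pd.Categorical(s["stage"], ordered=True,
                                categories=[f"t{i}" for i in range(stages)])
    return make_table_from(rows, s)


def make_table_from(rows, samples):
    return JunctionCountTable(
        pd.DataFrame(rows, columns=["event_id", "sample_id",
                                    "inclusion", "exclusion"]), samples)


class TestTimecourseRegulation:
    def test_flat_event_not_regulated(self):
        res = TimecourseRegulationModel(_switch_table()).fit(dispersion=0)
        calls = res.calls.set_index("event_id")
        assert not calls.loc["flat", "regulated"]

    def test_planted_switch_regulated_and_matches_exact_oracle(self):
        table = _switch_table(depth=200)
        res = TimecourseRegulationModel(table).fit(dispersion=0)
        calls = res.calls.set_index("event_id")
        assert calls.loc["switch", "regulated"]
        # the per-event p is the Bonferroni-scaled smallest consecutive-pair
        # Fisher p on pooled counts: recompute it via table enumeration
        pooled = (table.merged().groupby(["event_id", "stage"], observed=True)
                  [["inclusion", "exclusion"]].sum())
        ps = []
        stages = [f"t{i}" for i in range(4)]
        for s1, s2 in zip(stages[:-1], stages[1:]):
            i1, e1 = pooled.loc[("switch", s1)]
            i2, e2 = pooled.loc[("switch", s2)]
            ps.append(fisher_enumeration_oracle(int(i1), int(e1),
                                                int(i2), int(e2)))
        assert calls.loc["switch", "p"] == pytest.approx(
            min(1.0, min(ps) * len(ps)), rel=1e-6)

    def test_effect_size_gate(self):
        # tiny but highly significant shift must not be called
        table = _switch_table(depth=100_000, lo=50.0, hi=58.0)
        res = TimecourseRegulationModel(table).fit(dispersion=0)
        calls = res.calls.set_index("event_id")
        assert calls.loc["switch", "p_adj"] < 0.05
        assert calls.loc["switch", "max_abs_delta_psi"] < 10
        assert not calls.loc["switch", "regulated"]

    def test_single_stage_rejected(self):
        rows = [("e", "s1", 5, 5)]
        samples = pd.DataFrame([("s1", "t1", 1)],
                               columns=["sample_id", "stage", "replicate"])
        with pytest.raises(ValueError, match="two stages"):
            TimecourseRegulationModel(make_table_from(rows, samples))

    def test_null_type_one_error_controlled(self):
        """Constant-psi events under beta-binomial noise stay uncalled."""
        called = total = 0
        for seed in range(1, 11):
            cfg = SimulationConfig(seed=seed, n_events=200, n_increasing=0,
                                   n_decreasing=0)
            table, _ = simulate_timecourse_counts(cfg)
            res = TimecourseRegulationModel(table).fit(alpha=0.05)
            called += res.n_called
            total += 200
        assert called / total <= 0.05

    def test_power_on_sharp_switches(self):
        cfg = SimulationConfig(seed=11, switch_slope=0.2)
        table, truth = simulate_timecourse_counts(cfg)
        res = TimecourseRegulationModel(table).fit()
        m = res.calls.merge(truth, on="event_id")
        planted = m["true_class"] == "increasing"
        assert (m.loc[planted, "regulated"].mean()) >= 0.9


class TestKnockdownRegulation:
    def _kd_table(self, d1, d12, depth=400, base=30.0):
        rows, samples = [], []
        for cond, delta in (("control", 0.0), ("kd1", d1), ("kd12", d12)):
            for r in range(3):
                sid = f"{cond}_r{r}"
                samples.append((sid, cond, r))
                inc = int(depth * (base + delta) / 100)
                rows.append(("e", sid, inc, depth - inc))
        return JunctionCountTable(
            pd.DataFrame(rows, columns=["event_id", "sample_id",
                                        "inclusion", "exclusion"]),
            pd.DataFrame(samples, columns=["sample_id", "condition",
                                           "replicate"]))

    def test_consistent_shifts_called_dependent(self):
        res = KnockdownRegulationModel(self._kd_table(20, 35)).fit(dispersion=0)
        assert res.calls.iloc[0]["dependent"]

    def test_sign_conflict_not_dependent(self):
        res = KnockdownRegulationModel(self._kd_table(20, -20)).fit(dispersion=0)
        assert not res.calls.iloc[0]["dependent"]

    def test_single_contrast_not_dependent(self):
        res = KnockdownRegulationModel(self._kd_table(20, 0)).fit(dispersion=0)
        assert not res.calls.iloc[0]["dependent"]

    def test_missing_condition_rejected(self):
        table = self._kd_table(20, 35)
        table.samples = table.samples[table.samples["condition"] != "kd12"]
        table.counts = table.counts[
            table.counts["sample_id"].isin(table.samples["sample_id"])]
        with pytest.raises(ValueError, match="kd12"):
            KnockdownRegulationModel(table)


class TestOverdispersionEstimate:
    def test_recovers_simulated_rho(self):
        cfg = SimulationConfig(seed=5, n_events=300, n_increasing=0,
                               overdispersion=0.05, depth_mean=200)
        table, _ = simulate_timecourse_counts(cfg)
        rho = estimate_overdispersion(table)
        assert rho == pytest.approx(0.05, abs=0.02)

    def test_zero_for_binomial_data(self):
        cfg = SimulationConfig(seed=5, n_events=200, n_increasing=0,
                               overdispersion=0.0)
        table, _ = simulate_timecourse_counts(cfg)
        assert estimate_overdispersion(table) < 0.005
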