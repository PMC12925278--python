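"""Welch test, volcano classification, and the differential table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from infosome_lfq.differential import classify, run_differential, welch_t
from infosome_lfq.quantify import quantify_pipeline
from infosome_lfq.simulate import SimulationConfig, simulate

from conftest import biorep_matrix


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        t, df, p = welch_t((1, 2, 3), (1, 2, 3))
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(loc=rng.normal(), scale=rng.uniform(0.5, 2),
                           size=rng.integers(2, 8))
            t, df, p = welch_t(a, b)
            ref = stats.ttest_ind(b, a, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_swapping_groups_negates_t_keeps_p(self):
        a, b = (10, 12, 14), (20, 21, 22)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t2 == -t1 and df2 == df1 and p2 == p1

    def test_zero_variance_unequal_means_floors_p(self):
        t, _, p = welch_t((1.0, 1.0), (2.0, 2.0))
        assert np.isinf(t) and t > 0
        assert p == np.nextafter(0.0, 1.0)

    def test_common_shift_invariance(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=4), rng.normal(size=5)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(a + 7.5, b + 7.5)
        assert t1 == pytest.approx(t2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_groups_of_one_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_null_size_is_conservative_not_anticonservative(self):
        """At n=3 vs 3 the Welch approximation runs below the nominal 5% level."""
        rng = np.random.default_rng(14)
        a = rng.normal(size=(5000, 3))
        b = rng.normal(size=(5000, 3))
        p = stats.ttest_ind(b, a, axis=1, equal_var=False).pvalue
        rate = (p < 0.05).mean()
        assert 0.02 <= rate <= 0.055


class TestClassify:
    @pytest.mark.parametrize("lfc,p,status", [
        (1.5, 0.01, "up"),
        (1.5, 0.20, "ns"),       # fails p
        (-2.0, 0.001, "down"),
        (1.0, 0.049, "up"),      # fold-change boundary inclusive
        (1.0, 0.05, "ns"),       # p boundary strict
        (0.99, 0.001, "ns"),     # below fold-change threshold
        (-1.0, 0.049, "down"),
    ])
    def test_threshold_rules(self, lfc, p, status):
        assert classify(lfc, p) == status

    @settings(max_examples=100, derandomize=True)
    @given(
        lfc=st.floats(min_value=-5, max_value=5),
        p=st.floats(min_value=1e-12, max_value=1.0),
        dp=st.floats(min_value=0, max_value=0.5),
        dfc=st.floats(min_value=0, max_value=2),
    )
    def test_monotone_in_p_and_fold_change(self, lfc, p, dp, dfc):
        """Decreasing p or pushing |log2FC| outward never demotes a call to ns."""
        before = classify(lfc, p)
        stronger = classify(lfc + np.sign(lfc or 1) * dfc, max(p - dp, 1e-15))
        if before in ("up", "down"):
            assert stronger == before


class TestRunDifferential:
    def test_spiked_proteins_recovered(self):
        cfg = SimulationConfig(n_proteins=100, spike_fraction=0.10, spike_log2fc=2.0,
                               tech_cv=0.2, mnar_max=0.0, mcar_rate=0.0, seed=21)
        sim = simulate(cfg)
        res = quantify_pipeline(sim.matrix, sim.design)
        de = run_differential(res.matrix, "Control", "LN").set_index("protein_id")
        truth = sim.truth.proteins.set_index("protein_id")
        for pid in truth.index[truth["spiked"]]:
            want = "up" if truth.loc[pid, "true_log2fc"] > 0 else "down"
            assert de.loc[pid, "status"] == want

    def test_status_partition_and_sort_order(self, small_sim):
        res = quantify_pipeline(small_sim.matrix, small_sim.design)
        de = run_differential(res.matrix, "Control", "LN")
        counts = de["status"].value_counts()
        assert counts.sum() == len(de)
        assert set(counts.index) <= {"up", "down", "ns"}
        assert de["p_value"].is_monotonic_increasing

    def test_matches_scalar_welch(self, small_sim):
        res = quantify_pipeline(small_sim.matrix, small_sim.design)
        de = run_differential(res.matrix, "Control", "LN").set_index("protein_id")
        groups = res.matrix.data.columns.get_level_values("group")
        for pid in res.matrix.data.index[:25]:
            a = res.matrix.data.loc[pid, groups == "Control"].to_numpy()
            b = res.matrix.data.loc[pid, groups == "LN"].to_numpy()
            t, df, p = welch_t(a, b)
            assert de.loc[pid, "t"] == pytest.approx(t, rel=1e-12)
            assert de.loc[pid, "p_value"] == pytest.approx(p, rel=1e-12)

    def test_bh_q_matches_step_up_oracle(self, small_sim):
        res = quantify_pipeline(small_sim.matrix, small_sim.design)
        de = run_differential(res.matrix, "Control", "LN")
        p = de["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q_oracle = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q_oracle[i] = running
        assert np.allclose(de["q_value"].to_numpy(), q_oracle, atol=1e-12)

    def test_absent_group_is_error(self, small_sim):
        res = quantify_pipeline(small_sim.matrix, small_sim.design)
        with pytest.raises(Exception, match="absent"):
            run_differential(res.matrix, "Control", "Mock")

    def test_adding_constant_to_one_group_shifts_log2fc(self):
        rng = np.random.default_rng(30)
        vals = rng.normal(20, 1, size=(40, 6))
        qm = biorep_matrix(vals, ["A"] * 3 + ["B"] * 3, ["r1", "r2", "r3"] * 2,
                           log2=True)
        shifted = vals.copy()
        shifted[:, 3:] += 1.5
        qm2 = biorep_matrix(shifted, ["A"] * 3 + ["B"] * 3, ["r1", "r2", "r3"] * 2,
                            log2=True)
        de1 = run_differential(qm, "A", "B").set_index("protein_id")
        de2 = run_differential(qm2, "A", "B").set_index("protein_id")
        assert np.allclose(de2["log2fc"] - de1["log2fc"], 1.5, atol=1e-12)
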