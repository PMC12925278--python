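"""Aggregation, missingness filtering, median imputation, log2 normalization."""

import numpy as np
import pandas as pd
import pytest

from infosome_lfq.io import MatrixError, QuantMatrix
from infosome_lfq.quantify import (
    aggregate_fractions,
    aggregate_technical,
    filter_missingness,
    impute_median,
    log2_and_normalize,
    quantify_pipeline,
)
from infosome_lfq.simulate import SimulationConfig, simulate

from conftest import biorep_matrix, make_design

NA = np.nan


def run_matrix(values, design, protein_ids=None):
    values = np.asarray(values, dtype=float)
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(values.shape[0])]
    return QuantMatrix(pd.DataFrame(values, index=protein_ids,
                                    columns=design.run_ids), level="run")


class TestAggregateTechnical:
    design = make_design([("a", "G", "r1", 1, 1), ("b", "G", "r1", 1, 2)])

    @pytest.mark.parametrize("tech,expected", [
        ((2.0, 4.0), 3.0),       # arithmetic mean
        ((NA, 4.0), 4.0),        # mean of observed only
        ((NA, NA), NA),          # missing iff all injections missing
    ])
    def test_fraction_is_mean_of_observed_injections(self, tech, expected):
        qm = run_matrix([tech], self.design)
        out = aggregate_technical(qm, self.design)
        got = out.data.iloc[0, 0]
        assert got == expected if not np.isnan(expected) else np.isnan(got)

    def test_run_without_design_row_is_error(self):
        qm = QuantMatrix(pd.DataFrame([[1.0]], index=["P0"], columns=["ghost"]))
        with pytest.raises(MatrixError, match="ghost"):
            aggregate_technical(qm, self.design)

    def test_permutation_invariant_within_fraction(self):
        d1 = make_design([("a", "G", "r1", 1, 1), ("b", "G", "r1", 1, 2),
                          ("c", "G", "r1", 2, 1)])
        qm = run_matrix([[2.0, 4.0, 7.0]], d1)
        swapped = QuantMatrix(qm.data[["b", "a", "c"]], level="run")
        out1 = aggregate_technical(qm, d1)
        out2 = aggregate_technical(swapped, d1)
        pd.testing.assert_frame_equal(out1.data, out2.data)


class TestAggregateFractions:
    def _fraction_matrix(self, values, fractions):
        cols = pd.MultiIndex.from_tuples([("G", "r1", f) for f in fractions],
                                         names=["group", "bio_rep", "fraction"])
        return QuantMatrix(pd.DataFrame([values], index=["P0"], columns=cols),
                           level="fraction")

    @pytest.mark.parametrize("vals,expected", [
        ((3.0, 5.0), 8.0),                 # plain sum
        ((3.0, NA, 2.0, NA), 5.0),         # sum of observed fractions
        ((NA, NA), NA),                    # all missing stays missing
    ])
    def test_biorep_is_sum_of_observed_fractions(self, vals, expected):
        qm = self._fraction_matrix(vals, range(1, len(vals) + 1))
        out = aggregate_fractions(qm, design=None)
        got = out.data.iloc[0, 0]
        assert got == expected if not np.isnan(expected) else np.isnan(got)

    def test_unequal_fraction_counts_per_group(self, two_group_design):
        sim = simulate(SimulationConfig(n_proteins=5, seed=2))
        fr = aggregate_technical(sim.matrix, sim.design)
        out = aggregate_fractions(fr, sim.design)
        # 3 bio reps per group regardless of 2-vs-4 fractionation
        assert out.data.shape[1] == 6
        assert list(out.data.columns.get_level_values("group")).count("LN") == 3


class TestFilterMissingness:
    @pytest.mark.parametrize("row,kept", [
        # groups of 3 bio reps each: A = first 3 columns, B = last 3
        ([1.0, NA, NA, NA, NA, NA], True),    # 1/3 observed in A: 66.7% <= 70%
        ([NA, NA, NA, NA, NA, NA], False),    # 100% missing everywhere
        ([NA, NA, NA, 2.0, 3.0, 4.0], True),  # complete in B only
    ])
    def test_seventy_percent_rule_with_three_reps(self, row, kept):
        qm = biorep_matrix([row], ["A"] * 3 + ["B"] * 3, ["r1", "r2", "r3"] * 2)
        filtered, excluded = filter_missingness(qm, max_missing_frac=0.70)
        assert ("P0" in filtered.protein_ids) is kept
        assert ("P0" in excluded) is not kept

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(size=(50, 6))
        vals[rng.random((50, 6)) < 0.5] = NA
        qm = biorep_matrix(vals, ["A"] * 3 + ["B"] * 3, ["r1", "r2", "r3"] * 2)
        previous: set = set()
        for thr in (0.0, 0.34, 0.67, 1.0):
            kept = set(filter_missingness(qm, max_missing_frac=thr)[0].protein_ids)
            assert previous <= kept  # larger threshold retains a superset
            previous = kept


class TestImputeMedian:
    @pytest.mark.parametrize("group_vals,expected", [
        ((4.0, NA, 6.0), (4.0, 5.0, 6.0)),
        ((7.0, 7.0, NA), (7.0, 7.0, 7.0)),
    ])
    def test_within_group_median(self, group_vals, expected):
        qm = biorep_matrix([list(group_vals) + [1.0, 1.0, 1.0]],
                           ["A"] * 3 + ["B"] * 3, ["r1", "r2", "r3"] * 2)
        out = impute_median(qm)
        assert tuple(out.data.iloc[0, :3]) == expected

    def test_cross_sample_fallback_for_empty_group(self):
        qm = biorep_matrix([[NA, NA, NA, 2.0, 4.0, 8.0]],
                           ["A"] * 3 + ["B"] * 3, ["r1", "r2", "r3"] * 2)
        out = impute_median(qm)
        assert tuple(out.data.iloc[0, :3]) == (4.0, 4.0, 4.0)

    def test_observed_cells_untouched_and_output_complete(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(size=(30, 6))
        mask = rng.random((30, 6)) < 0.3
        vals[mask] = NA
        vals[:, 0] = 1.0  # guarantee an observation per protein
        qm = biorep_matrix(vals, ["A"] * 3 + ["B"] * 3, ["r1", "r2", "r3"] * 2)
        out = impute_median(qm)
        assert out.n_missing == 0
        observed = ~np.isnan(vals)
        assert np.array_equal(out.data.to_numpy()[observed], vals[observed])

    def test_protein_with_no_observation_is_error(self):
        qm = biorep_matrix([[NA, NA, NA, NA]], ["A", "A", "B", "B"],
                           ["r1", "r2", "r1", "r2"])
        with pytest.raises(MatrixError, match="zero observations"):
            impute_median(qm)


class TestLog2AndNormalize:
    def test_shifts_align_to_highest_median(self):
        # sample medians in log2: 10 and 12 -> shifts (+2, 0)
        qm = biorep_matrix([[2.0**9, 2.0**11], [2.0**10, 2.0**12], [2.0**11, 2.0**13]],
                           ["A", "B"], ["r1", "r1"])
        out, shifts = log2_and_normalize(qm)
        assert tuple(shifts) == (2.0, 0.0)
        assert tuple(out.data.median(axis=0)) == (12.0, 12.0)

    def test_identical_samples_are_identity(self):
        qm = biorep_matrix([[4.0, 4.0], [16.0, 16.0]], ["A", "B"], ["r1", "r1"])
        out, shifts = log2_and_normalize(qm)
        assert (shifts == 0).all()
        assert np.array_equal(out.data.to_numpy(), np.log2(qm.data.to_numpy()))

    def test_post_medians_equal_max_pre_median(self):
        rng = np.random.default_rng(6)
        qm = biorep_matrix(rng.lognormal(10, 1, size=(50, 6)),
                           ["A"] * 3 + ["B"] * 3, ["r1", "r2", "r3"] * 2)
        log2d = np.log2(qm.data)
        target = log2d.median(axis=0).max()
        out, _ = log2_and_normalize(qm)
        assert np.allclose(out.data.median(axis=0), target, atol=1e-9)

    def test_within_sample_differences_preserved(self):
        rng = np.random.default_rng(7)
        qm = biorep_matrix(rng.lognormal(10, 1, size=(20, 4)),
                           ["A", "A", "B", "B"], ["r1", "r2", "r1", "r2"])
        out, _ = log2_and_normalize(qm)
        log2d = np.log2(qm.data.to_numpy())
        diffs_before = log2d[1:] - log2d[:-1]
        diffs_after = out.data.to_numpy()[1:] - out.data.to_numpy()[:-1]
        assert np.allclose(diffs_before, diffs_after, atol=1e-12)

    def test_missing_or_nonpositive_values_rejected(self):
        with pytest.raises(MatrixError, match="missing"):
            log2_and_normalize(biorep_matrix([[1.0, NA]], ["A", "B"], ["r1", "r1"]))
        with pytest.raises(MatrixError, match="non-positive"):
            log2_and_normalize(biorep_matrix([[1.0, 0.0]], ["A", "B"], ["r1", "r1"],
                                             log2=True))


def test_pipeline_is_deterministic():
    sim = simulate(SimulationConfig(n_proteins=100, seed=9))
    r1 = quantify_pipeline(sim.matrix, sim.design)
    r2 = quantify_pipeline(sim.matrix, sim.design)
    pd.testing.assert_frame_equal(r1.matrix.data, r2.matrix.data)
    assert r1.excluded == r2.excluded
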