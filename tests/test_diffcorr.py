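import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffcorrnet.diffcorr import (
    all_pairs,
    differential_statistic,
    diffstat_matrix,
    fisher_z,
    group_correlations,
    pairwise_pearson,
)
from diffcorrnet.phenotype import classify
from diffcorrnet.preprocessing import preprocess
from diffcorrnet.simulate import SyntheticCohortSpec, generate_cohort

finite_r = st.floats(min_value=-0.99, max_value=0.99)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_at_half(self):
        # z(0.5) = (1/2) ln(3)
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3.0), rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(r=finite_r)
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_extremes_stay_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert np.isfinite(fisher_z(-1.0))

    def test_nonfinite_input_raises(self):
        with pytest.raises(ValueError):
            fisher_z(float("nan"))


class TestDifferentialStatistic:
    def test_hand_computed_reference(self):
        # (1/2)ln(3) / sqrt(1/64 + 1/375), computed independently of numpy
        expected = (0.5 * math.log(3.0)) / math.sqrt(1.0 / 64.0 + 1.0 / 375.0)
        got = differential_statistic(0.5, 0.0, 67, 378)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_zero_when_correlations_equal(self):
        assert differential_statistic(0.37, 0.37, 50, 80) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(rc=finite_r, rr=finite_r,
           n1=st.integers(min_value=5, max_value=500),
           n2=st.integers(min_value=5, max_value=500))
    def test_antisymmetric_under_group_swap(self, rc, rr, n1, n2):
        a = differential_statistic(rc, rr, n1, n2)
        b = differential_statistic(rr, rc, n2, n1)
        assert a == pytest.approx(-b, abs=1e-12)

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match="exceed 3"):
            differential_statistic(0.5, 0.0, 3, 100)


class TestPairwisePearson:
    def test_matches_numpy_on_complete_data(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, 5))
        r, n = pairwise_pearson(x)
        np.testing.assert_allclose(r, np.corrcoef(x, rowvar=False), atol=1e-12)
        assert (n == 40).all()

    def test_matches_pandas_pairwise_complete(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((60, 4))
        x[rng.random((60, 4)) < 0.15] = np.nan
        r, n = pairwise_pearson(x)
        expected = pd.DataFrame(x).corr(min_periods=4).to_numpy()
        np.testing.assert_allclose(r, expected, atol=1e-10)

    def test_pairwise_counts_equal_joint_observations(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 3))
        x[:5, 0] = np.nan
        x[3:10, 1] = np.nan
        _, n = pairwise_pearson(x)
        finite = ~np.isnan(x)
        for i in range(3):
            for j in range(3):
                assert n[i, j] == (finite[:, i] & finite[:, j]).sum()

    def test_collinear_pair_is_one(self):
        x = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0) + 3.0])
        r, _ = pairwise_pearson(x)
        assert r[0, 1] == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        r, _ = pairwise_pearson(x)
        assert np.isnan(r[0, 1])


class TestAllPairs:
    def test_pair_count_and_ordering(self, small_null_pipeline):
        matrix, labels = small_null_pipeline
        edges = all_pairs(matrix, labels, "pain")
        m = matrix.shape[1]
        assert len(edges) == m * (m - 1) // 2
        assert (edges["metabolite_i"] < edges["metabolite_j"]).all()
        ordered = edges.sort_values(
            ["metabolite_i", "metabolite_j"], kind="stable"
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(edges, ordered)

    def test_two_metabolites_one_pair(self):
        spec = SyntheticCohortSpec(
            n_case=10, n_control=12, n_metabolites=2, n_lod_metabolites=0,
            lod_fraction=0.0, missing_fraction=0.0, outlier_fraction=0.0, seed=3,
        )
        cohort = generate_cohort(spec)
        matrix, _ = preprocess(cohort.concentrations)
        labels = classify(cohort.outcomes)
        assert len(all_pairs(matrix, labels, "pain")) == 1

    def test_sign_matches_r_diff(self, small_null_pipeline):
        matrix, labels = small_null_pipeline
        edges = all_pairs(matrix, labels, "pain")
        pos = edges["r_diff"] > 0
        assert (edges.loc[pos, "sign"] == "positive").all()
        assert (edges.loc[~pos & (edges["r_diff"] < 0), "sign"] == "negative").all()

    def test_affine_invariance_of_r_diff(self, small_null_cohort):
        # Pearson correlation is affine-invariant, hence so is r_diff
        matrix, _ = preprocess(small_null_cohort.concentrations)
        labels = classify(small_null_cohort.outcomes)
        base = all_pairs(matrix, labels, "pain")
        rng = np.random.default_rng(7)
        scaled = matrix.copy()
        scale = rng.uniform(0.5, 3.0, size=scaled.shape[1])
        shift = rng.uniform(-2.0, 2.0, size=scaled.shape[1])
        scaled.values.iloc[:, :] = scaled.values.to_numpy() * scale + shift
        transformed = all_pairs(scaled, labels, "pain")
        np.testing.assert_allclose(
            base["r_diff"].to_numpy(), transformed["r_diff"].to_numpy(), atol=1e-9
        )


class TestGroupCorrelations:
    def test_planted_correlations_recovered_at_large_n(self):
        spec = SyntheticCohortSpec(
            n_case=500, n_control=500, n_metabolites=6,
            planted_edges=((0, 1, 0.8, 0.0),), background_r=0.0,
            n_lod_metabolites=0, lod_fraction=0.0, missing_fraction=0.0,
            outlier_fraction=0.0, seed=21,
        )
        cohort = generate_cohort(spec)
        matrix, _ = preprocess(cohort.concentrations)
        labels = classify(cohort.outcomes)
        case, control = group_correlations(matrix, labels, "pain")
        se = 1.0 / math.sqrt(500 - 3)  # Fisher-scale standard error
        assert abs(fisher_z(case.r.iloc[0, 1]) - fisher_z(0.8)) < 3 * se
        assert abs(fisher_z(control.r.iloc[0, 1]) - fisher_z(0.0)) < 3 * se

    def test_symmetric_unit_diagonal(self, small_null_pipeline):
        matrix, labels = small_null_pipeline
        case, control = group_correlations(matrix, labels, "pain")
        for gc in (case, control):
            r = gc.r.to_numpy()
            np.testing.assert_allclose(r, r.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(r), 1.0)

    def test_group_too_small_raises(self):
        spec = SyntheticCohortSpec(
            n_case=4, n_control=10, n_metabolites=3, n_lod_metabolites=0,
            lod_fraction=0.0, missing_fraction=0.0, outlier_fraction=0.0, seed=4,
        )
        cohort = generate_cohort(spec)
        matrix, _ = preprocess(cohort.concentrations)
        labels = classify(cohort.outcomes)
        # drop one case to go below the minimum of 4
        keep = labels.frame.index[1:]
        labels.frame = labels.frame.loc[keep]
        with pytest.raises(ValueError, match="at least 4"):
            group_correlations(matrix, labels, "pain")


class TestNullDistribution:
    def test_r_diff_approximately_standard_normal_under_null(self):
        # paired null groups of 100 samples; r_diff over replicates should be
        # close to N(0, 1)
        rng = np.random.default_rng(42)
        n, reps = 100, 2000
        stats = np.empty(reps)
        for k in range(reps):
            a = rng.standard_normal((n, 2))
            b = rng.standard_normal((n, 2))
            r_a = np.corrcoef(a, rowvar=False)[0, 1]
            r_b = np.corrcoef(b, rowvar=False)[0, 1]
            stats[k] = differential_statistic(r_a, r_b, n, n)
        assert abs(stats.mean()) < 0.05
        assert 0.9 < stats.std(ddof=1) < 1.1


class TestDiffstatMatrix:
    def test_unusable_pairs_are_nan(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((20, 3))
        x[:, 2] = 1.0  # zero variance
        case_mask = np.zeros(20, dtype=bool)
        case_mask[:8] = True
        stat = diffstat_matrix(x, case_mask)[0]
        assert np.isfinite(stat[0, 1])
        assert np.isnan(stat[0, 2]) and np.isnan(stat[1, 2])
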