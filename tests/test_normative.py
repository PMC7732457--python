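"""Normative reference fitting: FC construction, moments, exclusion mask."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connanomaly.normative import (
    ConnectivityMatrix,
    Modality,
    Representation,
    edge_matrix,
    edge_vector,
    excluded_count,
    fc_from_timeseries,
    fit_normative,
    n_edges,
    variance_exclusion_mask,
)
from conftest import functional_matrix, structural_matrix


class TestFcFromTimeseries:
    def test_default_atlas_entry_count(self, rng):
        series = rng.normal(size=(40, 379))
        fc = fc_from_timeseries(series)
        assert fc.values.size == 143_641  # 379^2 correlations

    def test_identical_columns_give_unit_correlation(self, rng):
        x = rng.normal(size=30)
        fc = fc_from_timeseries(np.column_stack([x, x, rng.normal(size=30)]))
        assert fc.values[0, 1] == pytest.approx(1.0)

    def test_antipodal_columns_give_minus_one(self, rng):
        x = rng.normal(size=30)
        fc = fc_from_timeseries(np.column_stack([x, -x]))
        assert fc.values[0, 1] == pytest.approx(-1.0)

    def test_constant_column_names_region(self, rng):
        series = rng.normal(size=(30, 3))
        series[:, 1] = 7.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            fc_from_timeseries(series)

    def test_too_few_timepoints(self, rng):
        with pytest.raises(ValueError, match="2 timepoints"):
            fc_from_timeseries(rng.normal(size=(1, 5)))

    def test_output_is_valid_correlation_matrix(self, rng):
        fc = fc_from_timeseries(rng.normal(size=(25, 8)))
        assert np.allclose(np.diag(fc.values), 1.0)
        assert np.array_equal(fc.values, fc.values.T)
        assert fc.values.min() >= -1.0 and fc.values.max() <= 1.0


class TestVarianceExclusionMask:
    def test_top_third_of_six(self):
        mask = variance_exclusion_mask(np.array([1., 2., 3., 4., 5., 6.]), 1 / 3)
        assert mask.tolist() == [False, False, False, False, True, True]

    def test_fraction_zero_excludes_nothing(self):
        assert not variance_exclusion_mask(np.arange(6.0), 0.0).any()

    def test_ties_broken_by_ascending_index(self):
        mask = variance_exclusion_mask(np.ones(6), 1 / 3)
        assert mask.tolist() == [True, True, False, False, False, False]

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            variance_exclusion_mask(np.arange(6.0), 1.0)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False),
                    min_size=1, max_size=60),
           st.floats(min_value=0, max_value=0.99))
    def test_count_and_dominance_properties(self, variances, fraction):
        v = np.array(variances)
        mask = variance_exclusion_mask(v, fraction)
        assert mask.sum() == excluded_count(fraction, v.size)
        if mask.any() and (~mask).any():
            assert v[mask].min() >= v[~mask].max()


class TestFitNormative:
    def _sc_cohort(self, rng, n_subjects=10, n=4):
        i, j = np.triu_indices(n, 1)
        cohort = []
        for s in range(n_subjects):
            vals = rng.poisson(50, size=i.size).astype(float)
            cohort.append(structural_matrix(f"c{s}", edge_matrix(vals, n)))
        return cohort

    def test_cohort_too_small(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            fit_normative(self._sc_cohort(rng, n_subjects=2))

    def test_mixed_modalities_rejected(self, rng):
        cohort = self._sc_cohort(rng, 3)
        cohort.append(functional_matrix("f", np.eye(4)))
        with pytest.raises(ValueError, match="mixed"):
            fit_normative(cohort)

    def test_constant_edge_is_degenerate(self, rng):
        cohort = self._sc_cohort(rng, 8)
        for c in cohort:
            c.values[0, 1] = c.values[1, 0] = 12.0
        ref = fit_normative(cohort)
        assert ref.sigma[0] == 0.0
        assert ref.degenerate_mask[0]

    def test_gaussian_moments_recovered(self):
        """Monte-Carlo: per-edge mean/sd of a Gaussian(50, 2) edge within 3 SE."""
        rng = np.random.default_rng(777)
        n_subj, mu, sigma = 1000, 50.0, 2.0
        cohort = []
        for s in range(n_subj):
            vals = rng.normal(mu, sigma, size=6)
            cohort.append(structural_matrix(f"c{s}", edge_matrix(vals, 4)))
        ref = fit_normative(cohort, representation=Representation.RAW_COUNT)
        se_mu = sigma / np.sqrt(n_subj)
        se_sd = sigma / np.sqrt(2 * n_subj)
        assert np.abs(ref.mu - mu).max() < 3 * se_mu * 2  # 6 edges, allow a margin
        assert np.abs(ref.sigma - sigma).max() < 3 * se_sd * 2

    def test_toy_exclusion_count_and_ranking(self, rng):
        cohort = self._sc_cohort(rng, 12)
        ref = fit_normative(cohort, exclusion_fraction=1 / 3)
        assert n_edges(4) == 6 and ref.excluded_mask.sum() == 2
        stack = np.stack([np.log1p(edge_vector(c.values)) for c in cohort])
        var = stack.var(axis=0, ddof=1)
        assert set(np.flatnonzero(ref.excluded_mask)) == set(np.argsort(-var)[:2])

    def test_subject_order_invariance(self, rng):
        cohort = self._sc_cohort(rng, 9)
        ref1 = fit_normative(cohort)
        ref2 = fit_normative(cohort[::-1])
        assert np.allclose(ref1.mu, ref2.mu)
        assert np.allclose(ref1.sigma, ref2.sigma)
        assert np.array_equal(ref1.excluded_mask, ref2.excluded_mask)

    def test_excluded_plus_retained_partition(self, rng):
        cohort = self._sc_cohort(rng, 10, n=6)
        ref = fit_normative(cohort)
        m = n_edges(6)
        assert ref.excluded_mask.sum() + (~ref.excluded_mask).sum() == m

    def test_log1p_monotone_in_counts(self, rng):
        cohort = self._sc_cohort(rng, 5)
        ref = fit_normative(cohort)
        low = structural_matrix("s", edge_matrix(np.full(6, 10.0), 4))
        high = structural_matrix("s", edge_matrix(np.full(6, 11.0), 4))
        assert (ref.transform(high) >= ref.transform(low)).all()

    def _fc_cohort(self, rng, n_subjects=8, n=6, t=40):
        return [fc_from_timeseries(rng.normal(size=(t, n)), f"c{s}")
                for s in range(n_subjects)]

    def test_functional_tangent_mean_near_zero(self, rng):
        """With the geometric mean as reference, control tangent coefficients
        average to ~0 edge-wise (the Karcher stationarity condition)."""
        cohort = self._fc_cohort(rng)
        ref = fit_normative(cohort)
        assert ref.representation is Representation.TANGENT
        assert np.abs(ref.mu).max() < 1e-6

    def test_functional_reference_is_spd(self, rng):
        ref = fit_normative(self._fc_cohort(rng))
        w = np.linalg.eigvalsh(ref.reference_matrix)
        assert w.min() > 0

    def test_rank_deficient_functional_cohort_fits(self, rng):
        # 6 regions, 5 timepoints: every correlation matrix is singular
        cohort = self._fc_cohort(rng, n_subjects=6, n=6, t=5)
        ref = fit_normative(cohort)
        assert np.isfinite(ref.mu).all() and np.isfinite(ref.sigma).all()


class TestConnectivityMatrix:
    def test_symmetrized_within_tolerance(self):
        v = np.array([[0.0, 1.0], [1.0 + 1e-9, 0.0]])
        cm = structural_matrix("s", v)
        assert cm.values[0, 1] == cm.values[1, 0]

    def test_asymmetry_rejected(self):
        v = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="asymmetry"):
            structural_matrix("s", v)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            structural_matrix("s", np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_functional_diagonal_forced_to_one(self):
        v = np.array([[0.5, 0.2], [0.2, 0.5]])
        cm = functional_matrix("s", v)
        assert np.allclose(np.diag(cm.values), 1.0)
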