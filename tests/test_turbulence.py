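import numpy as np
import pytest

from neuroturb.io import Parcellation, euclidean_distances
from neuroturb.phases import PhaseMatrix
from neuroturb.synth import PhaseFieldSpec, gen_parcellation, gen_phase_field
from neuroturb.turbulence import (
    DEFAULT_LAMBDAS,
    LocalOrderField,
    TransferFitError,
    amplitude_turbulence,
    cascade_flow,
    information_cascade,
    information_transfer,
    kernel,
    local_order,
    node_level_turbulence,
    scan_scales,
    windowed_lambda_fit,
)

from . import oracles
from .conftest import make_distance_matrix


def phases_for(dist, rng, n_time=40):
    return PhaseMatrix(
        rng.uniform(0, 2 * np.pi, size=(dist.n_nodes, n_time)), tr_seconds=2.0
    )


class TestKernel:
    def test_known_weight_at_100mm(self):
        dist = make_distance_matrix([[0, 0, 0], [100.0, 0, 0]])
        k = kernel(dist, 0.01)
        assert k.weights[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)
        assert k.weights[0, 0] == 1.0  # self-term r=0

    def test_lambda_to_zero_limit(self, small_distances):
        k = kernel(small_distances, 1e-12)
        np.testing.assert_allclose(k.weights, 1.0, atol=1e-9)

    def test_normalized_rows_sum_to_one(self, small_distances):
        k = kernel(small_distances, 0.05)
        np.testing.assert_allclose(k.normalized.sum(axis=1), 1.0, atol=1e-12)

    def test_nonpositive_lambda_rejected(self, small_distances):
        with pytest.raises(ValueError):
            kernel(small_distances, 0.0)


class TestLocalOrder:
    def test_uniform_phases_give_full_synchrony(self, small_distances, rng):
        phases = PhaseMatrix(
            np.broadcast_to(rng.uniform(0, 2 * np.pi, 30), (20, 30)).copy(), 2.0
        )
        R = local_order(phases, kernel(small_distances, 0.05)).R
        np.testing.assert_allclose(R, 1.0, atol=1e-12)

    def test_two_node_antiphase_closed_form(self):
        """Two antiphase nodes: R = (1-w)/(1+w) where w is the cross weight."""
        for sep, lam in [(10.0, 0.05), (20.0, 0.1), (5.0, 0.3)]:
            dist = make_distance_matrix([[0, 0, 0], [sep, 0, 0]])
            w = np.exp(-lam * sep)
            phases = PhaseMatrix(np.array([[0.0] * 8, [np.pi] * 8]), 2.0)
            R = local_order(phases, kernel(dist, lam)).R
            np.testing.assert_allclose(R, (1 - w) / (1 + w), atol=1e-12)

    def test_matches_brute_force(self, rng):
        parc = gen_parcellation(15, seed=1)
        dist = euclidean_distances(parc)
        phases = phases_for(dist, rng)
        R = local_order(phases, kernel(dist, 0.08)).R
        np.testing.assert_allclose(
            R, oracles.local_order(phases.phases, dist.r, 0.08), atol=1e-12
        )

    def test_global_phase_shift_invariance(self, small_distances, rng):
        phases = phases_for(small_distances, rng)
        shifted = PhaseMatrix(phases.phases + 1.234, 2.0)
        k = kernel(small_distances, 0.05)
        np.testing.assert_allclose(
            local_order(phases, k).R, local_order(shifted, k).R, atol=1e-12
        )

    def test_shape_mismatch_rejected(self, small_distances, rng):
        phases = PhaseMatrix(rng.uniform(0, 1, (5, 10)), 2.0)
        with pytest.raises(ValueError, match="nodes"):
            local_order(phases, kernel(small_distances, 0.05))


class TestAmplitudeTurbulence:
    def test_constant_field_is_zero(self):
        assert amplitude_turbulence(
            LocalOrderField(np.full((4, 9), 0.7), 0.1)
        ) == pytest.approx(0.0, abs=1e-15)

    def test_fair_bernoulli_field(self):
        R = np.zeros((2, 10))
        R[1] = 1.0
        assert amplitude_turbulence(LocalOrderField(R, 0.1)) == pytest.approx(0.5)

    def test_matches_population_std_oracle(self, rng):
        R = rng.uniform(0, 1, size=(15, 40))
        assert amplitude_turbulence(LocalOrderField(R, 0.1)) == pytest.approx(
            oracles.population_std(R), abs=1e-12
        )

    def test_bounded_by_half(self, rng):
        for _ in range(5):
            R = rng.uniform(0, 1, size=(10, 20))
            assert 0 <= amplitude_turbulence(LocalOrderField(R, 0.1)) <= 0.5


class TestNodeLevelTurbulence:
    def test_constant_node_is_zero_and_alternating_is_half(self):
        R = np.vstack([np.full(10, 0.3), np.tile([0.0, 1.0], 5)])
        out = node_level_turbulence(LocalOrderField(R, 0.1))
        np.testing.assert_allclose(out, [0.0, 0.5], atol=1e-15)

    def test_matches_per_row_oracle(self, rng):
        R = rng.uniform(0, 1, size=(15, 50))
        np.testing.assert_allclose(
            node_level_turbulence(LocalOrderField(R, 0.1)),
            oracles.node_std(R),
            atol=1e-12,
        )


class TestInformationTransfer:
    def test_exact_power_law_recovered(self):
        """Binned corr(r) = (r/r0)^-0.5 exactly over the fit range -> A=-0.5."""
        # two nodes per distance: construct correlations analytically via
        # a synthetic binned-correlation curve fed through the same bins
        rng = np.random.default_rng(5)
        n = 40
        T = 6000
        coords = np.zeros((n, 3))
        coords[:, 0] = np.linspace(0, 60, n)
        dist = make_distance_matrix(coords)
        # common field with correlation depending only on distance:
        # Gaussian process over nodes with cov = (r/10)^-0.5 clipped
        r = dist.r
        with np.errstate(divide="ignore"):
            cov = np.where(r > 0, np.minimum((r / 10.0) ** -0.5, 1.0), 1.0)
        # make positive definite
        w, V = np.linalg.eigh(cov)
        cov_pd = (V * np.maximum(w, 1e-6)) @ V.T
        d = np.sqrt(np.diag(cov_pd))
        cov_pd = cov_pd / np.outer(d, d)
        L = np.linalg.cholesky(cov_pd)
        R = 0.5 + 0.1 * (L @ rng.standard_normal((n, T)))
        field = LocalOrderField(np.clip(R, 0, 1), 0.05)
        fit = information_transfer(field, dist, fit_range_mm=(10, 40), n_bins=30)
        assert fit.transfer == pytest.approx(0.5, abs=0.05)
        assert fit.slope == pytest.approx(-0.5, abs=0.05)

    def test_constant_correlation_gives_zero_slope(self, rng):
        """corr(r) flat in r -> A = 0, transfer = 0."""
        n, T = 20, 3000
        coords = np.column_stack([np.linspace(0, 60, n), np.zeros(n), np.zeros(n)])
        dist = make_distance_matrix(coords)
        s = rng.standard_normal(T)
        e = rng.standard_normal((n, T))
        R = np.clip(0.5 + 0.05 * (np.sqrt(0.5) * s + np.sqrt(0.5) * e), 0, 1)
        fit = information_transfer(
            LocalOrderField(R, 0.05), dist, fit_range_mm=(5, 55), n_bins=10
        )
        assert fit.slope == pytest.approx(0.0, abs=0.06)

    def test_slope_matches_normal_equations_oracle(self, rng):
        parc = gen_parcellation(18, seed=3)
        dist = euclidean_distances(parc)
        R = rng.uniform(0.2, 0.8, size=(18, 50))
        field = LocalOrderField(R, 0.05)
        n_bins = 8
        fit_range = (dist.offdiag().min(), dist.offdiag().max())
        centers, means, counts = oracles.binned_pair_correlation(R, dist.r, n_bins)
        usable = (
            (centers >= fit_range[0])
            & (centers <= fit_range[1])
            & (counts > 0)
            & (means > 0)
        )
        slope, intercept = oracles.loglog_slope(centers[usable], means[usable])
        fit = information_transfer(field, dist, fit_range, n_bins)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.transfer == pytest.approx(-slope, abs=1e-10)

    def test_too_few_bins_raises(self, rng):
        dist = make_distance_matrix([[0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]])
        R = rng.uniform(0, 1, size=(3, 30))
        with pytest.raises(TransferFitError):
            information_transfer(LocalOrderField(R, 0.05), dist, (100, 200), 5)


class TestCascadeFlow:
    def test_exact_shift_gives_unit_flow(self, rng):
        R_lo = rng.uniform(0.1, 0.9, size=(6, 40))
        R_hi = np.roll(R_lo, 1, axis=1)  # hi(t+1) == lo(t)
        flow = cascade_flow(
            LocalOrderField(R_hi, 0.04), LocalOrderField(R_lo, 0.01), 1
        )
        assert flow == pytest.approx(1.0, abs=1e-12)

    def test_independent_fields_near_zero(self, rng):
        T = 400
        a = LocalOrderField(rng.uniform(0, 1, (8, T)), 0.04)
        b = LocalOrderField(rng.uniform(0, 1, (8, T)), 0.01)
        assert abs(cascade_flow(a, b, 1)) < 3 / np.sqrt(T)

    def test_matches_brute_force(self, rng):
        a = LocalOrderField(rng.uniform(0, 1, (2, 30)), 0.04)
        b = LocalOrderField(rng.uniform(0, 1, (2, 30)), 0.01)
        assert cascade_flow(a, b, 1) == pytest.approx(
            oracles.cascade_flow(a.R, b.R, 1), abs=1e-12
        )

    def test_constant_node_skipped_with_warning(self, rng):
        R_hi = rng.uniform(0, 1, (3, 30))
        R_lo = rng.uniform(0, 1, (3, 30))
        R_hi[0] = 0.5
        with pytest.warns(UserWarning, match="zero temporal variance"):
            flow = cascade_flow(
                LocalOrderField(R_hi, 0.04), LocalOrderField(R_lo, 0.01), 1
            )
        assert np.isfinite(flow)


class TestInformationCascade:
    def test_mean_of_flows(self):
        assert information_cascade([0.2, 0.4]) == pytest.approx(0.3)
        assert information_cascade([0.7] * 5) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            information_cascade([])


class TestScanScales:
    def test_default_grid_shapes(self, rng):
        parc = gen_parcellation(25, seed=9)
        dist = euclidean_distances(parc)
        phases = gen_phase_field(parc, PhaseFieldSpec(seed=2), 60)
        scan = scan_scales(
            PhaseMatrix(phases, 2.0), dist, n_bins=10,
            fit_range_mm=(5, 150), on_transfer_error="nan",
        )
        assert len(scan.lambdas) == 8
        assert scan.lambdas[0] == 0.01 and scan.lambdas[-1] == 0.21
        assert len(scan.cascade_flows) == 7
        assert scan.node_turbulence.shape == (8, 25)
        assert np.isfinite(scan.information_cascade)

    def test_single_lambda_has_no_cascade(self, rng):
        parc = gen_parcellation(25, seed=9)
        dist = euclidean_distances(parc)
        phases = PhaseMatrix(gen_phase_field(parc, PhaseFieldSpec(seed=2), 60), 2.0)
        scan = scan_scales(
            phases, dist, lambdas=(0.05,), n_bins=10,
            fit_range_mm=(5, 150), on_transfer_error="nan",
        )
        assert scan.turbulence.shape == (1,)
        assert scan.cascade_flows.size == 0

    def test_independent_of_evaluation_order(self, rng):
        """Each scale's measures equal the same computation done standalone."""
        parc = gen_parcellation(20, seed=4)
        dist = euclidean_distances(parc)
        phases = PhaseMatrix(gen_phase_field(parc, PhaseFieldSpec(seed=8), 50), 2.0)
        full = scan_scales(
            phases, dist, n_bins=8, fit_range_mm=(5, 150), on_transfer_error="nan"
        )
        for i, lam in enumerate(full.lambdas):
            solo = scan_scales(
                phases, dist, lambdas=(lam,), n_bins=8,
                fit_range_mm=(5, 150), on_transfer_error="nan",
            )
            assert solo.turbulence[0] == pytest.approx(full.turbulence[i], abs=1e-14)
            np.testing.assert_allclose(
                solo.node_turbulence[0], full.node_turbulence[i], atol=1e-14
            )

    def test_nonincreasing_grid_rejected(self, random_phases, small_distances):
        with pytest.raises(ValueError):
            scan_scales(random_phases, small_distances, lambdas=(0.1, 0.1))


class TestWindowedLambdaFit:
    def test_recovers_linear_profile(self):
        lambdas = np.array(DEFAULT_LAMBDAS)
        slope, intercept = windowed_lambda_fit(lambdas, 2.0 * lambdas + 1.0)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(1.0, abs=1e-12)
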