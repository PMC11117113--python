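import numpy as np
import pytest
from scipy import signal as sp_signal

from neuroturb.hopf import (
    HopfModelSpec,
    edr_coupling,
    estimate_frequencies,
    fc_by_distance,
    fit_global_coupling,
    simulate,
)
from neuroturb.io import ParcellatedSeries, euclidean_distances
from neuroturb.synth import gen_parcellation

from . import oracles
from .conftest import make_distance_matrix


def uncoupled_spec(a, omega=2 * np.pi * 0.05, n=2, noise=0.0, dt=0.02, seed=0):
    return HopfModelSpec(
        a=a, omega=omega, G=0.0, C=np.zeros((n, n)), noise_sd=noise,
        dt_seconds=dt, seed=seed,
    )


def estimated_radius(series):
    """Oscillation amplitude from the RMS of the recorded x-component."""
    return float(np.sqrt(2 * np.mean(series.values**2, axis=1)).mean())


class TestSimulate:
    def test_supercritical_radius_law(self):
        """a=0.25, no noise/coupling: |z| settles to sqrt(a)=0.5 within 1%."""
        series = simulate(uncoupled_spec(0.25), 200, 2.0, transient_seconds=300)
        assert estimated_radius(series) == pytest.approx(0.5, rel=0.01)

    def test_subcritical_decay_to_fixed_point(self):
        series = simulate(uncoupled_spec(-1.0), 50, 2.0, transient_seconds=100)
        assert np.abs(series.values).max() < 1e-3

    @pytest.mark.parametrize("a", [-0.5, 0.0, 0.25, 1.0])
    def test_radial_law_over_a_grid(self, a):
        # at criticality (a=0) the decay is algebraic, r(t) ~ 1/sqrt(2t), so
        # the transient must be long; explicit Euler also leaves a spurious
        # radius floor of omega*sqrt(dt/2), kept below tolerance via omega
        transient = 3000 if a == 0 else 400
        omega = 2 * np.pi * (0.01 if a == 0 else 0.05)
        series = simulate(
            uncoupled_spec(a, omega=omega), 150, 2.0, transient_seconds=transient
        )
        expected = np.sqrt(max(a, 0.0))
        assert estimated_radius(series) == pytest.approx(expected, abs=0.015)

    def test_limit_cycle_frequency(self):
        """a=1: dominant spectral peak of x at omega / 2 pi."""
        f0 = 0.05
        series = simulate(
            uncoupled_spec(1.0, omega=2 * np.pi * f0), 434, 2.0,
            transient_seconds=200,
        )
        freqs, pxx = sp_signal.periodogram(series.values[0], fs=0.5)
        assert freqs[np.argmax(pxx)] == pytest.approx(f0, abs=freqs[1] - freqs[0])

    def test_deterministic_in_seed(self):
        spec = uncoupled_spec(0.1, noise=0.01, seed=11)
        a = simulate(spec, 50, 2.0)
        b = simulate(spec, 50, 2.0)
        np.testing.assert_array_equal(a.values, b.values)

    def test_halving_dt_changes_amplitude_below_one_percent(self):
        r = [
            estimated_radius(
                simulate(uncoupled_spec(0.25, dt=dt), 200, 2.0, transient_seconds=300)
            )
            for dt in (0.1, 0.05)
        ]
        assert abs(r[1] - r[0]) / r[0] < 0.01

    def test_dt_larger_than_tr_rejected(self):
        with pytest.raises(ValueError):
            simulate(uncoupled_spec(0.1, dt=3.0), 20, 2.0)


class TestEstimateFrequencies:
    def test_sinusoid_peak_within_resolution(self):
        tr, T, f0 = 2.0, 434, 0.05
        t = np.arange(T) * tr
        x = np.vstack([np.cos(2 * np.pi * f0 * t), np.sin(2 * np.pi * f0 * t)])
        omega = estimate_frequencies(ParcellatedSeries(x, tr))
        df = 1.0 / (T * tr)
        np.testing.assert_allclose(omega / (2 * np.pi), f0, atol=df)

    def test_narrowband_noise_peak_inside_band(self, rng):
        tr, T = 2.0, 400
        freqs = np.fft.rfftfreq(T, tr)
        spectrum = np.where((freqs >= 0.04) & (freqs <= 0.06), 1.0, 0.0)
        x = np.vstack(
            [
                np.fft.irfft(
                    spectrum * np.exp(2j * np.pi * rng.uniform(size=freqs.size)), T
                )
                for _ in range(3)
            ]
        )
        omega = estimate_frequencies(ParcellatedSeries(x, tr), band_hz=(0.008, 0.08))
        f = omega / (2 * np.pi)
        assert ((f >= 0.035) & (f <= 0.065)).all()

    def test_identical_nodes_identical_estimates(self, rng):
        x = rng.standard_normal(200)
        omega = estimate_frequencies(ParcellatedSeries(np.vstack([x, x]), 2.0))
        assert omega[0] == omega[1]

    def test_flat_signal_rejected(self):
        x = np.vstack([np.ones(100), np.random.default_rng(0).standard_normal(100)])
        with pytest.raises(ValueError, match="flat"):
            estimate_frequencies(ParcellatedSeries(x, 2.0))


class TestFCByDistance:
    def test_identical_nodes_unit_fc(self):
        t = np.linspace(0, 1, 50)
        x = np.tile(np.sin(2 * np.pi * 3 * t), (4, 1))
        dist = make_distance_matrix(
            [[0, 0, 0], [10, 0, 0], [20, 0, 0], [40, 0, 0]]
        )
        fc = fc_by_distance(ParcellatedSeries(x, 2.0), dist, n_bins=3)
        filled = np.isfinite(fc.fc)
        np.testing.assert_allclose(fc.fc[filled], 1.0, atol=1e-12)
        np.testing.assert_allclose(fc.structure_function[filled], 0.0, atol=1e-12)

    def test_independent_nodes_near_zero_fc(self, rng):
        parc = gen_parcellation(20, seed=8)
        dist = euclidean_distances(parc)
        x = rng.standard_normal((20, 2000))
        fc = fc_by_distance(ParcellatedSeries(x, 2.0), dist, n_bins=5)
        ok = np.isfinite(fc.fc)
        assert np.abs(fc.fc[ok]).max() < 0.15
        np.testing.assert_allclose(fc.structure_function[ok], 2.0, atol=0.3)

    def test_matches_brute_force_binning(self, rng):
        parc = gen_parcellation(10, seed=9)
        dist = euclidean_distances(parc)
        x = rng.standard_normal((10, 40))
        fc = fc_by_distance(ParcellatedSeries(x, 2.0), dist, n_bins=6)
        centers, means, counts = oracles.binned_pair_correlation(x, dist.r, 6)
        np.testing.assert_allclose(fc.bin_centers_mm, centers, atol=1e-12)
        np.testing.assert_allclose(fc.fc, means, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(fc.bin_counts, counts)


class TestFitGlobalCoupling:
    @pytest.fixture(scope="class")
    def geometry(self):
        parc = gen_parcellation(40, seed=10)
        dist = euclidean_distances(parc)
        C = edr_coupling(dist)
        omega = 2 * np.pi * np.random.default_rng(1).uniform(0.04, 0.07, 40)
        base = HopfModelSpec(a=-0.02, omega=omega, G=0.0, C=C)
        return dist, base

    def test_single_value_grid(self, geometry):
        import dataclasses

        dist, base = geometry
        emp = [simulate(dataclasses.replace(base, G=0.8, seed=5), 100, 2.0,
                        subject_id="s0")]
        fit = fit_global_coupling(emp, dist, [0.7], base, n_sims=2, n_bins=12,
                                  fit_range_mm=(10, 60), seed=0)
        assert fit.g_opt == 0.7
        assert (fit.fit_distance >= 0).all()

    def test_recovers_generating_coupling_on_grid(self, geometry):
        dist, base = geometry
        import dataclasses
        gen = dataclasses.replace(base, G=1.0, seed=77)
        emp = [
            simulate(dataclasses.replace(gen, seed=77 + k), 150, 2.0,
                     subject_id=f"s{k}")
            for k in range(3)
        ]
        fit = fit_global_coupling(
            emp, dist, [0.0, 0.5, 1.0, 1.5, 2.0], base, n_sims=5,
            n_bins=15, fit_range_mm=(10, 60), seed=1,
        )
        assert fit.g_opt == 1.0
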