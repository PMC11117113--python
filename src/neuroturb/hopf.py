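"""Whole-brain model of coupled Stuart-Landau (Hopf normal form) oscillators.

Each node n obeys the normal form of a supercritical Hopf bifurcation with
bifurcation parameter a_n and intrinsic angular frequency omega_n, coupled
diffusively through a nonnegative matrix C scaled by a global coupling G:

    dx_n = [a_n x_n - (x_n^2 + y_n^2) x_n - omega_n y_n
            + G sum_p C_np (x_p - x_n)] dt + nu dW_n
    dy_n = [a_n y_n - (x_n^2 + y_n^2) y_n + omega_n x_n
            + G sum_p C_np (y_p - y_n)] dt + nu dW_n

For a_n < 0 an uncoupled noiseless node decays to the origin (noise-driven
fluctuations when nu > 0); for a_n > 0 it settles on a limit cycle of
radius sqrt(a_n) at frequency omega_n / 2 pi.  The default anatomical
coupling follows the exponential distance rule C_np = exp(-lambda_C r_np).

The model is fitted to data through the functional connectivity as a
function of distance, FC(r): the mean Pearson correlation of node pairs in
equal-width distance bins (equivalently Kolmogorov's structure function
S(r) = 2 (1 - FC(r)) under the correlation convention).  A grid sweep over
G picks the coupling whose simulated FC(r) is closest (Euclidean distance
over bins in the inertial subrange) to the empirical one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

from .io import DistanceMatrix, ParcellatedSeries
from .phases import DEFAULT_BAND_HZ
from .turbulence import DEFAULT_FIT_RANGE_MM, _binned_pair_statistic

__all__ = [
    "HopfModelSpec",
    "FCByDistance",
    "CouplingFitResult",
    "edr_coupling",
    "estimate_frequencies",
    "simulate",
    "fc_by_distance",
    "fit_global_coupling",
    "DEFAULT_EDR_LAMBDA",
]

#: Default decay rate (mm^-1) of the exponential-distance-rule coupling.
DEFAULT_EDR_LAMBDA = 0.18


class IntegrationError(RuntimeError):
    """Raised when the Euler-Maruyama trajectory blows up."""


@dataclass
class HopfModelSpec:
    """Parameters of the coupled-oscillator whole-brain model.

    ``a`` and ``omega`` broadcast over nodes; ``noise_sd`` is the additive
    Gaussian noise standard deviation nu (default 0.01); ``dt_seconds`` the
    Euler-Maruyama step.  ``C`` must be symmetric with zero diagonal.
    """

    a: np.ndarray | float
    omega: np.ndarray | float
    G: float
    C: np.ndarray
    noise_sd: float = 0.01
    dt_seconds: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = self.C.shape[0]
        if self.C.ndim != 2 or self.C.shape != (n, n):
            raise ValueError(f"C must be square, got shape {self.C.shape}")
        if not np.allclose(self.C, self.C.T):
            raise ValueError("coupling matrix must be symmetric")
        if (self.C < 0).any():
            raise ValueError("coupling weights must be nonnegative")
        if not np.allclose(np.diag(self.C), 0):
            raise ValueError("coupling matrix diagonal must be zero")
        self.a = np.broadcast_to(np.asarray(self.a, dtype=float), (n,)).copy()
        self.omega = np.broadcast_to(np.asarray(self.omega, dtype=float), (n,)).copy()
        if self.G < 0 or self.noise_sd < 0:
            raise ValueError("G and noise_sd must be nonnegative")
        if not self.dt_seconds > 0:
            raise ValueError("dt_seconds must be positive")

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]

    def with_bifurcation(self, a: np.ndarray) -> "HopfModelSpec":
        return replace(self, a=np.asarray(a, dtype=float))


@dataclass
class FCByDistance:
    """Binned functional connectivity and structure function versus distance."""

    bin_centers_mm: np.ndarray
    fc: np.ndarray
    bin_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def structure_function(self) -> np.ndarray:
        """Kolmogorov structure function S(r) = 2 (1 - FC(r))."""
        return 2.0 * (1.0 - self.fc)


@dataclass
class CouplingFitResult:
    """Outcome of the G grid sweep against empirical FC(r)."""

    g_grid: np.ndarray
    fit_distance: np.ndarray
    g_opt: float
    n_sims_per_g: int
    n_dropped: np.ndarray = field(default=None)  # type: ignore[assignment]


def edr_coupling(
    dist: DistanceMatrix, lambda_c: float = DEFAULT_EDR_LAMBDA
) -> np.ndarray:
    """Exponential-distance-rule coupling matrix with zero diagonal."""
    C = np.exp(-lambda_c * dist.r)
    np.fill_diagonal(C, 0.0)
    return C


def estimate_frequencies(
    series: ParcellatedSeries | list[ParcellatedSeries],
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> np.ndarray:
    """Per-node intrinsic angular frequency from the power-spectrum peak.

    omega_n = 2 pi f_n where f_n is the frequency of the largest
    periodogram value inside ``band_hz``.  Given a list of series (a
    cohort under one condition) the per-node band spectra are averaged
    across subjects before peak-picking.
    """
    cohort = [series] if isinstance(series, ParcellatedSeries) else list(series)
    if not cohort:
        raise ValueError("need at least one series")
    if cohort[0].n_timepoints < 32:
        raise ValueError("frequency estimation needs at least 32 time points")
    tr = cohort[0].tr_seconds
    freqs = None
    spectra = None
    for s in cohort:
        x = s.values - s.values.mean(axis=1, keepdims=True)
        if (x.std(axis=1) == 0).any():
            bad = int(np.argwhere(x.std(axis=1) == 0)[0, 0])
            raise ValueError(f"node {bad} has a flat (constant) signal")
        f, pxx = sp_signal.periodogram(x, fs=1.0 / tr, axis=1)
        freqs = f
        spectra = pxx if spectra is None else spectra + pxx
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1]) & (freqs > 0)
    if not in_band.any():
        raise ValueError(f"no spectral bin inside the band {band_hz}")
    band_freqs = freqs[in_band]
    peak_idx = spectra[:, in_band].argmax(axis=1)
    return 2.0 * np.pi * band_freqs[peak_idx]


def simulate(
    spec: HopfModelSpec,
    n_timepoints: int,
    tr_seconds: float,
    transient_seconds: float = 100.0,
    subject_id: str = "",
    condition: str = "",
    rng: np.random.Generator | None = None,
) -> ParcellatedSeries:
    """Euler-Maruyama integration of the coupled Hopf model.

    The x-component is recorded every TR after discarding the transient;
    the y-coupling uses (y_p - y_n), symmetric with the x equation.
    """
    if spec.dt_seconds > tr_seconds:
        raise ValueError("integration step must not exceed the TR")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    dt = spec.dt_seconds
    steps_per_tr = max(int(round(tr_seconds / dt)), 1)
    n_transient = int(round(transient_seconds / dt))
    a, omega, G, C, nu = spec.a, spec.omega, spec.G, spec.C, spec.noise_sd
    row_sum = C.sum(axis=1)
    sqrt_dt = np.sqrt(dt)
    x = 0.1 * rng.standard_normal(n)
    y = 0.1 * rng.standard_normal(n)
    out = np.empty((n, n_timepoints))
    total_steps = n_transient + n_timepoints * steps_per_tr
    rec = 0
    for step in range(total_steps):
        r2 = x * x + y * y
        cx = G * (C @ x - row_sum * x)
        cy = G * (C @ y - row_sum * y)
        dx = (a - r2) * x - omega * y + cx
        dy = (a - r2) * y + omega * x + cy
        if nu > 0:
            x = x + dt * dx + sqrt_dt * nu * rng.standard_normal(n)
            y = y + dt * dy + sqrt_dt * nu * rng.standard_normal(n)
        else:
            x = x + dt * dx
            y = y + dt * dy
        if step % 200 == 0 and np.abs(x).max() > 1e6:
            node = int(np.abs(x).argmax())
            raise IntegrationError(
                f"trajectory blow-up at step {step}, node {node}"
            )
        k = step - n_transient + 1
        if k > 0 and k % steps_per_tr == 0:
            out[:, rec] = x
            rec += 1
    if not np.isfinite(out).all():
        raise IntegrationError("non-finite sample in simulated output")
    return ParcellatedSeries(out, tr_seconds, subject_id, condition)


def fc_by_distance(
    series: ParcellatedSeries,
    dist: DistanceMatrix,
    n_bins: int = 50,
) -> FCByDistance:
    """Mean pairwise Pearson correlation in equal-width distance bins."""
    if series.n_nodes != dist.n_nodes:
        raise ValueError("series and distance matrix node counts differ")
    sd = series.values.std(axis=1)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} constant node(s); their pairs are skipped",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(series.values)
    iu = np.triu_indices(series.n_nodes, k=1)
    pair_corr = corr[iu]
    ok = np.isfinite(pair_corr)
    if ok.all():
        centers, means, counts = _binned_pair_statistic(pair_corr, dist, n_bins)
    else:
        d = dist.offdiag()
        edges = np.linspace(d.min(), d.max(), n_bins + 1)
        idx = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
        counts = np.bincount(idx[ok], minlength=n_bins).astype(float)
        sums = np.bincount(idx[ok], weights=pair_corr[ok], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        centers = 0.5 * (edges[:-1] + edges[1:])
    return FCByDistance(centers, means, counts)


def empirical_fc_by_distance(
    cohort: list[ParcellatedSeries], dist: DistanceMatrix, n_bins: int = 50
) -> FCByDistance:
    """Subject-averaged FC(r) for a cohort sharing one parcellation."""
    if not cohort:
        raise ValueError("empty cohort")
    acc = None
    centers = counts = None
    for s in cohort:
        f = fc_by_distance(s, dist, n_bins)
        acc = f.fc if acc is None else acc + f.fc
        centers, counts = f.bin_centers_mm, f.bin_counts
    return FCByDistance(centers, acc / len(cohort), counts)


def fit_global_coupling(
    empirical: list[ParcellatedSeries],
    dist: DistanceMatrix,
    g_grid: np.ndarray | list[float],
    base_spec: HopfModelSpec,
    n_sims: int = 100,
    fit_range_mm: tuple[float, float] = DEFAULT_FIT_RANGE_MM,
    n_bins: int = 50,
    n_timepoints: int | None = None,
    tr_seconds: float | None = None,
    seed: int = 0,
) -> CouplingFitResult:
    """Grid sweep of the global coupling G against empirical FC(r).

    For each G, ``n_sims`` fresh-seed simulations are run; the fitting
    performance is the Euclidean distance between empirical and simulated
    FC(r) over the bins whose centres fall in ``fit_range_mm``, averaged
    across simulations.  ``g_opt`` attains the minimum.
    """
    g_grid = np.asarray(g_grid, dtype=float)
    if g_grid.size == 0:
        raise ValueError("g_grid must be nonempty")
    if n_timepoints is None:
        n_timepoints = empirical[0].n_timepoints
    if tr_seconds is None:
        tr_seconds = empirical[0].tr_seconds
    emp = empirical_fc_by_distance(empirical, dist, n_bins)
    mask = (
        (emp.bin_centers_mm >= fit_range_mm[0])
        & (emp.bin_centers_mm <= fit_range_mm[1])
        & (emp.bin_counts > 0)
        & np.isfinite(emp.fc)
    )
    if mask.sum() < 1:
        raise ValueError(f"no usable FC(r) bin inside the fit range {fit_range_mm}")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(g_grid.size * n_sims)]
    fit_distance = np.empty(g_grid.size)
    n_dropped = np.zeros(g_grid.size, dtype=int)
    for gi, g in enumerate(g_grid):
        dists = []
        for si in range(n_sims):
            spec = replace(base_spec, G=float(g), seed=child_seeds[gi * n_sims + si])
            try:
                sim = simulate(spec, n_timepoints, tr_seconds)
                simfc = fc_by_distance(sim, dist, n_bins)
            except IntegrationError:
                n_dropped[gi] += 1
                continue
            diff = emp.fc[mask] - simfc.fc[mask]
            if not np.isfinite(diff).all():
                n_dropped[gi] += 1
                continue
            dists.append(np.linalg.norm(diff))
        if len(dists) < max(1, n_sims // 2):
            raise RuntimeError(
                f"more than half of the simulations failed at G={g}"
            )
        fit_distance[gi] = float(np.mean(dists))
    g_opt = float(g_grid[int(np.argmin(fit_distance))])
    return CouplingFitResult(g_grid, fit_distance, g_opt, n_sims, n_dropped)
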