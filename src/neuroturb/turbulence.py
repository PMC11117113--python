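"""Model-free turbulence framework for parcellated phase fields.

Local synchronization at spatial scale lambda (mm^-1) is the modulus of
the local Kuramoto order parameter

    R_lambda(n, t) = | sum_p C_np e^{i phi_p(t)} | / sum_p C_np,
    C_np = exp(-lambda * r(n, p)),   C_nn = 1,

an exponential-kernel-weighted average of the unit phase vectors around
node n.  Small lambda probes long distances (lambda = 0.01 mm^-1 is a
~100 mm neighbourhood), large lambda short ones (~5 mm at 0.21 mm^-1).

From the field R_lambda the framework derives, per scale:

- amplitude turbulence D_lambda: the population standard deviation of R
  pooled over nodes and time — the spatiotemporal variability of local
  synchronization;
- spatial information transfer: minus the slope of log mean time-correlation
  of R between node pairs against log distance, fitted inside the inertial
  subrange where correlation decays without loss;
- information cascade flow F_lambda: the lagged correlation of R at scale
  lambda with R at the next lower scale, measuring scale-to-scale
  transmission; the information cascade is its average over scales;
- node-level turbulence: the per-node standard deviation of R over time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import DistanceMatrix
from .phases import PhaseMatrix

__all__ = [
    "DEFAULT_LAMBDAS",
    "DEFAULT_FIT_RANGE_MM",
    "KernelMatrix",
    "LocalOrderField",
    "TransferFit",
    "ScaleScan",
    "kernel",
    "local_order",
    "amplitude_turbulence",
    "node_level_turbulence",
    "information_transfer",
    "cascade_flow",
    "information_cascade",
    "scan_scales",
]

#: Default spatial-scale grid (mm^-1), 8 scales from ~100 mm down to ~5 mm.
DEFAULT_LAMBDAS = (0.01, 0.03, 0.06, 0.09, 0.12, 0.15, 0.18, 0.21)

#: Default inertial subrange for distance fits, in mm.
DEFAULT_FIT_RANGE_MM = (10.0, 40.0)


class TransferFitError(RuntimeError):
    """Raised when too few usable distance bins remain for the log-log fit."""


@dataclass
class KernelMatrix:
    """Exponential distance kernel C_np = exp(-lambda r) with its row sums."""

    weights: np.ndarray
    lambda_scale: float
    row_sums: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        """Row-stochastic kernel (rows sum to one)."""
        return self.weights / self.row_sums[:, None]


@dataclass
class LocalOrderField:
    """R_lambda(n, t) in [0, 1]: local synchronization per node and time."""

    R: np.ndarray
    lambda_scale: float

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2:
            raise ValueError(f"R must be 2-D, got shape {self.R.shape}")
        # tolerate tiny float excursions from rounding in the complex sum
        if (self.R < -1e-12).any() or (self.R > 1 + 1e-12).any():
            raise ValueError("local order parameter must lie in [0, 1]")
        np.clip(self.R, 0.0, 1.0, out=self.R)

    @property
    def n_nodes(self) -> int:
        return self.R.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.R.shape[1]


@dataclass
class TransferFit:
    """Result of the log-log correlation-versus-distance fit at one scale."""

    transfer: float
    slope: float
    intercept: float
    n_bins_used: int


@dataclass
class ScaleScan:
    """Per-scale measures over an increasing lambda grid.

    ``cascade_flows`` is aligned with ``lambdas[1:]`` (each scale paired
    with its lower neighbour); ``information_cascade`` averages it.
    """

    lambdas: np.ndarray
    turbulence: np.ndarray
    transfer: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray
    cascade_flows: np.ndarray
    node_turbulence: np.ndarray  # (n_lambda, n_nodes)
    fit_range_mm: tuple[float, float] = DEFAULT_FIT_RANGE_MM
    n_bins: int = 50
    extras: dict = field(default_factory=dict)

    @property
    def information_cascade(self) -> float:
        return float(np.mean(self.cascade_flows))


def kernel(dist: DistanceMatrix, lambda_scale: float) -> KernelMatrix:
    """Exponential distance kernel at scale ``lambda_scale`` (mm^-1).

    The self-term r = 0 gives weight exactly 1, so every node contributes
    its own phase to its local order parameter.
    """
    if not lambda_scale > 0:
        raise ValueError(f"lambda_scale must be positive, got {lambda_scale}")
    weights = np.exp(-lambda_scale * dist.r)
    return KernelMatrix(weights, float(lambda_scale), weights.sum(axis=1))


def local_order(phases: PhaseMatrix, kern: KernelMatrix) -> LocalOrderField:
    """Modulus of the kernel-weighted mean phase vector, per node and time."""
    if phases.n_nodes != kern.weights.shape[0]:
        raise ValueError(
            f"phase matrix has {phases.n_nodes} nodes but kernel has "
            f"{kern.weights.shape[0]}"
        )
    z = np.exp(1j * phases.phases)  # (nodes, time)
    R = np.abs(kern.weights @ z) / kern.row_sums[:, None]
    return LocalOrderField(R, kern.lambda_scale)


def amplitude_turbulence(field: LocalOrderField) -> float:
    """Population std of R pooled over every node-time entry (D_lambda)."""
    flat = field.R.ravel()
    if flat.size < 2:
        raise ValueError("amplitude turbulence is undefined for a single entry")
    # population std == sqrt(<R^2> - <R>^2), computed in centred form
    return float(np.std(flat, ddof=0))


def node_level_turbulence(field: LocalOrderField) -> np.ndarray:
    """Per-node population std of R across time (node-level turbulence)."""
    if field.n_timepoints < 2:
        raise ValueError("node-level turbulence needs at least 2 time points")
    return np.std(field.R, axis=1, ddof=0)


def _binned_pair_statistic(
    values: np.ndarray, dist: DistanceMatrix, n_bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average a per-pair statistic within equal-width distance bins.

    Returns (bin_centers, bin_means, bin_counts); empty bins hold NaN.
    """
    d = dist.offdiag()
    edges = np.linspace(d.min(), d.max(), n_bins + 1)
    # np.digitize puts the right edge in the last bin
    idx = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, means, counts


def _pairwise_time_correlations(R: np.ndarray) -> np.ndarray:
    """Upper-triangle Pearson correlations of rows of R across time."""
    n = R.shape[0]
    sd = R.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(R)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} node(s) with zero temporal variance; "
            "their pairs are excluded",
            stacklevel=3,
        )
    iu = np.triu_indices(n, k=1)
    return corr[iu]


def information_transfer(
    field: LocalOrderField,
    dist: DistanceMatrix,
    fit_range_mm: tuple[float, float] = DEFAULT_FIT_RANGE_MM,
    n_bins: int = 50,
) -> TransferFit:
    """Spatial information transfer at one scale.

    Pearson time-correlations of R between all node pairs are averaged in
    equal-width distance bins; a least-squares line of log(mean corr) on
    log(bin centre) over the bins whose centres fall in the inertial
    subrange gives slope A and intercept B.  Transfer is -A: positive when
    the correlation of local synchronization decays with distance.

    Bins with nonpositive mean correlation have no logarithm and are
    dropped with a warning; fewer than 3 usable bins raises
    :class:`TransferFitError`.
    """
    corr = _pairwise_time_correlations(field.R)
    ok_pairs = np.isfinite(corr)
    d = dist.offdiag()
    edges = np.linspace(d.min(), d.max(), n_bins + 1)
    idx = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx[ok_pairs], minlength=n_bins).astype(float)
    sums = np.bincount(idx[ok_pairs], weights=corr[ok_pairs], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    in_range = (
        (centers >= fit_range_mm[0]) & (centers <= fit_range_mm[1]) & (counts > 0)
    )
    nonpositive = in_range & ~(means > 0)
    if nonpositive.any():
        warnings.warn(
            f"{int(nonpositive.sum())} distance bin(s) with nonpositive mean "
            "correlation excluded from the log-log fit",
            stacklevel=2,
        )
    usable = in_range & (means > 0)
    if usable.sum() < 3:
        raise TransferFitError(
            f"only {int(usable.sum())} usable distance bin(s) in the fit range "
            f"{fit_range_mm}; need at least 3"
        )
    slope, intercept = np.polyfit(np.log(centers[usable]), np.log(means[usable]), 1)
    return TransferFit(
        transfer=float(-slope),
        slope=float(slope),
        intercept=float(intercept),
        n_bins_used=int(usable.sum()),
    )


def cascade_flow(
    field_hi: LocalOrderField,
    field_lo: LocalOrderField,
    dt_steps: int = 1,
) -> float:
    """Lagged scale-to-scale correlation F_lambda.

    Per node, the Pearson correlation across time of R_lambda(n, t + dt)
    with R_{lambda - dlambda}(n, t); the flow is the node average.  Nodes
    whose R is constant in either field have an undefined correlation and
    are skipped with a warning.
    """
    if field_hi.n_nodes != field_lo.n_nodes:
        raise ValueError("fields must share the node count")
    T = field_hi.n_timepoints
    if field_lo.n_timepoints != T:
        raise ValueError("fields must share the time length")
    if T <= dt_steps + 2:
        raise ValueError(f"time length {T} too short for lag {dt_steps}")
    x = field_hi.R[:, dt_steps:]
    y = field_lo.R[:, : T - dt_steps]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    valid = (sx > 0) & (sy > 0)
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} node(s) with zero temporal variance skipped "
            "in cascade flow",
            stacklevel=2,
        )
    if not valid.any():
        raise ValueError("no node with nonzero temporal variance")
    r = (xc[valid] * yc[valid]).sum(axis=1) / (sx[valid] * sy[valid])
    return float(r.mean())


def information_cascade(flows: np.ndarray | list[float]) -> float:
    """Average of the per-scale cascade flows over the lambda scan."""
    flows = np.asarray(flows, dtype=float)
    if flows.size == 0:
        raise ValueError("information cascade needs at least one flow value")
    return float(flows.mean())


def scan_scales(
    phases: PhaseMatrix,
    dist: DistanceMatrix,
    lambdas: tuple[float, ...] | np.ndarray = DEFAULT_LAMBDAS,
    fit_range_mm: tuple[float, float] = DEFAULT_FIT_RANGE_MM,
    n_bins: int = 50,
    dt_steps: int = 1,
    on_transfer_error: str = "raise",
) -> ScaleScan:
    """Compute every per-scale measure over an increasing lambda grid.

    Cascade flow pairs each lambda with its lower grid neighbour, so the
    scan yields ``len(lambdas) - 1`` flow values.

    On small parcellations the log-log transfer fit can run out of usable
    distance bins at strongly localized scales; ``on_transfer_error="nan"``
    records NaN for the transfer measures at such scales (with a warning)
    instead of aborting the scan.
    """
    if on_transfer_error not in ("raise", "nan"):
        raise ValueError(f"unknown on_transfer_error {on_transfer_error!r}")
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0 or (np.diff(lambdas) <= 0).any():
        raise ValueError("lambdas must be a nonempty strictly increasing grid")
    fields: list[LocalOrderField] = []
    turbulence = np.empty(lambdas.size)
    transfer = np.empty(lambdas.size)
    slope = np.empty(lambdas.size)
    intercept = np.empty(lambdas.size)
    node_turb = np.empty((lambdas.size, phases.n_nodes))
    for i, lam in enumerate(lambdas):
        try:
            fld = local_order(phases, kernel(dist, lam))
            fields.append(fld)
            turbulence[i] = amplitude_turbulence(fld)
            node_turb[i] = node_level_turbulence(fld)
        except ValueError as exc:
            raise ValueError(f"at lambda={lam}: {exc}") from exc
        try:
            fit = information_transfer(fld, dist, fit_range_mm, n_bins)
            transfer[i], slope[i], intercept[i] = fit.transfer, fit.slope, fit.intercept
        except TransferFitError as exc:
            if on_transfer_error == "raise":
                raise TransferFitError(f"at lambda={lam}: {exc}") from exc
            warnings.warn(f"transfer fit skipped at lambda={lam}: {exc}", stacklevel=2)
            transfer[i] = slope[i] = intercept[i] = np.nan
    flows = np.empty(max(lambdas.size - 1, 0))
    for i in range(1, lambdas.size):
        try:
            flows[i - 1] = cascade_flow(fields[i], fields[i - 1], dt_steps)
        except ValueError as exc:
            raise ValueError(f"at lambda={lambdas[i]}: {exc}") from exc
    return ScaleScan(
        lambdas=lambdas,
        turbulence=turbulence,
        transfer=transfer,
        slope=slope,
        intercept=intercept,
        cascade_flows=flows,
        node_turbulence=node_turb,
        fit_range_mm=tuple(fit_range_mm),
        n_bins=n_bins,
    )


def windowed_lambda_fit(
    lambdas: np.ndarray, values: np.ndarray, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Least-squares slope/intercept of a per-scale profile against lambda.

    Generic utility for summarising how a measure profile changes with
    scale (optionally restricted to a lambda window).
    """
    lambdas = np.asarray(lambdas, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values)
    if window is not None:
        mask &= (lambdas >= window[0]) & (lambdas <= window[1])
    if mask.sum() < 2:
        raise ValueError("need at least 2 points for the lambda fit")
    slope, intercept = np.polyfit(lambdas[mask], values[mask], 1)
    return float(slope), float(intercept)
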