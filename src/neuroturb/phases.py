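"""Instantaneous-phase extraction from parcellated BOLD time series.

The turbulence measures act on the phase field phi(n, t) of narrow-band
signals.  The canonical route is: remove the per-node mean, zero-phase
band-pass filter in the slow BOLD band (default 0.008-0.08 Hz), then take
the angle of the analytic signal (Hilbert transform) per node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import ParcellatedSeries

__all__ = ["PhaseMatrix", "bandpass", "extract_phases", "DEFAULT_BAND_HZ"]

#: Default analysis band in Hz, the slow-fluctuation convention of the
#: whole-brain modelling literature.
DEFAULT_BAND_HZ = (0.008, 0.08)


@dataclass
class PhaseMatrix:
    """Node x time instantaneous phases in radians, wrapped to [-pi, pi].

    ``edge_samples`` flags how many samples at each end are dominated by
    filter/Hilbert edge effects (``ceil(1 / (low_hz * TR))``); downstream
    measures may exclude them but by default use every time point.
    """

    phases: np.ndarray
    tr_seconds: float
    source_band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    edge_samples: int = 0

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2:
            raise ValueError(f"phases must be 2-D, got shape {self.phases.shape}")
        if not np.isfinite(self.phases).all():
            bad = int(np.argwhere(~np.isfinite(self.phases))[0, 0])
            raise ValueError(f"non-finite phase for node {bad}")

    @property
    def n_nodes(self) -> int:
        return self.phases.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.phases.shape[1]

    def trimmed(self) -> np.ndarray:
        """Phases with the flagged edge samples removed (may be empty)."""
        k = self.edge_samples
        if k == 0 or 2 * k >= self.n_timepoints:
            return self.phases
        return self.phases[:, k:-k]


def bandpass(
    series: ParcellatedSeries,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    order: int = 2,
) -> ParcellatedSeries:
    """Zero-phase band-pass filter each node, after removing its mean.

    Uses a Butterworth filter in second-order sections applied
    forward-backward (``sosfiltfilt``), so the filter contributes no phase
    distortion — phase is the quantity the downstream measures consume.
    """
    nyquist = 0.5 / series.tr_seconds
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} Hz is at or above the Nyquist frequency "
            f"{nyquist} Hz for TR={series.tr_seconds} s"
        )
    x = series.values - series.values.mean(axis=1, keepdims=True)
    if low_hz > 0:
        sos = signal.butter(
            order, [low_hz, high_hz], btype="bandpass",
            fs=1.0 / series.tr_seconds, output="sos",
        )
    else:
        sos = signal.butter(
            order, high_hz, btype="lowpass",
            fs=1.0 / series.tr_seconds, output="sos",
        )
    filtered = signal.sosfiltfilt(sos, x, axis=1)
    return ParcellatedSeries(
        filtered, series.tr_seconds, series.subject_id, series.condition
    )


def extract_phases(
    series: ParcellatedSeries,
    source_band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> PhaseMatrix:
    """Per-node phase of the analytic signal (signal + i * quadrature).

    The caller is expected to band-pass first; the phase of a broadband
    signal is not interpretable as a single rotating component.
    """
    x = series.values - series.values.mean(axis=1, keepdims=True)
    analytic = signal.hilbert(x, axis=1)
    phases = np.angle(analytic)
    if not np.isfinite(phases).all():
        bad = int(np.argwhere(~np.isfinite(phases))[0, 0])
        raise ValueError(f"non-finite analytic phase for node {bad}")
    low_hz = source_band_hz[0]
    edge = (
        math.ceil(1.0 / (low_hz * series.tr_seconds)) if low_hz > 0 else 0
    )
    edge = min(edge, series.n_timepoints // 2)
    return PhaseMatrix(phases, series.tr_seconds, tuple(source_band_hz), edge)
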