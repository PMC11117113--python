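"""Domain containers and delimited-text I/O for parcellated BOLD data.

A dataset is a node x time matrix per subject and condition plus a
parcellation: one centre-of-gravity coordinate (MNI millimetres) and one
resting-state-network label per node.  Node order is positional and must
agree between a series file and the parcellation it is analysed with; no
name-based joining is attempted.

File dialect: tab- or comma-delimited, chosen by extension (``.tsv`` vs
``.csv``; anything else is treated as whitespace-delimited).  Series files
have no header (rows = nodes, columns = time points); parcellation files
have one header line with columns ``name, x, y, z, network``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "FormatError",
    "ParcellatedSeries",
    "Parcellation",
    "DistanceMatrix",
    "read_series",
    "write_series",
    "read_parcellation",
    "write_parcellation",
    "euclidean_distances",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected table format."""


def _delimiter_for(path: Path) -> str | None:
    suffix = path.suffix.lower()
    if suffix == ".tsv":
        return "\t"
    if suffix == ".csv":
        return ","
    return None  # whitespace


@dataclass
class ParcellatedSeries:
    """A node x time real matrix with its sampling interval and labels.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_nodes, n_timepoints)``.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    subject_id, condition
        Free-text labels used for pairing subjects across conditions.
    """

    values: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError(f"series must be 2-D, got shape {self.values.shape}")
        n_nodes, n_time = self.values.shape
        if n_nodes < 2:
            raise FormatError(f"series needs at least 2 nodes, got {n_nodes}")
        if n_time < 8:
            raise FormatError(f"series needs at least 8 time points, got {n_time}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at node {bad[0]}, time point {bad[1]}"
            )
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class Parcellation:
    """Node coordinates (mm), names and resting-state-network labels."""

    coordinates_mm: np.ndarray
    node_names: list[str] = field(default_factory=list)
    network_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates_mm = np.asarray(self.coordinates_mm, dtype=float)
        if self.coordinates_mm.ndim != 2 or self.coordinates_mm.shape[1] != 3:
            raise FormatError(
                f"coordinates must be (n_nodes, 3), got {self.coordinates_mm.shape}"
            )
        n = self.coordinates_mm.shape[0]
        if n < 2:
            raise FormatError(f"parcellation needs at least 2 nodes, got {n}")
        if not np.isfinite(self.coordinates_mm).all():
            bad = int(np.argwhere(~np.isfinite(self.coordinates_mm))[0, 0])
            raise FormatError(f"non-finite coordinate for node {bad}")
        if not self.node_names:
            self.node_names = [f"node{i:04d}" for i in range(n)]
        if not self.network_labels:
            self.network_labels = ["unlabelled"] * n
        if len(self.node_names) != n or len(self.network_labels) != n:
            raise FormatError("node_names/network_labels length must match node count")

    @property
    def n_nodes(self) -> int:
        return self.coordinates_mm.shape[0]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Euclidean distance matrix in millimetres."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.ndim != 2 or self.r.shape != (n, n):
            raise ValueError(f"distance matrix must be square, got {self.r.shape}")
        if not np.allclose(self.r, self.r.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.r < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangle distances as a flat vector (one entry per pair)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.r[iu]


def read_series(
    path: str | Path,
    tr_seconds: float,
    subject_id: str = "",
    condition: str = "",
    n_nodes: int | None = None,
) -> ParcellatedSeries:
    """Read a headerless numeric node x time table.

    ``n_nodes``, when given, is checked against the row count (the declared
    orientation guard: rows are nodes, columns are time points).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(
            path, sep=_delimiter_for(path) or r"\s+", header=None, dtype=str,
            engine="python", skip_blank_lines=True,
        )
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"{path}: ragged or malformed table ({exc})") from exc
    try:
        # numpy's strtod round-trips %.17g output exactly
        values = frame.to_numpy(dtype=str).astype(float)
    except ValueError:
        numeric = frame.apply(pd.to_numeric, errors="coerce")
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {frame.iat[i, j]!r} at row {i}, column {j}"
        ) from None
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: non-finite cell {frame.iat[i, j]!r} at row {i}, column {j}"
        )
    if n_nodes is not None and values.shape[0] != n_nodes:
        raise FormatError(
            f"{path}: expected {n_nodes} node rows, found {values.shape[0]}"
        )
    return ParcellatedSeries(values, tr_seconds, subject_id, condition)


def write_series(series: ParcellatedSeries, path: str | Path) -> None:
    path = Path(path)
    delim = _delimiter_for(path) or "\t"
    np.savetxt(path, series.values, fmt="%.17g", delimiter=delim)


_PARC_COLUMNS = ("name", "x", "y", "z", "network")


def read_parcellation(path: str | Path) -> Parcellation:
    """Read a parcellation table with header columns name, x, y, z, network."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_delimiter_for(path) or r"\s+", engine="python")
    missing = [c for c in _PARC_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    coords = frame[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(coords).any():
        bad = int(np.argwhere(np.isnan(coords))[0, 0])
        raise FormatError(f"{path}: non-finite coordinate at row {bad}")
    return Parcellation(
        coordinates_mm=coords,
        node_names=[str(v) for v in frame["name"]],
        network_labels=[str(v) for v in frame["network"]],
    )


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "name": parc.node_names,
            "x": parc.coordinates_mm[:, 0],
            "y": parc.coordinates_mm[:, 1],
            "z": parc.coordinates_mm[:, 2],
            "network": parc.network_labels,
        }
    )
    frame.to_csv(path, sep=_delimiter_for(path) or "\t", index=False, float_format="%.17g")


def euclidean_distances(parc: Parcellation) -> DistanceMatrix:
    """Pairwise Euclidean distances between parcel centres of gravity."""
    r = squareform(pdist(parc.coordinates_mm, metric="euclidean"))
    iu = np.triu_indices(parc.n_nodes, k=1)
    if (r[iu] == 0).any():
        warnings.warn(
            "duplicate node coordinates produce zero off-diagonal distances",
            stacklevel=2,
        )
    return DistanceMatrix(r)
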