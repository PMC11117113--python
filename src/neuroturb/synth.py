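"""Synthetic parcellations, phase fields and paired-condition cohorts.

Nothing in this module imitates real cortical geometry or scanner physics;
it provides ground-truth-bearing inputs for the turbulence measures and the
model-fitting pipeline.  Coordinates are drawn inside two mirrored
hemisphere-like boxes scaled so that pairwise distances span roughly the
0.2-173 mm range of a 1,000-parcel cortical atlas in MNI space; network
labels come from a 7-way spatial clustering, mirroring the seven canonical
resting-state networks.  Paired drug/placebo cohorts are simulated with the
Hopf whole-brain model so every downstream stage can be checked against
known generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .hopf import DEFAULT_EDR_LAMBDA, HopfModelSpec, edr_coupling, simulate
from .io import DistanceMatrix, Parcellation, ParcellatedSeries, euclidean_distances

__all__ = [
    "NETWORK_NAMES",
    "PhaseFieldSpec",
    "SyntheticCohortSpec",
    "gen_parcellation",
    "gen_phase_field",
    "gen_cohort",
]

#: Canonical 7-network nomenclature used for synthetic labels.
NETWORK_NAMES = ("VIS", "SOM", "DAN", "VEN", "LIM", "FPN", "DMN")

# Hemisphere-like boxes (mm): x in +/-[2, 57], y in [-70, 70], z in [-40, 40].
_BOX_X = (2.0, 57.0)
_BOX_Y = (-70.0, 70.0)
_BOX_Z = (-40.0, 40.0)


@dataclass
class PhaseFieldSpec:
    """Controls for the spatially structured synthetic phase field.

    ``spatial_decay`` (mm^-1) sets how fast inter-node phase similarity
    decays with distance; ``temporal_drift`` (rad/step) advances a common
    carrier phase; ``noise_level`` (rad) scales the spatially correlated
    disturbance field.  ``spatial_decay = 0`` collapses the disturbance to
    a single shared component, so the field is spatially uniform.
    """

    spatial_decay: float = 0.05
    temporal_drift: float = 0.3
    noise_level: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_decay < 0 or self.noise_level < 0:
            raise ValueError("spatial_decay and noise_level must be nonnegative")


@dataclass
class SyntheticCohortSpec:
    """A paired-condition cohort design for the Hopf simulator.

    The two conditions share the parcellation, coupling matrix and node
    frequencies and differ only in the declared parameters (global coupling
    ``G`` and/or bifurcation parameter ``a``), emulating a within-subject
    drug versus placebo design.
    """

    n_subjects: int = 15
    n_nodes: int = 100
    n_timepoints: int = 434
    tr_seconds: float = 2.0
    g_placebo: float = 0.6
    g_drug: float = 1.2
    a_placebo: float = -0.02
    a_drug: float = -0.02
    noise_sd: float = 0.01
    dt_seconds: float = 0.1
    edr_lambda: float = DEFAULT_EDR_LAMBDA
    omega_band_hz: tuple[float, float] = (0.04, 0.07)
    condition_names: tuple[str, str] = ("placebo", "drug")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_nodes < 2 or self.n_timepoints < 8:
            raise ValueError("invalid cohort dimensions")


def gen_parcellation(n_nodes: int, seed: int = 0) -> Parcellation:
    """Random two-hemisphere parcellation with 7 contiguous network labels.

    Coordinates are uniform inside two mirrored boxes; with the default
    scale and ~1,000 nodes the pairwise distances span roughly 1-190 mm.
    Labels are a deterministic 7-cluster k-means partition of the
    coordinates, giving spatially contiguous synthetic networks.
    """
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be at least 2, got {n_nodes}")
    rng = np.random.default_rng(seed)
    n_left = n_nodes // 2
    signs = np.concatenate([-np.ones(n_left), np.ones(n_nodes - n_left)])
    x = signs * rng.uniform(*_BOX_X, size=n_nodes)
    y = rng.uniform(*_BOX_Y, size=n_nodes)
    z = rng.uniform(*_BOX_Z, size=n_nodes)
    coords = np.column_stack([x, y, z])
    k = min(len(NETWORK_NAMES), n_nodes)
    km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(coords)
    # relabel clusters by their centroid order for a seed-stable naming
    order = np.argsort(km.cluster_centers_[:, 1] + 1e-3 * km.cluster_centers_[:, 0])
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    labels = [NETWORK_NAMES[rank[c]] for c in km.labels_]
    names = [f"node{i:04d}" for i in range(n_nodes)]
    return Parcellation(coords, names, labels)


def gen_phase_field(
    parc: Parcellation,
    spec: PhaseFieldSpec,
    n_timepoints: int,
) -> np.ndarray:
    """Phase matrix (node x time, [0, 2 pi)) with distance-graded coherence.

    A common carrier advances by ``temporal_drift`` per step; on top of it
    each node receives a disturbance obtained by kernel-smoothing i.i.d.
    node noise with exp(-spatial_decay * r), so nearby nodes stay phase
    aligned while distant nodes decohere as ``noise_level`` grows.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be positive")
    rng = np.random.default_rng(spec.seed)
    dist = euclidean_distances(parc)
    carrier = spec.temporal_drift * np.arange(n_timepoints)
    if spec.noise_level == 0:
        phases = np.broadcast_to(carrier, (parc.n_nodes, n_timepoints)).copy()
        return np.mod(phases, 2 * np.pi)
    K = np.exp(-spec.spatial_decay * dist.r)
    # unit-variance spatially correlated disturbance per time step
    weights = K / np.sqrt((K**2).sum(axis=1, keepdims=True))
    xi = rng.standard_normal((parc.n_nodes, n_timepoints))
    eta = weights @ xi
    phases = carrier[None, :] + spec.noise_level * eta
    return np.mod(phases, 2 * np.pi)


def _cohort_spec_to_hopf(
    spec: SyntheticCohortSpec,
    dist: DistanceMatrix,
    omega: np.ndarray,
    condition: str,
    seed: int,
) -> HopfModelSpec:
    drug = condition == spec.condition_names[1]
    return HopfModelSpec(
        a=spec.a_drug if drug else spec.a_placebo,
        omega=omega,
        G=spec.g_drug if drug else spec.g_placebo,
        C=edr_coupling(dist, spec.edr_lambda),
        noise_sd=spec.noise_sd,
        dt_seconds=spec.dt_seconds,
        seed=seed,
    )


def gen_cohort(
    spec: SyntheticCohortSpec,
    parc: Parcellation | None = None,
) -> tuple[list[ParcellatedSeries], Parcellation, dict]:
    """Simulate a paired drug/placebo cohort with the Hopf model.

    Returns the series (two per subject, paired by ``subject_id``), the
    shared parcellation, and a manifest of every ground-truth parameter
    (sufficient for parameter-recovery tests).
    """
    ss = np.random.SeedSequence(spec.seed)
    parc_seed, omega_seed, *subject_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in ss.spawn(2 + spec.n_subjects * 2)
    ]
    if parc is None:
        parc = gen_parcellation(spec.n_nodes, seed=parc_seed)
    dist = euclidean_distances(parc)
    omega_rng = np.random.default_rng(omega_seed)
    f = omega_rng.uniform(*spec.omega_band_hz, size=parc.n_nodes)
    omega = 2 * np.pi * f
    series: list[ParcellatedSeries] = []
    for i in range(spec.n_subjects):
        subject = f"sub{i:03d}"
        for j, condition in enumerate(spec.condition_names):
            seed = subject_seeds[2 * i + j]
            hopf = _cohort_spec_to_hopf(spec, dist, omega, condition, seed)
            try:
                series.append(
                    simulate(
                        hopf,
                        spec.n_timepoints,
                        spec.tr_seconds,
                        subject_id=subject,
                        condition=condition,
                    )
                )
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed for {subject}/{condition}: {exc}"
                ) from exc
    manifest = {
        "n_subjects": spec.n_subjects,
        "n_nodes": parc.n_nodes,
        "n_timepoints": spec.n_timepoints,
        "tr_seconds": spec.tr_seconds,
        "conditions": list(spec.condition_names),
        "G": {spec.condition_names[0]: spec.g_placebo,
              spec.condition_names[1]: spec.g_drug},
        "a": {spec.condition_names[0]: spec.a_placebo,
              spec.condition_names[1]: spec.a_drug},
        "noise_sd": spec.noise_sd,
        "dt_seconds": spec.dt_seconds,
        "edr_lambda": spec.edr_lambda,
        "omega_rad_s": omega.tolist(),
        "seed": spec.seed,
    }
    return series, parc, manifest
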