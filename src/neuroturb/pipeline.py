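"""End-to-end orchestration of the two analysis arms.

``run_model_free`` takes a paired cohort and produces the lambda-scan
measure tables, paired permutation statistics with FDR across scales,
node-level-turbulence Kolmogorov-Smirnov distances per scale, and the
top-quantile network attribution at a chosen scale.

``run_model_based`` estimates node frequencies per condition, sweeps the
global coupling G of the Hopf model against the condition's FC(r),
then runs the perturbation experiment at the fitted working point and
compares susceptibility and information capability between conditions
with the Wilcoxon rank-sum test.

Every defaulted parameter is echoed into the run manifest so no
assumption stays silent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hopf, perturbation, stats, turbulence
from .io import Parcellation, ParcellatedSeries, euclidean_distances
from .phases import DEFAULT_BAND_HZ, bandpass, extract_phases

__all__ = ["RunConfig", "run_model_free", "run_model_based", "load_config"]


@dataclass
class RunConfig:
    """All tunable settings of the pipeline, with the defaults spelled out."""

    lambdas: tuple[float, ...] = turbulence.DEFAULT_LAMBDAS
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ
    fit_range_mm: tuple[float, float] = turbulence.DEFAULT_FIT_RANGE_MM
    n_bins: int = 50
    cascade_definition: str = "flow"  # "flow" or "transfer"
    n_perm: int = 1000
    fdr_q: float = 0.05
    attribution_lambda: float = 0.12
    attribution_quantile: float = 0.15
    # model-based arm
    g_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 2.01, 0.25), 2))
    n_sims_per_g: int = 100
    edr_lambda: float = hopf.DEFAULT_EDR_LAMBDA
    model_a: float = -0.02
    model_noise_sd: float = 0.01
    model_dt_seconds: float = 0.1
    lambda_s: float = 0.18
    perturb_a_range: tuple[float, float] = (-0.02, 0.0)
    n_trials: int = 100
    n_perturbation_reps: int = 10
    seed: int = 0

    def manifest(self) -> dict:
        """Every setting of the run, defaults included, as plain data."""
        out = dataclasses.asdict(self)
        out["g_grid"] = [float(g) for g in self.g_grid]
        return out

    def dump_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML mapping of overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("lambdas", "band_hz", "fit_range_mm", "g_grid", "perturb_a_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _pair_cohort(
    cohort: list[ParcellatedSeries],
) -> tuple[list[str], tuple[str, str], dict]:
    """Group a flat cohort by subject and check each has both conditions."""
    conditions = []
    for s in cohort:
        if s.condition not in conditions:
            conditions.append(s.condition)
    if len(conditions) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conditions}")
    by_key = {(s.subject_id, s.condition): s for s in cohort}
    subjects = sorted({s.subject_id for s in cohort})
    for subject in subjects:
        for c in conditions:
            if (subject, c) not in by_key:
                raise ValueError(f"subject {subject} missing condition {c}")
    return subjects, (conditions[0], conditions[1]), by_key


def run_model_free(
    cohort: list[ParcellatedSeries],
    parc: Parcellation,
    config: RunConfig = RunConfig(),
) -> dict[str, pd.DataFrame]:
    """Model-free arm: lambda-scan measures and paired statistics.

    Returns a dict of tidy tables: ``measures`` (subject, condition,
    lambda, measure, value), ``node_turbulence``, ``stats`` (per measure
    and lambda: t, p, FDR-adjusted p, Cohen's d), ``ksd`` (node-level
    turbulence KS distance per lambda) and ``attribution`` (top-quantile
    network counts at ``config.attribution_lambda``).
    """
    subjects, conditions, by_key = _pair_cohort(cohort)
    dist = euclidean_distances(parc)
    lambdas = np.asarray(config.lambdas, dtype=float)

    measure_rows = []
    node_rows = []
    scans: dict[tuple[str, str], turbulence.ScaleScan] = {}
    for subject in subjects:
        for condition in conditions:
            series = by_key[(subject, condition)]
            filtered = bandpass(series, *config.band_hz)
            phases = extract_phases(filtered, config.band_hz)
            scan = turbulence.scan_scales(
                phases,
                dist,
                lambdas,
                config.fit_range_mm,
                config.n_bins,
                on_transfer_error="nan",
            )
            scans[(subject, condition)] = scan
            for i, lam in enumerate(lambdas):
                measure_rows.append(
                    (subject, condition, lam, "turbulence", scan.turbulence[i])
                )
                measure_rows.append(
                    (subject, condition, lam, "transfer", scan.transfer[i])
                )
                for node, v in enumerate(scan.node_turbulence[i]):
                    node_rows.append((subject, condition, lam, node, v))
            for i, lam in enumerate(lambdas[1:]):
                measure_rows.append(
                    (subject, condition, lam, "cascade_flow", scan.cascade_flows[i])
                )
            cascade_values = (
                scan.cascade_flows
                if config.cascade_definition == "flow"
                else scan.transfer[np.isfinite(scan.transfer)]
            )
            measure_rows.append(
                (
                    subject,
                    condition,
                    np.nan,
                    "information_cascade",
                    turbulence.information_cascade(cascade_values),
                )
            )
    measures = pd.DataFrame(
        measure_rows, columns=["subject", "condition", "lambda", "measure", "value"]
    )
    node_turb = pd.DataFrame(
        node_rows, columns=["subject", "condition", "lambda", "node", "value"]
    )

    # paired statistics per (measure, lambda); FDR across lambdas per measure
    stat_rows = []
    for measure, group in measures.groupby("measure"):
        cells = []
        for lam, cell in group.groupby("lambda", dropna=False):
            wide = cell.pivot(index="subject", columns="condition", values="value")
            if wide.isna().any().any():
                continue  # scale unusable for some subject (e.g. transfer fit)
            sample = stats.PairedSample(
                wide[conditions[1]].to_numpy(), wide[conditions[0]].to_numpy()
            )
            res = stats.permutation_paired_ttest(
                sample, config.n_perm, seed=config.seed
            )
            cells.append((measure, lam, res))
        if not cells:
            continue
        reject, p_adj = stats.fdr_correct(
            np.array([r.p_value for _, _, r in cells]), config.fdr_q
        )
        for (measure_, lam, res), rej, pa in zip(cells, reject, p_adj):
            stat_rows.append(
                (
                    measure_,
                    lam,
                    res.statistic,
                    res.p_value,
                    pa,
                    res.effect_size_d,
                    bool(rej),
                )
            )
    stats_table = pd.DataFrame(
        stat_rows,
        columns=["measure", "lambda", "t", "p_raw", "p_fdr", "cohens_d", "significant"],
    )

    # node-level turbulence: subject-averaged per node, KSD per lambda
    node_mean = (
        node_turb.groupby(["condition", "lambda", "node"])["value"].mean().unstack(0)
    )
    ksd_rows = []
    for lam in lambdas:
        sub = node_mean.xs(lam, level="lambda")
        ksd_rows.append(
            (lam, stats.ksd(sub[conditions[1]].to_numpy(), sub[conditions[0]].to_numpy()))
        )
    ksd_table = pd.DataFrame(ksd_rows, columns=["lambda", "ksd"])

    lam_attr = lambdas[np.argmin(np.abs(lambdas - config.attribution_lambda))]
    sub = node_mean.xs(lam_attr, level="lambda")
    node_diff = np.abs(
        sub[conditions[1]].to_numpy() - sub[conditions[0]].to_numpy()
    )
    attribution = stats.network_attribution(
        node_diff, parc.network_labels, config.attribution_quantile
    ).rename_axis("network").reset_index()
    attribution.insert(0, "lambda", lam_attr)

    return {
        "measures": measures,
        "node_turbulence": node_turb,
        "stats": stats_table,
        "ksd": ksd_table,
        "attribution": attribution,
    }


def run_model_based(
    cohort: list[ParcellatedSeries],
    parc: Parcellation,
    config: RunConfig = RunConfig(),
) -> dict:
    """Model-based arm: G sweep and perturbation analysis per condition.

    Returns per condition the coupling fit and the per-repetition
    susceptibility/information-capability values (the perturbation
    experiment is repeated ``config.n_perturbation_reps`` times with fresh
    trial seeds to yield a sample for the between-condition Wilcoxon
    rank-sum comparison).
    """
    subjects, conditions, by_key = _pair_cohort(cohort)
    dist = euclidean_distances(parc)
    C = hopf.edr_coupling(dist, config.edr_lambda)
    out: dict = {"conditions": conditions, "fits": {}, "perturbation": {}}
    ss = np.random.SeedSequence(config.seed)
    cond_seeds = ss.spawn(len(conditions))
    for ci, condition in enumerate(conditions):
        cond_cohort = [by_key[(s, condition)] for s in subjects]
        omega = hopf.estimate_frequencies(cond_cohort, config.band_hz)
        base = hopf.HopfModelSpec(
            a=config.model_a,
            omega=omega,
            G=0.0,
            C=C,
            noise_sd=config.model_noise_sd,
            dt_seconds=config.model_dt_seconds,
        )
        fit_seed, *rep_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in cond_seeds[ci].spawn(1 + config.n_perturbation_reps)
        ]
        fit = hopf.fit_global_coupling(
            cond_cohort,
            dist,
            np.asarray(config.g_grid),
            base,
            n_sims=config.n_sims_per_g,
            fit_range_mm=config.fit_range_mm,
            n_bins=config.n_bins,
            seed=fit_seed,
        )
        out["fits"][condition] = fit
        fitted = dataclasses.replace(base, G=fit.g_opt)
        chis, caps = [], []
        for rep_seed in rep_seeds:
            protocol = perturbation.PerturbationProtocol(
                a_range=config.perturb_a_range,
                n_trials=config.n_trials,
                lambda_s=config.lambda_s,
                seed=rep_seed,
            )
            res = perturbation.susceptibility_and_capability(
                fitted,
                protocol,
                cond_cohort[0].n_timepoints,
                cond_cohort[0].tr_seconds,
                dist,
                config.band_hz,
            )
            chis.append(res.susceptibility)
            caps.append(res.information_capability)
        out["perturbation"][condition] = {
            "susceptibility": np.array(chis),
            "information_capability": np.array(caps),
        }
    a, b = conditions
    pa, pb = out["perturbation"][a], out["perturbation"][b]
    out["comparison"] = pd.DataFrame(
        [
            (
                name,
                pa[name].mean(),
                pb[name].mean(),
                stats.wilcoxon_ranksum(pb[name], pa[name]).p_value,
            )
            for name in ("susceptibility", "information_capability")
        ],
        columns=["measure", f"mean_{a}", f"mean_{b}", "p_wilcoxon"],
    )
    return out
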