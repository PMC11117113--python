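#!/usr/bin/env python
"""Fit the Hopf whole-brain model's global coupling per condition.

For each condition, estimates node frequencies from the cohort spectra,
sweeps G over a grid (fresh simulations per G) and picks the coupling
whose simulated FC(r) best matches the condition's empirical FC(r) inside
the inertial subrange.  Writes the fit curves and compares the recovered
working points against the cohort's generating parameters.
"""

import argparse
import importlib.util
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from neuroturb.hopf import (
    HopfModelSpec,
    edr_coupling,
    estimate_frequencies,
    fit_global_coupling,
)
from neuroturb.io import euclidean_distances

_loader = importlib.util.spec_from_file_location(
    "model_free_driver", Path(__file__).parent / "02_model_free_analysis.py"
)
_driver = importlib.util.module_from_spec(_loader)
_loader.loader.exec_module(_driver)
load_cohort = _driver.load_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out-dir", type=Path, default=Path("results/model_fit"))
    parser.add_argument("--g-min", type=float, default=0.0)
    parser.add_argument("--g-max", type=float, default=2.0)
    parser.add_argument("--g-step", type=float, default=0.25)
    parser.add_argument("--n-sims", type=int, default=10)
    args = parser.parse_args()
    warnings.filterwarnings("ignore", category=UserWarning)

    cohort, parc = load_cohort(args.cohort_dir)
    manifest = json.loads((args.cohort_dir / "manifest.json").read_text())
    dist = euclidean_distances(parc)
    C = edr_coupling(dist)
    g_grid = np.round(np.arange(args.g_min, args.g_max + 1e-9, args.g_step), 4)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, condition in enumerate(manifest["conditions"]):
        cond = [s for s in cohort if s.condition == condition]
        omega = estimate_frequencies(cond)
        base = HopfModelSpec(a=-0.02, omega=omega, G=0.0, C=C)
        fit = fit_global_coupling(
            cond, dist, g_grid, base, n_sims=args.n_sims,
            fit_range_mm=(10.0, 80.0), n_bins=25, seed=args.seed + ci,
        )
        for g, d in zip(fit.g_grid, fit.fit_distance):
            rows.append((condition, g, d))
        g_true = manifest["G"][condition]
        print(
            f"{condition}: fitted G = {fit.g_opt} "
            f"(generating G = {g_true}; grid step {args.g_step})"
        )
    pd.DataFrame(rows, columns=["condition", "G", "fit_distance"]).to_csv(
        args.out_dir / "fit_curves.csv", index=False
    )
    print(f"wrote fit curves to {args.out_dir / 'fit_curves.csv'}")


if __name__ == "__main__":
    main()
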