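# neuroturb

Turbulence-based analysis of whole-brain dynamics for parcellated fMRI time
series: model-free measures of local synchronization and cross-scale
information transmission, a coupled Stuart–Landau (Hopf) whole-brain model
fitted through distance-resolved functional connectivity, and in-silico
perturbation analysis of the fitted model. Written for computational
neuroscientists studying how pharmacological or state manipulations reshape
large-scale brain dynamics, and tested end to end on synthetic cohorts with
known ground truth.

## The measures

Given node phases φ_p(t) and pairwise distances r(n,p), the local Kuramoto
order parameter at spatial scale λ (mm⁻¹),

    R_λ(n,t) = | Σ_p e^{−λ r(n,p)} e^{iφ_p(t)} | / Σ_p e^{−λ r(n,p)},

measures synchronization in a ~1/λ-sized neighbourhood of node n. Scanning
λ from 0.01 (≈100 mm) to 0.21 (≈5 mm) the package derives, per scale:

- **amplitude turbulence** D_λ = std over nodes and time of R_λ;
- **information transfer** −A_λ, the negative slope of log mean
  time-correlation of R_λ between node pairs vs log distance, fitted in the
  inertial subrange;
- **information cascade flow** 𝓕_λ = corr_t(R_λ(n,t+Δt), R_{λ−Δλ}(n,t))
  averaged over nodes, and the **information cascade**, its mean over scales;
- **node-level turbulence**, the per-node std of R_λ over time.

The model side couples Hopf normal-form oscillators
(dz = (a + iω − |z|²)z + coupling + noise) through an
exponential-distance-rule matrix, fits the global coupling G by matching
simulated to empirical FC(r), then perturbs the fitted model by redrawing
the bifurcation parameters a_n ∈ [−0.02, 0] and reports **susceptibility**
(mean shift χ of local synchronization) and **information capability**
(across-trial variability I of that shift). Drug/placebo contrasts are
tested with sign-flip permutation paired t-tests (FDR across scales),
Cohen's d, Kolmogorov–Smirnov distances over node-level turbulence, and
Wilcoxon rank-sum tests for χ and I.

## Worked example

The `analysis/` drivers run the two analysis arms on a synthetic paired
cohort (every computation lives in the package; the drivers are thin):

```bash
python analysis/01_simulate_cohort.py --seed 1 --n-subjects 8 --n-nodes 60 --n-timepoints 150
python analysis/02_model_free_analysis.py --seed 1
python analysis/03_fit_coupling.py --seed 1
python analysis/04_perturbation_analysis.py --seed 1 --n-reps 5
```

Stage 02 prints, for this cohort (placebo G = 0.6 vs drug-like G = 1.2):

```
8/24 (measure, lambda) cells significant after FDR at q=0.05
turbulence effect sizes by scale (Cohen's d, drug - placebo):
lambda
0.01   -1.256
0.03   -1.711
0.06   -0.961
0.09    0.992
0.12    2.103
0.15    2.292
0.18    2.308
0.21    2.268
```

i.e. the shifted working point changes amplitude turbulence with large,
scale-dependent effect sizes, and the node-level turbulence distributions
separate most at the largest spatial scales (KS distance 1.0 at λ = 0.01
falling to ≈0.1 by λ = 0.12). Stage 03 recovers the generating coupling
order (`placebo: fitted G = 0.5`, `drug: fitted G = 0.75` on a 0.25-spaced
grid — drug above placebo, with the absolute drug value pulled down by
frequency estimation from short series), and stage 04 finds the two fitted
models differ significantly in susceptibility (Wilcoxon p ≈ 0.008) but not
information capability at this reduced scale.

Library use mirrors the drivers:

```python
from neuroturb import synth, pipeline

cohort, parc, truth = synth.gen_cohort(synth.SyntheticCohortSpec(seed=1))
tables = pipeline.run_model_free(cohort, parc, pipeline.RunConfig())
print(tables["stats"])
```

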