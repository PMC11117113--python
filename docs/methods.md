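# Methods

`neuroturb` implements a turbulence-style analysis of whole-brain dynamics on
parcellated BOLD time series, together with the coupled-oscillator model that
is used to probe those dynamics in silico. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data can
and cannot establish.

## Model-free framework

All measures derive from the **local Kuramoto order parameter**. Given
instantaneous phases φ_p(t) (per node, radians) and the pairwise Euclidean
distances r(n,p) between parcel centres of gravity (mm), the exponential
kernel at spatial scale λ (mm⁻¹)

    C_np = exp(−λ · r(n,p)),   C_nn = 1

defines

    R_λ(n,t) = | Σ_p C_np · e^{iφ_p(t)} | / Σ_p C_np ∈ [0, 1],

the modulus of the kernel-weighted mean phase vector: local synchronization
around node n at scale λ. Small λ probes long distances (λ = 0.01 mm⁻¹ is a
~100 mm neighbourhood), large λ short ones (~5 mm at 0.21 mm⁻¹). The
self-term is included with weight exactly one, so an isolated node is fully
"synchronized" with itself and R → 1 as the kernel localizes.

Per scale the framework derives:

- **Amplitude turbulence D_λ** — the population standard deviation of R
  pooled over all node–time entries (√(⟨R²⟩ − ⟨R⟩²), computed in centred form
  for numerical stability; identical analytically, far better conditioned for
  near-constant fields). D_λ ∈ [0, 0.5] since R is bounded in [0, 1].
- **Spatial information transfer** — pairwise Pearson time-correlations of R
  between nodes are averaged within equal-width distance bins; a least-squares
  line of log(mean correlation) on log(bin centre), restricted to the inertial
  subrange, gives slope A_λ and intercept B_λ. Transfer is −A_λ, positive when
  correlation decays with distance. Bins whose mean correlation is ≤ 0 have no
  logarithm and are excluded with a warning; fewer than three usable bins is
  an error (or NaN-with-warning inside a scan, see below).
- **Information cascade flow 𝓕_λ** — per node, the Pearson correlation across
  time of R_λ(n, t+Δt) with R_{λ−Δλ}(n, t), averaged over nodes; Δt is one
  sample (one TR) and Δλ the gap to the next lower grid scale. The
  **information cascade** is the mean of 𝓕_λ over the scan. A config switch
  (`cascade_definition="transfer"`) instead averages the transfer values
  across scales, an alternative summary some of the source literature uses.
- **Node-level turbulence** — the per-node standard deviation of R over time
  (population convention), whose between-condition distributions feed the
  Kolmogorov–Smirnov distance and the top-quantile network attribution.

### Scale grid

The default grid is λ ∈ {0.01, 0.03, 0.06, 0.09, 0.12, 0.15, 0.18, 0.21}
mm⁻¹ — eight scales from ~100 mm down to ~5 mm with a 0.03 step above the
first. This is the grid of the turbulence literature this framework follows
and contains every scale at which downstream results are reported (0.09,
0.12, 0.18); cascade flow uses each scale's actual lower-neighbour gap.

### Phase extraction

Phases come from the analytic signal (Hilbert transform) of band-passed,
per-node-demeaned series. Defaults: Butterworth order 2 in second-order
sections applied forward–backward (zero phase — phase is the quantity of
interest), band 0.008–0.08 Hz, the standard slow-BOLD band of this
literature. The filter is a convention, not a fitted quantity, and is
surfaced in the run manifest. The first/last ⌈1/(low·TR)⌉ samples are flagged
as edge-dominated; measures use all samples by default (matching the use of
every TR downstream) and `PhaseMatrix.trimmed()` offers the conservative
alternative.

### Distance binning

Equal-width bins (default 50) spanning the observed distance range, bin
centres as r. The inertial subrange for the transfer and FC(r) fits defaults
to 10–40 mm and is configurable; every output records it. At desk scale
(tens of nodes) the analysis drivers use fewer bins (10–25) and a wider
subrange (10–80 mm) so each bin keeps enough pairs; with ~1,000 nodes the
defaults apply. Inside `scan_scales` the transfer fit may be allowed to
produce NaN (`on_transfer_error="nan"`) because strongly localized scales on
small parcellations can leave fewer than three usable bins; the pipeline uses
this policy and drops such cells from the statistics rather than aborting the
scan.

## Whole-brain Hopf model

Each node follows the normal form of a supercritical Hopf bifurcation
(Stuart–Landau) with diffusive coupling:

    dx_n = [a_n x_n − (x_n²+y_n²)x_n − ω_n y_n + G Σ_p C_np (x_p − x_n)] dt + ν dW
    dy_n = [a_n y_n − (x_n²+y_n²)y_n + ω_n x_n + G Σ_p C_np (y_p − y_n)] dt + ν dW

For a_n < 0 an uncoupled noiseless node decays to the origin; for a_n > 0 it
settles on a limit cycle of radius √a_n at frequency ω_n/2π. Defaults:
ν = 0.01 (additive Gaussian noise), a_n = −0.02 homogeneously (the noisy
edge-of-criticality regime the perturbation range implies), ω_n estimated
from data as 2π times the within-band periodogram peak (band spectra averaged
across subjects of a condition before peak-picking).

**Coupling matrix.** Default is the exponential distance rule,
C_np = exp(−λ_C · r(n,p)) with zero diagonal and λ_C = 0.18 mm⁻¹ — a
documented assumption, configurable, and replaceable by a user-supplied
(e.g. tractography-derived) connectome.

**Integration.** Euler–Maruyama with dt = 0.1 s, 100 s transient discarded,
x-component recorded every TR. These are the standard values of the
model-fitting literature and are configurable. Halving dt changes the
steady-state amplitude by under 1 % (asserted in tests). Two discretisation
effects are worth knowing: explicit Euler inflates the limit-cycle radius by
≈ ω²dt/(4a) relatively (about 1 % at ω = 2π·0.05, dt = 0.1, a = 0.25; the
analytic-law tests use dt = 0.02 so they measure the law rather than the
step), and at exact criticality (a = 0) it leaves a spurious radius floor of
ω√(dt/2).

**FC(r) and the fit.** FC(r) is the mean pairwise Pearson correlation per
distance bin (so FC(0) = 1 and Kolmogorov's structure function is
S(r) = 2(1 − FC(r))). The global coupling is fitted by grid sweep: for each G,
`n_sims` fresh-seed simulations (default 100; the desk-scale drivers and
tests use 5–10) are reduced to FC(r); the fitting distance is the Euclidean
norm of (empirical − simulated) FC over bins inside the inertial subrange,
averaged over simulations; g_opt is the argmin. Parameter recovery on
synthetic cohorts generated at known G recovers the generating value exactly
on a 0.5-spaced grid in ≥ 4/5 seeded repeats (60 nodes, 5 sims per G).
When node frequencies must be estimated from short series the fitted optimum
can shift by a grid step, which is visible in the analysis drivers and is a
property of the estimation, not of the sweep.

## Perturbation analysis

A trial redraws every a_n uniformly from the protocol range (default
[−0.02, 0]) and simulates perturbed and unperturbed models. Both runs are
reduced to per-node time-means of R at the probe scale λ_s = 0.18 mm⁻¹
(computed through the same band-pass → Hilbert → local-order path as
empirical data). With the per-trial node response δ_n = mean_t R̃ − mean_t R:

- **susceptibility** χ = ⟨⟨δ_n⟩_trials⟩_nodes — the mean shift of local
  synchronization under perturbation;
- **information capability** I = ⟨sd_trials(δ_n)⟩_nodes — the across-trial
  variability of that shift (population SD), an encoding measure.

The averaging order (time → trials → nodes) follows the definitions exactly,
and a per-trial audit table is retained. Perturbed and unperturbed runs in a
trial share the noise realization by default (paired noise): this isolates
the effect of the parameter redraw, makes the zero-width-perturbation null
exact (χ = I = 0 identically), and reduces Monte-Carlo variance; an unpaired
mode exists because the pairing is a design choice, not part of the
definition. Default 100 trials (drivers use 20–30 at desk scale). Because χ
and I are scalars per experiment, the pipeline repeats the experiment
(default 10 repetitions, fresh trial seeds) to obtain per-condition samples
for the Wilcoxon rank-sum comparison.

## Group statistics

- **Permutation paired t-test**: the observed paired t statistic is referred
  to a null of random sign-flips of the per-subject differences — the
  standard permutation scheme for paired designs. All 2ⁿ patterns are
  enumerated when 2ⁿ ≤ n_perm (p is then an exact proportion, with floor
  1/2ⁿ one-sided and 2/2ⁿ two-sided since the null is symmetric); otherwise
  n_perm random flips with the add-one convention (1+hits)/(1+n_perm), which
  never reports p = 0. Type-I error is calibrated within [0.03, 0.07] at
  α = 0.05 over 500 seeded null replicates (asserted in tests).
- **FDR**: Benjamini–Hochberg step-up, applied per measure across the eight
  scales — matching the per-panel comparison structure of the λ-scan.
- **Effect size**: Cohen's d, pooled-SD convention by default (mean paired
  difference over the pooled SD of the two condition samples); the
  paired-difference convention (mean diff / SD of diffs) is available by
  flag, since which convention produced any given published d is generally
  not recoverable.
- **Wilcoxon rank sum**: exact null for combined n ≤ 20 without ties, normal
  approximation with tie correction otherwise.
- **KSD**: sup-norm distance between empirical CDFs.
- **Network attribution**: nodes at or above the (1−q) empirical quantile of
  the per-node absolute condition difference (default top 15 %, at
  λ = 0.12) are tallied per resting-state network; threshold ties are all
  included and the realized count reported.

## Synthetic data: what it does and does not establish

The generator provides three levels of ground truth:

1. `gen_parcellation` — uniform coordinates in two mirrored hemisphere-like
   boxes sized so ~1,000 nodes span roughly 1–190 mm of pairwise distance
   (bracketing the 0.2–173 mm range of a 1,000-parcel cortical atlas), with
   seven spatially contiguous k-means "networks".
2. `gen_phase_field` — a common drifting carrier plus a spatially correlated
   disturbance (kernel-smoothed node noise), giving phase fields whose
   coherence decays with distance at a controlled rate. These are oracle
   inputs for the measures, not brain models.
3. `gen_cohort` — paired drug/placebo cohorts simulated with the Hopf model.
   The two conditions share geometry, coupling matrix and node frequencies
   and differ only in declared parameters; defaults are G = 0.6 (placebo-like)
   versus G = 1.2 (drug-like) at a = −0.02, TR 2 s. The contrast was chosen
   once so that the shifted working point produces a clearly detectable
   condition difference at cohort scale, emulating the large effect sizes a
   pharmacological intervention study is powered for; mean amplitude
   turbulence at λ = 0.01 is higher under the drug-like condition in the
   majority of seeded cohorts at the default generator settings, and this
   direction is frozen as a regression test. The direction and magnitude of
   per-scale differences do depend on geometry and node count — small
   synthetic brains are not quantitatively comparable to a 1,000-parcel
   cortex.

None of the generators mimic scanner noise, motion, hemodynamic convolution
or real cortical geometry ("BOLD" is the oscillator x-component directly, as
in the model-fitting literature). Passing tests therefore establish the
correctness and calibration of the *methods* — not that any particular
empirical effect would reproduce on real pharmacological fMRI, which is not
redistributable here.

## Problem sizes

The test suite and the reproduction script run everything at reduced scale —
cohorts of 2–8 subjects, 15–60 nodes, 50–150 time points, 5–10 simulations
per G, 20–30 perturbation trials — chosen so the full suite completes in a
couple of minutes while every structural property (oracle equivalence,
invariants, recovery, calibration) is still exercised. All sizes are
parameters; nothing in the implementation assumes them.

## Known limitations

- The transfer fit needs enough node pairs per distance bin; on parcellations
  far below a few hundred nodes, strongly localized scales may yield no
  usable fit (reported as NaN and excluded from statistics).
- Node frequency estimation is limited by spectral resolution 1/(T·TR); short
  series bias the G fit as noted above.
- The Euler integrator's bias terms above; use a smaller dt where the
  asymptotic laws themselves are under study.
- FDR is applied per measure family across scales; other family choices are
  defensible and change which borderline cells survive.
- No vortex tracking, surrogate-data testing, hemodynamic model, or
  heterogeneous delays; the coupling matrix is distance-rule by default, not
  subject-specific anatomy.
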