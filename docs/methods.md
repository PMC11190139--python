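# Methods

This note documents the models, conventions, numerical choices and known
limitations of `laminarq`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## MP2RAGEME signal model

Longitudinal magnetization over one sequence repetition is modelled as a
composition of affine maps mz → a·mz + b: an inversion pulse, free
recovery over the gap TA, a train of n_exc small-flip excitations at
spacing TR_GRE1 (each an instantaneous rotation followed by exponential
recovery, composed in closed form via the geometric series), free recovery
TB, the second train at TR_GRE2, and free recovery TC. The periodic steady
state is the fixed point m* = B/(1−A) of the composed map; the model
raises an invalid-parameter error if |A| ≥ 1 (no physical steady state).
Block signals are sin(FA)·mz just before the k-space-center excitation
(excitation n_exc//2, consistent with linear phase encoding); proton
density and receive gain are common positive factors that cancel in the
UNI contrast, so signals are returned on a unit-M0 scale.

**Inversion efficiency convention.** The inversion pulse acts as
mz → (1 − 2·inv_eff)·mz: `inv_eff` is the *fraction of longitudinal
magnetization inverted*, so 1 is an ideal 180° pulse, 0 is no pulse, and
the default 0.96 (a typical adiabatic value, configurable) maps mz to
−0.92·mz. This convention makes the no-inversion limit an identity, which
is the natural null case; efficiencies quoted as cos(θ) factors can be
converted via inv_eff = (1 + cosθ_eff)/2. The efficiency only shifts the
lookup curve, which the round-trip construction absorbs.

**Readout-block placement.** Blocks are centered on TI1 and TI2; the
multi-echo readout affects only the T2* decay of the acquired images, not
longitudinal recovery. This is the standard treatment when no intra-block
timing details are available.

**Validation.** `laminarq.bloch` contains a deliberately naive simulator —
event-by-event excitations, relaxation integrated in ≤1 ms exponential
substeps, steady state reached by iterating five repetitions from thermal
equilibrium rather than solving a fixed point. The closed-form model
agrees with it to well below 0.1% relative error across tissue T1s
(800–2500 ms); the residual is dominated by the oracle's remaining
transient, which shrinks with more repetitions.

## T1 lookup inversion

UNI(T1) is tabulated on a 500–5000 ms grid at 1 ms steps, covering the
plausible 7T tissue range. Inversion uses linear interpolation restricted
to the largest strictly monotone run of the tabulated curve that overlaps
the cortical regime (1500–2500 ms); with the default protocol the whole
grid is monotone. UNI values outside the branch's attainable range are
flagged missing (NaN), never clamped — missing voxels are excluded from
profile averaging downstream. Round-trip identity holds exactly at grid
nodes and to within the grid step elsewhere.

## T2* estimation

Per voxel, the monoexponential model s_k = S0·exp(−TE_k·R2*) is fitted by
unweighted nonlinear least squares: a closed-form log-linear OLS solution
initializes a damped Gauss–Newton iteration on (S0, R2*), vectorized over
voxels (a per-voxel call into a generic optimizer would be impractical at
~10⁵–10⁶ voxels on one CPU; the 2-parameter Gauss–Newton update is exact
and cheap). Log-linear alone is noise-biased because the log transform
reweights errors; the refinement removes that bias. Voxels with any
non-positive echo, or a non-decaying initial fit, are flagged missing.
Steps that would leave the physical region (S0 > 0, R2* > 0) are halved;
convergence tolerance 1e-10 on the relative R2* step, max 50 iterations.
On noiseless input the fit reproduces the log-linear closed form and the
true T2* to ≥ 6 significant digits.

## Synthetic phantoms

**Geometry.** A slab along the third axis: WM below, a GM ribbon, CSF
above, with optional sinusoidal in-plane undulation of the boundary
(default amplitude 0.7 mm, period 22.4 mm). Voxel size defaults to 0.7 mm
isotropic, matching the acquisition. The default ribbon thickness is
8.4 mm (12 voxels) — deliberately thicker than cortex — so that the
distance-ratio depths of a discrete voxel grid populate all 10 depth bins;
a 4-voxel ribbon is the geometric minimum the constructor accepts but
cannot fill 10 bins under binned sampling. Folded geometry is out of
scope: folding exercises nothing in the computations under test, while
undulation already makes the depth field non-trivial.

**Tissue values.** GM baseline profiles are monotone-increasing cubics in
normalized depth: T1(d) = 1745 + 190d + 90d² − 40d³ ms (boundary value
1745 ms, ribbon average exactly 1860 ms — the scale of control-group
values in 7T frontocortical data) and T2*(d) = 26 + 4d ms. WM/CSF are
fixed at literature-typical 7T values (T1 1200/4000 ms, T2* 27/100 ms),
all configurable.

**Rendering.** Per voxel the two block signals are forward-simulated from
the T1 truth, scaled by proton density and the first-echo T2* decay
(identical first echo times, so the decay factor cancels exactly in UNI);
the four echo magnitudes decay from |S2|. Gaussian noise with SD equal to
`noise_sd` × the local noiseless signal is added independently per image
(Rician magnitude noise reduces to Gaussian at the SNRs exercised, and
Gaussian keeps the oracles analytic). Rendering is bit-reproducible from
its seed.

## Cohort generator

Defaults emulate the study design: 48 patients, 10 controls; age ~
Normal(37, 10) truncated to the 20–55 y inclusion window; ~70% female;
IDS severity ~ Normal(33.5, 13.5) truncated to ≥ 9 for patients and
Normal(4, 3) truncated to ≥ 0 for controls; CTQ ~ Normal(46.8, 19.2) and
Normal(39.9, 9.2) truncated to the 25–125 instrument range; 50%
antidepressant use and 44% comorbid anxiety among patients; one patient's
IDS/CTQ masked as missing (incomplete questionnaires are the norm in such
cohorts, and the reference design has exactly one).

The subject's T1 offset in the affected ROI (default lOFC) is

- controls: shift = σ_b·ε,
- patients: shift = d·σ_b + ρ·σ_b·z_IDS + √(1−ρ²)·σ_b·η,

with ε, η independent standard normals and z_IDS the severity score
standardized by its truncated-normal *population* moments. Both groups
then have shift SD exactly σ_b (default 70 ms, the scale of printed metric
SDs), the standardized group difference equals d (default 0.6) and the
within-patient Pearson correlation with severity equals ρ (default 0.27)
in population. Note the implied population Kendall τ is smaller (≈ 0.17
under this generator); τ and r are different statistics and the generator
calibrates r. The effect is an additive, depth-uniform shift by default,
with an optional 2·depth-weighted variant to exercise AUC sensitivity,
since real depth-dependence of group effects is not well constrained.

**Two tiers.** The voxel tier exercises physics + laminar sampling; the
profile tier draws the 10-depth profiles directly (baseline + shift +
i.i.d. Gaussian per-depth noise, default SD 25 ms for T1 and 1 ms for
T2*, per hemisphere) so that thousand-replicate calibration loops run in
seconds. Between-subject variance is attached only to the affected ROI —
the shift is defined as that ROI's offset — so non-affected ROIs carry
measurement noise only; their group tests remain correctly null-calibrated
but understate the between-subject variance of real cortex.

**What passing tests do not show.** The phantoms have planar topology, no
partial-volume mixing beyond voxel-box assignment, no B0/B1 field effects,
no motion, and relative (not spatially uniform) noise. Passing recovery
and calibration tests therefore validates the estimators and the
inference chain, not robustness to real-world segmentation error or
artifact.

## Laminar sampling

Depth is the equidistant (distance-ratio) convention, d = D_WM/(D_WM +
D_CSF) from Euclidean distance transforms with physical voxel spacing —
transparent and oracle-checkable. Volume-preserving (equivolume) layering,
used by surface-based laminar toolchains, is a noted extension point; for
slab phantoms the two agree up to a smooth monotone reparameterization,
which the binned contract tolerates. ROI refinement dilates with the
6-connected cross (city-block metric), default 2 voxels (midpoint of the
1–3 voxel range such pipelines use), then intersects with GM. Profiles are
means over 10 equal-width bins, half-open [i/10, (i+1)/10) with the last
bin closed; bins with fewer than `min_voxels` (default 10) finite voxels
are missing; profiles with more than 2 missing bins are rejected. Binned
means were chosen over surface-interpolated sampling as the simplest
estimator with the same 10-values-per-profile contract.

## Profile metrics

OLS cubic fit over normalized depth at the bin centers (i−0.5)/10, with
missing bins excluded rather than imputed, requiring ≥ 8 of 10 points.
AUC = 10·∫₀¹ p(x)dx in closed form from the coefficients: the ×10 factor
makes the AUC of a flat profile equal 10× its mean (AUC/mean ≈ 10 for
near-flat cortical profiles), i.e. the area is measured in depth-index
units across the 10 sampling points. A trapezoidal-on-raw-points AUC is
available behind a flag (`auc_from_fit=False`) since either reading of
the convention only rescales group statistics, which are scale-invariant.
Offset = p(0), the fitted value exactly at the WM/GM boundary, not an
extrapolation into WM.

## Inference

ANCOVA is OLS of metric ~ group + age + sex (sex as a male indicator, no
interactions); the group F is the squared t of the case coefficient
(identical to the partial F for a single-df term), denominator df = N − 4.
Because the covariate-adjusted d used by point-and-click ANCOVA software
is not uniquely defined, two effect sizes are reported side by side: the
pooled-SD d = (M_case − M_control)/s_pooled and the adjusted
d = t·√(1/n₁ + 1/n₂); neither is privileged. The 95% CI is for the
adjusted control-minus-case difference, so a patient elevation prints a
negative interval. Perfect fits (zero residual within rounding) report
F = 0, p = 1 rather than numerical noise.

Kendall's τ-b with tie correction is the primary severity statistic
(Pearson r of the generator and τ of the report are kept distinct); p
comes from the tie-adjusted normal approximation, the CI from a seeded
2000-resample subject-level bootstrap (percentile method). Within-patient
analyses run only for cells significant at α = 0.05 in the case-control
stage, mirroring gated exploratory designs; α is uncorrected by default
(effect sizes and CIs accompany every test), with Benjamini–Hochberg
available to callers via the tidy p columns. Lateralization uses paired
t-tests on left/right profile means; subjects missing a hemisphere are
dropped from that test and counted.

## Calibration and problem sizes

The test suite checks, at profile tier: type-I error of the full chain
(generate → profiles → metrics → ANCOVA) within 0.05 ± 0.02 over 1000
null replicates of the 48/10 design; ≥ 90% coverage of the true −42 ms
adjusted group difference by the ANCOVA CI and of the population τ by the
bootstrap CI over 100 replicate cohorts (population τ estimated once by a
60,000-patient Monte Carlo). Voxel-tier checks use 32³–64³ grids and a
single subject where one suffices; these sizes were chosen so the whole
suite runs in a couple of minutes on a laptop-class CPU while keeping
every Monte Carlo well above its resolution needs. With 10 controls the
design's power at d = 0.6 is far below 1, so single-cohort significance
is seed-dependent — the examples say so rather than hiding it.

## Determinism

All randomness flows from a single master seed: the pipeline derives
cohort and profile seeds via `numpy.random.SeedSequence`, the cohort
generator derives per-subject rendering seeds, and every bootstrap takes
an explicit seed. Re-running any stage with the same config and seed is
bit-reproducible; the run log records the derived seeds and the config is
snapshotted verbatim into every results directory.

## Known limitations

- Slab (unfolded) geometry; equidistant rather than equivolume depth.
- No B1+/B0 correction, no phase/QSM processing, no k-space effects
  (SENSE, partial Fourier), no motion simulation.
- Between-subject variability outside the affected ROI is not modelled.
- Magnitude noise is Gaussian and proportional to the local signal;
  Rician/spatially-uniform noise is a straightforward extension.
- The CSF T1 default (4000 ms) sits inside the lookup's monotone branch
  for the default protocol; protocols with a narrower branch will flag
  CSF as missing, which downstream stages treat correctly.
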