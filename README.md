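# laminarq

Quantitative 7T laminar MRI analysis of intracortical myelin (T1) and iron
(T2*), built for case-control studies of frontocortical microstructure and
exercised end to end on synthetic cortical phantoms with known ground
truth.

## The problem

Ultra-high-field quantitative MRI can resolve microstructure *within* the
cortical ribbon. Longer T1 indicates lower intracortical myelin content,
shorter T2\* indicates higher iron concentration. A typical study design
acquires a single MP2RAGEME scan per subject, derives T1 and T2\* maps,
samples them at graded cortical depths inside anatomically defined regions
of interest (rostral ACC, medial/lateral OFC, and primary somatosensory
cortex as a control region), reduces each 10-point depth profile to a few
scalar metrics, and compares patients with controls while adjusting for
age and sex.

Clinical cohorts of this kind are rarely shareable, so this package pairs
the full analysis chain with a synthetic-data generator that emulates the
study design at the voxel level (imaging physics and laminar geometry) and
at the profile level (fast statistical calibration). Every stage is tested
against independent oracles: a brute-force Bloch simulator for the signal
model, exhaustive nearest-boundary search for the depth field, explicit
normal equations for the ANCOVA, and O(n²) pair counting for Kendall's τ.

## The model

**Signal model.** The MP2RAGEME sequence acquires two gradient-echo blocks
after an inversion pulse (TI₁/TI₂ = 670/3675.4 ms, 4°/4° flip angles,
turbo factor 150, TR = 6778 ms); the second block is multi-echo
(TE = 3, 11.5, 19, 28.5 ms). Longitudinal magnetization follows a periodic
steady state that is solved in closed form. The two block signals combine
into the bias-field-insensitive UNI contrast

UNI = S₁S₂ / (S₁² + S₂²) ∈ [−0.5, 0.5],

which is monotone in T1 over a wide branch, so T1 is estimated by lookup
inversion. T2\* comes from a per-voxel monoexponential fit
s_k = S₀·exp(−TE_k/T2\*) (log-linear initialization, Gauss–Newton
refinement).

**Laminar sampling.** Cortical depth is the distance-ratio field
d = D_WM/(D_WM + D_CSF) on gray-matter voxels (0 at the WM/GM boundary,
1 at GM/CSF). Atlas ROI masks are dilated 1–3 voxels and intersected with
the GM segmentation; each map is then averaged over 10 equal-width depth
bins, giving exactly 10 values per subject × ROI × hemisphere × contrast.

**Profile metrics.** Each profile reduces to: the **mean** across depths;
the **AUC**, 10·∫₀¹ p(x) dx of an OLS 3rd-order polynomial fit p (so a
flat profile has AUC = 10 × mean); and the **offset** p(0), the value at
the WM/GM transitional zone.

**Inference.** Per ROI × contrast × metric, an ANCOVA (OLS of
metric ~ group + age + sex) with F(1, N−4) for the group term, pooled and
covariate-adjusted Cohen's d, and a 95% CI for the adjusted HC−patient
difference. Hemisphere lateralization is checked with paired t-tests
before averaging. Within patients, severity (IDS) and trauma (CTQ)
associations use Kendall's τ-b with a tie-adjusted asymptotic p and a
2000-resample bootstrap CI, gated on stage-1 significance; medication and
comorbidity use the same ANCOVA machinery.

## Worked example

`examples/` contains one narrative script per capability. The headline
run (`examples/03_case_control_stats.py`) generates a 48-patient/
10-control cohort whose lOFC T1 profiles carry a calibrated additive
elevation (Cohen's d = 0.6, severity correlation 0.27 — less myelin, more
severe depression), then runs the full gated two-stage analysis:

```
lateralization: 0/8 tests significant -> hemispheres averaged downstream

stage 1 (lOFC rows): F(1, 54) per metric, CI is HC - MDD in ms
contrast metric  statistic     p  effect_size_pooled    ci_lo   ci_hi  significant
      T1   mean      4.618 0.036               0.806  -86.457  -3.001         True
      T1    auc      4.621 0.036               0.806 -864.808 -30.117         True
      T1 offset      3.821 0.056               0.714  -91.431   1.156        False
  T2star   mean      0.308 0.581              -0.358   -0.120   0.212        False
  ...
stage 2 (within patients, gated cells):
 roi metric        analysis  statistic     p    ci_lo   ci_hi  n
lOFC   mean             ids      0.095 0.345   -0.096   0.285 47
lOFC   mean             ctq     -0.053 0.601   -0.242   0.133 47
...
```

Reading the output: no hemispheric asymmetry is detected, so profiles are
averaged. The patient group shows a significant T1 elevation in the lOFC
mean and AUC (F(1,54) ≈ 4.6, p ≈ 0.04, negative HC−MDD interval ⇒ higher
T1, i.e. less myelin, in patients) while the T2\* (iron) metrics and the
control region stay null. Stage 2 then reports severity, trauma,
medication and comorbidity analyses for the gated cells only. With 10
controls the design is deliberately low-powered, so stage-1 significance
varies across seeds exactly as a single real cohort would.

Other examples: `01_t1_t2star_mapping.py` (signal model, lookup inversion
and T2\* fitting, with noise) and `02_phantom_profiles.py` (voxel-level
phantom → maps → depth field → lOFC profile and metrics).

A thin CLI mirrors the pipeline for shell use:

```bash
laminarq run-all --seed 2 --out results/demo
laminarq simulate --out results/sim --n-phantoms 1   # NIfTI phantom export
```

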