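# intracort

Longitudinal mapping of relative intracortical myelin content from
T1-weighted / T2-weighted MRI intensity ratios.

## The problem

T1w intensity rises with cortical myelin content and T2w intensity falls
with it, so the voxelwise ratio **R = T1w / T2w** is a practical in-vivo
proxy for relative intracortical myelin that cancels multiplicative
nuisance fields shared by the two acquisitions. Tracking R across two
scans per subject lets one ask how much myelin the cortex loses over time —
in healthy aging, and after a mild traumatic brain injury (mTBI) — and
*where*. The statistical difficulty is that a realistic design confounds
everything of interest: the healthy-control group is older, scanned on
different hardware, and rescanned after ~3.3 years, while the injured group
is younger, scanned on one scanner, and rescanned after ~6 months.

`intracort` implements the full analysis for two-visit, two-group cohorts:

* **ratio volumes** — voxelwise R with guarded division and gray-matter
  masking (`compute_ratio_volume`, `mask_to_gm`);
* **surface sampling** — each white-surface vertex receives a
  length-weighted average of R over the voxels traversed by the straight
  transcortical segment to its paired pial vertex, via exact ray–voxel
  marching with partial-voxel weights (`sample_surface`,
  `trace_segment_voxels`), then parcel-wise aggregation
  (`vertex_map_to_regions`);
* **longitudinal statistics** — per-subject fractional change
  `ΔR = (R_f − R_b)/R_b` after regressing age and sex out of the visitwise
  values, linear rescaling of all changes to the mTBI group's mean
  interscan interval, Welch tests per region with Holm family-wise
  correction, z-difference maps `Δz = z_TBI − z_HC`, leave-one-out regional
  vulnerability `v = (ΔR_r − ΔR_S)/ΔR_S`, and an age-overlap sensitivity
  subset (`DeltaRModel`);
* **a mixed model** — `y = Xβ + Zu + ε` with fixed effects diagnosis, age,
  sex, scanner and age × sex, and per-subject random intercept and slope on
  `Δt`, the deviation of the subject's interscan interval from the
  grand-mean interval (`MyelinMixedModel`, ML fitting, likelihood-ratio /
  AIC / BIC comparison via `compare_models`);
* **cognition** — BTACT-style scores standardized against reference norms,
  Spearman correlations with myelin measures, Benjamini–Yekutieli FDR
  control under dependence (`correlation_battery`);
* **a synthetic cohort generator** — spherical-shell cortex phantoms and
  two-group longitudinal region tables with known injected decline, so
  every stage can be validated against exact ground truth
  (`make_longitudinal_cohort`, `make_image_cohort`, `PhantomSpec`).

The package follows the statsmodels idiom: build a model object from a
DataFrame, call `.fit()`, read a results object with a `summary()`.

## Worked example

```python
import intracort as ic

cohort, truth = ic.make_longitudinal_cohort(ic.CohortConfig(seed=7))
result = ic.DeltaRModel(cohort).fit()
print(result.summary())
```

```
Regional ΔR analysis
  groups: HC n=80, mTBI n=97
  target ISI: 0.50 y; alpha=0.05; correction=holm
  mean ΔR (mTBI, at target ISI): -19.49 %
  mean ΔR (HC, interpolated):    -0.98 %
  regions with adjusted p < alpha: 8 / 8

 region_id          region_name  delta_r_tbi  delta_r_hc    diff   v_tbi  delta_z  p_adjusted
         0   inferior_occipital      -0.2014     -0.0100 -0.1914  0.0386   0.0153      0.0000
         2       occipital_pole      -0.1564     -0.0077 -0.1487 -0.2192  -0.0151      0.0000
         7        temporal_pole      -0.1986     -0.0102 -0.1884  0.0219  -0.0060      0.0000
         ...
```

(Abbreviated; the real table has one row per region with both native- and
rescaled-interval HC changes.) Reading the numbers: the generator injects a
20 % loss per 0.5 y after mTBI and 2 %/yr in controls, so the fitted mTBI
mean change at the 0.5-y target interval is ≈ −20 %, the interpolated
healthy reference is ≈ −1 %, and their difference is ≈ −19 percentage
points in every region. The designated occipital region declines at 0.78×
the group rate, and its recovered vulnerability `v_tbi ≈ −0.22` says it
experiences 22 % *less* demyelination than the rest of the cortex. All
eight regional Welch tests survive Holm correction.

The same analysis runs from the shell:

```sh
intracort simulate --seed 7 --out sim/
intracort stats --cohort sim/cohort.csv --out results/
intracort run --seed 7 --out results/      # simulate + stats + cognition
```

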