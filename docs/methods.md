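# Methods

`intracort` implements a longitudinal analysis of relative intracortical
myelin content measured by the T1w/T2w MRI intensity ratio, together with a
synthetic-cohort generator that supplies ground truth for every stage. This
note records the model, the defaults, the numerical choices and their
rationale, and what the synthetic data does and does not establish.

## The myelin measure

T1-weighted intensity increases with myelin and T2-weighted intensity
decreases with it, so the voxelwise ratio `R = T1w / T2w` amplifies the
myelin signal while cancelling multiplicative fields common to both
acquisitions. `compute_ratio_volume` divides co-registered, bias-corrected
volumes voxel by voxel; voxels whose T2 intensity falls below a relative
floor (`1e-6` times the 99th percentile of valid T2, unit-independent) are
marked *invalid* rather than given a number, and invalid voxels propagate as
missing through all downstream averages — zero-filling would bias weighted
means downward. `R` is not clipped to a physiological range before
averaging. Gray-matter restriction is a label-mask intersection
(`mask_to_gm`).

## Surface sampling

Each white-surface (GM/WM interface) vertex is paired with a pial vertex —
by stored index correspondence by default (`search_ring=0`), optionally by
nearest-neighbor search within the k-ring mesh neighborhood of the
corresponded vertex (`search_ring=k`), a topological constraint that keeps
pairings local on the mesh. The straight transcortical segment between the
paired vertices is traversed through the ratio volume by exact ray–box
marching: endpoints are mapped through the inverse affine, every integer
plane crossing is located analytically, and each sub-interval's world-mm arc
length is the in-voxel weight. A voxel spans the half-open cube `[i, i+1)`
in voxel coordinates, so crossing points belong deterministically to the
voxel being entered; in-voxel lengths sum to the segment length to within
1e-9 mm by construction. The vertex value is the length-weighted mean of
`R` over traversed voxels that are gray matter *and* valid, renormalized
over the contributing length; a vertex with no such voxel is missing.
Segment length doubles as the cortical-thickness proxy, and
`normalize_by_icv` provides head-size normalization of regional summaries.

Regional aggregation follows a fixed order for group maps: average across
subjects at each vertex first, then across the vertices of a parcel, with
missing vertices excluded from both stages. Subject-level statistics use
per-subject regional means instead.

## Longitudinal statistics

With baseline `R_b` and follow-up `R_f`, the subject- and region-wise
fractional change is `ΔR = (R_f − R_b) / R_b`. Age and sex are regressed
out of `R_b` and `R_f` (OLS residuals plus the restored mean) before `ΔR`
is formed; the interscan interval (ISI) is deliberately not regressed out
because it carries the longitudinal effect of interest. Adjustment is
performed **within each diagnostic group** by default: the two groups'
ages barely overlap, so a pooled age regression would absorb part of the
diagnosis effect into the age coefficient (measured on synthetic cohorts:
the injected −20 % mTBI change shrinks to −16 % under pooled adjustment and
is recovered unbiasedly under per-group adjustment). A pooled option
remains for sensitivity checks.

Because the groups' ISIs differ (mean 3.3 y vs 0.5 y), changes are referred
to a common interval — the mTBI group's mean ISI — assuming a constant rate
of change: `ΔR × target / own_ISI`. The healthy-control reference change at
that interval is obtained per subject by the same linear rescaling, then
averaged per region; regional tables report both the native-interval and
rescaled HC change, since either convention is defensible.

Group contrasts per region use Welch's two-sided t test (Satterthwaite
degrees of freedom) on the rescaled per-subject changes; within-group
baseline-vs-follow-up contrasts use the paired t test. Family-wise error
across regions is controlled with Holm's step-down procedure (uniformly
more powerful than Bonferroni at the same guarantee; Bonferroni available
as an option).

Two descriptive maps complement the tests. The **z-difference map**
standardizes each group's regional mean-R map across regions (mean 0, sd 1
within group — no assumption that the groups share distribution
parameters, which matters when scan parameters differ) and reports
`Δz = z_TBI − z_HC` per region; it flags regions whose relative standing
differs at baseline. The **vulnerability** of region r is the
leave-one-out relative excess change, `v = (ΔR_r − ΔR_S) / ΔR_S` with S
all other regions; positive v means v·100 % more demyelination than the
rest of the cortex. Leave-one-out means are compared to zero exactly (no
tolerance); a zero mean yields an undefined (NaN) v.

The age-overlap sensitivity analysis keeps controls younger than the
oldest mTBI subject and mTBI subjects older than the youngest control, and
re-runs the identical ΔR procedure on the subset.

## The mixed model

Cortex-mean (or per-region) `R` from both visits is modeled as
`y = Xβ + Zu + ε` with fixed effects intercept, diagnosis (0 = HC,
1 = mTBI), age, sex (0/1), scanner (0 = Siemens, 1 = GE) and age × sex, and
per-subject random effects accounting for ISI variability: a random
intercept `b0 ~ N(0, σ0²)` and a random slope `b1 ~ N(0, σ1²)` on `Δt`,
the deviation of the subject's ISI from the **grand-mean** ISI across both
groups (`Δt = 0` at baseline). Grand-mean rather than group-mean centering
is essential: group-wise centering would absorb part of the
time-by-diagnosis interaction the model must retain. Intercept and slope
are independent by default (diagonal G), matching the separate priors; a
correlated 2×2 option exists behind a flag. Age enters linearly by
default, with an option for polynomial terms, and fitting is by maximum
likelihood (not REML) so that likelihood-ratio comparisons between nested
fixed-effect models are valid; model comparison reports the LR statistic,
its chi-square p value, and AIC/BIC of both models.

Estimation is delegated to statsmodels' `MixedLM`, which profiles a
Cholesky-parameterized covariance; the optimizer runs L-BFGS with gradient
tolerance 1e-6, step tolerance 1e-12 and an iteration cap of 1e5, and a
derivative-free (Powell/Nelder–Mead) restart is attempted whenever the
gradient method reports non-convergence, keeping whichever optimum has the
higher likelihood. Non-convergence is reported via a flag, never raised.

## Cognition

Six BTACT subscores (EVMI, EVMD, WMS, VF, IR, PS) are standardized against
reference-cohort norms as `z = (x − μ)/σ` (norms are configuration inputs;
the generator emits self-consistent ones). Associations with myelin
measures use Spearman's rank correlation (average ranks for ties) with a
two-sided p from the t approximation for n > 10 and the exact permutation
distribution for n ≤ 10. Because the subscores are intercorrelated, the
battery is corrected with the Benjamini–Yekutieli step-up rule, whose
harmonic-sum penalty `c(m) = Σ 1/i` buys false-discovery-rate control
under arbitrary dependence; the multiplicity family is one battery per
call and is deliberately configurable, since the appropriate family is a
study-design choice.

## The synthetic cohort generator

The generator defines the study conditions and supplies exact ground
truth. Defaults: 80 healthy controls (ages truncated-normal 75.4 ± 7 y on
[60, 90], 53 % male, 70/80 on a GE scanner, ISI 3.3 ± 0.8 y) and 97 mTBI
subjects (43.1 ± 17 y on [19, 79], 63 % male, all Siemens, ISI
0.5 ± 0.03 y). The printed age dispersions of the emulated design are not
usable as standard deviations (they exceed the printed ranges), so the
sds above are chosen to respect the printed means and ranges. Regional
baselines are anchored to printed healthy-cortex values (inferior
occipital 1.25 … temporal pole 0.96, eight regions by default; a 74-region
variant spans the same range for whole-parcellation studies). Injected
decline: 2 %/yr of baseline in controls and 40 %/yr (20 % per 0.5-y
interval) after mTBI, with the designated occipital region declining at
0.78× the group rate in both groups — 22 % less demyelination than the
rest of the cortex. An optional acute deficit multiplies mTBI levels in
designated regions at both visits, emulating primary-injury demyelination
present from baseline.

Noise model: a per-subject baseline level factor (log-normal, sd 0.03), a
per-subject decline-rate jitter (log-normal, **mean one**, sd 0.10 — mean
one so the injected group change is exact in expectation), and per
region × visit multiplicative measurement noise (log-normal, mean one, sd
0.01, with a configurable within-subject regional correlation, since the
true correlation is not identified). Age, sex and scanner act
multiplicatively on R levels (log-linear), so they cancel exactly in ΔR —
which is why the pipeline's scanner-offset robustness holds by
construction under multiplicative models. All randomness flows through
per-subject substreams derived by stable hashing of the subject id from a
single seed; identical configuration and seed give byte-identical tables.

The image-fidelity path renders the same trajectories as spherical-shell
T1/T2/GM phantoms: two concentric icospheres (white at 25 mm, pial at
28 mm by default) in a 64³ 1-mm grid, sector parcels by longitude, T2 = 1
and T1 = regional R inside the shell, independent multiplicative
log-normal noise on T1 and T2 (the T1 factor de-biased so the *ratio* has
expectation exactly the target). A spherical shell exercises segment
tracing, pairing and parcel statistics with exact geometric truth;
gyrification, scanner physics and bias fields are intentionally absent, so
passing tests demonstrate correctness of the algorithms, not robustness to
folded-cortex geometry or acquisition artifacts. Sector-boundary voxels
are shared between parcels, which bounds noiseless regional recovery at
the default resolution to within 1 % rather than machine precision.

## Problem sizes and tolerances

Simulation-based checks use sizes that keep the full suite fast while
leaving Monte-Carlo error well below the effects tested: 50 replicates of
40 + 40 subjects for injected-effect recovery (recovered group difference
and vulnerability are required within 2 Monte-Carlo standard errors of the
injected −19 pp and −0.22); 500 replicates of 100-subject cohorts for the
null likelihood-ratio calibration (rejection rate in [0.03, 0.07] at
α = 0.05) and 200 for fixed-effect unbiasedness; 500 study-size cohorts
with 74 regions and no effect for family-wise control (any-rejection
probability ≤ 0.05 plus twice the binomial simulation error). Exact
identities (ΔR, rescaling, vulnerability, z-scores, Holm/BY thresholds)
are asserted at 1e-12; traversal length conservation at 1e-9 mm; agreement
with a 10⁴-point dense-sampling oracle at 1e-3 relative.

## Known limitations

* The phantom is unfolded; partial-volume behavior on real, curved cortex
  is not represented.
* Inter-subject surface registration is out of scope — synthetic subjects
  share the template mesh by construction.
* The per-region Welch test's far-tail calibration degrades for small
  cohorts (any-rejection inflation was measured at n = 40 per group and
  vanishes at study size); family-wise guarantees are therefore stated at
  the study's cohort sizes.
* Bias-field correction, registration and segmentation are upstream
  contracts, not package functionality.
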