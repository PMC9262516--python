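"""Longitudinal regional statistics for myelin change.

Implements the regional analysis of two-visit T1w/T2w ratio cohorts:

* confound adjustment of baseline/follow-up R (residualize on age and sex,
  restore the grand mean);
* the fractional change ΔR = (R_f - R_b) / R_b per subject and region;
* linear rescaling of ΔR to a common interscan interval (ISI), and the
  interpolated healthy-control reference change at the mTBI mean ISI;
* Welch and paired t tests with Holm (or Bonferroni) family-wise correction;
* z-score difference maps Δz = z_TBI - z_HC, where each group's regional
  mean-R map is standardized across regions within the group;
* the leave-one-out regional vulnerability v = (u(ΔR_r) - u(ΔR_S)) / u(ΔR_S);
* the age-overlap sensitivity subset.

`DeltaRModel` bundles the full procedure behind a statsmodels-style
Model/Results pair; the individual operations are importable functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "isi_deviations",
    "adjust_for_confounds",
    "compute_delta_r",
    "rescale_delta_linear",
    "interpolate_reference_delta",
    "paired_t",
    "welch_t",
    "fwe_correct",
    "region_zscores",
    "delta_z",
    "vulnerability",
    "group_delta_difference",
    "age_overlap_subset",
    "DeltaRModel",
    "DeltaRResults",
]


# ---------------------------------------------------------------- primitives


def isi_deviations(isis: pd.Series | np.ndarray) -> np.ndarray:
    """Deviations Δt_i = u(t) - t_i of each ISI from the grand mean.

    The grand mean is taken across *both* diagnostic groups; group-wise
    centering would absorb part of the time-by-diagnosis interaction that the
    mixed model is meant to retain.
    """
    t = np.asarray(isis, dtype=float)
    if t.size == 0:
        raise ValueError("empty cohort")
    if np.any(t <= 0):
        raise ValueError("interscan intervals must be strictly positive")
    return t.mean() - t


def adjust_for_confounds(values, age, sex) -> np.ndarray:
    """Regress age and sex out of per-subject values, restoring the mean.

    Ordinary least squares on (intercept, age, sex); the returned adjusted
    values are the residuals plus the original grand mean, hence uncorrelated
    with age and sex but on the original scale.  ISI is deliberately *not*
    regressed out — it carries the longitudinal effect of interest.
    """
    y = np.asarray(values, dtype=float)
    X = np.column_stack([np.ones_like(y), np.asarray(age, float), np.asarray(sex, float)])
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than covariates")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariates (constant age or sex?)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta + y.mean()


def compute_delta_r(r_baseline, r_followup) -> np.ndarray:
    """Fractional change ΔR = (R_f - R_b) / R_b."""
    rb = np.asarray(r_baseline, dtype=float)
    rf = np.asarray(r_followup, dtype=float)
    if np.any(rb <= 0):
        raise ValueError("baseline R must be positive")
    return (rf - rb) / rb


def rescale_delta_linear(delta_r, isi_years, target_isi_years) -> np.ndarray:
    """Rescale a fractional change to a target interval, assuming a constant
    rate of change (linear interpolation/extrapolation in time)."""
    isi = np.asarray(isi_years, dtype=float)
    if np.any(isi <= 0) or target_isi_years <= 0:
        raise ValueError("interscan intervals must be strictly positive")
    return np.asarray(delta_r, dtype=float) * target_isi_years / isi


def interpolate_reference_delta(
    hc_table: pd.DataFrame, target_isi_years: float,
    value_col: str = "R",
) -> pd.Series:
    """Expected per-region ΔR of the reference (HC) group at a target ISI.

    Each HC subject's ΔR is computed from their two visits, linearly rescaled
    from their own ISI to ``target_isi_years``, then averaged per region.
    Subjects missing a visit are dropped with a warning-free skip (the
    returned n accounts for it).
    """
    wide = hc_table.pivot_table(
        index=["subject_id", "region_id"], columns="visit", values=value_col
    )
    wide = wide.dropna(subset=["baseline", "followup"])
    isi = hc_table.groupby("subject_id")["isi_years"].first()
    dr = compute_delta_r(wide["baseline"], wide["followup"])
    scaled = rescale_delta_linear(
        dr, isi.loc[wide.index.get_level_values("subject_id")].to_numpy(), target_isi_years
    )
    out = pd.Series(scaled, index=wide.index).groupby("region_id").mean()
    out.name = "delta_r_hc"
    return out


# ------------------------------------------------------------------- tests


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    df: float


def paired_t(before, after) -> TestResult:
    """Two-sided paired-sample t test of equal means."""
    a = np.asarray(before, float)
    b = np.asarray(after, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("paired samples of equal length >= 3 required")
    d = b - a
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return TestResult(0.0, 1.0, len(a) - 1.0)
    res = stats.ttest_rel(b, a)
    return TestResult(float(res.statistic), float(res.pvalue), float(res.df))


def welch_t(x, y) -> TestResult:
    """Welch's two-sided t test (Satterthwaite df) for heteroskedastic samples."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per sample")
    if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
        if np.allclose(x.mean(), y.mean()):
            return TestResult(0.0, 1.0, float(len(x) + len(y) - 2))
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), float(res.df))


def fwe_correct(pvalues, alpha: float = 0.05, method: str = "holm"):
    """Family-wise error correction across regions.

    Holm's step-down procedure by default (uniformly more powerful than
    Bonferroni at the same guarantee); ``method="bonferroni"`` is available.
    Returns ``(reject, p_adjusted)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if method not in {"holm", "bonferroni"}:
        raise ValueError(f"unsupported correction {method!r}")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method=method)
    return reject, p_adj


# --------------------------------------------------------------- map scores


def region_zscores(region_means: pd.Series | np.ndarray) -> np.ndarray:
    """Standardize one group's regional mean-R map across regions.

    z_j = (R_j - u(R)) / sigma(R) with u, sigma over the group's regions, so
    each group's map has mean 0 and sd 1 without assuming the two groups
    share distribution parameters.
    """
    x = np.asarray(region_means, dtype=float)
    sd = x.std(ddof=0)
    if sd <= 0:
        raise ValueError("zero variance across regions; z-scores undefined")
    return (x - x.mean()) / sd


def delta_z(tbi_region_means, hc_region_means) -> np.ndarray:
    """Δz = z_TBI - z_HC per region, each group standardized within itself."""
    return region_zscores(tbi_region_means) - region_zscores(hc_region_means)


def vulnerability(region_delta_r) -> np.ndarray:
    """Leave-one-out relative excess demyelination per region.

    v_r = (u(ΔR_r) - u(ΔR_S)) / u(ΔR_S), with S all other regions.  Positive
    v means the region loses v*100 % more myelin than the rest of the cortex.
    Regions whose leave-one-out mean is zero get NaN (undefined).
    """
    x = np.asarray(region_delta_r, dtype=float)
    if x.size < 2:
        raise ValueError("vulnerability needs at least two regions")
    loo = (x.sum() - x) / (x.size - 1)
    out = np.full_like(x, np.nan)
    nz = loo != 0
    out[nz] = (x[nz] - loo[nz]) / loo[nz]
    return out


def group_delta_difference(delta_r_tbi, delta_r_hc) -> np.ndarray:
    """Per-region difference u(ΔR_TBI) - u(ΔR_HC) (HC interpolated to the
    mTBI mean ISI upstream)."""
    return np.asarray(delta_r_tbi, float) - np.asarray(delta_r_hc, float)


def age_overlap_subset(cohort: pd.DataFrame) -> pd.DataFrame:
    """Restrict to the age-overlap subgroups.

    HCs are kept iff younger than the oldest mTBI subject; mTBI subjects are
    kept iff older than the youngest HC, yielding subgroups with identical
    age ranges for the sensitivity re-analysis.
    """
    ages = cohort.groupby("subject_id").agg(
        group=("group", "first"), age=("age_years", "first")
    )
    hc = ages[ages.group == "HC"]
    tbi = ages[ages.group != "HC"]
    if hc.empty or tbi.empty:
        raise ValueError("both diagnostic groups must be present")
    keep_hc = hc.index[hc.age < tbi.age.max()]
    keep_tbi = tbi.index[tbi.age > hc.age.min()]
    keep = set(keep_hc) | set(keep_tbi)
    if not keep_hc.size or not keep_tbi.size:
        raise ValueError("age ranges do not overlap; sensitivity subset is empty")
    return cohort[cohort.subject_id.isin(keep)].copy()


# ---------------------------------------------------------- model / results


@dataclass
class DeltaRResults:
    """Results of the regional ΔR analysis.

    ``region_table`` has one row per region with the group mean fractional
    changes (both at each group's native ISI and rescaled to the target ISI),
    their difference, vulnerability per group, baseline Δz, and Welch p
    values raw and family-wise adjusted.
    """

    region_table: pd.DataFrame
    target_isi_years: float
    alpha: float
    correction: str
    n_subjects: dict[str, int]
    subject_deltas: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def summary(self) -> str:
        t = self.region_table
        lines = [
            "Regional ΔR analysis",
            f"  groups: HC n={self.n_subjects.get('HC', 0)}, "
            f"mTBI n={self.n_subjects.get('mTBI', 0)}",
            f"  target ISI: {self.target_isi_years:.2f} y; "
            f"alpha={self.alpha}; correction={self.correction}",
            f"  mean ΔR (mTBI, at target ISI): {100 * t.delta_r_tbi.mean():+.2f} %",
            f"  mean ΔR (HC, interpolated):    {100 * t.delta_r_hc.mean():+.2f} %",
            f"  regions with adjusted p < alpha: {int(t.significant.sum())} / {len(t)}",
            "",
            t.to_string(index=False, float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


class DeltaRModel:
    """The regional longitudinal ΔR procedure as a fittable model.

    Built from a long-format cohort table (subject x visit x region rows of
    R with covariates), ``fit()`` runs: confound adjustment per region and
    visit -> per-subject ΔR -> rescaling of mTBI changes to the group's mean
    ISI and interpolation of the HC reference change to the same interval ->
    Welch tests per region with family-wise correction -> difference, Δz and
    vulnerability maps.

    Parameters
    ----------
    cohort
        Long-format table with columns subject_id, group (HC/mTBI), sex,
        age_years, scanner, visit (baseline/followup), isi_years, region_id,
        region_name (optional), R.
    target_isi_years
        Interval to which all changes are referred; defaults to the mTBI
        group's mean ISI.
    adjust
        "per-group" (default) residualizes age/sex within each diagnostic
        group, preserving each group's mean change; "pooled" residualizes
        across both groups jointly (with age confounded with diagnosis this
        also absorbs part of the group effect); "none" skips.
    """

    REQUIRED = {"subject_id", "group", "sex", "age_years", "visit", "isi_years", "region_id", "R"}

    def __init__(
        self,
        cohort: pd.DataFrame,
        target_isi_years: float | None = None,
        alpha: float = 0.05,
        correction: str = "holm",
        adjust: str = "per-group",
    ) -> None:
        missing = self.REQUIRED - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
        if adjust not in {"pooled", "per-group", "none"}:
            raise ValueError(f"unknown adjust mode {adjust!r}")
        bad = cohort.groupby("subject_id")["visit"].nunique()
        if (bad != 2).any():
            raise ValueError("every subject needs exactly one baseline and one follow-up")
        if (cohort["R"] <= 0).any():
            raise ValueError("R values must be positive")
        self.cohort = cohort.copy()
        self.alpha = alpha
        self.correction = correction
        self.adjust = adjust
        if target_isi_years is None:
            target_isi_years = (
                cohort[cohort.group == "mTBI"].groupby("subject_id")["isi_years"].first().mean()
            )
        self.target_isi_years = float(target_isi_years)

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "DeltaRModel":
        return cls(cohort, **kwargs)

    @staticmethod
    def _residualize(matrix: np.ndarray, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        """Residualize all region columns at once, restoring column means."""
        if matrix.shape[0] <= 3:
            raise ValueError("need more observations than covariates")
        X = np.column_stack([np.ones(len(age)), age, sex])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient covariates (constant age or sex?)")
        beta, *_ = np.linalg.lstsq(X, matrix, rcond=None)
        return matrix - X @ beta + matrix.mean(axis=0, keepdims=True)

    # internal: adjusted wide table (subject x region, columns baseline/followup)
    def _adjusted_wide(self) -> pd.DataFrame:
        df = self.cohort
        subj = df.groupby("subject_id").agg(
            group=("group", "first"), sex=("sex", "first"),
            age=("age_years", "first"), isi=("isi_years", "first"),
        )
        mats = {
            visit: df[df.visit == visit].pivot_table(
                index="subject_id", columns="region_id", values="R"
            )
            for visit in ("baseline", "followup")
        }
        subjects = mats["baseline"].index
        if not mats["followup"].index.equals(subjects):
            raise ValueError("baseline and follow-up cover different subjects")
        meta = subj.loc[subjects]
        age = meta.age.to_numpy()
        sex = meta.sex.to_numpy()
        for visit in mats:
            values = mats[visit].to_numpy(dtype=float)
            if self.adjust == "pooled":
                values = self._residualize(values, age, sex)
            elif self.adjust == "per-group":
                for grp in meta.group.unique():
                    sel = (meta.group == grp).to_numpy()
                    values[sel] = self._residualize(values[sel], age[sel], sex[sel])
            mats[visit] = pd.DataFrame(values, index=subjects, columns=mats[visit].columns)

        long = pd.concat(
            {visit: m.stack() for visit, m in mats.items()}, axis=1
        ).reset_index()
        long.columns = ["subject_id", "region_id", "baseline", "followup"]
        long["group"] = meta.group.loc[long.subject_id].to_numpy()
        long["isi_years"] = meta.isi.loc[long.subject_id].to_numpy()
        return long

    def fit(self) -> DeltaRResults:
        adj = self._adjusted_wide()
        if (adj["baseline"] <= 0).any():
            raise ValueError("confound adjustment produced nonpositive baseline R")
        adj["delta_r"] = compute_delta_r(adj["baseline"], adj["followup"])
        adj["delta_r_scaled"] = rescale_delta_linear(
            adj["delta_r"], adj["isi_years"], self.target_isi_years
        )

        region_ids = np.sort(adj.region_id.unique())
        names = (
            self.cohort.drop_duplicates("region_id").set_index("region_id")["region_name"]
            if "region_name" in self.cohort.columns
            else pd.Series({r: f"region_{r}" for r in region_ids})
        )

        tbi = adj[adj.group == "mTBI"]
        hc = adj[adj.group == "HC"]
        if tbi.empty or hc.empty:
            raise ValueError("both diagnostic groups must be present")

        g_tbi = tbi.groupby("region_id")["delta_r_scaled"].mean().reindex(region_ids)
        g_hc_scaled = hc.groupby("region_id")["delta_r_scaled"].mean().reindex(region_ids)
        g_hc_native = hc.groupby("region_id")["delta_r"].mean().reindex(region_ids)
        g_tbi_native = tbi.groupby("region_id")["delta_r"].mean().reindex(region_ids)

        # vectorized Welch test per region (identical to welch_t columnwise)
        x = tbi.pivot_table(index="subject_id", columns="region_id",
                            values="delta_r_scaled").reindex(columns=region_ids).to_numpy()
        y = hc.pivot_table(index="subject_id", columns="region_id",
                           values="delta_r_scaled").reindex(columns=region_ids).to_numpy()
        nx, ny = x.shape[0], y.shape[0]
        if nx < 3 or ny < 3:
            raise ValueError("need at least 3 subjects per group")
        vx = x.var(axis=0, ddof=1) / nx
        vy = y.var(axis=0, ddof=1) / ny
        denom = np.sqrt(vx + vy)
        mean_diff = x.mean(axis=0) - y.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = mean_diff / denom
            dof = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
        pvals = np.where(
            denom > 0,
            2.0 * stats.t.sf(np.abs(np.where(denom > 0, tstat, 0.0)),
                             np.where(denom > 0, dof, nx + ny - 2)),
            np.where(np.isclose(mean_diff, 0.0), 1.0, 0.0),
        )
        stats_rows = pvals.tolist()
        reject, p_adj = fwe_correct(stats_rows, alpha=self.alpha, method=self.correction)

        # baseline z-score maps from the groups' regional mean R (unadjusted
        # scale differences are removed by the within-group standardization)
        base = self.cohort[self.cohort.visit == "baseline"]
        base_means = base.groupby(["group", "region_id"])["R"].mean()
        dz = delta_z(
            base_means.loc["mTBI"].reindex(region_ids).to_numpy(),
            base_means.loc["HC"].reindex(region_ids).to_numpy(),
        )

        table = pd.DataFrame(
            {
                "region_id": region_ids,
                "region_name": names.reindex(region_ids).to_numpy(),
                "delta_r_tbi": g_tbi.to_numpy(),
                "delta_r_hc": g_hc_scaled.to_numpy(),
                "delta_r_tbi_native": g_tbi_native.to_numpy(),
                "delta_r_hc_native": g_hc_native.to_numpy(),
                "diff": group_delta_difference(g_tbi.to_numpy(), g_hc_scaled.to_numpy()),
                "v_tbi": vulnerability(g_tbi.to_numpy()),
                "v_hc": vulnerability(g_hc_scaled.to_numpy()),
                "delta_z": dz,
                "p_raw": stats_rows,
                "p_adjusted": p_adj,
                "significant": reject,
            }
        )
        n_subjects = (
            self.cohort.groupby("group")["subject_id"].nunique().to_dict()
        )
        return DeltaRResults(
            region_table=table,
            target_isi_years=self.target_isi_years,
            alpha=self.alpha,
            correction=self.correction,
            n_subjects=n_subjects,
            subject_deltas=adj,
        )
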