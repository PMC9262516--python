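"""Two-group longitudinal cohorts with known regional myelin trajectories.

The generator emulates the study design this package analyzes: an older
healthy-control (HC) group rescanned after a long interval (mean interscan
interval, ISI, 3.3 years) and a younger mild-TBI group rescanned ~6 months
after injury (mean ISI 0.5 years), with group-specific regional decline in
the T1w/T2w ratio R, age/sex/scanner confounds acting multiplicatively on R
levels, and several noise sources.  Ground truth is returned alongside so
every downstream stage can be checked against the injected effects.

Two fidelity levels: the *region* path emits a long-format cohort table
directly (fast, used for statistics); the *image* path emits per-visit T1/T2
phantom volumes for a subset of subjects (slow, used for geometric
end-to-end checks).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phantom import PhantomSpec, RegionalProfile, default_profile, make_intensity_volumes, make_template_geometry

__all__ = [
    "GroupDesign",
    "CohortConfig",
    "make_longitudinal_cohort",
    "make_image_cohort",
    "make_cognition_scores",
    "BTACT_SCALES",
]

# BTACT subscore means/sds at the acute timepoint of the mTBI cohort; used
# both as generator scales and as self-consistent reference norms.
BTACT_SCALES = {
    "EVMI": (3.46, 2.82),
    "EVMD": (2.24, 2.26),
    "WMS": (3.69, 1.57),
    "VF": (12.41, 6.99),
    "IR": (1.40, 1.24),
    "PS": (27.20, 13.95),
}


@dataclass
class GroupDesign:
    """Demographic and scan-schedule parameters for one diagnostic group."""

    n: int
    age_mean: float
    age_sd: float
    age_min: float
    age_max: float
    male_fraction: float
    ge_scanner_fraction: float  # scanner coded 0 = Siemens, 1 = GE
    isi_mean: float
    isi_sd: float
    isi_min: float = 0.05


@dataclass
class CohortConfig:
    """Full generator configuration; defaults are the study conditions."""

    hc: GroupDesign = field(
        default_factory=lambda: GroupDesign(
            n=80, age_mean=75.4, age_sd=7.0, age_min=60.0, age_max=90.0,
            male_fraction=0.53, ge_scanner_fraction=70 / 80,
            isi_mean=3.3, isi_sd=0.8, isi_min=0.25,
        )
    )
    tbi: GroupDesign = field(
        default_factory=lambda: GroupDesign(
            n=97, age_mean=43.1, age_sd=17.0, age_min=19.0, age_max=79.0,
            male_fraction=0.63, ge_scanner_fraction=0.0,
            isi_mean=0.5, isi_sd=0.03, isi_min=0.1,
        )
    )
    subject_random_sd: float = 0.03  # between-subject baseline level (log scale)
    trajectory_sd: float = 0.10  # per-subject decline-rate jitter (mean-one log-normal)
    measurement_sd: float = 0.01  # per region x visit observation noise (multiplicative)
    regional_noise_corr: float = 0.0  # within-subject correlation of regional noise
    age_log_slope: float = -0.002  # confound: log-R per year of age
    sex_log_effect: float = 0.01  # confound: log-R offset for males
    scanner_log_effect: float = 0.01  # confound: log-R offset for GE scanners
    # acute deficit: per-region fractional reduction of mTBI R levels (both
    # visits), emulating primary-injury demyelination present from baseline
    acute_deficit: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_random_sd", "trajectory_sd", "measurement_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.regional_noise_corr <= 1.0:
            raise ValueError("regional_noise_corr must be in [0, 1]")
        for g in (self.hc, self.tbi):
            if g.isi_mean <= 0 or g.isi_min <= 0:
                raise ValueError("interscan intervals must be strictly positive")


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Per-subject substream derived by stable hashing of the subject id."""
    digest = hashlib.blake2s(subject_id.encode(), digest_size=8).digest()
    sub = int.from_bytes(digest, "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence([seed, sub]))


def _trunc_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def _mean_one_lognormal(rng, sd_log, size=None):
    """exp(sd*Z - sd^2/2): multiplicative noise with expectation exactly 1."""
    return np.exp(sd_log * rng.standard_normal(size) - 0.5 * sd_log**2)


def make_longitudinal_cohort(
    config: CohortConfig | None = None,
    profile: RegionalProfile | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a two-visit, two-group regional cohort table.

    Each subject has exactly two visits; at follow-up the noiseless regional
    ratio is ``R_b * (1 - rate * ISI)`` with ``rate`` the group's regional
    annual decline times a per-subject mean-one jitter.  Confounds (age, sex,
    scanner) scale R multiplicatively, so they cancel exactly in the
    fractional change ΔR.

    Returns the long-format cohort table and a ground-truth dict with the
    per-subject rates and the analytic expected ΔR per group and region.
    """
    config = config or CohortConfig()
    profile = profile or default_profile()
    region_ids = profile.region_ids
    n_regions = len(region_ids)
    baseline = profile.baseline_array()

    deficit = np.ones(n_regions)
    if config.acute_deficit:
        name_to_idx = {profile.names[r]: k for k, r in enumerate(region_ids)}
        for name, frac in config.acute_deficit.items():
            if name not in name_to_idx:
                raise ValueError(f"acute_deficit names unknown region {name!r}")
            deficit[name_to_idx[name]] = 1.0 - frac

    rows = []
    truth_rates = {}
    subjects = []
    for group, design, prefix in (("HC", config.hc, "hc"), ("mTBI", config.tbi, "tbi")):
        decline = np.array([profile.annual_decline_frac[group][r] for r in region_ids])
        for i in range(design.n):
            sid = f"{prefix}{i:03d}"
            rng = _subject_rng(config.seed, sid)
            age = _trunc_normal(rng, design.age_mean, design.age_sd, design.age_min, design.age_max)
            sex = int(rng.random() < design.male_fraction)  # 1 = male
            scanner = int(rng.random() < design.ge_scanner_fraction)  # 1 = GE
            isi = max(design.isi_min, rng.normal(design.isi_mean, design.isi_sd))
            level = np.exp(
                config.subject_random_sd * rng.standard_normal()
                + config.age_log_slope * (age - 60.0)
                + config.sex_log_effect * sex
                + config.scanner_log_effect * scanner
            )
            jitter = _mean_one_lognormal(rng, config.trajectory_sd)
            rates = decline * jitter
            r_b = baseline * level
            if group == "mTBI":
                r_b = r_b * deficit
            r_f = r_b * (1.0 - rates * isi)
            if np.any(r_f <= 0):
                raise ValueError(
                    f"decline configuration drives R nonpositive for subject {sid}"
                )
            truth_rates[sid] = rates
            subjects.append(sid)
            for visit, r_true in (("baseline", r_b), ("followup", r_f)):
                if config.measurement_sd > 0:
                    rho = config.regional_noise_corr
                    shared = rng.standard_normal()
                    indep = rng.standard_normal(n_regions)
                    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
                    s = config.measurement_sd
                    obs = r_true * np.exp(s * z - 0.5 * s**2)
                else:
                    obs = r_true
                for k, rid in enumerate(region_ids):
                    rows.append(
                        {
                            "subject_id": sid,
                            "group": group,
                            "sex": sex,
                            "age_years": age,
                            "scanner": scanner,
                            "visit": visit,
                            "isi_years": isi,
                            "region_id": rid,
                            "region_name": profile.names[rid],
                            "R": obs[k],
                        }
                    )

    table = pd.DataFrame(rows)
    truth = {
        "region_ids": region_ids,
        "region_names": [profile.names[r] for r in region_ids],
        "baseline_R": dict(zip(region_ids, baseline)),
        "subject_rates": truth_rates,
        # expected fractional change per region when rescaled to the mTBI
        # group's mean ISI (rate jitter is mean one, so exact in expectation)
        "expected_delta_r_at_target": {
            group: {
                rid: -profile.annual_decline_frac[group][rid] * config.tbi.isi_mean
                for rid in region_ids
            }
            for group in ("HC", "mTBI")
        },
        "target_isi_years": config.tbi.isi_mean,
        "acute_deficit": dict(config.acute_deficit),
    }
    return table, truth


def make_image_cohort(
    config: CohortConfig,
    profile: RegionalProfile,
    spec: PhantomSpec,
    n_per_group: int = 2,
    noise_sd: float = 0.0,
):
    """Image-fidelity path: per-visit T1/T2/GM phantom volumes per subject.

    Yields ``(subject_row, visits)`` where ``visits`` maps visit name to the
    ``(t1, t2, gm)`` volume triple, and ``subject_row`` carries the covariates
    plus the per-region truth.  Geometry is the shared template mesh.
    """
    cfg = replace(
        config,
        hc=replace(config.hc, n=min(n_per_group, config.hc.n)),
        tbi=replace(config.tbi, n=min(n_per_group, config.tbi.n)),
        measurement_sd=0.0,
    )
    table, truth = make_longitudinal_cohort(cfg, profile)
    geometry, parcellation = make_template_geometry(spec)
    out = []
    for sid, sub in table.groupby("subject_id", sort=True):
        meta = sub.iloc[0][["subject_id", "group", "sex", "age_years", "scanner", "isi_years"]]
        visits = {}
        for visit in ("baseline", "followup"):
            rsub = sub[sub.visit == visit].set_index("region_id")["R"]
            scale = {rid: rsub[rid] / profile.baseline_R[rid] for rid in profile.region_ids}
            rng_seed = int.from_bytes(
                hashlib.blake2s(f"{sid}|{visit}".encode(), digest_size=4).digest(), "little"
            )
            visits[visit] = make_intensity_volumes(
                geometry, parcellation, profile, spec,
                noise_sd=noise_sd, seed=rng_seed, region_scale=scale,
            )
        out.append((meta, visits))
    return geometry, parcellation, out, truth


def make_cognition_scores(
    cohort: pd.DataFrame,
    coupling: float | dict[str, float] = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    scales: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Six BTACT-style scores per subject and visit, linear in cortical mean R.

    ``score = mu_s + coupling_s * sigma_s * (meanR - mean(meanR)) + eps`` with
    ``eps ~ N(0, (noise_sd * sigma_s)^2)``, where ``(mu_s, sigma_s)`` are the
    per-test scales (defaults anchored to the acute mTBI battery).  Returns
    the cognition table and a self-consistent reference-norms table
    (columns score, mu, sigma) for z-scoring.
    """
    scales = scales or BTACT_SCALES
    mean_r = (
        cohort.groupby(["subject_id", "visit"], sort=True)
        .agg(group=("group", "first"), mean_R=("R", "mean"))
        .reset_index()
    )
    center = mean_r["mean_R"].mean()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC06]))
    rows = []
    for _, rec in mean_r.iterrows():
        row = {"subject_id": rec.subject_id, "visit": rec.visit, "group": rec.group}
        for score, (mu, sigma) in scales.items():
            c = coupling[score] if isinstance(coupling, dict) else coupling
            row[score] = (
                mu
                + c * sigma * (rec.mean_R - center)
                + noise_sd * sigma * rng.standard_normal()
            )
        rows.append(row)
    norms = pd.DataFrame(
        [{"score": s, "mu": mu, "sigma": sd} for s, (mu, sd) in scales.items()]
    )
    return pd.DataFrame(rows), norms
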