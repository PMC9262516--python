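"""Spherical-shell cortex phantoms with known regional myelin profiles.

The phantom is a pair of concentric icosphere meshes (white surface at
``inner_radius_mm``, pial surface offset radially by ``thickness_mm``) with a
sector parcellation, plus T1/T2 intensity volumes whose gray-matter shell
carries a prescribed regional T1/T2 ratio.  It exercises segment tracing,
vertex pairing and parcel statistics with exact ground truth; cortical folding
is deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .surfaces import CorticalSurfacePair, Parcellation
from .volumes import BACKGROUND, GM, WM, LabelVolume, ScalarVolume

__all__ = [
    "PhantomSpec",
    "RegionalProfile",
    "default_profile",
    "parcellation_profile",
    "make_template_geometry",
    "make_intensity_volumes",
]

# Baseline regional T1w/T2w ratios anchored to printed healthy-cortex values:
# primary sensory/occipital cortex is heavily myelinated (ratios ~1.2-1.25),
# cingulate and polar temporal cortex lightly myelinated (~0.96-1.08).
DEFAULT_BASELINES = {
    "inferior_occipital": 1.25,
    "anterior_transverse_temporal": 1.23,
    "occipital_pole": 1.21,
    "transverse_frontopolar": 1.19,
    "subcentral": 1.18,
    "precentral": 1.16,
    "dorsoposterior_cingulate": 1.08,
    "temporal_pole": 0.96,
}


@dataclass
class PhantomSpec:
    """Geometry and grid parameters for a spherical-shell phantom."""

    n_subdivisions: int = 3
    inner_radius_mm: float = 25.0
    thickness_mm: float = 3.0
    n_regions: int = 8
    voxel_size_mm: float = 1.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_regions < 2:
            raise ValueError("n_regions must be at least 2")
        if self.inner_radius_mm <= 0:
            raise ValueError("inner_radius_mm must be positive")

    @property
    def pial_radius_mm(self) -> float:
        return self.inner_radius_mm + self.thickness_mm


@dataclass
class RegionalProfile:
    """Per-region baseline ratio and annual fractional decline by group."""

    baseline_R: dict[int, float]
    annual_decline_frac: dict[str, dict[int, float]] = field(default_factory=dict)
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, r0 in self.baseline_R.items():
            if r0 <= 0:
                raise ValueError(f"baseline_R must be positive (region {rid})")
        if not self.names:
            self.names = {rid: f"region_{rid}" for rid in self.baseline_R}

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.baseline_R)

    def baseline_array(self) -> np.ndarray:
        return np.array([self.baseline_R[r] for r in self.region_ids])


def default_profile(
    hc_decline_per_year: float = 0.02,
    tbi_decline_per_year: float = 0.40,
    low_vulnerability_region: str | None = "occipital_pole",
    low_vulnerability_factor: float = 0.78,
) -> RegionalProfile:
    """Eight-region profile with the study's injected decline rates.

    Healthy aging loses 2 %/yr of baseline; mTBI loses 40 %/yr (20 % over the
    0.5-year mean interscan interval).  The designated occipital region
    declines at ``low_vulnerability_factor`` times the group rate in both
    groups, i.e. 22 % less demyelination than the rest of the cortex.
    """
    names = dict(enumerate(DEFAULT_BASELINES))
    baselines = {rid: DEFAULT_BASELINES[name] for rid, name in names.items()}
    decline = {}
    for group, rate in (("HC", hc_decline_per_year), ("mTBI", tbi_decline_per_year)):
        per_region = {}
        for rid, name in names.items():
            f = low_vulnerability_factor if name == low_vulnerability_region else 1.0
            per_region[rid] = rate * f
        decline[group] = per_region
    return RegionalProfile(baselines, decline, names)


def parcellation_profile(
    n_regions: int = 74,
    hc_decline_per_year: float = 0.02,
    tbi_decline_per_year: float = 0.40,
    baseline_range: tuple[float, float] = (0.96, 1.25),
) -> RegionalProfile:
    """Profile with a full-parcellation region count (74 bilateral regions in
    the Destrieux-style scheme), baselines spanning the printed cortical range
    and uniform group decline rates; used for whole-cortex statistics."""
    lo, hi = baseline_range
    baselines = {i: lo + (hi - lo) * i / max(n_regions - 1, 1) for i in range(n_regions)}
    decline = {
        "HC": {i: hc_decline_per_year for i in range(n_regions)},
        "mTBI": {i: tbi_decline_per_year for i in range(n_regions)},
    }
    return RegionalProfile(baselines, decline, {i: f"parcel_{i:02d}" for i in range(n_regions)})


def _sector_labels(points: np.ndarray, n_regions: int) -> np.ndarray:
    """Assign contiguous angular-sector labels by longitude around +z."""
    theta = np.arctan2(points[:, 1], points[:, 0])  # (-pi, pi]
    frac = (theta + np.pi) / (2 * np.pi)
    labels = np.floor(frac * n_regions).astype(np.int64)
    return np.clip(labels, 0, n_regions - 1)


def make_template_geometry(
    spec: PhantomSpec, seed: int = 0
) -> tuple[CorticalSurfacePair, Parcellation]:
    """Concentric icosphere pair plus a sector parcellation.

    The two meshes share triangulation and vertex indexing; the pial mesh is
    the white mesh scaled radially, so every paired vertex sits exactly
    ``thickness_mm`` away.  Construction is deterministic; ``seed`` is part of
    the interface for forward compatibility with jittered variants.
    """
    del seed  # construction is fully deterministic
    ico = trimesh.creation.icosphere(subdivisions=spec.n_subdivisions, radius=1.0)
    unit = np.asarray(ico.vertices, dtype=float)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    white = unit * spec.inner_radius_mm
    pial = unit * spec.pial_radius_mm
    surfaces = CorticalSurfacePair(white, pial, np.asarray(ico.faces, dtype=np.int64))
    labels = _sector_labels(unit, spec.n_regions)
    names = {i: name for i, name in enumerate(DEFAULT_BASELINES)} if spec.n_regions == len(
        DEFAULT_BASELINES
    ) else {i: f"sector_{i}" for i in range(spec.n_regions)}
    # only keep names for labels that actually occur
    present = np.unique(labels)
    parc = Parcellation(labels, {int(i): names[int(i)] for i in present})
    if len(present) != spec.n_regions:
        raise ValueError("parcellation produced empty sectors; refine the mesh")
    return surfaces, parc


def make_intensity_volumes(
    geometry: CorticalSurfacePair,
    parcellation: Parcellation,
    profile: RegionalProfile,
    spec: PhantomSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    region_scale: dict[int, float] | None = None,
) -> tuple[ScalarVolume, ScalarVolume, LabelVolume]:
    """T1/T2 volumes whose GM shell carries the profile's regional ratios.

    The grid is centered on the sphere; a voxel is GM when its center lies in
    the shell, WM when inside the white sphere, background otherwise.  Within
    GM of region r the expected voxelwise T1/T2 equals ``baseline_R[r]``
    (optionally scaled per region by ``region_scale``, e.g. for follow-up
    visits).  Noise is independent multiplicative log-normal on T1 and T2 with
    standard deviation ``noise_sd`` of the multiplicative factor; the T1
    factor is de-biased so the *ratio* has expectation exactly the target.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    shape = tuple(spec.grid_shape)
    vox = spec.voxel_size_mm
    half = np.array(shape) * vox / 2.0
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = vox
    affine[:3, 3] = -half  # grid centered on the origin (corner convention)

    if spec.pial_radius_mm > min(half):
        raise ValueError("phantom sphere exceeds grid bounds")

    centers_1d = [(np.arange(s) + 0.5) * vox - h for s, h in zip(shape, half)]
    gx, gy, gz = np.meshgrid(*centers_1d, indexing="ij")
    radius = np.sqrt(gx**2 + gy**2 + gz**2)

    labels = np.full(shape, BACKGROUND, dtype=np.int32)
    labels[radius < spec.inner_radius_mm] = WM
    gm_mask = (radius >= spec.inner_radius_mm) & (radius < spec.pial_radius_mm)
    labels[gm_mask] = GM

    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    region = _sector_labels(pts, spec.n_regions).reshape(shape)

    baseline = np.zeros(max(profile.region_ids) + 1)
    for rid in profile.region_ids:
        s = region_scale.get(rid, 1.0) if region_scale else 1.0
        baseline[rid] = profile.baseline_R[rid] * s

    t1 = np.full(shape, 0.05)
    t2 = np.full(shape, 0.05)
    t1[labels == WM] = 1.6  # WM: bright T1, dark T2 -> high ratio
    t2[labels == WM] = 0.8
    t2[gm_mask] = 1.0
    t1[gm_mask] = baseline[region[gm_mask]]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        # sd of exp(sigma Z) is ~sigma for small sigma; solve exactly
        sigma = np.sqrt(np.log1p(noise_sd**2))
        f1 = np.exp(sigma * rng.standard_normal(shape) - sigma**2)
        f2 = np.exp(sigma * rng.standard_normal(shape))
        # E[f1] * E[1/f2] = exp(-sigma^2/2) * exp(sigma^2/2)... the ratio
        # f1/f2 = exp(sigma(Z1 - Z2) - sigma^2) has expectation exactly 1.
        t1 = t1 * f1
        t2 = t2 * f2

    return (
        ScalarVolume(t1, affine),
        ScalarVolume(t2, affine),
        LabelVolume(labels, affine),
    )
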