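"""Synthetic cohorts and voxel datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes,
without any real data:

* **Cohort** — subjects are assigned to the 8 ATN groups with fixed sizes
  (defaults follow the reference cohort profile, n = 437, so rare groups
  stay rare).  Each biomarker is drawn from the normal or abnormal Gaussian
  component dictated by the subject's group flags — bimodal across the
  cohort, consistent within a group.  p-tau and t-tau share a configurable
  within-subject correlation (default 0.7).  Covariates (age per group,
  sex, education, TICV, log-normal WMH) confound hippocampal volume through
  linear coefficients, so covariate adjustment is exercised non-trivially;
  age also rises across later groups, as in observed cohorts.
* **Voxels** — a 3-D grid of GM-volume-like values: baseline + a planted
  region effect at the subject's position along a chosen sequence +
  covariate effects + Gaussian noise, optionally smoothed with a Gaussian
  kernel of given FWHM.  Region profiles are monotone (planted decline),
  biphasic (transient expansion then decline) or null.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference
from .cohort import CohortTable
from .errors import ValidationError
from .images import VoxelDataset, ROIMask
from .sequences import GroupSequence, group_flags

__all__ = [
    "MarkerModel",
    "EffectProfile",
    "Region",
    "SimulationSpec",
    "GroundTruth",
    "simulate_cohort",
    "simulate_voxels",
    "smooth_volume",
    "default_spec",
]


@dataclass(frozen=True)
class MarkerModel:
    """Normal/abnormal Gaussian components for one biomarker."""

    normal_mean: float
    normal_sd: float
    abnormal_mean: float
    abnormal_sd: float

    def __post_init__(self) -> None:
        if self.normal_sd <= 0 or self.abnormal_sd <= 0:
            raise ValidationError("component SDs must be positive")

    def params(self, abnormal: bool) -> tuple[float, float]:
        return (
            (self.abnormal_mean, self.abnormal_sd)
            if abnormal
            else (self.normal_mean, self.normal_sd)
        )


@dataclass(frozen=True)
class EffectProfile:
    """Mean offsets (volume units) at the 4 positions of a sequence."""

    kind: str                        # "monotone" | "biphasic" | "null" | "custom"
    sequence: GroupSequence
    offsets: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=float)
        if off.shape != (4,):
            raise ValidationError("offsets must have length 4")
        if self.kind == "custom":
            pass  # any shape; used to compose truths via overlapping regions
        elif self.kind == "monotone":
            if np.any(np.diff(off) > 0):
                raise ValidationError("monotone profile offsets must be non-increasing")
        elif self.kind == "biphasic":
            if not (off[1] > off[0] and off[3] == off.min()):
                raise ValidationError(
                    "biphasic profile must rise at position 2 and bottom at position 4"
                )
        elif self.kind == "null":
            if np.any(off != 0):
                raise ValidationError("null profile offsets must all be zero")
        else:
            raise ValidationError(f"unknown profile kind {self.kind!r}")


@dataclass(frozen=True)
class Region:
    """Axis-aligned box of voxels sharing one effect profile."""

    name: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open
    profile: EffectProfile

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.box)


def _default_markers() -> dict[str, MarkerModel]:
    # Component means/SDs chosen so per-group marker distributions match the
    # reference cohort profile: a high/low Aβ ratio split, low/high p-tau
    # and t-tau, and preserved/atrophic adjusted hippocampal volume.
    return {
        "abeta_ratio": MarkerModel(0.110, 0.012, 0.060, 0.013),
        "ptau": MarkerModel(41.0, 10.0, 90.0, 30.0),
        "ttau": MarkerModel(300.0, 100.0, 650.0, 250.0),
        "hippocampal_volume": MarkerModel(3140.0, 180.0, 2580.0, 170.0),
    }


def _default_hv_coefs() -> dict[str, float]:
    # μl change per covariate unit: age in years, sex 0/1, education years,
    # TICV ml, WMH ml.
    return {"age": -10.0, "sex": -40.0, "education": 0.0, "ticv": 0.8, "wmh": -5.0}


def _default_voxel_coefs() -> dict[str, float]:
    # modulated-GM units per covariate unit
    return {"age": -0.004, "sex": 0.0, "education": 0.0, "ticv": 0.0002, "wmh": -0.002}


@dataclass(frozen=True)
class SimulationSpec:
    """Everything the generator needs; defaults are the study conditions."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(reference.GROUP_SIZES)
    )
    markers: dict[str, MarkerModel] = field(default_factory=_default_markers)
    tau_correlation: float = 0.7
    #: which group flag picks the t-tau component: "n" (round-trips in
    #: ttau classification mode) or "t" (t-tau tracks tau status, as
    #: observed group means do)
    ttau_component: str = "n"
    ticv_mean: float = 1450.0        # ml
    ticv_sd: float = 130.0
    wmh_log_mean: float = 0.7        # log-ml; median ~2 ml, right-skewed
    wmh_log_sd: float = 1.0
    hv_covariate_coefs: dict[str, float] = field(default_factory=_default_hv_coefs)
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    baseline: float = 0.5            # modulated-GM units inside the head
    background: float = 0.01         # outside the GM box (below mask threshold)
    gm_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = (
        (2, 22), (2, 22), (2, 22)
    )
    regions: tuple[Region, ...] = ()
    voxel_covariate_coefs: dict[str, float] = field(
        default_factory=_default_voxel_coefs
    )
    residual_sd: float = 0.1         # voxel noise SD, modulated-GM units (0 = noiseless)
    smoothing_fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValidationError("group sizes must be non-negative")
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be non-negative")
        if self.smoothing_fwhm_mm < 0:
            raise ValidationError("smoothing FWHM must be non-negative")
        if self.ttau_component not in ("n", "t"):
            raise ValidationError("ttau_component must be 'n' or 't'")
        if min(self.grid_shape) < 1 or self.voxel_size_mm <= 0:
            raise ValidationError("grid dims and voxel size must be positive")
        for reg in self.regions:
            for (lo, hi), dim in zip(reg.box, self.grid_shape):
                if not (0 <= lo < hi <= dim):
                    raise ValidationError(
                        f"region {reg.name!r} box {reg.box} outside grid "
                        f"{self.grid_shape}"
                    )


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    group: pd.Series                       # true group label per subject
    marker_components: pd.DataFrame        # bool per subject x marker (abnormal)
    spec: SimulationSpec
    region_id: np.ndarray | None = None    # int grid, -1 = no region
    region_names: list[str] = field(default_factory=list)

    def region_mask(self, name: str) -> ROIMask:
        idx = self.region_names.index(name)
        return ROIMask(name=name, data=self.region_id == idx)


def default_spec(**overrides) -> SimulationSpec:
    """The default study conditions, with keyword overrides."""
    return replace(SimulationSpec(), **overrides) if overrides else SimulationSpec()


def simulate_cohort(
    spec: SimulationSpec | None = None, seed: int | None = None
) -> tuple[CohortTable, GroundTruth]:
    """Draw a cohort with fixed per-group sizes and component-driven markers."""
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    rows = []
    comp_rows = []
    sid = 0
    for grp, n in spec.group_sizes.items():
        a, t, nflag = group_flags(grp)
        prof = reference.GROUP_PROFILE.get(grp)
        age_mean, age_sd = prof["age"] if prof else (71.0, 5.5)
        pct_female = prof["pct_female"][0] / 100.0 if prof else 0.5
        edu_mean, edu_sd = prof["education"] if prof else (14.0, 3.0)
        for _ in range(n):
            sid += 1
            age = rng.normal(age_mean, age_sd)
            sex = float(rng.random() < pct_female)
            education = max(rng.normal(edu_mean, edu_sd), 5.0)
            ticv = rng.normal(spec.ticv_mean, spec.ticv_sd)
            wmh = float(np.exp(rng.normal(spec.wmh_log_mean, spec.wmh_log_sd)))

            abeta_m, abeta_s = spec.markers["abeta_ratio"].params(a)
            abeta = max(rng.normal(abeta_m, abeta_s), 1e-4)

            # p-tau and t-tau share a latent correlation within subject
            rho = spec.tau_correlation
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]])
            ptau_m, ptau_s = spec.markers["ptau"].params(t)
            ttau_flag = nflag if spec.ttau_component == "n" else t
            ttau_m, ttau_s = spec.markers["ttau"].params(ttau_flag)
            ptau = max(ptau_m + ptau_s * z[0], 1.0)
            ttau = max(ttau_m + ttau_s * z[1], 1.0)

            hv_m, hv_s = spec.markers["hippocampal_volume"].params(nflag)
            coefs = spec.hv_covariate_coefs
            hv = (
                hv_m
                + rng.normal(0.0, hv_s)
                + coefs.get("age", 0.0) * (age - 70.0)
                + coefs.get("sex", 0.0) * (sex - 0.5)
                + coefs.get("education", 0.0) * (education - 14.0)
                + coefs.get("ticv", 0.0) * (ticv - spec.ticv_mean)
                + coefs.get("wmh", 0.0) * (wmh - 3.0)
            )
            rows.append(
                {
                    "subject_id": f"sim{sid:04d}",
                    "age": age, "sex": sex, "education": education,
                    "ticv": ticv, "wmh": wmh,
                    "abeta_ratio": abeta, "ptau": ptau, "ttau": ttau,
                    "hippocampal_volume": max(hv, 100.0),
                    "diagnosis": None,
                }
            )
            comp_rows.append(
                {"abeta_ratio": a, "ptau": t, "ttau": ttau_flag,
                 "hippocampal_volume": nflag, "group": grp}
            )
    df = pd.DataFrame(rows)
    truth = GroundTruth(
        group=pd.Series([r["group"] for r in comp_rows], name="group"),
        marker_components=pd.DataFrame(comp_rows).drop(columns="group"),
        spec=spec,
    )
    return CohortTable(df=df, source="simulate_cohort"), truth


def simulate_voxels(
    cohort: CohortTable,
    truth: GroundTruth,
    spec: SimulationSpec | None = None,
    seed: int | None = None,
) -> tuple[VoxelDataset, GroundTruth]:
    """Generate the voxel stack for a simulated cohort.

    Voxel value = baseline (background outside the GM box) + the region
    profile offset at the subject's position along the region's sequence
    (subjects outside the sequence's states sit at baseline) + covariate
    effects + Gaussian noise, then optional FWHM smoothing.
    """
    spec = spec or truth.spec
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1_000_003)
    n = len(cohort)
    if len(truth.group) != n:
        raise ValidationError("ground-truth groups disagree with cohort size")
    shape = spec.grid_shape

    base = np.full(shape, spec.background)
    if spec.gm_box is None:
        base[:] = spec.baseline
    else:
        base[tuple(slice(lo, hi) for lo, hi in spec.gm_box)] = spec.baseline

    # id map records the *first* region covering a voxel; later overlapping
    # regions still add their offsets (overlays compose additively)
    region_id = np.full(shape, -1, dtype=int)
    offsets_per_subject = np.zeros((len(spec.regions), n))
    for ridx, reg in enumerate(spec.regions):
        sl = reg.slices()
        region_id[sl] = np.where(region_id[sl] == -1, ridx, region_id[sl])
        for i, grp in enumerate(truth.group):
            pos = reg.profile.sequence.position_of(grp)
            if pos is not None:
                offsets_per_subject[ridx, i] = reg.profile.offsets[pos - 1]

    cov = cohort.df
    coefs = spec.voxel_covariate_coefs
    cov_effect = (
        coefs.get("age", 0.0) * (cov["age"].to_numpy() - 70.0)
        + coefs.get("sex", 0.0) * (cov["sex"].to_numpy() - 0.5)
        + coefs.get("education", 0.0) * (cov["education"].to_numpy() - 14.0)
        + coefs.get("ticv", 0.0) * (cov["ticv"].to_numpy() - spec.ticv_mean)
        + coefs.get("wmh", 0.0) * (cov["wmh"].to_numpy() - 3.0)
    )

    values = np.empty((n,) + shape)
    for i in range(n):
        img = base + cov_effect[i]
        for ridx, reg in enumerate(spec.regions):
            img[reg.slices()] += offsets_per_subject[ridx, i]
        img = img + rng.normal(0.0, spec.residual_sd, size=shape)
        if spec.smoothing_fwhm_mm > 0:
            img = smooth_volume(img, spec.smoothing_fwhm_mm, spec.voxel_size_mm)
        values[i] = img

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    dataset = VoxelDataset(
        values=values, affine=affine, subject_ids=cohort.subject_ids
    )
    truth.region_id = region_id
    truth.region_names = [r.name for r in spec.regions]
    return dataset, truth


def smooth_volume(
    image: np.ndarray, fwhm_mm: float, voxel_size_mm: float | np.ndarray
) -> np.ndarray:
    """Gaussian smoothing with a renormalized truncated kernel.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, in mm, converted to voxels.
    Edges divide by the smoothed all-ones image so a constant input stays
    constant (mass-preserving renormalization); FWHM 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValidationError("FWHM must be non-negative")
    image = np.asarray(image, dtype=float)
    if fwhm_mm == 0:
        return image.copy()
    voxel_size = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / voxel_size
    num = ndimage.gaussian_filter(image, sigma=sigma_vox, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(
        np.ones_like(image), sigma=sigma_vox, mode="constant", cval=0.0
    )
    return num / den
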