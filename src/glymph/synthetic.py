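"""Synthetic diffusion phantoms and survival cohorts with known ground truth.

The phantom emulates the anatomy the ALPS index relies on: at the level
of the lateral-ventricle body, projection fibers (superoinferior, z) and
association fibers (anteroposterior, y) run side by side in each
hemisphere, and the perivascular space runs along x, perpendicular to
both.  Phantoms are axis-aligned boxes on a regular grid: per-hemisphere
projection and association fiber slabs flanking a central CSF
"ventricle", embedded in isotropic background tissue.  A perivascular
x-diffusivity elevation can be planted in both fiber regions, which
fixes the ground-truth ALPS index analytically.

The DWI forward model is the two-compartment (bi-tensor) signal

    S(b, g) = S0 [ (1 - f) exp(-b g' D g) + f exp(-b d_iso) ]

with d_iso = 3.0e-3 mm2/s (body-temperature free water) and Rician
magnitude noise, so the same phantoms exercise both the single-tensor
ALPS chain and the free-water fit.

The cohort generator draws per-subject biomarkers, distorts them with
per-site location/scale batch effects, and samples survival times from
a Weibull proportional-hazards model with planted per-SD log hazard
ratios, plus independent uniform censoring calibrated to a target rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glymph.alps import AlpsRoiSet, TumorSegmentation
from glymph.diffusion import DiffusionVolume
from glymph.scheme import AcquisitionScheme

__all__ = [
    "FiberSpec",
    "TensorPhantom",
    "CohortSpec",
    "D_ISO",
    "make_phantom",
    "uniform_phantom",
    "simulate_dwi",
    "make_rois",
    "make_tumor_labels",
    "apply_tumor_to_phantom",
    "hemisphere_nawm_mask",
    "simulate_cohort",
    "COHORT_COLUMNS",
]

#: free-water diffusivity, mm2/s
D_ISO = 3.0e-3

# region label codes
BACKGROUND, PROJ_LEFT, PROJ_RIGHT, ASSOC_LEFT, ASSOC_RIGHT, CSF = 0, 1, 2, 3, 4, 5
REGION_LEGEND = {
    BACKGROUND: "background",
    PROJ_LEFT: "proj_left",
    PROJ_RIGHT: "proj_right",
    ASSOC_LEFT: "assoc_left",
    ASSOC_RIGHT: "assoc_right",
    CSF: "csf",
}

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class FiberSpec:
    """Eigenvalue triple of the fiber tensors, in mm2/s.

    ``dxx`` plants a perivascular x-diffusivity; ``None`` means the
    plain cigar tensor (x diffusivity = lambda_perp, ALPS = 1 between
    fiber regions... i.e. the ground-truth ALPS equals dxx/lambda_perp).
    """

    lambda_parallel: float = 1.4e-3
    lambda_perp: float = 0.3e-3
    dxx: float | None = None

    def __post_init__(self) -> None:
        dxx = self.lambda_perp if self.dxx is None else self.dxx
        if min(self.lambda_parallel, self.lambda_perp, dxx) < 0:
            raise ValueError("fiber eigenvalues must be nonnegative")
        if dxx >= self.lambda_parallel:
            raise ValueError(
                "perivascular dxx must stay below lambda_parallel so the "
                "principal fiber axis is preserved"
            )

    @property
    def x_diffusivity(self) -> float:
        return self.lambda_perp if self.dxx is None else self.dxx

    @property
    def true_alps(self) -> float:
        """Analytic ALPS index of the fiber pair (dxx / lambda_perp)."""
        return self.x_diffusivity / self.lambda_perp


@dataclass
class TensorPhantom:
    """Grid of ground-truth tensors, baseline signal and FW fractions."""

    shape: tuple[int, int, int]
    voxel_size: float
    tensors: np.ndarray  # (x, y, z, 3, 3) mm2/s
    s0: np.ndarray  # (x, y, z)
    fw_true: np.ndarray  # (x, y, z) in [0, 1]
    region_labels: np.ndarray  # (x, y, z) int, REGION_LEGEND codes
    regions: dict[str, Box] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.fw_true < 0) or np.any(self.fw_true > 1):
            raise ValueError("fw_true must lie in [0, 1]")
        evals = np.linalg.eigvalsh(self.tensors)
        if np.any(evals < -1e-12):
            raise ValueError("phantom tensors must be positive semidefinite")

    @property
    def midline(self) -> int:
        return self.shape[0] // 2


def _default_regions(shape: tuple[int, int, int]) -> dict[str, Box]:
    nx, ny, nz = shape
    if min(shape) < 20:
        raise ValueError("structured phantom needs every grid dim >= 20")
    mx = nx // 2
    y_proj = (round(0.25 * ny), round(0.45 * ny))
    y_assoc = (round(0.55 * ny), round(0.75 * ny))
    x_left = (2, mx - 3)
    x_right = (mx + 3, nx - 2)
    z_proj = (2, nz - 2)
    z_assoc = (round(0.2 * nz), round(0.8 * nz))
    csf = ((mx - 2, mx + 2), (y_proj[0], y_assoc[1]), z_assoc)
    return {
        "proj_left": (x_left, y_proj, z_proj),
        "proj_right": (x_right, y_proj, z_proj),
        "assoc_left": (x_left, y_assoc, z_assoc),
        "assoc_right": (x_right, y_assoc, z_assoc),
        "csf": csf,
    }


def _box_slices(box: Box) -> tuple[slice, slice, slice]:
    return tuple(slice(lo, hi) for lo, hi in box)  # type: ignore[return-value]


def _boxes_overlap(a: Box, b: Box) -> bool:
    return all(a[i][0] < b[i][1] and b[i][0] < a[i][1] for i in range(3))


def make_phantom(
    shape: tuple[int, int, int] = (32, 32, 32),
    fibers: FiberSpec | tuple[FiberSpec, FiberSpec] = FiberSpec(),
    fw: float | dict[str, float] = 0.0,
    background_md: float = 0.65e-3,
    include_csf: bool = True,
    voxel_size: float = 1.0,
    regions: dict[str, Box] | None = None,
    seed: int | None = None,
) -> TensorPhantom:
    """Build the structured two-hemisphere fiber phantom.

    ``background_md`` is the *tissue-compartment* diffusivity of the
    non-fiber white matter; the apparent MD seen by a single-tensor fit
    is higher once the planted free-water fraction is mixed in, which
    puts typical NAWM voxels at the in-vivo 0.75-0.85e-3 mm2/s range.

    ``fibers`` is one spec for both hemispheres or a (left, right) pair,
    which lets different perivascular x-diffusivities (hence different
    ground-truth ALPS) be planted per hemisphere.  ``fw`` is either one
    free-water fraction for all tissue regions or a dict over
    {"background", "proj", "assoc"}; CSF is always f = 1.  ``regions``
    overrides the default box layout (same keys as
    :data:`REGION_LEGEND` names).  ``seed`` is accepted for interface
    symmetry; construction is deterministic.
    """
    del seed
    if background_md < 0:
        raise ValueError("background_md must be nonnegative")
    fib_left, fib_right = (
        fibers if isinstance(fibers, tuple) else (fibers, fibers)
    )
    boxes = dict(_default_regions(shape)) if regions is None else dict(regions)
    if not include_csf:
        boxes.pop("csf", None)

    for pk in ("proj_left", "proj_right"):
        for ak in ("assoc_left", "assoc_right"):
            if pk in boxes and ak in boxes and _boxes_overlap(boxes[pk], boxes[ak]):
                raise ValueError(
                    f"fiber regions {pk} and {ak} overlap with conflicting "
                    "orientations"
                )

    if isinstance(fw, dict):
        fw_map = {"background": 0.0, "proj": 0.0, "assoc": 0.0, **fw}
    else:
        fw_map = {"background": float(fw), "proj": float(fw), "assoc": float(fw)}
    for v in fw_map.values():
        if not 0.0 <= v <= 1.0:
            raise ValueError("fw fractions must lie in [0, 1]")

    def _fiber_tensor(kind: str, hemi: str) -> np.ndarray:
        spec = fib_left if hemi == "left" else fib_right
        dxx = spec.x_diffusivity
        if kind == "proj":  # principal axis z
            return np.diag([dxx, spec.lambda_perp, spec.lambda_parallel])
        return np.diag([dxx, spec.lambda_parallel, spec.lambda_perp])  # axis y

    code_of = {
        "proj_left": PROJ_LEFT,
        "proj_right": PROJ_RIGHT,
        "assoc_left": ASSOC_LEFT,
        "assoc_right": ASSOC_RIGHT,
        "csf": CSF,
    }

    tensors = np.broadcast_to(np.diag([background_md] * 3), tuple(shape) + (3, 3)).copy()
    fw_true = np.full(shape, fw_map["background"])
    labels = np.zeros(shape, dtype=np.int16)
    for name, box in boxes.items():
        sl = _box_slices(box)
        if name == "csf":
            tensors[sl] = np.diag([D_ISO] * 3)
            fw_true[sl] = 1.0
        else:
            kind, hemi = name.split("_")
            tensors[sl] = _fiber_tensor(kind, hemi)
            fw_true[sl] = fw_map[kind]
        labels[sl] = code_of[name]

    return TensorPhantom(
        shape=tuple(shape),
        voxel_size=float(voxel_size),
        tensors=tensors,
        s0=np.ones(shape),
        fw_true=fw_true,
        region_labels=labels,
        regions=boxes,
    )


def uniform_phantom(
    shape: tuple[int, int, int] = (16, 16, 16),
    diffusivities: tuple[float, float, float] = (0.3e-3, 0.3e-3, 1.4e-3),
    fw: float = 0.0,
    voxel_size: float = 1.0,
) -> TensorPhantom:
    """A featureless phantom: one axis-aligned tensor and FW everywhere."""
    if min(diffusivities) < 0:
        raise ValueError("diffusivities must be nonnegative")
    tensors = np.broadcast_to(np.diag(diffusivities), tuple(shape) + (3, 3)).copy()
    return TensorPhantom(
        shape=tuple(shape),
        voxel_size=float(voxel_size),
        tensors=tensors,
        s0=np.ones(shape),
        fw_true=np.full(shape, float(fw)),
        region_labels=np.zeros(shape, dtype=np.int16),
        regions={},
    )


def simulate_dwi(
    phantom: TensorPhantom,
    scheme: AcquisitionScheme,
    snr: float = np.inf,
    seed: int = 0,
    noise: str = "rician",
    d_iso: float = D_ISO,
) -> DiffusionVolume:
    """Forward-simulate the bi-tensor signal, then apply magnitude noise.

    ``snr`` is S0 / sigma on the b0 signal (``inf`` disables noise).
    ``noise`` is "rician" (magnitude MRI standard) or "gaussian" (for
    debugging).  Same seed, same output, bit for bit.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if noise not in ("rician", "gaussian"):
        raise ValueError(f"unknown noise model {noise!r}")
    g = phantom.tensors
    if g.shape != tuple(phantom.shape) + (3, 3):
        raise ValueError("phantom tensor grid does not match phantom shape")

    bvecs, bvals = scheme.bvecs, scheme.bvals
    # g' D g per voxel and volume
    quad = np.einsum("ni,...ij,nj->...n", bvecs, phantom.tensors, bvecs)
    f = phantom.fw_true[..., None]
    atten = (1.0 - f) * np.exp(-bvals * quad) + f * np.exp(-bvals * d_iso)
    signal = phantom.s0[..., None] * atten

    if np.isfinite(snr):
        s0_ref = float(np.median(phantom.s0[phantom.s0 > 0]))
        sigma = s0_ref / snr
        rng = np.random.default_rng(seed)
        if noise == "rician":
            e1 = rng.normal(0.0, sigma, signal.shape)
            e2 = rng.normal(0.0, sigma, signal.shape)
            signal = np.sqrt((signal + e1) ** 2 + e2**2)
        else:
            signal = np.clip(signal + rng.normal(0.0, sigma, signal.shape), 0.0, None)

    return DiffusionVolume(
        signal=signal,
        scheme=scheme,
        voxel_size=phantom.voxel_size,
        brain_mask=np.ones(phantom.shape, dtype=bool),
    )


def _sphere_mask(
    shape: tuple[int, int, int], center: tuple[int, int, int], radius_mm: float,
    voxel_size: float,
) -> np.ndarray:
    ax = [np.arange(n) for n in shape]
    dx = (ax[0][:, None, None] - center[0]) * voxel_size
    dy = (ax[1][None, :, None] - center[1]) * voxel_size
    dz = (ax[2][None, None, :] - center[2]) * voxel_size
    return dx * dx + dy * dy + dz * dz <= radius_mm * radius_mm


def _box_center(box: Box) -> tuple[int, int, int]:
    return tuple((lo + hi - 1) // 2 for lo, hi in box)  # type: ignore[return-value]


def make_rois(phantom: TensorPhantom, diameter_mm: float = 4.0) -> AlpsRoiSet:
    """Voxelized spherical ROIs (default 4-mm diameter) centered in each
    fiber region, one projection/association pair per hemisphere."""
    if not phantom.regions:
        raise ValueError("phantom has no fiber regions (uniform phantom?)")
    radius = diameter_mm / 2.0
    masks: dict[str, np.ndarray] = {}
    code_of = {
        "proj_left": PROJ_LEFT,
        "proj_right": PROJ_RIGHT,
        "assoc_left": ASSOC_LEFT,
        "assoc_right": ASSOC_RIGHT,
    }
    for name, code in code_of.items():
        box = phantom.regions.get(name)
        if box is None:
            raise ValueError(f"phantom lacks region {name}")
        center = _box_center(box)
        mask = _sphere_mask(phantom.shape, center, radius, phantom.voxel_size)
        if not np.all(phantom.region_labels[mask] == code):
            raise ValueError(
                f"a {diameter_mm}-mm sphere does not fit inside region {name}"
            )
        masks[name] = mask
    return AlpsRoiSet(
        proj_left=masks["proj_left"],
        assoc_left=masks["assoc_left"],
        proj_right=masks["proj_right"],
        assoc_right=masks["assoc_right"],
        voxel_size=phantom.voxel_size,
    )


# tumor geometry: nested cubes (Chebyshev radii, voxels) around a center
# offset along +z from the ipsilateral projection-ROI center.  The offsets
# are chosen so exactly the requested label reaches the ROI sphere
# (Euclidean radius 2 voxels at 1 mm isotropic).
_TUMOR_RADII = {"flair_hyperintense": 4, "enhancing": 2, "necrosis": 1}
_TUMOR_OFFSET = {"none": 8, "flair": 6, "enhancing": 4, "necrosis": 0}
TUMOR_LEGEND = {1: "flair_hyperintense", 2: "enhancing", 3: "necrosis"}


def make_tumor_labels(
    phantom: TensorPhantom, side: str, overlap_mode: str = "none"
) -> TumorSegmentation:
    """Nested flair/enhancing/necrosis label cubes in one hemisphere.

    ``overlap_mode`` selects which label (if any) reaches the
    ipsilateral projection ROI; contralateral ROIs never intersect the
    tumor.  Raises if the requested pattern cannot be realized on the
    grid.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if overlap_mode not in _TUMOR_OFFSET:
        raise ValueError(f"unknown overlap_mode {overlap_mode!r}")
    rois = make_rois(phantom)
    center = np.array(_box_center(phantom.regions[f"proj_{side}"]))
    center[2] += _TUMOR_OFFSET[overlap_mode]

    nx = phantom.shape[0]
    mx = phantom.midline
    x_lo, x_hi = (0, mx) if side == "left" else (mx, nx)
    labels = np.zeros(phantom.shape, dtype=np.int16)
    # paint outer to inner so inner labels win
    for code, name in ((1, "flair_hyperintense"), (2, "enhancing"), (3, "necrosis")):
        r = _TUMOR_RADII[name]
        sl = tuple(
            slice(max(lo, c - r), min(hi, c + r + 1))
            for c, (lo, hi) in zip(
                center, ((x_lo, x_hi), (0, phantom.shape[1]), (0, phantom.shape[2]))
            )
        )
        labels[sl] = code

    seg = TumorSegmentation(
        labels=labels, legend=dict(TUMOR_LEGEND), voxel_size=phantom.voxel_size
    )

    # verify the constructed overlap pattern
    ipsi = rois.union(side)
    contra = rois.union("left" if side == "right" else "right")
    if np.any(labels[contra] > 0):
        raise ValueError("tumor reaches the contralateral ROIs; grid too small")
    hit = {name: bool(np.any(labels[ipsi] == code)) for code, name in TUMOR_LEGEND.items()}
    expected = {
        "none": (False, False, False),
        "flair": (True, False, False),
        "enhancing": (True, True, False),
        "necrosis": (True, True, True),
    }[overlap_mode]
    got = (hit["flair_hyperintense"], hit["enhancing"], hit["necrosis"])
    # for 'flair'/'enhancing' the outer labels necessarily also touch;
    # the requirement is on the *deepest* label reaching the ROI
    deepest = {(False, False, False): "none"}.get(got)
    if got[2]:
        deepest = "necrosis"
    elif got[1]:
        deepest = "enhancing"
    elif got[0]:
        deepest = "flair"
    want = {"none": "none", "flair": "flair", "enhancing": "enhancing", "necrosis": "necrosis"}
    if deepest != want[overlap_mode]:
        raise ValueError(
            f"overlap_mode={overlap_mode!r} not realizable on this grid "
            f"(got deepest overlap {deepest!r}, expected pattern {expected})"
        )
    return seg


def apply_tumor_to_phantom(
    phantom: TensorPhantom, seg: TumorSegmentation
) -> TensorPhantom:
    """Replace tensors/FW inside the tumor labels: isotropic, elevated MD
    and FW relative to fiber tissue (necrosis near-fluid)."""
    md_of = {1: 1.1e-3, 2: 1.3e-3, 3: 2.2e-3}
    fw_of = {1: 0.30, 2: 0.35, 3: 0.70}
    tensors = phantom.tensors.copy()
    fw_true = phantom.fw_true.copy()
    for code in (1, 2, 3):
        m = seg.labels == code
        tensors[m] = np.diag([md_of[code]] * 3)
        fw_true[m] = fw_of[code]
    return TensorPhantom(
        shape=phantom.shape,
        voxel_size=phantom.voxel_size,
        tensors=tensors,
        s0=phantom.s0.copy(),
        fw_true=fw_true,
        region_labels=phantom.region_labels.copy(),
        regions=dict(phantom.regions),
    )


def hemisphere_nawm_mask(
    phantom: TensorPhantom,
    side: str,
    seg: TumorSegmentation | None = None,
    margin: int = 2,
) -> np.ndarray:
    """Interior tissue mask of one hemisphere (no CSF, no tumor labels):
    stands in for a normal-appearing-white-matter mask."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    nx, ny, nz = phantom.shape
    mx = phantom.midline
    mask = np.zeros(phantom.shape, dtype=bool)
    if side == "left":
        mask[margin : mx - 1, margin : ny - margin, margin : nz - margin] = True
    else:
        mask[mx + 1 : nx - margin, margin : ny - margin, margin : nz - margin] = True
    mask &= phantom.region_labels != CSF
    if seg is not None:
        mask &= seg.labels == 0
    return mask


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "subject_id",
    "site",
    "age",
    "sex",
    "alps_cnawm",
    "alps_inawm",
    "fw_cnawm",
    "enh_vol_ml",
    "os_days",
    "event",
]

# ipsilateral ROI-category frequencies, matched to the contralateral /
# ipsilateral breakdown of a ~280-subject GBM cohort
DEFAULT_CATEGORY_PROBS = {
    "iNAWM": 0.679,
    "flair_tumor": 0.238,
    "enhancing_tumor": 0.058,
    "excluded_necrosis": 0.025,
}


@dataclass
class CohortSpec:
    """Ground-truth recipe for a multi-site survival cohort.

    Biomarker distributions and demographics default to GBM-cohort
    scale: ALPS ~ N(1.40, 0.15), FW ~ N(0.21, 0.06), age ~ N(63, 11),
    ~62% male.  ``beta_*`` are log hazard ratios per SD (per indicator
    for sex); survival times follow a Weibull baseline whose default
    scale puts the null median near 15 months.  ``site_effects`` maps
    site -> feature -> (additive shift, multiplicative scale about the
    shifted site mean).
    """

    n_per_site: tuple[int, ...] = (100, 100)
    site_names: tuple[str, ...] = ("siteA", "siteB")
    alps_mean: float = 1.40
    alps_sd: float = 0.15
    fw_mean: float = 0.21
    fw_sd: float = 0.06
    beta_alps: float = -0.3
    beta_fw: float = 0.3
    beta_age: float = 0.2
    beta_sex: float = 0.0
    weibull_shape: float = 1.2
    weibull_scale: float = 612.0  # days; null median ~ 15 months
    censor_rate: float = 0.2
    site_effects: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    age_mean: float = 63.0
    age_sd: float = 11.0
    male_frac: float = 0.62
    eligibility_columns: bool = True
    p_bilateral: float = 0.03
    midline_shift_sd: float = 2.5
    category_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_site):
            raise ValueError("need at least 2 subjects per site")
        if len(self.n_per_site) != len(self.site_names):
            raise ValueError("n_per_site and site_names length mismatch")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        for sd in (self.alps_sd, self.fw_sd, self.age_sd):
            if sd <= 0:
                raise ValueError("all sds must be positive")


def _distort(
    values: np.ndarray, theo_mean: float, effect: tuple[float, float] | None
) -> np.ndarray:
    if effect is None:
        return values
    shift, scale = effect
    shifted = values + shift
    center = theo_mean + shift
    return center + scale * (shifted - center)


def _calibrate_censoring(
    t_event: np.ndarray, u_cens: np.ndarray, target: float
) -> np.ndarray:
    """Censoring times C = c_max * U with c_max bisected so that
    mean(C < T) hits the target censoring fraction."""
    if target <= 0:
        return np.full_like(t_event, np.inf)

    def frac(c_max: float) -> float:
        return float(np.mean(c_max * u_cens < t_event))

    lo, hi = 1e-6, float(t_event.max()) * 2
    while frac(hi) > target and hi < 1e9:
        hi *= 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return hi * u_cens


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a multi-site cohort table with ground truth retained.

    Observed biomarker columns carry the site distortions; columns with
    the ``_true`` suffix keep the pre-distortion values that generated
    the survival times.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for site, n in zip(spec.site_names, spec.n_per_site):
        age = rng.normal(spec.age_mean, spec.age_sd, n)
        sex = (rng.random(n) < spec.male_frac).astype(int)  # male = 1
        alps_c = rng.normal(spec.alps_mean, spec.alps_sd, n)
        alps_i = rng.normal(spec.alps_mean, spec.alps_sd, n)
        fw = np.clip(rng.normal(spec.fw_mean, spec.fw_sd, n), 0.01, 0.80)
        enh_vol = np.clip(rng.lognormal(2.4, 0.8, n), 0.1, 120.0)

        lp = (
            spec.beta_alps * (alps_c - spec.alps_mean) / spec.alps_sd
            + spec.beta_fw * (fw - spec.fw_mean) / spec.fw_sd
            + spec.beta_age * (age - spec.age_mean) / spec.age_sd
            + spec.beta_sex * sex
        )
        u = rng.random(n)
        t_event = spec.weibull_scale * (
            -np.log(u) / np.exp(lp)
        ) ** (1.0 / spec.weibull_shape)
        t_cens = _calibrate_censoring(t_event, rng.random(n), spec.censor_rate)
        os_days = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

        eff = spec.site_effects.get(site, {})
        df = pd.DataFrame(
            {
                "subject_id": [f"{site}_{i:04d}" for i in range(n)],
                "site": site,
                "age": age,
                "sex": sex,
                "alps_cnawm": _distort(alps_c, spec.alps_mean, eff.get("alps_cnawm")),
                "alps_inawm": _distort(alps_i, spec.alps_mean, eff.get("alps_inawm")),
                "fw_cnawm": _distort(fw, spec.fw_mean, eff.get("fw_cnawm")),
                "enh_vol_ml": enh_vol,
                "os_days": os_days,
                "event": event,
                "alps_cnawm_true": alps_c,
                "alps_inawm_true": alps_i,
                "fw_cnawm_true": fw,
                "lp_true": lp,
            }
        )
        if spec.eligibility_columns:
            df["bilateral"] = rng.random(n) < spec.p_bilateral
            df["midline_shift_mm"] = np.abs(
                rng.normal(0.0, spec.midline_shift_sd, n)
            )
            cats = list(spec.category_probs)
            probs = np.array([spec.category_probs[c] for c in cats], dtype=float)
            probs = probs / probs.sum()
            df["roi_category_ipsi"] = rng.choice(cats, size=n, p=probs)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# full imaging cohort on disk
# ---------------------------------------------------------------------------

_OVERLAP_OF_CATEGORY = {
    "iNAWM": "none",
    "flair_tumor": "flair",
    "enhancing_tumor": "enhancing",
    "excluded_necrosis": "necrosis",
}


def simulate_imaging_cohort(
    cohort: pd.DataFrame,
    out_dir,
    shape: tuple[int, int, int] = (24, 24, 24),
    snr: float = 40.0,
    schemes: dict[str, AcquisitionScheme] | None = None,
    lambda_perp: float = 0.3e-3,
    seed: int = 0,
) -> tuple[list[dict], str]:
    """Write per-subject NIfTI/bval/bvec files realizing a cohort table.

    Each subject gets a phantom whose contralateral (resp. ipsilateral)
    perivascular x-diffusivity is ``alps_cnawm * lambda_perp`` (resp.
    ``alps_inawm * lambda_perp``), so the planted ground-truth ALPS per
    hemisphere equals the table value, free water planted in the
    background tissue at ``fw_cnawm``, and a tumor whose label overlap
    matches ``roi_category_ipsi``.  By default site schemes alternate
    between the b=1000 and b=2000 protocols in site order.

    Returns (subject manifest for :class:`glymph.pipeline.RunConfig`,
    path of the clinical CSV).
    """
    from pathlib import Path

    from glymph import io as gio
    from glymph.scheme import b2000_scheme, b1000_scheme

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sites = list(pd.unique(cohort["site"]))
    if schemes is None:
        schemes = {
            site: (b1000_scheme(31) if i % 2 == 0 else b2000_scheme())
            for i, site in enumerate(sites)
        }

    manifest: list[dict] = []
    for _, row in cohort.iterrows():
        sid = str(row["subject_id"])
        tumor_side = "left" if rng.random() < 0.5 else "right"
        contra = "right" if tumor_side == "left" else "left"
        sub_seed = int(rng.integers(0, 2**31 - 1))

        def _spec(alps_value: float) -> FiberSpec:
            dxx = float(np.clip(alps_value, 0.2, 3.5)) * lambda_perp
            return FiberSpec(lambda_perp=lambda_perp, dxx=dxx)

        spec_of = {
            tumor_side: _spec(row["alps_inawm"]),
            contra: _spec(row["alps_cnawm"]),
        }
        fw_val = float(np.clip(row["fw_cnawm"], 0.01, 0.9))
        phantom = make_phantom(
            shape=shape,
            fibers=(spec_of["left"], spec_of["right"]),
            fw={"background": fw_val, "proj": 0.0, "assoc": 0.0},
        )
        category = str(row.get("roi_category_ipsi", "iNAWM"))
        seg = make_tumor_labels(
            phantom, tumor_side, _OVERLAP_OF_CATEGORY.get(category, "none")
        )
        phantom = apply_tumor_to_phantom(phantom, seg)
        rois = make_rois(phantom)
        cnawm = hemisphere_nawm_mask(phantom, contra, seg)
        cnawm &= phantom.region_labels == BACKGROUND

        scheme = schemes[str(row["site"])]
        dwi = simulate_dwi(phantom, scheme, snr=snr, seed=sub_seed)

        base = out_dir / sid
        gio.save_nifti(f"{base}_dwi.nii.gz", dwi.signal, phantom.voxel_size)
        gio.save_bval_bvec(base, scheme)
        gio.save_nifti(f"{base}_seg.nii.gz", seg.labels, phantom.voxel_size, dtype=np.int16)
        gio.save_nifti(f"{base}_cnawm.nii.gz", cnawm, phantom.voxel_size, dtype=np.uint8)
        mask_paths = {}
        for key in ("proj_left", "assoc_left", "proj_right", "assoc_right"):
            p = f"{base}_roi_{key}.nii.gz"
            gio.save_nifti(p, getattr(rois, key), phantom.voxel_size, dtype=np.uint8)
            mask_paths[key] = str(p)
        sidecar = {
            "tumor_side": tumor_side,
            "tumor_legend": {str(k): v for k, v in seg.legend.items()},
            "masks": mask_paths,
        }
        gio.save_json(f"{base}_rois.json", sidecar)
        manifest.append(
            {
                "subject_id": sid,
                "site": str(row["site"]),
                "tumor_side": tumor_side,
                "dwi": f"{base}_dwi.nii.gz",
                "bval": str(base.with_suffix(".bval")),
                "bvec": str(base.with_suffix(".bvec")),
                "seg": f"{base}_seg.nii.gz",
                "rois": f"{base}_rois.json",
                "cnawm_mask": f"{base}_cnawm.nii.gz",
            }
        )

    clinical_cols = [
        c
        for c in (
            "subject_id",
            "site",
            "age",
            "sex",
            "os_days",
            "event",
            "bilateral",
            "midline_shift_mm",
        )
        if c in cohort.columns
    ]
    clinical_path = out_dir / "clinical.csv"
    cohort[clinical_cols].to_csv(clinical_path, index=False, float_format="%.10g")
    return manifest, str(clinical_path)
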