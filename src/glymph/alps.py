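"""ALPS index computation and ROI categorization against a tumor mask.

The ALPS (analysis along the perivascular space) index is the ratio of
water diffusivity along the x axis — perpendicular to both the
projection fibers (z) and the association fibers (y), i.e. along the
deep medullary perivascular spaces — to the diffusivity along the fiber
axes:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where each term is the ROI-mean image-axis diffusivity in a 4-mm
spherical ROI placed in the projection / association fiber region.
Lower values suggest reduced perivascular flow.

ROIs are categorized by their relation to the tumor: the hemisphere
opposite the tumor is contralateral normal-appearing white matter
(cNAWM); the ipsilateral ROI pair is classified by label overlap with
priority necrosis > enhancing > FLAIR-hyperintense > none (iNAWM);
necrosis overlap excludes the hemisphere from group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from glymph.diffusion import ScalarMaps

__all__ = [
    "CATEGORIES",
    "AlpsRoiSet",
    "AlpsMeasurement",
    "TumorSegmentation",
    "select_reference",
    "categorize_roi",
    "alps_index",
]

CATEGORIES = ("cNAWM", "iNAWM", "flair_tumor", "enhancing_tumor", "excluded_necrosis")

HEMISPHERES = ("left", "right")


@dataclass
class AlpsRoiSet:
    """Per-hemisphere projection/association ROI masks with categories."""

    proj_left: np.ndarray
    assoc_left: np.ndarray
    proj_right: np.ndarray
    assoc_right: np.ndarray
    voxel_size: float = 1.0
    categories: dict[str, str | None] = field(
        default_factory=lambda: {"left": None, "right": None}
    )
    tumor_side: str | None = None

    def __post_init__(self) -> None:
        for hemi in HEMISPHERES:
            p, a = self.proj(hemi), self.assoc(hemi)
            if p.shape != a.shape:
                raise ValueError("proj/assoc masks on different grids")
            if not p.any() or not a.any():
                raise ValueError(f"empty ROI mask in {hemi} hemisphere")
            if np.any(p & a):
                raise ValueError(f"{hemi} proj and assoc ROIs overlap")

    def proj(self, hemisphere: str) -> np.ndarray:
        return self.proj_left if hemisphere == "left" else self.proj_right

    def assoc(self, hemisphere: str) -> np.ndarray:
        return self.assoc_left if hemisphere == "left" else self.assoc_right

    def union(self, hemisphere: str) -> np.ndarray:
        return self.proj(hemisphere) | self.assoc(hemisphere)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.proj_left.shape


@dataclass
class TumorSegmentation:
    """Integer tumor label volume with a label legend."""

    labels: np.ndarray
    legend: dict[int, str]  # label -> {flair_hyperintense, enhancing, necrosis}
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from legend")

    def mask(self, kind: str) -> np.ndarray:
        codes = [c for c, k in self.legend.items() if k == kind]
        return np.isin(self.labels, codes)

    @property
    def enhancing_volume_ml(self) -> float:
        voxel_ml = float(np.prod(np.broadcast_to(self.voxel_size, (3,)))) / 1000.0
        return float(self.mask("enhancing").sum()) * voxel_ml


@dataclass
class AlpsMeasurement:
    """ROI-mean diffusivities, the ALPS ratio, and FA/MD covariates."""

    hemisphere: str
    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float
    alps: float
    fa_proj: float
    fa_assoc: float
    md_proj: float
    md_assoc: float
    category: str | None = None
    valid: bool = True


def select_reference(
    fa_maps: dict[str, np.ndarray], template: np.ndarray
) -> str:
    """Subject whose FA map minimizes the sum of squared differences to
    the template; ties broken by lowest subject id."""
    if not fa_maps:
        raise ValueError("empty FA map collection")
    template = np.asarray(template, dtype=float)
    best_id, best_ssd = None, np.inf
    for sid in sorted(fa_maps):
        fa = np.asarray(fa_maps[sid], dtype=float)
        if fa.shape != template.shape:
            raise ValueError(f"FA map {sid!r} not on the template grid")
        ssd = float(np.sum((fa - template) ** 2))
        if ssd < best_ssd:
            best_id, best_ssd = sid, ssd
    return best_id


def categorize_roi(
    rois: AlpsRoiSet, seg: TumorSegmentation, tumor_side: str
) -> AlpsRoiSet:
    """Fill ROI categories from tumor overlap (>= 1 shared voxel).

    Contralateral hemisphere -> cNAWM.  Ipsilateral: overlap priority
    necrosis > enhancing > flair_hyperintense, else iNAWM.  Bilateral
    tumors (label voxels in both hemispheres) are an error — such
    subjects are excluded upstream.
    """
    if tumor_side not in HEMISPHERES:
        raise ValueError("tumor_side must be 'left' or 'right'")
    if seg.labels.shape != rois.shape:
        raise ValueError("segmentation not on the ROI grid")

    mx = seg.labels.shape[0] // 2
    tumor = seg.labels > 0
    if tumor[:mx].any() and tumor[mx:].any():
        raise ValueError("bilateral tumor: label voxels in both hemispheres")

    contra = "left" if tumor_side == "right" else "right"
    ipsi_mask = rois.union(tumor_side)
    if np.any(seg.mask("necrosis") & ipsi_mask):
        ipsi_cat = "excluded_necrosis"
    elif np.any(seg.mask("enhancing") & ipsi_mask):
        ipsi_cat = "enhancing_tumor"
    elif np.any(seg.mask("flair_hyperintense") & ipsi_mask):
        ipsi_cat = "flair_tumor"
    else:
        ipsi_cat = "iNAWM"

    return replace(
        rois,
        categories={tumor_side: ipsi_cat, contra: "cNAWM"},
        tumor_side=tumor_side,
    )


def _roi_mean(map3d: np.ndarray, mask: np.ndarray) -> float:
    return float(map3d[mask].mean())


def alps_index(
    maps: ScalarMaps, rois: AlpsRoiSet, hemisphere: str
) -> AlpsMeasurement:
    """ALPS index for one hemisphere from its own ROI pair.

    A nonpositive denominator flags the measurement invalid (excluded
    downstream) instead of raising.
    """
    if hemisphere not in HEMISPHERES:
        raise ValueError("hemisphere must be 'left' or 'right'")
    proj, assoc = rois.proj(hemisphere), rois.assoc(hemisphere)
    if maps.dxx.shape != proj.shape:
        raise ValueError("scalar maps not on the ROI grid")

    dxx_proj = _roi_mean(maps.dxx, proj)
    dxx_assoc = _roi_mean(maps.dxx, assoc)
    dyy_proj = _roi_mean(maps.dyy, proj)
    dzz_assoc = _roi_mean(maps.dzz, assoc)
    values = (dxx_proj, dxx_assoc, dyy_proj, dzz_assoc)
    if not all(np.isfinite(values)):
        raise ValueError("non-finite ROI-mean diffusivity")

    denom = (dyy_proj + dzz_assoc) / 2.0
    numer = (dxx_proj + dxx_assoc) / 2.0
    valid = denom > 0
    alps = numer / denom if valid else np.nan

    return AlpsMeasurement(
        hemisphere=hemisphere,
        dxx_proj=dxx_proj,
        dxx_assoc=dxx_assoc,
        dyy_proj=dyy_proj,
        dzz_assoc=dzz_assoc,
        alps=alps,
        fa_proj=_roi_mean(maps.fa, proj),
        fa_assoc=_roi_mean(maps.fa, assoc),
        md_proj=_roi_mean(maps.md, proj),
        md_assoc=_roi_mean(maps.md, assoc),
        category=rois.categories.get(hemisphere),
        valid=bool(valid),
    )
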