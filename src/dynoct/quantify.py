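"""Volumetric spheroid quantification: mask, volume, mean dynamics, viability.

The workflow mirrors routine spheroid analysis: an intensity-based mask
isolates the spheroid (optionally within a rough ROI), then the dynamics
maps are summarized over the mask.  A voxel counts as *viable* when its
dynamics metric is strictly greater than a fixed cutoff — 3 dB² for LIV,
2×10⁻⁴ ms⁻¹ for OCDSl — and the viable cell ratio is
viable volume / entire spheroid volume (volumes by voxel counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask

from .stack import DynamicsVolume

#: viability cutoffs
DEFAULT_LIV_CUTOFF_DB2 = 3.0
DEFAULT_OCDS_CUTOFF_MS_INV = 2e-4
#: default offset of the intensity threshold above the background median, dB
DEFAULT_BACKGROUND_OFFSET_DB = 10.0

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open (y, z, x)


@dataclass
class SpheroidMask:
    """Boolean spheroid segmentation plus how it was obtained."""

    mask: np.ndarray  # (location, depth, fast) bool
    voxel_volume_um3: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.mask.shape}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    @property
    def volume_um3(self) -> float:
        return self.n_voxels * self.voxel_volume_um3


@dataclass
class SpheroidQuant:
    """Scalar spheroid summaries."""

    n_voxels: int
    volume_um3: float
    mean_liv_db2: Optional[float]
    mean_ocds_ms_inv: Optional[float]
    viable_ratio_liv: Optional[float]
    viable_ratio_ocds: Optional[float]
    liv_cutoff_db2: float
    ocds_cutoff_ms_inv: float

    def to_dict(self) -> dict[str, Any]:
        return dict(self.__dict__)


def _roi_mask(shape: tuple[int, int, int],
              roi: Box | Mapping[int, Sequence[tuple[float, float]]] | None
              ) -> np.ndarray:
    """ROI as boolean volume: full grid (None), 3D box, or per-slice polygons.

    Polygons are given per slow-axis slice index as (depth, fast) vertex
    lists; slices without a polygon are excluded.
    """
    if roi is None:
        return np.ones(shape, dtype=bool)
    if isinstance(roi, Mapping):
        m = np.zeros(shape, dtype=bool)
        for y, verts in roi.items():
            if not 0 <= int(y) < shape[0]:
                raise IndexError(f"ROI slice index {y} outside grid of {shape[0]} locations")
            m[int(y)] = polygon2mask(shape[1:], np.asarray(verts, dtype=float))
        return m
    (y0, y1), (z0, z1), (x0, x1) = roi
    for (a, b), n, name in (((y0, y1), shape[0], "location"),
                            ((z0, z1), shape[1], "depth"),
                            ((x0, x1), shape[2], "fast")):
        if not (0 <= a < b <= n):
            raise IndexError(f"ROI box [{a}, {b}) invalid on {name} axis of length {n}")
    m = np.zeros(shape, dtype=bool)
    m[y0:y1, z0:z1, x0:x1] = True
    return m


def segment_spheroid(mean_intensity_db: np.ndarray,
                     threshold_db: float | None = None,
                     *,
                     roi: Box | Mapping[int, Sequence[tuple[float, float]]] | None = None,
                     background_box: Box | None = None,
                     background_offset_db: float = DEFAULT_BACKGROUND_OFFSET_DB,
                     largest_component: bool = False,
                     voxel_volume_um3: float = 1.0) -> SpheroidMask:
    """Intensity-based spheroid mask: (intensity > threshold) ∧ ROI.

    The threshold is either absolute (``threshold_db``) or relative to the
    sample background: the median intensity inside ``background_box`` plus
    ``background_offset_db``.  ``largest_component`` keeps only the largest
    26-connected component, discarding stray bright voxels in the medium.
    An empty result is returned (not raised) with a warning recorded in
    ``provenance``; downstream summaries refuse empty masks.
    """
    vol = np.asarray(mean_intensity_db, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError(f"mean intensity must be 3D, got shape {vol.shape}")
    if threshold_db is None:
        if background_box is None:
            raise ValueError("either threshold_db or background_box is required")
        bg = _roi_mask(vol.shape, background_box)
        threshold_db = float(np.median(vol[bg])) + background_offset_db
    mask = (vol > threshold_db) & _roi_mask(vol.shape, roi)
    provenance: dict[str, Any] = {
        "threshold_db": float(threshold_db),
        "roi": "full_grid" if roi is None else "custom",
        "largest_component": largest_component,
    }
    if largest_component and mask.any():
        lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    if not mask.any():
        provenance["warning"] = "empty mask: threshold above all ROI intensities"
    return SpheroidMask(mask=mask, voxel_volume_um3=voxel_volume_um3,
                        provenance=provenance)


def _check_shapes(mask: SpheroidMask, vol: DynamicsVolume, name: str) -> None:
    if vol.values.shape != mask.mask.shape:
        raise ValueError(
            f"{name} volume shape {vol.values.shape} != mask shape {mask.mask.shape}"
        )


def quantify(mask: SpheroidMask,
             liv: DynamicsVolume | None = None,
             ocds: DynamicsVolume | None = None,
             liv_cutoff: float = DEFAULT_LIV_CUTOFF_DB2,
             ocds_cutoff: float = DEFAULT_OCDS_CUTOFF_MS_INV) -> SpheroidQuant:
    """Masked means and viable cell ratios of the dynamics volumes.

    Viability is strict: a voxel exactly at the cutoff counts as
    non-viable.
    """
    if mask.is_empty:
        raise ValueError("cannot quantify an empty spheroid mask")
    n = mask.n_voxels
    out: dict[str, Optional[float]] = {
        "mean_liv_db2": None, "viable_ratio_liv": None,
        "mean_ocds_ms_inv": None, "viable_ratio_ocds": None,
    }
    if liv is not None:
        _check_shapes(mask, liv, "LIV")
        v = liv.values[mask.mask]
        out["mean_liv_db2"] = float(v.mean())
        out["viable_ratio_liv"] = float((v > liv_cutoff).sum() / n)
    if ocds is not None:
        _check_shapes(mask, ocds, "OCDS")
        v = ocds.values[mask.mask]
        out["mean_ocds_ms_inv"] = float(v.mean())
        out["viable_ratio_ocds"] = float((v > ocds_cutoff).sum() / n)
    return SpheroidQuant(
        n_voxels=n,
        volume_um3=mask.volume_um3,
        liv_cutoff_db2=liv_cutoff,
        ocds_cutoff_ms_inv=ocds_cutoff,
        **out,
    )


def binarize_viability(dynamics: DynamicsVolume,
                       cutoff: float,
                       spheroid_mask: SpheroidMask | np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Binary viable / necrotic maps by thresholding a dynamics volume.

    Viable = value strictly above the cutoff; necrotic = the complement
    within the spheroid mask (full grid if no mask is given).  The two
    maps partition the mask.
    """
    if spheroid_mask is None:
        region = np.ones(dynamics.values.shape, dtype=bool)
    elif isinstance(spheroid_mask, SpheroidMask):
        region = spheroid_mask.mask
    else:
        region = np.asarray(spheroid_mask, dtype=bool)
    if region.shape != dynamics.values.shape:
        raise ValueError(
            f"mask shape {region.shape} != dynamics shape {dynamics.values.shape}"
        )
    viable = region & (dynamics.values > cutoff)
    necrotic = region & ~viable
    return viable, necrotic
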