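"""Hemispheric/lesion volumetry, edema correction and midline-shift quantification.

Volumes follow the planimetric rule: labeled in-plane area per slice, summed
over slices and multiplied by the slice spacing, i.e.

    V = (voxel count) * in_plane_spacing^2 * (slice_thickness + slice_gap).

Lesion burden is expressed as a percentage of hemispheric volume, with and
without correction for the space-occupying effect of vasogenic edema:

    %HLVuc = LV / ((HVc + HVi) / 2) * 100
    %HLVec = (HVc^2 + LV*(HVc + HVi) - HVi^2) / (HVc*(HVc + HVi)) * 100

where LV is the lesion volume and HVc/HVi the contralateral/ipsilateral
hemisphere volumes. The corrected form is algebraically identical to
100*(LV - (HVi - HVc))/HVc — the lesion minus the hemispheric swelling,
normalized to the unswollen hemisphere — and the implementation verifies that
identity on every call. Midline shift is MLS = (A - B)/2 from the bilateral
cortex-to-third-ventricle distances A (ipsilateral) and B (contralateral),
taken at the slice of maximum lateral ventricle displacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import LabelMask, SliceLandmarks, VoxelGeometry

__all__ = [
    "VolumetryResult",
    "MidlineShiftResult",
    "region_volume",
    "percent_hlv_uncorrected",
    "percent_hlv_edema_corrected",
    "midline_shift",
    "landmarks_from_masks",
    "volumetry_for_animal",
]

logger = logging.getLogger(__name__)

_IDENTITY_RTOL = 1e-9


@dataclass(frozen=True)
class VolumetryResult:
    """Per-animal hemispheric and lesion volumetry (mm^3 and percent)."""

    hv_c: float
    hv_i: float
    lv: float
    pct_hlv_uc: float
    pct_hlv_ec: float

    @property
    def swelling_mm3(self) -> float:
        """Space-occupying volume of the ipsilateral hemisphere, HVi - HVc."""
        return self.hv_i - self.hv_c


@dataclass(frozen=True)
class MidlineShiftResult:
    """A/B distances (mm) and MLS = (A - B)/2 at the maximum-displacement slice."""

    a_mm: float
    b_mm: float
    mls_mm: float
    slice_index: int


def region_volume(mask: LabelMask, region: str, geometry: VoxelGeometry) -> float:
    """Volume of a labeled region in mm^3 (voxel count x voxel volume)."""
    count = int(mask.region_mask(region).sum())
    return count * geometry.voxel_volume_mm3


def percent_hlv_uncorrected(lv: float, hv_c: float, hv_i: float) -> float:
    """Lesion volume as percent of the mean hemispheric volume (no edema correction)."""
    if hv_c + hv_i <= 0:
        raise ValueError("hemispheric volumes sum to zero")
    return 100.0 * lv / ((hv_c + hv_i) / 2.0)


def percent_hlv_edema_corrected(lv: float, hv_c: float, hv_i: float) -> float:
    """Edema-corrected percent hemispheric lesion volume.

    Evaluates the published expression and cross-checks it against the
    equivalent form 100*(LV - (HVi - HVc))/HVc. A negative value (swelling
    exceeding the lesion) is reported as-is with a warning, never clipped:
    silently hiding it would mask segmentation or simulation errors.
    """
    if hv_c <= 0:
        raise ValueError("contralateral hemispheric volume must be positive")
    value = 100.0 * (hv_c ** 2 + lv * (hv_c + hv_i) - hv_i ** 2) / (hv_c * (hv_c + hv_i))
    check = 100.0 * (lv - (hv_i - hv_c)) / hv_c
    scale = max(abs(value), abs(check), 1.0)
    if abs(value - check) > _IDENTITY_RTOL * scale:
        raise AssertionError(
            f"edema-correction identity violated: {value!r} vs {check!r}"
        )
    if value < 0:
        logger.warning(
            "edema-corrected lesion volume is negative (%.3f%%): swelling exceeds lesion",
            value,
        )
    return value


def midline_shift(landmarks: Sequence[SliceLandmarks]) -> MidlineShiftResult:
    """MLS at the slice of maximum lateral displacement.

    Selects the record maximizing (A - B)/2; ties go to the lowest slice
    index for determinism.
    """
    if not landmarks:
        raise ValueError("midline shift needs at least one landmark record")
    best = min(landmarks, key=lambda r: (-(r.a_mm - r.b_mm), r.slice_index))
    return MidlineShiftResult(
        a_mm=best.a_mm,
        b_mm=best.b_mm,
        mls_mm=(best.a_mm - best.b_mm) / 2.0,
        slice_index=best.slice_index,
    )


def landmarks_from_masks(
    mask: LabelMask, geometry: VoxelGeometry, ipsi_high_x: bool = True
) -> list[SliceLandmarks]:
    """Derive per-slice A/B distances from a third-ventricle label.

    Convenience for synthetic data (real measurements are made manually on
    the images): on each slice containing the third ventricle, A and B are
    the distances along x from the ventricle's centroid to the outer cortex
    border (half a voxel beyond the outermost brain voxel center) on the
    ipsilateral and contralateral side, measured in the ventricle's centroid
    row. Manually supplied landmark files take precedence over this.
    """
    vent = mask.region_mask("third_ventricle")
    brain = mask.region_mask("brain")
    sp = geometry.in_plane_spacing
    records: list[SliceLandmarks] = []
    for z in range(mask.spatial_shape[2]):
        vz = vent[:, :, z]
        if not vz.any():
            continue
        xs, ys = np.nonzero(vz)
        x_v = float(xs.mean())
        row = int(round(float(ys.mean())))
        brain_row = np.nonzero(brain[:, row, z])[0]
        if brain_row.size == 0:
            continue
        x_hi = float(brain_row.max()) + 0.5
        x_lo = float(brain_row.min()) - 0.5
        a = (x_hi - x_v) * sp if ipsi_high_x else (x_v - x_lo) * sp
        b = (x_v - x_lo) * sp if ipsi_high_x else (x_hi - x_v) * sp
        if a > 0 and b > 0:
            records.append(SliceLandmarks(slice_index=z, a_mm=a, b_mm=b))
    return records


def volumetry_for_animal(
    mask: LabelMask,
    geometry: VoxelGeometry,
    landmarks: Sequence[SliceLandmarks],
) -> tuple[VolumetryResult, MidlineShiftResult]:
    """Full volumetric workup of one animal: volumes, %HLV both ways, MLS."""
    hv_c = region_volume(mask, "hemisphere_contra", geometry)
    hv_i = region_volume(mask, "hemisphere_ipsi", geometry)
    lv = region_volume(mask, "lesion", geometry)
    vol = VolumetryResult(
        hv_c=hv_c,
        hv_i=hv_i,
        lv=lv,
        pct_hlv_uc=percent_hlv_uncorrected(lv, hv_c, hv_i),
        pct_hlv_ec=percent_hlv_edema_corrected(lv, hv_c, hv_i),
    )
    return vol, midline_shift(landmarks)
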