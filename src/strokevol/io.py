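"""Images, masks, landmarks, manifests and the shared voxel-geometry conventions.

Conventions used throughout the package:

* voxel indices are 0-based; axes of a 3-D volume are (x, y, slice) with the
  slice axis third;
* x runs left-right in the coronal plane and the *ipsilateral* (occluded)
  hemisphere is the high-x half by default, matching a right-sided occlusion;
* multi-echo data are 4-D, (x, y, slice, echo), magnitude-valued;
* echo times are in milliseconds, distances in millimetres, volumes in mm^3.

Images and masks are NIfTI-1 files (via nibabel); echo times and voxel
geometry travel in a small JSON/YAML sidecar next to the image; landmarks,
manifests and result tables are plain TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VoxelGeometry",
    "EchoTrainImage",
    "LabelMask",
    "SliceLandmarks",
    "ManifestRow",
    "CohortManifest",
    "DEFAULT_LEGEND",
    "REGION_MEMBERS",
    "FormatError",
    "ValidationError",
    "read_echo_train",
    "write_echo_train",
    "read_label_mask",
    "write_label_mask",
    "read_landmarks",
    "write_landmarks",
    "read_manifest",
    "write_manifest",
    "write_t2_map",
]


class FormatError(ValueError):
    """A file could not be interpreted in the expected format."""


class ValidationError(ValueError):
    """Well-formed data violated a domain invariant."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel geometry of a multi-slice acquisition.

    Parameters
    ----------
    in_plane_spacing
        Edge length of a voxel along x and y, mm (isotropic in-plane).
    slice_thickness
        Excited slice thickness, mm.
    slice_gap
        Inter-slice gap, mm; 0 for contiguous slices.
    slice_axis
        Index of the slice dimension in a 3-D volume.
    """

    in_plane_spacing: float
    slice_thickness: float
    slice_gap: float = 0.0
    slice_axis: int = 2

    def __post_init__(self) -> None:
        if not (self.in_plane_spacing > 0 and self.slice_thickness > 0):
            raise ValidationError("voxel spacings must be strictly positive")
        if self.slice_gap < 0:
            raise ValidationError("slice gap must be >= 0")
        if self.slice_axis != 2:
            raise ValidationError("slice axis must be the third dimension")

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume attributed to one voxel: spacing^2 x (thickness + gap)."""
        return self.in_plane_spacing ** 2 * (self.slice_thickness + self.slice_gap)


@dataclass(frozen=True)
class EchoTrainImage:
    """A multi-echo magnitude image stack: (x, y, slice, echo) plus echo times."""

    voxels: np.ndarray
    echo_times: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=float)
        echo_times = np.asarray(self.echo_times, dtype=float)
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "echo_times", echo_times)
        if voxels.ndim != 4:
            raise FormatError(f"expected a 4-D (x, y, slice, echo) array, got {voxels.ndim}-D")
        if echo_times.ndim != 1 or len(echo_times) != voxels.shape[3]:
            raise ValidationError(
                f"{len(echo_times)} echo times for {voxels.shape[3]} echoes"
            )
        if not (np.all(np.diff(echo_times) > 0) and np.all(echo_times > 0)):
            raise ValidationError("echo times must be strictly increasing and positive")
        if np.any(voxels < 0):
            raise ValidationError("magnitude images cannot contain negative intensities")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]


#: Canonical label integers for the regions the pipeline consumes.
DEFAULT_LEGEND: dict[int, str] = {
    0: "background",
    1: "hemisphere_contra",
    2: "hemisphere_ipsi",
    3: "lesion",
    4: "roi_ischemic",
    5: "roi_contralateral",
    6: "third_ventricle",
}

#: Label hierarchy: which legend names make up each queryable region.
#: The lesion (and its core ROI) is ipsilateral tissue, so lesion voxels are
#: structurally a subset of the ipsilateral hemisphere.
REGION_MEMBERS: dict[str, frozenset[str]] = {
    "background": frozenset({"background"}),
    "hemisphere_contra": frozenset({"hemisphere_contra", "roi_contralateral"}),
    "hemisphere_ipsi": frozenset({"hemisphere_ipsi", "lesion", "roi_ischemic"}),
    "lesion": frozenset({"lesion", "roi_ischemic"}),
    "roi_ischemic": frozenset({"roi_ischemic"}),
    "roi_contralateral": frozenset({"roi_contralateral"}),
    "third_ventricle": frozenset({"third_ventricle"}),
    "brain": frozenset(
        {"hemisphere_contra", "roi_contralateral", "hemisphere_ipsi",
         "lesion", "roi_ischemic", "third_ventricle"}
    ),
}


@dataclass(frozen=True)
class LabelMask:
    """Integer label volume (x, y, slice) with a legend mapping labels to regions."""

    labels: np.ndarray
    legend: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise FormatError(f"expected a 3-D label volume, got {labels.ndim}-D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise FormatError("label volume must be integer-typed")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "legend", dict(self.legend))
        present = set(np.unique(labels).tolist())
        unknown = present - set(self.legend) - {0}
        if unknown:
            raise ValidationError(f"labels {sorted(unknown)} missing from legend")
        self._check_lesion_laterality()

    def _check_lesion_laterality(self) -> None:
        # A lesion voxel embedded in the contralateral hemisphere (face-adjacent
        # to contralateral tissue but to no ipsilateral/lesion tissue) breaks
        # the lesion-within-ipsilateral invariant. Voxels at the midline touch
        # both sides and pass.
        lesion = self.region_mask("lesion")
        if not lesion.any():
            return
        ipsi_side = self.region_mask("hemisphere_ipsi")
        contra = self.region_mask("hemisphere_contra")
        touches_contra = _face_neighbor_any(lesion, contra)
        touches_ipsi = _face_neighbor_any(lesion, ipsi_side & ~lesion) | _face_neighbor_any(
            lesion, lesion
        )
        bad = lesion & touches_contra & ~touches_ipsi
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValidationError(
                f"lesion voxel at {idx} lies inside the contralateral hemisphere"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_for(self, name: str) -> int:
        for value, region in self.legend.items():
            if region == name:
                return value
        raise KeyError(f"region {name!r} not in legend")

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask of a region, resolving the label hierarchy."""
        try:
            members = REGION_MEMBERS[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r}") from None
        values = [v for v, name in self.legend.items() if name in members]
        return np.isin(self.labels, values)


def _face_neighbor_any(candidates: np.ndarray, target: np.ndarray) -> np.ndarray:
    """True where a candidate voxel has a 6-connected neighbor in `target`."""
    out = np.zeros_like(candidates, dtype=bool)
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        out[tuple(lo)] |= target[tuple(hi)]
        out[tuple(hi)] |= target[tuple(lo)]
    return out & candidates


@dataclass(frozen=True)
class SliceLandmarks:
    """Cortex-to-third-ventricle distances on one slice.

    ``a_mm`` is measured from the ipsilateral outer cortex border to the
    middle of the third ventricle, ``b_mm`` from the contralateral border.
    """

    slice_index: int
    a_mm: float
    b_mm: float

    def __post_init__(self) -> None:
        if not (self.a_mm > 0 and self.b_mm > 0):
            raise ValidationError(
                f"slice {self.slice_index}: landmark distances must be positive"
            )


@dataclass(frozen=True)
class ManifestRow:
    animal_id: str
    group: str
    image_path: str
    meta_path: str
    mask_path: str
    landmark_path: str


@dataclass(frozen=True)
class CohortManifest:
    """Animal -> group -> file mapping for one cohort."""

    rows: tuple[ManifestRow, ...]

    def __post_init__(self) -> None:
        ids = [r.animal_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValidationError("animal_id values must be unique")
        groups = {r.group for r in self.rows}
        if len(groups) < 2:
            raise ValidationError("a cohort manifest needs two non-empty groups")

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.rows:
            if r.group not in seen:
                seen.append(r.group)
        return tuple(seen)


# ---------------------------------------------------------------------------
# NIfTI image + sidecar I/O


def _affine(geometry: VoxelGeometry) -> np.ndarray:
    step = geometry.slice_thickness + geometry.slice_gap
    return np.diag([geometry.in_plane_spacing, geometry.in_plane_spacing, step, 1.0])


def _load_sidecar(meta_path: Path) -> dict:
    text = Path(meta_path).read_text()
    if str(meta_path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def write_echo_train(image: EchoTrainImage, image_path: str | Path, meta_path: str | Path) -> None:
    """Write a 4-D NIfTI plus a JSON/YAML sidecar with echo times and geometry."""
    nib.save(
        nib.Nifti1Image(image.voxels.astype(np.float64), _affine(image.geometry)),
        str(image_path),
    )
    meta = {
        "echo_times_ms": [float(t) for t in image.echo_times],
        "in_plane_spacing_mm": image.geometry.in_plane_spacing,
        "slice_thickness_mm": image.geometry.slice_thickness,
        "slice_gap_mm": image.geometry.slice_gap,
    }
    meta_path = Path(meta_path)
    if meta_path.suffix in (".yaml", ".yml"):
        meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    else:
        meta_path.write_text(json.dumps(meta, indent=1))


def read_echo_train(image_path: str | Path, meta_path: str | Path) -> EchoTrainImage:
    """Read a 4-D multi-echo NIfTI and its echo-time/geometry sidecar."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected 4-D NIfTI, got {data.ndim}-D")
    meta = _load_sidecar(Path(meta_path))
    echo_times = np.asarray(meta["echo_times_ms"], dtype=float)
    if len(echo_times) != data.shape[3]:
        raise ValidationError(
            f"{meta_path}: {len(echo_times)} echo times for a {data.shape[3]}-echo image"
        )
    geometry = VoxelGeometry(
        in_plane_spacing=float(meta["in_plane_spacing_mm"]),
        slice_thickness=float(meta["slice_thickness_mm"]),
        slice_gap=float(meta.get("slice_gap_mm", 0.0)),
    )
    return EchoTrainImage(voxels=data, echo_times=echo_times, geometry=geometry)


def write_label_mask(mask: LabelMask, mask_path: str | Path, geometry: VoxelGeometry) -> None:
    nib.save(
        nib.Nifti1Image(mask.labels.astype(np.int16), _affine(geometry)),
        str(mask_path),
    )


def read_label_mask(
    mask_path: str | Path, legend: Mapping[int, str] | None = None
) -> LabelMask:
    """Read an integer label NIfTI and validate it against a legend."""
    img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{mask_path}: expected 3-D label NIfTI, got {data.ndim}-D")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise FormatError(f"{mask_path}: label volume contains non-integer values")
        data = rounded.astype(np.int32)
    return LabelMask(labels=data, legend=dict(legend) if legend else dict(DEFAULT_LEGEND))


# ---------------------------------------------------------------------------
# TSV I/O

_LANDMARK_COLUMNS = ["slice_index", "A_mm", "B_mm"]


def write_landmarks(records: Sequence[SliceLandmarks], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.slice_index, r.a_mm, r.b_mm) for r in records], columns=_LANDMARK_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False)


def read_landmarks(path: str | Path) -> list[SliceLandmarks]:
    """Read per-slice A/B cortex-to-ventricle distances from TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing landmark columns {missing}")
    return [
        SliceLandmarks(int(row.slice_index), float(row.A_mm), float(row.B_mm))
        for row in df.itertuples()
    ]


_MANIFEST_COLUMNS = ["animal_id", "group", "image_path", "meta_path", "mask_path", "landmark_path"]


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in manifest.rows], columns=_MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing manifest columns {missing}")
    rows = tuple(
        ManifestRow(
            str(r.animal_id), str(r.group), str(r.image_path),
            str(r.meta_path), str(r.mask_path), str(r.landmark_path),
        )
        for r in df.itertuples()
    )
    return CohortManifest(rows=rows)


def write_t2_map(t2map, geometry: VoxelGeometry, prefix: str | Path) -> dict[str, Path]:
    """Write a fitted T2 map as four NIfTI volumes: t2, s0, r_squared, valid."""
    prefix = Path(prefix)
    out: dict[str, Path] = {}
    planes = {
        "t2": t2map.t2.astype(np.float64),
        "s0": t2map.s0.astype(np.float64),
        "r_squared": t2map.r_squared.astype(np.float64),
        "valid": t2map.valid.astype(np.int16),
    }
    for name, data in planes.items():
        path = prefix.with_name(prefix.name + f"_{name}.nii.gz")
        nib.save(nib.Nifti1Image(data, _affine(geometry)), str(path))
        out[name] = path
    return out
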