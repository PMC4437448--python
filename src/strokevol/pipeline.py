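"""End-to-end per-animal and cohort analysis.

One animal in, one result row out: fit the T2 map from the echo train,
compute hemispheric/lesion volumetry with and without edema correction from
the label mask, take the midline shift from the landmark records, and the
ipsilateral-contralateral T2 difference from the ischemic-core ROI. A cohort
run maps this over a manifest and hands the resulting table to the
two-group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io, relaxometry, stats, volumetry

__all__ = [
    "AnalysisConfig",
    "DEFAULT_ENDPOINTS",
    "estimate_midline_x",
    "estimate_noise_floor",
    "analyze_animal",
    "analyze_cohort",
    "run_study",
]

#: Endpoint columns compared between groups by default.
DEFAULT_ENDPOINTS = ("pct_hlv_ec", "pct_hlv_uc", "mls_mm", "delta_t2")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the per-animal analysis.

    ``noise_floor_k``: echoes below k x (estimated background SD) are dropped
    per voxel before fitting; the background SD is estimated from the image
    border unless ``noise_floor`` overrides it with an absolute threshold.
    """

    fit_method: str = "log_linear"
    t2_bounds: tuple[float, float] = relaxometry.DEFAULT_T2_BOUNDS
    noise_floor: float | None = None
    noise_floor_k: float = 3.0
    alpha: float = 0.05
    endpoints: tuple[str, ...] = DEFAULT_ENDPOINTS
    test_plan: dict[str, tuple[str, ...]] = field(default_factory=dict)


def estimate_noise_floor(image: io.EchoTrainImage, k: float = 3.0) -> float:
    """k x SD of the first-echo border frame (assumed to be background air)."""
    first = image.voxels[:, :, :, 0]
    frame = np.concatenate(
        [first[:2].ravel(), first[-2:].ravel(), first[:, :2].ravel(), first[:, -2:].ravel()]
    )
    return float(k * frame.std())


def estimate_midline_x(mask: io.LabelMask) -> float:
    """Interhemispheric plane (voxel x-coordinate) from the hemisphere labels.

    Midpoint between the innermost ipsilateral and contralateral voxel
    columns; with the default convention the ipsilateral hemisphere occupies
    the high-x side.
    """
    ipsi = mask.region_mask("hemisphere_ipsi")
    contra = mask.region_mask("hemisphere_contra")
    if not (ipsi.any() and contra.any()):
        raise ValueError("mask must contain both hemispheres")
    xs_ipsi = np.nonzero(ipsi.any(axis=(1, 2)))[0]
    xs_contra = np.nonzero(contra.any(axis=(1, 2)))[0]
    if xs_ipsi.mean() > xs_contra.mean():
        return (float(xs_ipsi.min()) + float(xs_contra.max())) / 2.0
    return (float(xs_ipsi.max()) + float(xs_contra.min())) / 2.0


def analyze_animal(
    image: io.EchoTrainImage,
    mask: io.LabelMask,
    landmarks: Sequence[io.SliceLandmarks],
    config: AnalysisConfig = AnalysisConfig(),
    midline_x: float | None = None,
) -> dict:
    """Full single-animal workup; returns one flat result row."""
    if mask.spatial_shape != image.spatial_shape:
        raise io.ValidationError("mask and image spatial shapes differ")
    floor = (
        config.noise_floor
        if config.noise_floor is not None
        else estimate_noise_floor(image, config.noise_floor_k)
    )
    t2map = relaxometry.fit_t2_map(
        image, method=config.fit_method, t2_bounds=config.t2_bounds, noise_floor=floor
    )
    vol, mls = volumetry.volumetry_for_animal(mask, image.geometry, landmarks)
    mid = midline_x if midline_x is not None else estimate_midline_x(mask)
    roi = relaxometry.roi_delta_t2(t2map, mask.region_mask("roi_ischemic"), mid)
    return {
        "hv_c": vol.hv_c,
        "hv_i": vol.hv_i,
        "lv": vol.lv,
        "pct_hlv_uc": vol.pct_hlv_uc,
        "pct_hlv_ec": vol.pct_hlv_ec,
        "swelling_mm3": vol.swelling_mm3,
        "a_mm": mls.a_mm,
        "b_mm": mls.b_mm,
        "mls_mm": mls.mls_mm,
        "mls_slice": mls.slice_index,
        "t2_ipsi": roi.t2_ipsi,
        "t2_contra": roi.t2_contra,
        "delta_t2": roi.delta_t2,
    }


def analyze_cohort(
    manifest: io.CohortManifest, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Analyze every animal in a manifest; one row per animal."""
    rows = []
    for entry in manifest.rows:
        image = io.read_echo_train(entry.image_path, entry.meta_path)
        mask = io.read_label_mask(entry.mask_path)
        landmarks = io.read_landmarks(entry.landmark_path)
        row = analyze_animal(image, mask, landmarks, config)
        rows.append({"animal_id": entry.animal_id, "group": entry.group, **row})
    return pd.DataFrame(rows)


def run_study(
    manifest: io.CohortManifest,
    out_dir: str | Path,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze a cohort and compare its groups; writes results and report files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = analyze_cohort(manifest, config)
    comparisons = stats.compare_cohort(
        results, endpoints=list(config.endpoints),
        test_plan=config.test_plan or None, alpha=config.alpha,
    )
    comp_table = stats.comparisons_to_table(comparisons)
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    comp_table.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    (out / "report.txt").write_text(stats.format_report(comparisons) + "\n")
    return results, comp_table
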