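"""Mono-exponential T2 relaxometry from multi-echo spin-echo trains.

The signal model is the standard single-compartment magnitude decay

    S(TE) = S0 * exp(-TE / T2)

fitted per voxel across the echo train, either by weighted linear regression
of ln S on TE (``log_linear``; weights are the squared signal, the usual
first-order variance propagation of log-transformed data) or by iterative
least squares on the native signal scale (``nonlinear``), initialized from
the log-linear solution. Echoes at or below a configurable noise floor are
dropped per voxel before fitting; at least three usable echoes are required.

ROI-level output is the mean T2 over the core of the ischemic lesion, pooled
across all lesion-bearing slices, minus the mean over the mirror-image
contralateral region — the ipsilateral-minus-contralateral T2 difference used
as a vasogenic-edema readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.special import i0e

__all__ = [
    "VoxelFit",
    "T2Map",
    "RoiT2Result",
    "fit_t2_voxel",
    "fit_t2_map",
    "mirror_roi",
    "roi_delta_t2",
]

DEFAULT_T2_BOUNDS: tuple[float, float] = (1.0, 1000.0)


class VoxelFit(NamedTuple):
    """Result of one voxelwise decay fit."""

    t2: float
    s0: float
    r_squared: float
    valid: bool


@dataclass(frozen=True)
class T2Map:
    """Per-voxel T2/S0 fields with fit diagnostics.

    ``t2`` (ms), ``s0`` and ``r_squared`` are NaN wherever ``valid`` is
    False; ``r_squared`` is computed on the native signal scale for both fit
    methods and clipped to [0, 1].
    """

    t2: np.ndarray
    s0: np.ndarray
    r_squared: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.t2.shape, self.s0.shape, self.r_squared.shape, self.valid.shape}
        if len(shapes) != 1:
            raise ValueError("T2 map fields must share one spatial shape")
        v = self.valid
        if v.any():
            if np.any(~np.isfinite(self.t2[v])) or np.any(self.s0[v] <= 0):
                raise ValueError("valid voxels must have finite T2 and positive S0")


@dataclass(frozen=True)
class RoiT2Result:
    """Pooled ROI T2 means and their ipsilateral-contralateral difference (ms)."""

    t2_ipsi: float
    t2_contra: float
    delta_t2: float
    n_voxels_ipsi: int
    n_voxels_contra: int


def _invalid() -> VoxelFit:
    return VoxelFit(t2=math.nan, s0=math.nan, r_squared=math.nan, valid=False)


def _loglinear_estimate(te: np.ndarray, signal: np.ndarray) -> tuple[float, float]:
    """Weighted regression of ln S on TE with weights S^2; returns (t2, s0).

    The slope of ln S vs TE is -1/T2; weighting by the squared signal undoes
    the noise amplification of the log transform at late echoes.
    """
    w = signal ** 2
    y = np.log(signal)
    wsum = w.sum()
    x_bar = (w * te).sum() / wsum
    y_bar = (w * y).sum() / wsum
    sxx = (w * (te - x_bar) ** 2).sum()
    sxy = (w * (te - x_bar) * (y - y_bar)).sum()
    if sxx == 0 or sxy == 0:
        return math.nan, math.nan
    slope = sxy / sxx
    intercept = y_bar - slope * x_bar
    return -1.0 / slope, math.exp(intercept)


def _native_r_squared(te: np.ndarray, signal: np.ndarray, t2: float, s0: float) -> float:
    pred = s0 * np.exp(-te / t2)
    ss_res = float(((signal - pred) ** 2).sum())
    ss_tot = float(((signal - signal.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def _rician_mle(t: np.ndarray, s: np.ndarray, sigma: float,
                x0: np.ndarray) -> tuple[float, float]:
    """Maximize the Rician log-likelihood of the magnitudes over (S0, T2).

    The magnitude of complex Gaussian data at underlying amplitude A follows
    the Rice distribution; with known sigma the negative log-likelihood is
    sum of (m^2 + A^2)/(2 sigma^2) - log I0(m A / sigma^2) up to constants.
    Using all echoes with the correct likelihood avoids both the upward bias
    of low-SNR magnitudes and the information loss of discarding them.
    """
    v = sigma ** 2

    def nll(p: np.ndarray) -> float:
        s0, t2 = p
        if s0 <= 0 or t2 <= 0:
            return 1e300
        amp = s0 * np.exp(-t / t2)
        x = s * amp / v
        ll = -(amp ** 2) / (2.0 * v) + np.log(i0e(x)) + x
        return float(-ll.sum())

    res = minimize(nll, x0=x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    return float(res.x[1]), float(res.x[0])


def fit_t2_voxel(
    signal,
    echo_times,
    method: str = "log_linear",
    t2_bounds: tuple[float, float] = DEFAULT_T2_BOUNDS,
    noise_floor: float = 0.0,
    sigma: float | None = None,
) -> VoxelFit:
    """Fit S(TE) = S0 exp(-TE/T2) to one voxel's echo train.

    Parameters
    ----------
    signal
        Non-negative magnitudes, one per echo.
    echo_times
        Echo times in ms, strictly increasing.
    method
        ``"log_linear"`` or ``"nonlinear"``.
    t2_bounds
        Physical plausibility window (ms); estimates outside it are flagged
        invalid rather than clipped.
    noise_floor
        Echoes with signal <= this are dropped before fitting.
    sigma
        Known (or estimated) noise SD of the underlying complex channels.
        When given with ``method="nonlinear"``, the fit maximizes the Rician
        likelihood of the magnitudes instead of minimizing squared residuals,
        which removes the rectified-noise bias of late low-SNR echoes.

    Returns
    -------
    VoxelFit
        ``valid`` is False (with NaN estimates) when fewer than three echoes
        clear the noise floor or the estimate is unphysical; degenerate input
        never raises.
    """
    signal = np.asarray(signal, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if signal.shape != te.shape:
        raise ValueError("signal and echo_times must have the same length")
    usable = signal > max(noise_floor, 0.0)
    if int(usable.sum()) < 3:
        return _invalid()
    s = signal[usable]
    t = te[usable]

    t2, s0 = _loglinear_estimate(t, s)
    if method == "nonlinear":
        if not (math.isfinite(t2) and t2 > 0 and math.isfinite(s0) and s0 > 0):
            t2, s0 = float(np.median(t)), float(s.max())
        x0 = np.array([min(max(s0, 1e-12), 1e12), min(max(t2, t2_bounds[0]), t2_bounds[1])])
        if sigma is not None and sigma > 0:
            t2, s0 = _rician_mle(t, s, sigma, x0)
        else:
            sol = least_squares(
                lambda p: p[0] * np.exp(-t / p[1]) - s,
                x0=x0,
                bounds=([1e-12, t2_bounds[0] / 10], [np.inf, t2_bounds[1] * 10]),
                method="trf",
            )
            s0, t2 = float(sol.x[0]), float(sol.x[1])
    elif method != "log_linear":
        raise ValueError(f"unknown fit method {method!r}")

    if not (math.isfinite(t2) and math.isfinite(s0)):
        return _invalid()
    if not (t2_bounds[0] <= t2 <= t2_bounds[1]) or s0 <= 0:
        return _invalid()
    return VoxelFit(t2=float(t2), s0=float(s0),
                    r_squared=_native_r_squared(t, s, t2, s0), valid=True)


def fit_t2_map(
    image,
    method: str = "log_linear",
    t2_bounds: tuple[float, float] = DEFAULT_T2_BOUNDS,
    noise_floor: float = 0.0,
    sigma: float | None = None,
) -> T2Map:
    """Voxelwise T2 fit of a whole echo-train image.

    Identical, voxel for voxel, to calling :func:`fit_t2_voxel` on every
    voxel; voxels with fewer than three echoes above the noise floor are
    skipped cheaply (they would come back invalid anyway).
    """
    voxels = image.voxels
    te = np.asarray(image.echo_times, dtype=float)
    shape = voxels.shape[:3]
    t2 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    r2 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    candidates = (voxels > max(noise_floor, 0.0)).sum(axis=3) >= 3
    for ix, iy, iz in np.argwhere(candidates):
        fit = fit_t2_voxel(
            voxels[ix, iy, iz, :], te, method=method,
            t2_bounds=t2_bounds, noise_floor=noise_floor, sigma=sigma,
        )
        if fit.valid:
            t2[ix, iy, iz] = fit.t2
            s0[ix, iy, iz] = fit.s0
            r2[ix, iy, iz] = fit.r_squared
            valid[ix, iy, iz] = True
    return T2Map(t2=t2, s0=s0, r_squared=r2, valid=valid)


def mirror_roi(roi: np.ndarray, midline_x: float) -> np.ndarray:
    """Reflect a boolean ROI across the sagittal plane x = midline_x.

    The ROI must lie entirely on one side of the midline. Reflected voxel
    indices are rounded to the nearest integer; reflections falling outside
    the volume are dropped, and an all-outside reflection is an error. When
    2*midline_x is an integer the reflection maps voxel centers to voxel
    centers and is an exact involution.
    """
    roi = np.asarray(roi, dtype=bool)
    idx = np.argwhere(roi)
    if idx.size == 0:
        raise ValueError("empty ROI cannot be mirrored")
    x = idx[:, 0].astype(float)
    if not (np.all(x > midline_x) or np.all(x < midline_x)):
        raise ValueError("ROI must lie entirely on one side of the midline")
    x_ref = np.rint(2.0 * midline_x - x).astype(int)
    inside = (x_ref >= 0) & (x_ref < roi.shape[0])
    if not inside.any():
        raise ValueError("mirrored ROI falls entirely outside the image")
    out = np.zeros_like(roi)
    out[x_ref[inside], idx[inside, 1], idx[inside, 2]] = True
    return out


def roi_delta_t2(t2map: T2Map, roi_ipsi: np.ndarray, midline_x: float) -> RoiT2Result:
    """Mean T2 in an ipsilateral ROI minus its mirrored contralateral ROI.

    Means pool all valid voxels across every slice the ROI touches
    (voxel-weighted, not slice-averaged); invalid fits are excluded.
    """
    roi_ipsi = np.asarray(roi_ipsi, dtype=bool)
    roi_contra = mirror_roi(roi_ipsi, midline_x)
    sel_ipsi = roi_ipsi & t2map.valid
    sel_contra = roi_contra & t2map.valid
    if not sel_ipsi.any():
        raise ValueError("no valid T2 fits in the ipsilateral ROI")
    if not sel_contra.any():
        raise ValueError("no valid T2 fits in the mirrored contralateral ROI")
    t2_ipsi = float(t2map.t2[sel_ipsi].mean())
    t2_contra = float(t2map.t2[sel_contra].mean())
    return RoiT2Result(
        t2_ipsi=t2_ipsi,
        t2_contra=t2_contra,
        delta_t2=t2_ipsi - t2_contra,
        n_voxels_ipsi=int(sel_ipsi.sum()),
        n_voxels_contra=int(sel_contra.sum()),
    )
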