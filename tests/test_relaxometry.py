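"""Voxelwise decay fitting, ROI mirroring and the hemispheric T2 difference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strokevol import (
    EchoTrainImage,
    PhantomSpec,
    VoxelGeometry,
    fit_t2_map,
    fit_t2_voxel,
    generate_phantom,
    mirror_roi,
    roi_delta_t2,
)
from strokevol.relaxometry import T2Map
from strokevol.volumetry import landmarks_from_masks  # noqa: F401  (doc cross-ref)


class TestVoxelFit:
    @pytest.mark.parametrize("method", ["log_linear", "nonlinear"])
    def test_exact_recovery_of_noiseless_decay(self, method, echo_times):
        signal = 1000.0 * np.exp(-echo_times / 50.0)
        fit = fit_t2_voxel(signal, echo_times, method=method)
        assert fit.valid
        assert fit.t2 == pytest.approx(50.0, rel=1e-9)
        assert fit.s0 == pytest.approx(1000.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        t2=st.floats(min_value=5.0, max_value=500.0),
        s0=st.floats(min_value=1.0, max_value=1e5),
    )
    def test_noiseless_recovery_property(self, t2, s0):
        te = np.arange(18.0, 217.0, 18.0)
        fit = fit_t2_voxel(s0 * np.exp(-te / t2), te, method="log_linear")
        assert fit.valid
        assert abs(fit.t2 - t2) / t2 < 1e-6
        assert abs(fit.s0 - s0) / s0 < 1e-6

    def test_zero_signal_is_invalid_not_an_exception(self, echo_times):
        fit = fit_t2_voxel(np.zeros(12), echo_times)
        assert not fit.valid
        assert np.isnan(fit.t2)

    def test_fewer_than_three_usable_echoes_invalid(self, echo_times):
        signal = np.zeros(12)
        signal[:2] = 100.0
        assert not fit_t2_voxel(signal, echo_times).valid

    def test_out_of_bounds_t2_flagged_invalid(self, echo_times):
        # effectively flat signal: implied T2 far above the physical window
        signal = 1000.0 * np.exp(-echo_times / 50000.0)
        fit = fit_t2_voxel(signal, echo_times, t2_bounds=(1.0, 1000.0))
        assert not fit.valid

    def test_log_linear_matches_weighted_regression_oracle(self, echo_times):
        # fixed perturbation, then compare against numpy's weighted polyfit
        # (an independent implementation of the same weighted LS problem)
        rng = np.random.default_rng(42)
        signal = 800.0 * np.exp(-echo_times / 65.0) + rng.normal(0.0, 4.0, 12)
        fit = fit_t2_voxel(signal, echo_times, method="log_linear")
        # np.polyfit weights multiply residuals before squaring: w=signal
        # corresponds to weights signal^2 on squared residuals
        slope, intercept = np.polyfit(echo_times, np.log(signal), 1, w=signal)
        assert fit.t2 == pytest.approx(-1.0 / slope, rel=1e-10)
        assert fit.s0 == pytest.approx(np.exp(intercept), rel=1e-10)

    def test_rician_mle_reduces_magnitude_bias(self, echo_times):
        # long-T2 voxel with visible noise: the sigma-aware fit should sit
        # closer to truth on average than plain least squares on magnitudes
        rng = np.random.default_rng(3)
        t2_true, s0, sigma = 80.0, 1000.0, 25.0
        err_plain, err_mle = [], []
        for _ in range(50):
            s = s0 * np.exp(-echo_times / t2_true)
            m = np.hypot(s + sigma * rng.standard_normal(12),
                         sigma * rng.standard_normal(12))
            err_plain.append(fit_t2_voxel(m, echo_times, "nonlinear").t2 - t2_true)
            err_mle.append(
                fit_t2_voxel(m, echo_times, "nonlinear", sigma=sigma).t2 - t2_true
            )
        assert abs(np.mean(err_mle)) < abs(np.mean(err_plain))


class TestMapFit:
    def test_uniform_phantom_constant_map(self, echo_times):
        te = echo_times
        voxels = np.broadcast_to(
            500.0 * np.exp(-te / 42.0), (4, 4, 2, 12)
        ).copy()
        image = EchoTrainImage(voxels=voxels, echo_times=te,
                               geometry=VoxelGeometry(0.3, 2.0))
        t2map = fit_t2_map(image)
        assert t2map.valid.all()
        assert np.allclose(t2map.t2, 42.0, rtol=1e-9)

    def test_map_equals_voxel_loop_oracle(self, echo_times):
        rng = np.random.default_rng(0)
        t2f = rng.uniform(30.0, 90.0, (8, 8, 2))
        s0f = rng.uniform(500.0, 1500.0, (8, 8, 2))
        s0f[:2, :, :] = 0.0  # background corner
        voxels = s0f[..., None] * np.exp(-echo_times / t2f[..., None])
        voxels += rng.normal(0.0, 5.0, voxels.shape)
        voxels = np.clip(voxels, 0.0, None)
        image = EchoTrainImage(voxels=voxels, echo_times=echo_times,
                               geometry=VoxelGeometry(0.3, 2.0))
        t2map = fit_t2_map(image, noise_floor=15.0)
        for ix in range(8):
            for iy in range(8):
                for iz in range(2):
                    ref = fit_t2_voxel(voxels[ix, iy, iz], echo_times,
                                       noise_floor=15.0)
                    assert t2map.valid[ix, iy, iz] == ref.valid
                    if ref.valid:
                        assert t2map.t2[ix, iy, iz] == ref.t2
                        assert t2map.s0[ix, iy, iz] == ref.s0
                    else:
                        assert np.isnan(t2map.t2[ix, iy, iz])

    def test_background_voxels_invalid(self, small_phantom):
        _, image, truth = small_phantom
        t2map = fit_t2_map(image)
        background = truth.masks.labels == 0
        assert not t2map.valid[background].any()


class TestMirror:
    def test_single_voxel_reflection(self):
        roi = np.zeros((21, 5, 3), dtype=bool)
        roi[15, 2, 1] = True  # midline 10, offset +5
        mirrored = mirror_roi(roi, midline_x=10.0)
        assert mirrored[5, 2, 1]
        assert mirrored.sum() == 1

    def test_involution_and_size_preserved(self):
        rng = np.random.default_rng(5)
        roi = np.zeros((30, 8, 4), dtype=bool)
        sel = rng.random((10, 8, 4)) < 0.3
        roi[18:28][sel] = True  # entirely right of midline 14.5
        mirrored = mirror_roi(roi, midline_x=14.5)
        assert mirrored.sum() == roi.sum()
        assert np.array_equal(mirror_roi(mirrored, midline_x=14.5), roi)

    def test_straddling_roi_rejected(self):
        roi = np.zeros((10, 2, 1), dtype=bool)
        roi[2, 0, 0] = roi[8, 0, 0] = True
        with pytest.raises(ValueError):
            mirror_roi(roi, midline_x=5.0)

    def test_reflection_outside_image_rejected(self):
        roi = np.zeros((10, 2, 1), dtype=bool)
        roi[9, 0, 0] = True
        with pytest.raises(ValueError):
            mirror_roi(roi, midline_x=-2.0)


def _map_from_fields(t2_field):
    shape = t2_field.shape
    return T2Map(
        t2=t2_field.astype(float),
        s0=np.full(shape, 1000.0),
        r_squared=np.ones(shape),
        valid=np.isfinite(t2_field) & (t2_field > 0),
    )


class TestRoiDeltaT2:
    def test_symmetric_map_gives_zero_delta(self):
        t2 = np.full((20, 6, 2), 55.0)
        roi = np.zeros((20, 6, 2), dtype=bool)
        roi[14:17, 2:4, :] = True
        res = roi_delta_t2(_map_from_fields(t2), roi, midline_x=9.5)
        assert res.delta_t2 == 0.0
        assert res.n_voxels_ipsi == roi.sum()

    def test_constructed_elevation_recovered(self):
        t2 = np.full((20, 6, 2), 55.0)
        roi = np.zeros((20, 6, 2), dtype=bool)
        roi[14:17, 2:4, :] = True
        t2[roi] = 75.0
        res = roi_delta_t2(_map_from_fields(t2), roi, midline_x=9.5)
        assert res.delta_t2 == pytest.approx(20.0)

    def test_antisymmetric_under_roi_swap(self):
        rng = np.random.default_rng(8)
        t2 = rng.uniform(40.0, 90.0, (20, 6, 2))
        roi = np.zeros((20, 6, 2), dtype=bool)
        roi[13:18, 1:5, :] = True
        fwd = roi_delta_t2(_map_from_fields(t2), roi, midline_x=9.5)
        swapped = roi_delta_t2(
            _map_from_fields(t2), mirror_roi(roi, 9.5), midline_x=9.5
        )
        assert swapped.delta_t2 == pytest.approx(-fwd.delta_t2, abs=1e-12)

    def test_error_identifies_side_without_valid_voxels(self):
        t2 = np.full((20, 6, 2), np.nan)
        t2[14:17, 2:4, :] = 60.0  # ipsi side valid, mirror side NaN
        roi = np.zeros((20, 6, 2), dtype=bool)
        roi[14:17, 2:4, :] = True
        with pytest.raises(ValueError, match="contralateral"):
            roi_delta_t2(_map_from_fields(t2), roi, midline_x=9.5)

    def test_noisy_phantom_delta_within_2ms_over_20_seeds(self):
        errors = []
        for seed in range(20):
            spec = PhantomSpec(matrix=64, noise_model="rician", snr=50.0, seed=seed)
            image, truth = generate_phantom(spec)
            floor = 3.0 * spec.noise_sigma
            t2map = fit_t2_map(image, method="log_linear", noise_floor=floor)
            roi = truth.masks.region_mask("roi_ischemic")
            res = roi_delta_t2(t2map, roi, truth.midline_x)
            errors.append(abs(res.delta_t2 - truth.true_delta_t2))
        assert max(errors) < 2.0
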