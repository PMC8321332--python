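"""Classical and referenceless temperature reconstruction."""

import numpy as np
import pytest

from prfthermo.core import ImageSeries, PRFParams, ROILabelMap, wrap_phase
from prfthermo.errors import MaskError
from prfthermo.phantom import (
    HotspotSpec,
    PhantomConfig,
    gen_hotspot_field,
    gen_phantom_series,
)
from prfthermo.thermometry import (
    classical_prf_map,
    delta_T_from_phase,
    estimate_background_phase,
    phase_from_delta_T,
    referenceless_map,
    temperature_curves,
)

KERNELS_3 = ("linear", "thin_plate_spline", "multiquadric")


def _forward_series(delta_T_frames, params, background=0.0, amplitude=10.0):
    """Simulate the phase of known ΔT fields under the PRF model."""
    phases = [wrap_phase(background + phase_from_delta_T(d, params)) for d in delta_T_frames]
    mags = [np.full_like(p, amplitude) for p in phases]
    return ImageSeries(
        magnitude=np.stack(mags),
        phase=np.stack(phases),
        echo_time=params.echo_time,
        field_strength=params.field_strength,
        pixel_spacing=(1.0, 1.0),
    )


class TestClassicalPRF:
    def test_target_equals_baseline_gives_zero(self, heated_bundle):
        series, _, _ = heated_bundle
        tmap = classical_prf_map(series, 2, 2)
        np.testing.assert_allclose(tmap.delta_T, 0.0, atol=1e-12)

    def test_forward_inverse_round_trip(self, rng):
        params = PRFParams(echo_time=0.01)
        truth = 12.0 * rng.random((16, 16))
        series = _forward_series([np.zeros_like(truth), truth], params)
        tmap = classical_prf_map(series, 0, 1, params)
        np.testing.assert_allclose(tmap.delta_T, truth, atol=1e-6)

    def test_te_scaling_leaves_deltaT_unchanged(self, rng):
        """Doubling TE doubles Δφ per °C; the recovered ΔT must not move."""
        truth = 8.0 * rng.random((12, 12))
        maps = []
        for te in (0.01, 0.02):
            params = PRFParams(echo_time=te)
            series = _forward_series([np.zeros_like(truth), truth], params)
            maps.append(classical_prf_map(series, 0, 1, params).delta_T)
        np.testing.assert_allclose(maps[0], maps[1], atol=1e-9)

    def test_wrap_saturation_is_counted_not_repaired(self):
        params = PRFParams(echo_time=0.01)
        # |Δφ| per °C ≈ 0.0401 rad: 100 °C wraps past π
        truth = np.full((6, 6), 100.0)
        series = _forward_series([np.zeros_like(truth), truth], params)
        tmap = classical_prf_map(series, 0, 1, params)
        assert np.abs(tmap.delta_T).max() <= np.pi / abs(params.rad_per_degC) + 1e-9
        assert tmap.extras["saturated_pixels"] == 0  # aliased but not at the boundary

    def test_invalid_frame_index_rejected(self, heated_bundle):
        series, _, _ = heated_bundle
        with pytest.raises(IndexError):
            classical_prf_map(series, 0, series.n_frames)


class TestBackgroundEstimation:
    def _masks(self, shape=(40, 40)):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        r = np.hypot(yy - shape[0] / 2, xx - shape[1] / 2)
        return r <= 8, (r > 8) & (r <= 16)

    @pytest.mark.parametrize("interpolator", KERNELS_3 + (1,))
    def test_affine_phase_recovered_exactly(self, interpolator):
        inner, outer = self._masks()
        yy, xx = np.mgrid[0:40, 0:40]
        phase = 0.1 + 0.005 * yy - 0.003 * xx
        est, stats = estimate_background_phase(phase, inner, outer, interpolator)
        np.testing.assert_allclose(est[inner], phase[inner], atol=1e-8)
        assert stats["outer_residual_max_abs"] < 1e-8

    def test_zero_phase_gives_zero_estimate(self):
        inner, outer = self._masks()
        est, _ = estimate_background_phase(np.zeros((40, 40)), inner, outer, "linear")
        np.testing.assert_allclose(est[inner | outer], 0.0, atol=1e-10)
        assert np.all(np.isnan(est[~(inner | outer)]))

    def test_hot_spot_bump_excluded_from_background(self):
        inner, outer = self._masks()
        yy, xx = np.mgrid[0:40, 0:40]
        affine = 0.2 + 0.004 * yy + 0.002 * xx
        bump = -0.6 * np.exp(-((yy - 20.0) ** 2 + (xx - 20.0) ** 2) / 18.0)
        bump[~inner] = 0.0  # heating confined to the inner region
        est, _ = estimate_background_phase(affine + bump, inner, outer, "linear")
        np.testing.assert_allclose(est[inner], affine[inner], atol=1e-8)

    def test_empty_or_overlapping_masks_rejected(self):
        inner, outer = self._masks()
        phase = np.zeros((40, 40))
        with pytest.raises(MaskError):
            estimate_background_phase(phase, np.zeros_like(inner), outer, "linear")
        with pytest.raises(MaskError):
            estimate_background_phase(phase, inner, inner, "linear")


class TestReferenceless:
    def test_null_case_is_cold(self, noiseless_config):
        series, rois, _ = gen_phantom_series(noiseless_config, n_frames=1, seed=5)
        for interpolator in KERNELS_3:
            tmap = referenceless_map(series, 0, rois, interpolator=interpolator)
            assert np.abs(tmap.delta_T[rois.mask("inner_roi")]).max() < 0.01

    @pytest.mark.parametrize("interpolator", KERNELS_3)
    def test_recovers_16C_hot_spot(self, static_hot_bundle, interpolator):
        series, rois, truth = static_hot_bundle
        tmap = referenceless_map(series, 0, rois, interpolator=interpolator)
        peak = tmap.delta_T[rois.mask("inner_roi")].max()
        assert peak == pytest.approx(16.0, abs=0.1)

    def test_matches_classical_when_heating_confined_to_inner(self, noiseless_config):
        """With affine background and strictly-confined heating, baseline
        subtraction and background extrapolation must agree to 1e-3 °C."""
        series0, rois, _ = gen_phantom_series(noiseless_config, n_frames=1, seed=6)
        params = PRFParams.from_series(series0)
        inner = rois.mask("inner_roi")
        spot = gen_hotspot_field(
            noiseless_config.grid_shape,
            noiseless_config.pixel_spacing_mm,
            (80.0, 78.75),
            sigma_mm=4.0,
            peak_deltaT=12.0,
        )
        spot = np.where(inner, spot, 0.0)
        base_phase = series0.phase[0]
        heated_phase = wrap_phase(base_phase + phase_from_delta_T(spot, params))
        series = ImageSeries(
            magnitude=np.stack([series0.magnitude[0]] * 2),
            phase=np.stack([base_phase, heated_phase]),
            frame_interval=series0.frame_interval,
            echo_time=series0.echo_time,
            field_strength=series0.field_strength,
            pixel_spacing=series0.pixel_spacing,
        )
        classical = classical_prf_map(series, 0, 1, params)
        for interpolator in KERNELS_3:
            refless = referenceless_map(series, 1, rois, interpolator=interpolator)
            diff = np.abs(classical.delta_T - refless.delta_T)[inner]
            assert diff.max() < 1e-3

    def test_peak_scales_linearly_with_amplitude(self, noiseless_config):
        peaks = {}
        for k, amp in ((1.0, 16.0), (0.5, 8.0), (2.0, 32.0)):
            series, rois, _ = gen_phantom_series(
                noiseless_config, hotspot=HotspotSpec(peak_deltaT=amp), n_frames=1, seed=0
            )
            tmap = referenceless_map(series, 0, rois, interpolator="linear")
            peaks[k] = tmap.delta_T[rois.mask("inner_roi")].max()
        assert peaks[0.5] == pytest.approx(0.5 * peaks[1.0], rel=0.01)
        assert peaks[2.0] == pytest.approx(2.0 * peaks[1.0], rel=0.01)

    def test_null_scatter_grows_as_snr_drops(self, small_config):
        """Lower magnitude SNR → noisier referenceless null maps (the low-SNR
        failure mechanism): mean ΔT std increases monotonically with σ_g."""
        sigmas = (0.5, 1.0, 2.0, 4.0)
        scatter = []
        for noise in sigmas:
            cfg = PhantomConfig(**{**small_config.__dict__, "noise_sigma": noise})
            stds = []
            for rep in range(20):
                series, rois, _ = gen_phantom_series(cfg, n_frames=1, seed=1000 + rep)
                tmap = referenceless_map(
                    series, 0, rois, interpolator="linear", seed=rep, max_nodes=250
                )
                stds.append(tmap.delta_T[rois.mask("inner_roi")].std())
            scatter.append(np.mean(stds))
        assert all(a < b for a, b in zip(scatter, scatter[1:]))


class TestTemperatureCurves:
    def _maps(self, fields, valid=None):
        params = PRFParams(echo_time=0.01)
        from prfthermo.thermometry import TemperatureMap

        maps = []
        for i, f in enumerate(fields):
            maps.append(
                TemperatureMap(
                    delta_T=f,
                    validity=np.ones_like(f, dtype=bool) if valid is None else valid,
                    method="classical_prf",
                    frame_index=i,
                    params=params,
                    time_s=3.0 * i,
                )
            )
        return maps

    def test_constant_maps_give_constant_curves(self):
        maps = self._maps([np.full((9, 9), 2.5)] * 4)
        curves = temperature_curves(maps, (4, 4), neighborhood_radius=2)
        np.testing.assert_allclose(curves.pixel, 2.5)
        np.testing.assert_allclose(curves.neighborhood, 2.5)
        np.testing.assert_allclose(curves.times, [0.0, 3.0, 6.0, 9.0])

    def test_radius_zero_collapses_to_pixel_curve(self, rng):
        maps = self._maps([rng.normal(size=(9, 9)) for _ in range(3)])
        curves = temperature_curves(maps, (3, 5), neighborhood_radius=0)
        np.testing.assert_allclose(curves.pixel, curves.neighborhood)

    def test_peak_frame_matches_injected_heating(self, heated_bundle):
        series, rois, truth = heated_bundle
        maps = [classical_prf_map(series, 0, t) for t in range(series.n_frames)]
        hot_pixel = np.unravel_index(np.argmax(truth.delta_T.sum(axis=0)), truth.delta_T[0].shape)
        curves = temperature_curves(maps, hot_pixel, neighborhood_radius=1)
        truth_peak_frame = int(np.argmax(truth.delta_T[:, hot_pixel[0], hot_pixel[1]]))
        assert int(np.nanargmax(curves.pixel)) == truth_peak_frame

    def test_invalid_point_is_flagged_not_zeroed(self):
        valid = np.zeros((9, 9), dtype=bool)
        valid[:4] = True
        maps = self._maps([np.ones((9, 9))] * 2, valid=valid)
        curves = temperature_curves(maps, (8, 8), neighborhood_radius=0)
        assert curves.flagged.all()
        assert np.isnan(curves.pixel).all()

    def test_point_outside_map_rejected(self):
        maps = self._maps([np.zeros((5, 5))])
        with pytest.raises(IndexError):
            temperature_curves(maps, (9, 2))
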