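"""Study pipeline: per-sonication maxima, Wilcoxon tests, method comparison."""

import json

import numpy as np
import pytest

from oracles import signflip_enumeration_p as _signflip_enumeration_p
from prfthermo.analysis import (
    StudyConfig,
    compare_methods,
    max_rise_per_sonication,
    run_study,
    wilcoxon_signed_rank,
)
from prfthermo.errors import DegenerateInputError, UnknownMethodError
from prfthermo.phantom import (
    HotspotSpec,
    PhantomConfig,
    Sonication,
    SonicationSchedule,
    SonicationTimeSeries,
    gen_phantom_series,
    gen_probe_timeseries,
    gen_sonication_schedule,
)


def _flat_trace(schedule, value=20.0):
    t = np.arange(0.0, schedule.total_duration_s + 1.0)
    return SonicationTimeSeries("p", t, np.full_like(t, value), schedule)


class TestMaxRise:
    def test_flat_trace_gives_zeros(self):
        sched = gen_sonication_schedule(n=4, seed=0)
        np.testing.assert_allclose(max_rise_per_sonication(_flat_trace(sched), sched), 0.0)

    def test_matches_saturation_closed_form(self):
        sched = SonicationSchedule([Sonication(5.0, 20.0, 85.0, 2353.0)])
        ts = gen_probe_timeseries(
            sched, gains_C=(10.0, 3.0), noise_sigma_C=0.0, coupling_jitter=0.0, seed=0
        )[0]
        rises = max_rise_per_sonication(ts, sched)
        assert rises[0] == pytest.approx(10.0 * (1 - np.exp(-20.0 / 8.0)), rel=1e-6)

    def test_weak_and_strong_regimes_extracted(self):
        """A sub-1 °C sonication and a ~16 °C one must both be read back."""
        sched = SonicationSchedule(
            [Sonication(0.0, 20.0, 85.0, 2353.0), Sonication(105.0, 20.0, 85.0, 2353.0)]
        )
        weak_gain = 0.5 / (1 - np.exp(-20.0 / 8.0))
        strong_gain = 16.0 / (1 - np.exp(-20.0 / 8.0))
        t = np.arange(0.0, sched.total_duration_s + 1.0)
        from prfthermo.phantom import thermal_envelope

        weak = thermal_envelope(t, SonicationSchedule([sched[0]]), normalize=False)
        strong = thermal_envelope(t, SonicationSchedule([sched[1]]), normalize=False)
        ts = SonicationTimeSeries("p", t, 20.0 + weak_gain * weak + strong_gain * strong, sched)
        rises = max_rise_per_sonication(ts, sched)
        assert rises[0] == pytest.approx(0.5, abs=0.05)
        assert rises[1] == pytest.approx(16.0, abs=0.5)
        assert rises[0] < 1.0 < 15.0 < rises[1]

    def test_invariant_to_constant_offset(self):
        sched = gen_sonication_schedule(n=3, seed=1)
        ts = gen_probe_timeseries(sched, seed=1)[0]
        shifted = SonicationTimeSeries("p", ts.times_s, ts.temps_C + 7.5, sched)
        np.testing.assert_allclose(
            max_rise_per_sonication(shifted, sched), max_rise_per_sonication(ts, sched)
        )

    def test_uncovered_window_names_sonication(self):
        sched = gen_sonication_schedule(n=3, seed=2)
        t = np.arange(0.0, sched[2].start_s + 5.0)
        short = SonicationTimeSeries("p", t, np.full_like(t, 20.0), sched)
        with pytest.raises(ValueError, match="sonication 2"):
            max_rise_per_sonication(short, sched)


class TestWilcoxon:
    def test_constant_positive_shift_reaches_floor_p(self, rng):
        b = rng.normal(size=10)
        result = wilcoxon_signed_rank(b + 1.0, b)
        assert result.statistic == 55.0
        assert result.p_value == pytest.approx(2.0 / 1024.0)
        assert result.method == "exact"

    def test_identical_samples_are_degenerate(self, rng):
        a = rng.normal(size=8)
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank(a, a.copy())

    @pytest.mark.parametrize("n", [5, 8, 11, 12])
    def test_exact_p_matches_enumeration_oracle(self, n, rng):
        for _ in range(10):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            result = wilcoxon_signed_rank(a, b)
            assert result.p_value == pytest.approx(_signflip_enumeration_p(a - b), abs=1e-12)

    def test_exact_p_matches_enumeration_with_ties(self, rng):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.5])
        b = np.array([0.0, 1.0, 1.0, 2.0, 7.0, 4.0, 4.0])  # tied |differences|
        result = wilcoxon_signed_rank(a, b)
        assert result.p_value == pytest.approx(_signflip_enumeration_p(a - b), abs=1e-12)

    def test_exact_p_matches_scipy(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        for _ in range(5):
            a, b = rng.normal(size=9), rng.normal(size=9)
            ours = wilcoxon_signed_rank(a, b)
            ref = scipy_wilcoxon(a, b, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_uses_corrected_normal_approximation(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        a, b = rng.normal(size=40), rng.normal(size=40)
        ours = wilcoxon_signed_rank(a, b)
        ref = scipy_wilcoxon(a, b, alternative="two-sided", method="approx", correction=True)
        assert ours.method == "normal_approx"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])


@pytest.fixture(scope="module")
def noisy_quadratic_bundle():
    """Noisy unheated acquisition over a convex quadratic background phase."""
    cfg = PhantomConfig(
        grid_shape=(64, 64),
        pixel_spacing_mm=(2.5, 2.5),
        background_phase_coeffs=(0.1, 0.004, -0.003, 3e-4, 0.0, 3e-4),
    )
    return gen_phantom_series(cfg, n_frames=7, seed=9)


class TestCompareMethods:
    def test_method_equal_to_reference_is_degenerate_zero(self, noisy_null_bundle):
        series, rois, _ = noisy_null_bundle
        result = compare_methods(series, rois, ["classical_prf"], reference="classical_prf")
        m = result.methods["classical_prf"]
        np.testing.assert_allclose(m.errors, 0.0)
        assert m.degenerate and m.test is None

    def test_unknown_method_error_lists_valid_names(self, noisy_null_bundle):
        series, rois, _ = noisy_null_bundle
        with pytest.raises(UnknownMethodError, match="classical_prf"):
            compare_methods(series, rois, ["kriging"])

    def test_bias_negates_when_method_and_reference_swap(self, noisy_quadratic_bundle):
        series, rois, _ = noisy_quadratic_bundle
        fwd = compare_methods(series, rois, ["referenceless_poly"],
                              reference="classical_prf", poly_degree=1, seed=0)
        rev = compare_methods(series, rois, ["classical_prf"],
                              reference="referenceless_poly", poly_degree=1, seed=0)
        np.testing.assert_allclose(
            fwd.methods["referenceless_poly"].errors,
            -rev.methods["classical_prf"].errors,
            atol=1e-10,
        )

    def test_rmse_bounds_bias(self, noisy_quadratic_bundle):
        series, rois, _ = noisy_quadratic_bundle
        result = compare_methods(
            series, rois, ["referenceless_rbf_linear", "referenceless_poly"],
            poly_degree=1, seed=0,
        )
        for m in result.methods.values():
            assert m.rmse >= abs(m.bias) - 1e-12
            if m.test is not None:
                assert 0.0 <= m.test.p_value <= 1.0

    def test_clean_linear_rbf_agrees_with_prf_reference(self, heated_bundle):
        series, rois, _ = heated_bundle
        result = compare_methods(series, rois, ["referenceless_rbf_linear"], seed=0)
        m = result.methods["referenceless_rbf_linear"]
        assert abs(m.bias) < 0.1 and m.rmse < 0.1

    def test_undermodelled_polynomial_overestimates_significantly(self, noisy_quadratic_bundle):
        """An affine fit across a convex quadratic background inflates the
        apparent heating: positive bias, significant at α = 0.05 — while the
        linear RBF (degree-1 tail + kernel term) stays non-significant."""
        series, rois, _ = noisy_quadratic_bundle
        result = compare_methods(
            series, rois, ["referenceless_poly", "referenceless_rbf_linear"],
            reference="classical_prf", poly_degree=1, seed=0,
        )
        poly = result.methods["referenceless_poly"]
        assert poly.bias > 1.0
        assert poly.test.p_value < 0.05
        rbf = result.methods["referenceless_rbf_linear"]
        assert rbf.test.p_value >= 0.05


@pytest.fixture(scope="module")
def tiny_study_config():
    return StudyConfig(
        phantom=PhantomConfig(grid_shape=(64, 64), pixel_spacing_mm=(2.5, 2.5)),
        n_sonications=2,
        imaged_weak=0,
        imaged_strong=1,
        n_frames=7,
        methods=("referenceless_rbf_linear", "referenceless_poly"),
    )


class TestRunStudy:
    def test_report_bundle_completeness(self, tiny_study_config, tmp_path):
        summary = run_study(tiny_study_config, seed=5, out_dir=tmp_path / "study")
        out = tmp_path / "study"
        for name in ("summary.json", "snr_report.csv", "max_rises.csv",
                     "comparison.csv", "probe1.csv", "probe2.csv"):
            assert (out / name).exists()
        for fig in ("snr_by_region.png", "max_rise_per_sonication.png",
                    "probe_traces.png", "interpolation_errors.png"):
            assert (out / "figures" / fig).exists()
        assert set(summary["comparison"]) == set(tiny_study_config.methods)

    def test_same_seed_gives_identical_summaries(self, tiny_study_config, tmp_path):
        run_study(tiny_study_config, seed=11, out_dir=tmp_path / "a", emit_figures=False)
        run_study(tiny_study_config, seed=11, out_dir=tmp_path / "b", emit_figures=False)
        assert (tmp_path / "a/summary.json").read_bytes() == (
            tmp_path / "b/summary.json"
        ).read_bytes()

    def test_sonication_bookkeeping(self, tiny_study_config, tmp_path):
        import pandas as pd

        run_study(tiny_study_config, seed=3, out_dir=tmp_path / "s", emit_figures=False)
        rises = pd.read_csv(tmp_path / "s" / "max_rises.csv")
        assert len(rises) == 2
        assert list(rises.columns) == ["sonication", "probe1", "probe2"]
        summary = json.loads((tmp_path / "s" / "summary.json").read_text())
        assert summary["probes"]["probe1"]["n_sonications"] == 2


class TestCLI:
    def test_simulate_snr_reconstruct_chain(self, tmp_path):
        from click.testing import CliRunner

        from prfthermo.cli import main

        runner = CliRunner()
        cfg = PhantomConfig(grid_shape=(64, 64), pixel_spacing_mm=(2.5, 2.5))
        cfg_path = tmp_path / "phantom.yaml"
        cfg.to_yaml(cfg_path)
        data_dir = tmp_path / "data"
        r = runner.invoke(main, ["simulate", "--config", str(cfg_path), "--seed", "1",
                                 "--n-frames", "2", "--out", str(data_dir)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["snr", "--data", str(data_dir),
                                 "--out", str(tmp_path / "snr.csv")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "snr.csv").exists()
        r = runner.invoke(main, ["reconstruct", "--data", str(data_dir), "--kernel",
                                 "linear", "--out", str(tmp_path / "maps")])
        assert r.exit_code == 0, r.output
        assert list((tmp_path / "maps").glob("*.nii"))
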