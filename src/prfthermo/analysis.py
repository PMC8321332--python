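"""Comparison pipeline: per-sonication maxima, paired Wilcoxon tests, and
interpolation-error analysis of referenceless methods against PRF maps.

``run_study`` chains the stages end to end on synthetic data: simulate a
treatment (schedule, probe traces, imaged sonications) → SNR report →
temperature reconstruction by every method → method-vs-reference comparison
with paired two-sided Wilcoxon signed-rank tests at α = 0.05 → CSV/JSON/PNG
report bundle. Everything is seed-deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, rankdata

from .core import ImageSeries, PRFParams, ROILabelMap
from .errors import DegenerateInputError, UnknownMethodError
from .phantom import (
    HotspotSpec,
    PhantomConfig,
    Sonication,
    SonicationSchedule,
    SonicationTimeSeries,
    gen_phantom_series,
    gen_probe_timeseries,
    gen_sonication_schedule,
)
from .snr import snr_over_series
from .thermometry import TemperatureMap, classical_prf_map, referenceless_map

logger = logging.getLogger("prfthermo.study")

#: largest n for which the exact signed-rank null distribution is enumerated
EXACT_N_MAX = 12

ALPHA = 0.05

METHODS = (
    "classical_prf",
    "referenceless_rbf_linear",
    "referenceless_rbf_thin_plate_spline",
    "referenceless_rbf_gaussian",
    "referenceless_rbf_multiquadric",
    "referenceless_poly",
)


# ---------------------------------------------------------------------------
# per-sonication maxima
# ---------------------------------------------------------------------------

def max_rise_per_sonication(ts: SonicationTimeSeries, schedule: SonicationSchedule) -> np.ndarray:
    """Maximum temperature rise within each sonication window.

    For sonication k the window spans heating plus the cooling tail; the rise
    is the window maximum minus the temperature at window start (linearly
    interpolated). Adding a constant to the whole trace leaves the result
    unchanged.
    """
    times, temps = ts.times_s, ts.temps_C
    rises = np.empty(len(schedule))
    for k, son in enumerate(schedule):
        if son.start_s < times[0] - 1e-9 or son.end_s > times[-1] + 1e-9:
            raise ValueError(
                f"sonication {k} window [{son.start_s}, {son.end_s}] s outside "
                f"sampled range [{times[0]}, {times[-1]}] s"
            )
        in_window = (times >= son.start_s) & (times <= son.end_s)
        start_temp = float(np.interp(son.start_s, times, temps))
        rises[k] = float(temps[in_window].max()) - start_temp
    return rises


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_pairs: int  # pairs remaining after dropping zero differences
    method: str  # "exact" or "normal_approx"

    def __iter__(self):  # allows `stat, p = wilcoxon_signed_rank(...)`
        return iter((self.statistic, self.p_value))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by convolution over the 2^n sign assignments.

    Ranks are doubled to integers (mid-ranks may be half-integral) and the
    null distribution of 2·W+ is built by iterative polynomial convolution —
    each rank contributes a factor (1 + z^(2r))/2.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a, b, alternative: str = "two-sided") -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped before ranking; ties receive mid-ranks. The
    null distribution is enumerated exactly for n ≤ 12 remaining pairs and
    approximated by a tie-corrected normal with continuity correction beyond
    that. The statistic reported is W+, the sum of ranks of positive
    differences.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is implemented")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    if n < 5:
        raise ValueError(f"need at least 5 nonzero paired differences, got {n}")

    ranks = rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())

    if n <= EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, "exact")

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var <= 0:
        raise DegenerateInputError("zero variance after tie correction")
    correction = 0.5 * np.sign(w_plus - mean)
    z = (w_plus - mean - correction) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, "normal_approx")


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------

@dataclass
class MethodErrors:
    name: str
    errors: np.ndarray  # per-frame inner-ROI mean error vs reference, °C
    bias: float
    rmse: float
    test: WilcoxonResult | None
    degenerate: bool = False


@dataclass
class ComparisonResult:
    """Per-method error curves against a common reference, with paired tests."""

    reference: str
    frames: np.ndarray
    methods: dict = field(default_factory=dict)  # name -> MethodErrors
    alpha: float = ALPHA
    n_tests: int = 0

    def __post_init__(self):
        for m in self.methods.values():
            if m.rmse + 1e-12 < abs(m.bias):
                raise ValueError(f"method {m.name}: RMSE {m.rmse} < |bias| {abs(m.bias)}")
            if m.test is not None and not 0.0 <= m.test.p_value <= 1.0:
                raise ValueError(f"method {m.name}: p outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.methods.items():
            for f, e in zip(self.frames, m.errors):
                rows.append({"method": name, "frame": int(f), "error_C": float(e)})
        return pd.DataFrame(rows)


def _method_map(
    series: ImageSeries,
    frame: int,
    rois: ROILabelMap,
    method: str,
    params: PRFParams,
    baseline_frame: int,
    poly_degree: int,
    seed: int,
) -> TemperatureMap:
    if method == "classical_prf":
        return classical_prf_map(series, baseline_frame, frame, params)
    if method.startswith("referenceless_rbf_"):
        kernel = method[len("referenceless_rbf_"):]
        return referenceless_map(series, frame, rois, interpolator=kernel,
                                 params=params, seed=seed)
    if method == "referenceless_poly":
        return referenceless_map(series, frame, rois, interpolator=poly_degree,
                                 params=params, seed=seed)
    raise UnknownMethodError(method, list(METHODS))


def inner_roi_means(
    series: ImageSeries,
    rois: ROILabelMap,
    method: str,
    frames,
    params: PRFParams | None = None,
    baseline_frame: int = 0,
    poly_degree: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Inner-ROI mean ΔT of one method at each requested frame."""
    if params is None:
        params = PRFParams.from_series(series)
    inner = rois.mask("inner_roi")
    out = np.empty(len(frames))
    for i, f in enumerate(frames):
        tmap = _method_map(series, int(f), rois, method, params, baseline_frame, poly_degree, seed)
        out[i] = float(tmap.delta_T[inner & tmap.validity].mean())
    return out


def compare_methods(
    series: ImageSeries,
    rois: ROILabelMap,
    methods,
    reference="classical_prf",
    truth=None,
    params: PRFParams | None = None,
    frames=None,
    baseline_frame: int = 0,
    poly_degree: int = 2,
    seed: int = 0,
) -> ComparisonResult:
    """Score methods against a reference via per-frame inner-ROI mean ΔT.

    ``reference`` is a method name, or ``"truth"`` with a
    :class:`~prfthermo.phantom.TruthRecord` passed as ``truth``. The pairing
    axis is frames: each method contributes one inner-ROI mean per frame, and
    the paired Wilcoxon test compares those samples against the reference's.
    A method identical to the reference yields an all-zero error curve and is
    flagged degenerate rather than tested.
    """
    if not methods:
        raise ValueError("methods list is empty")
    for m in methods:
        if m not in METHODS:
            raise UnknownMethodError(m, list(METHODS))
    if params is None:
        params = PRFParams.from_series(series)
    if frames is None:
        frames = [f for f in range(series.n_frames) if f != baseline_frame]
    frames = np.asarray(frames, dtype=int)

    if reference == "truth":
        if truth is None:
            raise ValueError("reference='truth' needs a TruthRecord")
        inner = rois.mask("inner_roi")
        inner2d = inner if inner.ndim == 2 else inner[..., 0]
        ref_vals = np.array([float(truth.frame_truth(int(f))[inner2d].mean()) for f in frames])
    else:
        if reference not in METHODS:
            raise UnknownMethodError(reference, list(METHODS) + ["truth"])
        ref_vals = inner_roi_means(series, rois, reference, frames, params,
                                   baseline_frame, poly_degree, seed)

    result = ComparisonResult(reference=reference, frames=frames)
    n_tests = 0
    for name in methods:
        vals = inner_roi_means(series, rois, name, frames, params,
                               baseline_frame, poly_degree, seed)
        errors = vals - ref_vals
        bias = float(errors.mean())
        rmse = float(np.sqrt((errors**2).mean()))
        try:
            test = wilcoxon_signed_rank(vals, ref_vals)
            degenerate = False
            n_tests += 1
        except DegenerateInputError:
            test, degenerate = None, True
        result.methods[name] = MethodErrors(
            name=name, errors=errors, bias=bias, rmse=rmse, test=test, degenerate=degenerate
        )
    result.n_tests = n_tests
    result.__post_init__()
    return result


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Configuration of the full synthetic study.

    Two sonications of the treatment schedule are imaged: a *weak* one whose
    focal rise stays below 1 °C and a *strong* ~16 °C one, mirroring the two
    regimes a safety monitor must distinguish.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_sonications: int = 56
    imaged_weak: int = 3  # schedule indices (0-based)
    imaged_strong: int = 4
    weak_peak_C: float = 0.5
    strong_peak_C: float = 16.0
    n_frames: int = 10
    methods: tuple = (
        "referenceless_rbf_linear",
        "referenceless_rbf_thin_plate_spline",
        "referenceless_rbf_multiquadric",
        "referenceless_poly",
    )
    poly_degree: int = 2

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        doc = yaml.safe_load(open(path)) or {}
        phantom = PhantomConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in doc.pop("phantom", {}).items()
        })
        doc = {k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()}
        return cls(phantom=phantom, **doc)


def _imaged_series(cfg: StudyConfig, schedule, index, peak_C, seed):
    """Image one sonication: frames start at its heating onset."""
    son = schedule[index]
    local = SonicationSchedule([
        Sonication(start_s=0.0, heat_duration_s=son.heat_duration_s,
                   cooling_s=son.cooling_s, energy_j=son.energy_j)
    ])
    hotspot = HotspotSpec(peak_deltaT=peak_C)
    return gen_phantom_series(
        cfg.phantom, schedule=local, hotspot=hotspot, n_frames=cfg.n_frames, seed=seed
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_study(config: StudyConfig | None = None, seed: int = 0, out_dir="study_out",
              emit_figures: bool = True) -> dict:
    """Execute the full pipeline and write a report bundle.

    Stages: simulate → SNR → reconstruct → compare → report. Emits CSV
    tables, NIfTI-free summary JSON and (optionally) PNG figures. Two runs
    with the same seed produce byte-identical ``summary.json``.
    """
    if config is None:
        config = StudyConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {"seed": int(seed), "alpha": ALPHA}
    timings = {}
    current = {"stage": None, "t0": 0.0}

    def stage(name):
        logger.info("stage %s", name)
        current["stage"], current["t0"] = name, time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - current["t0"], 3)
        current["stage"] = None

    try:
        stage("simulate")
        schedule = gen_sonication_schedule(n=config.n_sonications, seed=seed)
        probes = gen_probe_timeseries(schedule, seed=seed + 1)
        for ts in probes:
            ts.to_csv(out_dir / f"{ts.probe_id}.csv")
        done("simulate")

        stage("probe_analysis")
        rises = {ts.probe_id: max_rise_per_sonication(ts, schedule) for ts in probes}
        pd.DataFrame(
            {"sonication": np.arange(len(schedule)), **{k: v for k, v in rises.items()}}
        ).to_csv(out_dir / "max_rises.csv", index=False)
        try:
            probe_test = wilcoxon_signed_rank(rises["probe1"], rises["probe2"])
        except (ValueError, DegenerateInputError) as err:
            probe_test = None
            summary["probe_wilcoxon"] = {"skipped": str(err)}
        summary["probes"] = {
            pid: {
                "max_rise_C": float(r.max()),
                "mean_rise_C": float(r.mean()),
                "n_sonications": int(len(r)),
            }
            for pid, r in rises.items()
        }
        if probe_test is not None:
            summary["probe_wilcoxon"] = {
                "statistic": probe_test.statistic,
                "p_value": probe_test.p_value,
                "n_pairs": probe_test.n_pairs,
                "method": probe_test.method,
                "significant": bool(probe_test.p_value < ALPHA),
            }
        done("probe_analysis")

        stage("imaging")
        series_w, rois_w, truth_w = _imaged_series(
            config, schedule, config.imaged_weak, config.weak_peak_C, seed + 2
        )
        series_s, rois_s, truth_s = _imaged_series(
            config, schedule, config.imaged_strong, config.strong_peak_C, seed + 3
        )
        done("imaging")

        stage("snr")
        report = snr_over_series(series_s, rois_s)
        report.to_csv(out_dir / "snr_report.csv")
        by_region = report.table.groupby("region")["snr"].mean()
        summary["snr_mean_by_region"] = {k: float(v) for k, v in by_region.items()}
        done("snr")

        stage("compare")
        comparison = compare_methods(
            series_s,
            rois_s,
            methods=list(config.methods),
            reference="classical_prf",
            poly_degree=config.poly_degree,
            seed=seed,
        )
        comparison.to_frame().to_csv(out_dir / "comparison.csv", index=False)
        summary["comparison"] = {
            name: {
                "bias_C": m.bias,
                "rmse_C": m.rmse,
                "p_value": None if m.test is None else m.test.p_value,
                "test_method": None if m.test is None else m.test.method,
                "degenerate": m.degenerate,
                "significant": None if m.test is None else bool(m.test.p_value < ALPHA),
            }
            for name, m in comparison.methods.items()
        }
        summary["n_tests"] = comparison.n_tests + (probe_test is not None)
        # peak recovered temperature on the strong sonication, per method
        frames = comparison.frames
        peaks = {}
        for name in ("classical_prf",) + tuple(config.methods):
            vals = inner_roi_means(series_s, rois_s, name, frames,
                                   poly_degree=config.poly_degree, seed=seed)
            peaks[name] = float(np.max(vals))
        summary["peak_inner_mean_C"] = peaks
        summary["truth_peak_inner_mean_C"] = float(
            max(
                truth_s.frame_truth(int(f))[rois_s.mask("inner_roi")].mean()
                for f in frames
            )
        )
        done("compare")

        if emit_figures:
            stage("figures")
            _emit_figures(out_dir, schedule, probes, rises, report, comparison,
                          series_w, series_s)
            done("figures")

        summary["timings_s"] = timings
        summary_path = out_dir / "summary.json"
        # timings vary run to run; the deterministic payload excludes them
        deterministic = {k: v for k, v in summary.items() if k != "timings_s"}
        summary_path.write_text(
            json.dumps(deterministic, indent=2, sort_keys=True, default=_json_default)
        )
        (out_dir / "timings.json").write_text(
            json.dumps(timings, indent=2, sort_keys=True)
        )
    except Exception as err:
        raise RuntimeError(
            f"study failed in stage {current['stage'] or '?'}: {err}"
        ) from err
    return summary


def _emit_figures(out_dir, schedule, probes, rises, snr_report, comparison,
                  series_weak, series_strong):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = Path(out_dir) / "figures"
    fig_dir.mkdir(exist_ok=True)

    # SNR per region over frames
    fig, ax = plt.subplots(figsize=(6, 4))
    for region, grp in snr_report.table.groupby("region"):
        by_frame = grp.groupby("frame")["snr"].mean()
        ax.plot(by_frame.index, by_frame.values, marker="o", label=region)
    ax.set_xlabel("frame")
    ax.set_ylabel("SNR")
    ax.legend()
    ax.set_title("SNR per region across frames")
    fig.savefig(fig_dir / "snr_by_region.png", dpi=110)
    plt.close(fig)

    # max rise per sonication
    fig, ax = plt.subplots(figsize=(8, 4))
    idx = np.arange(len(schedule))
    ax.bar(idx - 0.2, rises["probe1"], width=0.4, label="probe 1")
    ax.bar(idx + 0.2, rises["probe2"], width=0.4, label="probe 2")
    ax.set_xlabel("sonication")
    ax.set_ylabel("max temperature rise (°C)")
    ax.legend()
    ax.set_title("Maximum rise per sonication")
    fig.savefig(fig_dir / "max_rise_per_sonication.png", dpi=110)
    plt.close(fig)

    # probe traces
    fig, ax = plt.subplots(figsize=(8, 4))
    for ts in probes:
        ax.plot(ts.times_s, ts.temps_C, label=ts.probe_id, linewidth=0.7)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("temperature (°C)")
    ax.legend()
    ax.set_title("Probe temperature traces")
    fig.savefig(fig_dir / "probe_traces.png", dpi=110)
    plt.close(fig)

    # interpolation error curves vs PRF reference
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, m in comparison.methods.items():
        ax.plot(comparison.frames, m.errors, marker="o", label=name)
    ax.axhline(0.0, color="k", linewidth=0.5)
    ax.set_xlabel("frame")
    ax.set_ylabel("ΔT error vs PRF reference (°C)")
    ax.legend(fontsize=7)
    ax.set_title("Interpolated temperature errors")
    fig.savefig(fig_dir / "interpolation_errors.png", dpi=110)
    plt.close(fig)
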