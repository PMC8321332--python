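"""Synthetic phantom, sonication and probe-signal generators with ground truth.

The generators emulate a focused-ultrasound quality-assurance bench: a
cylindrical tissue-mimicking phantom (105 mm diameter) resting on an ex vivo
skin layer over a coupling gel pad, imaged as 3 s gradient-echo temporal
frames over a 16 mm slab while a schedule of ~20 s sonications (85 s cooling,
~2353 J) heats a Gaussian focal spot. Complex Gaussian acquisition noise
gives Rician magnitude and noisy phase. Every generator is seed-deterministic
and returns the ground truth needed to score downstream reconstructions
without re-generation.

Heating has no acoustic or bioheat physics here: the focal spot is an
isotropic spatial Gaussian whose amplitude follows exponential saturation
during a sonication and exponential decay afterwards — the minimal temporal
structure consistent with probe-style heating/cooling curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .core import DEFAULT_LABELS, ImageSeries, PRFParams, ROILabelMap, wrap_phase
from .errors import GeometryError
from .thermometry import phase_from_delta_T


@dataclass
class PhantomConfig:
    """Geometry, signal and noise of the synthetic acquisition.

    Region amplitudes are in arbitrary signal units; with complex-noise σ_g,
    the Eq.-style SNR of a region is amplitude/σ_g, so the defaults give
    phantom SNR ≈ 20 and skin/gel SNR ≈ 2–4 (water-rich phantom, fat-like
    low-signal interface layers). Background-phase coefficients are in mm
    coordinates relative to the image centre: 3 terms (c0, c_row, c_col) for
    an affine field or 6 (+ c_rr, c_rc, c_cc) for a quadratic one.
    """

    phantom_diameter_mm: float = 105.0
    skin_thickness_mm: float = 3.0
    gel_thickness_mm: float = 10.0
    slab_thickness_mm: float = 16.0
    grid_shape: tuple = (96, 96)
    pixel_spacing_mm: tuple = (1.5, 1.5)
    n_slices: int = 1
    amplitude_phantom: float = 20.0
    amplitude_skin: float = 3.0
    amplitude_gel: float = 2.5
    noise_sigma: float = 1.0
    frame_interval_s: float = 3.0
    echo_time_s: float = 0.01
    field_strength_t: float = 1.5
    background_phase_coeffs: tuple = (0.3, 0.01, -0.008)
    phase_drift_rad_per_s: float = 0.0

    def __post_init__(self):
        for name in (
            "phantom_diameter_mm",
            "skin_thickness_mm",
            "gel_thickness_mm",
            "slab_thickness_mm",
            "frame_interval_s",
            "echo_time_s",
            "field_strength_t",
            "noise_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("amplitude_phantom", "amplitude_skin", "amplitude_gel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if len(self.background_phase_coeffs) not in (3, 6):
            raise ValueError("background_phase_coeffs needs 3 (affine) or 6 (quadratic) terms")

    @property
    def prf_params(self) -> PRFParams:
        return PRFParams(echo_time=self.echo_time_s, field_strength=self.field_strength_t)

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        doc = yaml.safe_load(open(path)) or {}
        doc = {k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()}
        return cls(**doc)

    def to_yaml(self, path):
        doc = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass(frozen=True)
class Sonication:
    start_s: float
    heat_duration_s: float
    cooling_s: float
    energy_j: float
    focus_mm: tuple = (0.0, 0.0)

    @property
    def end_heat_s(self) -> float:
        return self.start_s + self.heat_duration_s

    @property
    def end_s(self) -> float:
        return self.end_heat_s + self.cooling_s


@dataclass
class SonicationSchedule:
    """Non-overlapping sonication windows (start, heat, cooling, energy)."""

    sonications: list

    def __post_init__(self):
        prev_end = -np.inf
        for k, s in enumerate(self.sonications):
            if s.heat_duration_s <= 0 or s.cooling_s <= 0:
                raise ValueError(f"sonication {k}: durations must be positive")
            if s.start_s < prev_end - 1e-9:
                raise ValueError(f"sonication {k} overlaps the previous one in time")
            prev_end = s.end_s

    def __len__(self):
        return len(self.sonications)

    def __iter__(self):
        return iter(self.sonications)

    def __getitem__(self, k):
        return self.sonications[k]

    @property
    def total_duration_s(self) -> float:
        return self.sonications[-1].end_s if self.sonications else 0.0


def _truncated_positive_normal(rng, mean, sd, size):
    """Normal draws resampled until strictly positive (sd = 0 → constant)."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    while np.any(out <= 0):
        bad = out <= 0
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return out


def gen_sonication_schedule(
    n: int = 56,
    mean_duration: float = 20.0,
    sd_duration: float = 2.9,
    cooling: float = 85.0,
    mean_energy: float = 2353.0,
    sd_energy: float = 611.0,
    seed: int = 0,
    focus_radius_mm: float = 30.0,
) -> SonicationSchedule:
    """Draw a treatment schedule of ``n`` back-to-back sonications.

    Durations and energies come from truncated-positive normal distributions
    with the stated moments; each sonication is followed by the fixed cooling
    interval. Focus positions are drawn uniformly inside a disc of
    ``focus_radius_mm`` around the phantom axis (the treated region).
    """
    if n < 1:
        raise ValueError("need at least one sonication")
    if mean_duration <= 0 or mean_energy <= 0 or cooling <= 0:
        raise ValueError("means and cooling must be positive")
    if sd_duration < 0 or sd_energy < 0:
        raise ValueError("standard deviations must be nonnegative")
    rng = np.random.default_rng(seed)
    durations = _truncated_positive_normal(rng, mean_duration, sd_duration, n)
    energies = _truncated_positive_normal(rng, mean_energy, sd_energy, n)
    radii = focus_radius_mm * np.sqrt(rng.uniform(size=n))
    angles = rng.uniform(0, 2 * np.pi, n)
    sonications = []
    t = 0.0
    for k in range(n):
        sonications.append(
            Sonication(
                start_s=t,
                heat_duration_s=float(durations[k]),
                cooling_s=float(cooling),
                energy_j=float(energies[k]),
                focus_mm=(float(radii[k] * np.sin(angles[k])), float(radii[k] * np.cos(angles[k]))),
            )
        )
        t = sonications[-1].end_s
    return SonicationSchedule(sonications=sonications)


def gen_hotspot_field(
    grid_shape: tuple,
    pixel_spacing_mm: tuple,
    center_mm: tuple,
    sigma_mm: float,
    peak_deltaT: float,
) -> np.ndarray:
    """Isotropic Gaussian ΔT field with its exact peak at ``center_mm``.

    Coordinates are (row, col) in mm from the image origin (pixel 0,0).
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    extent = [(s - 1) * p for s, p in zip(grid_shape, pixel_spacing_mm)]
    if any(not 0 <= c <= e for c, e in zip(center_mm, extent)):
        raise GeometryError(f"hot-spot center {center_mm} outside grid extent {extent}")
    coords = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    dist2 = sum(
        ((g * p - c) ** 2) for g, p, c in zip(coords, pixel_spacing_mm, center_mm)
    )
    return peak_deltaT * np.exp(-dist2 / (2.0 * sigma_mm**2))


def thermal_envelope(
    times: np.ndarray,
    schedule: SonicationSchedule,
    tau_rise_s: float = 8.0,
    tau_decay_s: float = 20.0,
    normalize: bool = True,
) -> np.ndarray:
    """Heating/cooling amplitude over time, superposed across sonications.

    During a sonication the amplitude saturates as 1 − e^(−t/τ_rise); after
    it, the value reached at switch-off decays as e^(−t/τ_decay). With
    ``normalize`` the per-sonication contribution is rescaled to peak exactly
    at 1 at the end of heating; otherwise the saturation asymptote is 1.
    """
    if tau_rise_s <= 0 or tau_decay_s <= 0:
        raise ValueError("time constants must be positive")
    times = np.asarray(times, dtype=float)
    env = np.zeros_like(times)
    for son in schedule:
        rel = times - son.start_s
        heat = (rel >= 0) & (times < son.end_heat_s)
        cool = times >= son.end_heat_s
        sat_end = 1.0 - np.exp(-son.heat_duration_s / tau_rise_s)
        scale = 1.0 / sat_end if normalize else 1.0
        contrib = np.zeros_like(times)
        contrib[heat] = scale * (1.0 - np.exp(-rel[heat] / tau_rise_s))
        contrib[cool] = scale * sat_end * np.exp(-(times[cool] - son.end_heat_s) / tau_decay_s)
        env += contrib
    return env


@dataclass
class HotspotSpec:
    """Focal heating: Gaussian in space, saturation/decay in time."""

    center_mm: tuple | None = None  # default: phantom axis
    sigma_mm: float = 4.0
    peak_deltaT: float = 16.0
    tau_rise_s: float = 8.0
    tau_decay_s: float = 20.0


@dataclass
class TruthRecord:
    """Everything needed to score reconstructions against the generator."""

    background_phase: np.ndarray
    delta_T: np.ndarray  # (n_frames, rows, cols)
    noise_sigma: float
    drift_rad_per_s: float
    frame_times_s: np.ndarray
    params: PRFParams
    config: PhantomConfig

    def frame_truth(self, t: int) -> np.ndarray:
        return self.delta_T[t]


def _build_geometry(config: PhantomConfig):
    """Label image of the stacked bench: phantom disc over skin over gel."""
    ny, nx = config.grid_shape
    sy, sx = config.pixel_spacing_mm
    yy, xx = np.mgrid[0:ny, 0:nx]
    y_mm, x_mm = yy * sy, xx * sx
    radius = config.phantom_diameter_mm / 2.0
    stack_mm = config.phantom_diameter_mm + config.skin_thickness_mm + config.gel_thickness_mm
    top_mm = max(((ny - 1) * sy - stack_mm) / 2.0, 0.0)
    cy_mm = top_mm + radius
    cx_mm = (nx - 1) * sx / 2.0

    labels = np.zeros((ny, nx), dtype=np.int16)
    disc = (y_mm - cy_mm) ** 2 + (x_mm - cx_mm) ** 2 <= radius**2
    labels[disc] = DEFAULT_LABELS["phantom"]
    under = np.abs(x_mm - cx_mm) <= radius
    skin_top = top_mm + config.phantom_diameter_mm
    skin = under & (y_mm > skin_top) & (y_mm <= skin_top + config.skin_thickness_mm) & ~disc
    labels[skin] = DEFAULT_LABELS["skin_interface"]
    gel_top = skin_top + config.skin_thickness_mm
    gel = under & (y_mm > gel_top) & (y_mm <= gel_top + config.gel_thickness_mm) & ~disc
    labels[gel] = DEFAULT_LABELS["gel_pad"]
    return labels, (cy_mm, cx_mm)


#: the "heated disc" extends to where the Gaussian spot falls to 1% of peak
_HEATED_DISC_SIGMAS = float(np.sqrt(2.0 * np.log(100.0)))  # ≈ 3.03σ


def _thermometry_rois(labels, center_mm, sigma_mm, pixel_spacing_mm,
                      dilate_px: int = 2, annulus_px: int = 8):
    """Inner (heated disc + 2 px) and outer (8 px annulus) referenceless ROIs.

    The outer baseline ring must stay effectively unheated, so the heated
    disc is taken out to the 1%-of-peak contour of the Gaussian spot before
    dilation; residual heating under the ring is then < 0.02 °C for a 16 °C
    spot and cannot bias the background fit.
    """
    ny, nx = labels.shape
    sy, sx = pixel_spacing_mm
    yy, xx = np.mgrid[0:ny, 0:nx]
    dist2 = (yy * sy - center_mm[0]) ** 2 + (xx * sx - center_mm[1]) ** 2
    heated = dist2 <= (_HEATED_DISC_SIGMAS * sigma_mm) ** 2
    inner = ndimage.binary_dilation(heated, iterations=dilate_px)
    outer = ndimage.binary_dilation(inner, iterations=annulus_px) & ~inner
    outer &= labels == DEFAULT_LABELS["phantom"]
    return inner, outer


def _background_phase(config: PhantomConfig):
    ny, nx = config.grid_shape
    sy, sx = config.pixel_spacing_mm
    yy, xx = np.mgrid[0:ny, 0:nx]
    y = yy * sy - (ny - 1) * sy / 2.0
    x = xx * sx - (nx - 1) * sx / 2.0
    c = config.background_phase_coeffs
    bg = c[0] + c[1] * y + c[2] * x
    if len(c) == 6:
        bg = bg + c[3] * y * y + c[4] * y * x + c[5] * x * x
    return bg


def gen_phantom_series(
    config: PhantomConfig,
    schedule: SonicationSchedule | None = None,
    hotspot: HotspotSpec | None = None,
    n_frames: int = 8,
    seed: int = 0,
    time_offset_s: float = 0.0,
):
    """Simulate an acquisition: returns (ImageSeries, ROILabelMap, TruthRecord).

    Per frame, the noiseless complex image is
    ``amplitude(region) · exp(i·(background + drift·t + PRF phase of ΔT(t)))``;
    independent zero-mean Gaussian noise of the configured σ is added to the
    real and imaginary parts, and magnitude/wrapped phase are extracted. When
    a schedule is given the hot-spot amplitude follows the thermal envelope
    at each frame time (``time_offset_s`` shifts the frame clock relative to
    the schedule); without one, the hot spot is held at its peak.
    """
    params = config.prf_params
    labels, (cy_mm, cx_mm) = _build_geometry(config)
    bg_phase = _background_phase(config)
    times = time_offset_s + np.arange(n_frames) * config.frame_interval_s

    amp = np.zeros(config.grid_shape, dtype=float)
    amp[labels == DEFAULT_LABELS["phantom"]] = config.amplitude_phantom
    amp[labels == DEFAULT_LABELS["skin_interface"]] = config.amplitude_skin
    amp[labels == DEFAULT_LABELS["gel_pad"]] = config.amplitude_gel

    if hotspot is not None:
        if hotspot.center_mm is not None:
            center = hotspot.center_mm
        else:
            # snap the default (phantom-axis) centre onto a pixel centre so
            # the sampled field attains the exact configured peak
            center = (
                round(cy_mm / config.pixel_spacing_mm[0]) * config.pixel_spacing_mm[0],
                round(cx_mm / config.pixel_spacing_mm[1]) * config.pixel_spacing_mm[1],
            )
        cy_px = int(round(center[0] / config.pixel_spacing_mm[0]))
        cx_px = int(round(center[1] / config.pixel_spacing_mm[1]))
        in_grid = 0 <= cy_px < labels.shape[0] and 0 <= cx_px < labels.shape[1]
        if not in_grid or labels[cy_px, cx_px] != DEFAULT_LABELS["phantom"]:
            raise GeometryError(f"hot spot centered at {center} mm lies outside the phantom")
        spatial = gen_hotspot_field(
            config.grid_shape, config.pixel_spacing_mm, center, hotspot.sigma_mm, 1.0
        )
        if schedule is not None:
            envelope = thermal_envelope(
                times, schedule, hotspot.tau_rise_s, hotspot.tau_decay_s
            )
        else:
            envelope = np.ones(n_frames)
        delta_T = hotspot.peak_deltaT * envelope[:, None, None] * spatial[None]
        inner, outer = _thermometry_rois(
            labels, center, hotspot.sigma_mm, config.pixel_spacing_mm
        )
    else:
        delta_T = np.zeros((n_frames, *config.grid_shape))
        inner, outer = _thermometry_rois(
            labels, (cy_mm, cx_mm), HotspotSpec().sigma_mm, config.pixel_spacing_mm
        )

    rng = np.random.default_rng(seed)
    n_sl = max(int(config.n_slices), 1)
    frames_mag, frames_phase = [], []
    for t_idx in range(n_frames):
        phase_true = bg_phase + config.phase_drift_rad_per_s * times[t_idx]
        phase_true = phase_true + phase_from_delta_T(delta_T[t_idx], params)
        clean = amp * np.exp(1j * phase_true)
        slices_m, slices_p = [], []
        for _ in range(n_sl):
            noisy = clean + config.noise_sigma * (
                rng.standard_normal(clean.shape) + 1j * rng.standard_normal(clean.shape)
            )
            slices_m.append(np.abs(noisy))
            slices_p.append(wrap_phase(np.angle(noisy)))
        if n_sl == 1:
            frames_mag.append(slices_m[0])
            frames_phase.append(slices_p[0])
        else:
            frames_mag.append(np.stack(slices_m, axis=-1))
            frames_phase.append(np.stack(slices_p, axis=-1))

    spacing = tuple(config.pixel_spacing_mm)
    slice_locs = None
    if n_sl > 1:
        thickness = config.slab_thickness_mm / n_sl
        spacing = spacing + (thickness,)
        slice_locs = (np.arange(n_sl) - (n_sl - 1) / 2.0) * thickness

    def expand(mask):
        return np.repeat(mask[..., None], n_sl, axis=-1) if n_sl > 1 else mask

    series = ImageSeries(
        magnitude=np.stack(frames_mag),
        phase=np.stack(frames_phase),
        frame_interval=config.frame_interval_s,
        echo_time=config.echo_time_s,
        field_strength=config.field_strength_t,
        pixel_spacing=spacing,
        slice_locations=slice_locs,
    )
    rois = ROILabelMap(
        labels=expand(labels).astype(np.int16),
        registry=dict(DEFAULT_LABELS),
        inner_roi=expand(inner),
        outer_roi=expand(outer),
    )
    truth = TruthRecord(
        background_phase=bg_phase,
        delta_T=delta_T,
        noise_sigma=config.noise_sigma,
        drift_rad_per_s=config.phase_drift_rad_per_s,
        frame_times_s=times,
        params=params,
        config=replace(config),
    )
    return series, rois, truth


@dataclass
class SonicationTimeSeries:
    """One optical probe's temperature trace aligned to a schedule (≥ 1 Hz)."""

    probe_id: str
    times_s: np.ndarray
    temps_C: np.ndarray
    schedule: SonicationSchedule | None = None

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.temps_C = np.asarray(self.temps_C, dtype=float)
        if self.times_s.shape != self.temps_C.shape:
            raise ValueError("times and temperatures must align")
        if len(self.times_s) > 1:
            dt = np.diff(self.times_s)
            if np.any(dt <= 0):
                raise ValueError("sample times must be strictly increasing")
            if np.any(dt > 1.0 + 1e-9):
                raise ValueError("sampling rate must be at least 1 Hz")

    def to_csv(self, path):
        pd.DataFrame({"time_s": self.times_s, "temp_C": self.temps_C}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, probe_id="probe", schedule=None):
        df = pd.read_csv(path)
        return cls(probe_id=probe_id, times_s=df["time_s"].to_numpy(),
                   temps_C=df["temp_C"].to_numpy(), schedule=schedule)


def gen_probe_timeseries(
    schedule: SonicationSchedule,
    probe_positions_mm=((0.0, 0.0), (0.0, 45.0)),
    gains_C=(10.0, 3.0),
    tau_rise_s: float = 8.0,
    tau_decay_s: float = 20.0,
    ambient_C: float = 20.0,
    noise_sigma_C: float = 0.05,
    coupling_jitter: float = 0.3,
    seed: int = 0,
    rate_hz: float = 1.0,
):
    """Simulate the two interferometric probes under the phantom.

    Probe 1 sits on the phantom axis (full coupling), probe 2 off-centre
    (weaker coupling): ``gains_C`` are the per-sonication asymptotic rises at
    the schedule's mean energy, scaled per sonication by its energy and a
    seeded lognormal coupling jitter, so probe 1 runs hotter by construction.
    Temperatures follow exponential saturation during heating and exponential
    decay during cooling, superposed across sonications, plus Gaussian
    measurement noise. Returns a list of two :class:`SonicationTimeSeries`.
    """
    if len(probe_positions_mm) != 2 or len(gains_C) != 2:
        raise ValueError("exactly two probes are modelled")
    if any(g < 0 for g in gains_C):
        raise ValueError("gains must be nonnegative")
    if tau_rise_s <= 0 or tau_decay_s <= 0:
        raise ValueError("time constants must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, schedule.total_duration_s + 1.0 / rate_hz, 1.0 / rate_hz)
    mean_energy = float(np.mean([s.energy_j for s in schedule]))
    out = []
    for p, (gain, _pos) in enumerate(zip(gains_C, probe_positions_mm)):
        temps = np.full_like(times, float(ambient_C))
        for son in schedule:
            jitter = float(np.exp(rng.normal(0.0, coupling_jitter))) if coupling_jitter else 1.0
            amplitude = gain * (son.energy_j / mean_energy) * jitter
            single = SonicationSchedule([son])
            temps = temps + amplitude * thermal_envelope(
                times, single, tau_rise_s, tau_decay_s, normalize=False
            )
        if noise_sigma_C:
            temps = temps + rng.normal(0.0, noise_sigma_C, times.shape)
        out.append(
            SonicationTimeSeries(
                probe_id=f"probe{p + 1}", times_s=times, temps_C=temps, schedule=schedule
            )
        )
    return out
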