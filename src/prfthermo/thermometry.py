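"""Phase-to-temperature conversion: classical and referenceless PRF thermometry.

The proton resonance frequency of water shifts approximately linearly with
temperature (α ≈ −0.01 ppm/°C for aqueous tissue), so in a gradient-echo
acquisition the temperature change between two time points appears as a phase
difference:

    ΔT = Δφ / (2π · γ · α·10⁻⁶ · B₀ · TE)

Classical PRF thermometry takes Δφ against a pre-heating baseline frame.
Referenceless (self-referenced) thermometry avoids the baseline: assuming the
background phase varies smoothly across the image, it fits an interpolant
(RBF network or low-order polynomial) to an unheated annulus around the
treated region (the *outer* ROI) and extrapolates it under the heated region
(the *inner* ROI) as the background-phase estimate; the actual-minus-estimated
phase then converts to ΔT as above.

No phase unwrapping beyond the principal value is performed; pixels whose
phase difference saturates near ±π are counted and reported, not repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ImageSeries, PRFParams, ROILabelMap, phase_difference, wrap_phase
from .errors import MaskError
from .rbf import canonical_kernel, evaluate_rbf, fit_polynomial_wls, fit_rbf

#: |Δφ| above this fraction of π counts as wrap-saturated
_SATURATION_FRACTION = 0.999


@dataclass
class TemperatureMap:
    """Per-pixel temperature change (°C) with validity mask and provenance."""

    delta_T: np.ndarray
    validity: np.ndarray
    method: str
    frame_index: int
    params: PRFParams
    time_s: float = 0.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.delta_T = np.asarray(self.delta_T, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.delta_T.shape != self.validity.shape:
            raise ValueError("delta_T and validity shapes differ")
        if not np.all(np.isfinite(self.delta_T[self.validity])):
            raise ValueError("delta_T must be finite on the validity mask")


def delta_T_from_phase(delta_phi: np.ndarray, params: PRFParams) -> np.ndarray:
    """Convert a (principal-value) phase difference map to ΔT in °C."""
    return np.asarray(delta_phi, dtype=float) / params.rad_per_degC


def phase_from_delta_T(delta_T: np.ndarray, params: PRFParams) -> np.ndarray:
    """Forward model: phase shift produced by a temperature-change field."""
    return np.asarray(delta_T, dtype=float) * params.rad_per_degC


def classical_prf_map(
    series: ImageSeries,
    baseline_frame: int,
    target_frame: int,
    params: PRFParams | None = None,
) -> TemperatureMap:
    """Baseline-subtraction PRF temperature map of one frame.

    The phase of ``baseline_frame`` is subtracted pixel-by-pixel (wrap-safe)
    from ``target_frame`` and scaled to °C. ``extras["saturated_pixels"]``
    counts pixels whose |Δφ| sits at the wrap boundary — temperatures there
    alias and are passed through unrepaired.
    """
    if params is None:
        params = PRFParams.from_series(series)
    _, phase_base = series.frame(baseline_frame)
    _, phase_tgt = series.frame(target_frame)
    dphi = phase_difference(phase_tgt, phase_base)
    saturated = int(np.count_nonzero(np.abs(dphi) >= _SATURATION_FRACTION * np.pi))
    delta_T = delta_T_from_phase(dphi, params)
    return TemperatureMap(
        delta_T=delta_T,
        validity=np.ones_like(delta_T, dtype=bool),
        method="classical_prf",
        frame_index=target_frame,
        params=params,
        time_s=target_frame * series.frame_interval,
        extras={"baseline_frame": baseline_frame, "saturated_pixels": saturated},
    )


def _pixel_coords_mm(mask: np.ndarray, pixel_spacing) -> np.ndarray:
    idx = np.argwhere(mask).astype(float)
    return idx * np.asarray(pixel_spacing, dtype=float)


def estimate_background_phase(
    phase: np.ndarray,
    inner_mask: np.ndarray,
    outer_mask: np.ndarray,
    interpolator="linear",
    pixel_spacing=(1.0, 1.0),
    max_nodes: int = 500,
    seed: int = 0,
    shape_param="auto",
    include_tail: bool | None = True,
    weights: np.ndarray | None = None,
):
    """Fit the outer-ROI phase and extrapolate it across inner ∪ outer.

    Parameters
    ----------
    interpolator
        An RBF kernel name (``linear``, ``thin_plate_spline``, ``gaussian``,
        ``multiquadric``) or an integer polynomial degree for the weighted
        least-squares polynomial alternative.
    include_tail
        RBF kernels only. Defaults to True for *all* kernels here — unlike
        plain interpolation, background estimation extrapolates into a hole,
        and the degree-1 tail is what carries smooth planar phase trends
        (e.g. shim gradients) across it.
    weights
        Optional per-node weights for the polynomial fit (e.g. magnitude
        weighting); ignored for RBF kernels.

    Returns
    -------
    (estimate, stats)
        ``estimate`` is a full-shape float array holding the fitted
        background phase over inner ∪ outer and NaN elsewhere. ``stats``
        holds the outer-mask residual summary (mean, std, max_abs, n_nodes)
        and the fitted model.
    """
    phase = np.asarray(phase, dtype=float)
    inner_mask = np.asarray(inner_mask, dtype=bool)
    outer_mask = np.asarray(outer_mask, dtype=bool)
    if inner_mask.shape != phase.shape or outer_mask.shape != phase.shape:
        raise MaskError("mask shapes must match the phase image")
    if not inner_mask.any():
        raise MaskError("inner mask is empty")
    if not outer_mask.any():
        raise MaskError("outer mask is empty")
    if np.any(inner_mask & outer_mask):
        raise MaskError("inner and outer masks must be disjoint")

    nodes = _pixel_coords_mm(outer_mask, pixel_spacing)
    values = phase[outer_mask]

    if isinstance(interpolator, (int, np.integer)):
        model = fit_polynomial_wls(nodes, values, weights=weights, degree=int(interpolator))
        fitted_outer = model(nodes)
    else:
        model = fit_rbf(
            nodes,
            values,
            kernel=canonical_kernel(interpolator),
            shape_param=shape_param,
            max_nodes=max_nodes,
            seed=seed,
            include_tail=include_tail,
        )
        fitted_outer = evaluate_rbf(model, nodes)

    estimate = np.full(phase.shape, np.nan)
    estimate[outer_mask] = model(_pixel_coords_mm(outer_mask, pixel_spacing))
    estimate[inner_mask] = model(_pixel_coords_mm(inner_mask, pixel_spacing))

    resid = fitted_outer - values
    stats = {
        "outer_residual_mean": float(resid.mean()),
        "outer_residual_std": float(resid.std()),
        "outer_residual_max_abs": float(np.abs(resid).max()),
        "n_outer_nodes": int(len(values)),
        "model": model,
    }
    return estimate, stats


def referenceless_map(
    series: ImageSeries,
    target_frame: int,
    rois: ROILabelMap,
    interpolator="linear",
    params: PRFParams | None = None,
    **fit_options,
) -> TemperatureMap:
    """Referenceless temperature map over the inner ROI of one frame.

    ΔT = (actual phase − extrapolated background phase) / (2π γ α·10⁻⁶ B₀ TE),
    evaluated on the inner ROI only (validity mask = inner ROI).
    """
    if params is None:
        params = PRFParams.from_series(series)
    inner = rois.mask("inner_roi")
    outer = rois.mask("outer_roi")
    _, phase = series.frame(target_frame)
    estimate, stats = estimate_background_phase(
        phase,
        inner,
        outer,
        interpolator=interpolator,
        pixel_spacing=series.pixel_spacing,
        **fit_options,
    )
    dphi = wrap_phase(np.where(inner, phase - estimate, 0.0))
    delta_T = np.where(inner, delta_T_from_phase(dphi, params), 0.0)
    if isinstance(interpolator, (int, np.integer)):
        method = "referenceless_poly"
    else:
        method = f"referenceless_rbf_{canonical_kernel(interpolator)}"
    stats = {k: v for k, v in stats.items() if k != "model"}
    return TemperatureMap(
        delta_T=delta_T,
        validity=inner,
        method=method,
        frame_index=target_frame,
        params=params,
        time_s=target_frame * series.frame_interval,
        extras=stats,
    )


@dataclass
class TemperatureCurves:
    """Single-pixel and neighbourhood-mean ΔT time courses at one location."""

    times: np.ndarray
    pixel: np.ndarray
    neighborhood: np.ndarray
    flagged: np.ndarray  # True where the point fell outside a map's validity

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "deltaT_pixel_C": self.pixel,
                "deltaT_neighborhood_C": self.neighborhood,
                "flagged": self.flagged,
            }
        )


def temperature_curves(
    maps: list[TemperatureMap],
    point: tuple,
    neighborhood_radius: int = 2,
) -> TemperatureCurves:
    """ΔT-vs-time at a pixel and averaged over a disc around it.

    Mirrors the console display of a crosshair point and its small
    neighbourhood. Samples where the point (or the entire disc) falls outside
    a map's validity mask are flagged and set to NaN, never silently zeroed.
    With radius 0 both curves coincide.
    """
    if not maps:
        raise ValueError("no maps given")
    shape = maps[0].delta_T.shape
    point = tuple(int(p) for p in point)
    if len(point) != len(shape) or any(not 0 <= p < s for p, s in zip(point, shape)):
        raise IndexError(f"point {point} outside map shape {shape}")

    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - p) ** 2 for g, p in zip(grids, point))
    disc = dist2 <= neighborhood_radius**2

    times = np.array([m.time_s for m in maps], dtype=float)
    pix = np.full(len(maps), np.nan)
    neigh = np.full(len(maps), np.nan)
    flagged = np.zeros(len(maps), dtype=bool)
    for i, m in enumerate(maps):
        if m.delta_T.shape != shape:
            raise ValueError("maps disagree in shape")
        if m.validity[point]:
            pix[i] = m.delta_T[point]
        else:
            flagged[i] = True
        valid_disc = disc & m.validity
        if valid_disc.any():
            neigh[i] = m.delta_T[valid_disc].mean()
        else:
            flagged[i] = True
    return TemperatureCurves(times=times, pixel=pix, neighborhood=neigh, flagged=flagged)
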