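"""Domain types and phase arithmetic for PRF-shift MR thermometry.

The central container is :class:`ImageSeries`: a time-ordered stack of
magnitude/phase frame pairs with the acquisition metadata (echo time, field
strength, pixel spacing, frame interval) needed to convert phase differences
into temperature changes. Phase is always stored in radians on the half-open
interval (−π, π]; pixel coordinates are 0-based row-major (row, column[, slice]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, MaskError, MetadataError

TWO_PI = 2.0 * np.pi

#: Gyromagnetic ratio of the proton, Hz per tesla.
GAMMA_HZ_PER_T = 42.576e6

#: PRF thermal coefficient of aqueous tissue, ppm per °C. Negative: the water
#: resonance frequency decreases as temperature rises.
ALPHA_PPM_PER_C = -0.01


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Map arbitrary radian values onto the principal interval (−π, π]."""
    phase = np.asarray(phase, dtype=float)
    wrapped = np.mod(phase + np.pi, TWO_PI) - np.pi  # lands in [−π, π)
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def phase_difference(phase_a: np.ndarray, phase_b: np.ndarray) -> np.ndarray:
    """Wrap-safe phase subtraction: principal value of ``phase_a − phase_b``.

    Computed as the angle of the complex ratio
    ``exp(i·phase_a) / exp(i·phase_b)``, so adding any multiple of 2π to either
    input leaves the result unchanged. The result lies in (−π, π].

    Raises
    ------
    GeometryError
        If the two arrays have different shapes.
    """
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise GeometryError(f"phase shape mismatch: {a.shape} vs {b.shape}")
    diff = np.angle(np.exp(1j * a) * np.exp(-1j * b))
    # np.angle returns values in [−π, π]; fold the closed −π endpoint onto +π
    return np.where(diff <= -np.pi, np.pi, diff)


@dataclass(frozen=True)
class PRFParams:
    """Constants of the PRF phase-to-temperature conversion.

    ΔT = Δφ / (2π · γ · α·10⁻⁶ · B₀ · TE), with α in ppm/°C, γ in Hz/T,
    B₀ in tesla and TE in seconds. With the (negative) aqueous-tissue α,
    heating produces a negative phase shift and a positive ΔT.
    """

    echo_time: float
    field_strength: float = 1.5
    alpha: float = ALPHA_PPM_PER_C
    gamma: float = GAMMA_HZ_PER_T

    def __post_init__(self):
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        for name in ("gamma", "field_strength", "echo_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def rad_per_degC(self) -> float:
        """Phase change per °C of heating, radians (negative for water)."""
        return TWO_PI * self.gamma * self.alpha * 1e-6 * self.field_strength * self.echo_time

    @classmethod
    def from_series(cls, series: "ImageSeries", **overrides) -> "PRFParams":
        kwargs = {"echo_time": series.echo_time, "field_strength": series.field_strength}
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class ImageSeries:
    """Time-ordered magnitude + phase frames with acquisition metadata.

    ``magnitude`` and ``phase`` are stacked as ``(n_frames, *frame_shape)``
    where ``frame_shape`` is 2D ``(rows, cols)`` or 3D ``(rows, cols, slices)``.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    frame_interval: float = 3.0
    echo_time: float = 0.01
    field_strength: float = 1.5
    pixel_spacing: tuple = (1.0, 1.0)
    slice_locations: np.ndarray | None = None

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise GeometryError(
                f"magnitude/phase shape mismatch: "
                f"{self.magnitude.shape} vs {self.phase.shape}"
            )
        if self.magnitude.ndim not in (3, 4):
            raise GeometryError(
                "expected (n_frames, rows, cols[, slices]) stacks, "
                f"got ndim={self.magnitude.ndim}"
            )
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude values must be nonnegative")
        if np.any(self.phase <= -np.pi - 1e-12) or np.any(self.phase > np.pi + 1e-12):
            raise ValueError("phase values must lie in (−π, π]")
        for name in ("frame_interval", "echo_time", "field_strength"):
            if getattr(self, name) is None or getattr(self, name) <= 0:
                raise MetadataError(name, f"{name} must be a positive number")
        spacing = tuple(float(s) for s in self.pixel_spacing)
        if len(spacing) != self.magnitude.ndim - 1 or any(s <= 0 for s in spacing):
            raise MetadataError(
                "pixel_spacing",
                f"pixel_spacing {spacing} does not match frame dimensionality "
                f"{self.magnitude.ndim - 1}",
            )
        self.pixel_spacing = spacing
        if self.slice_locations is not None:
            self.slice_locations = np.asarray(self.slice_locations, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.magnitude.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (0-based, uniform spacing)."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """Return the (magnitude, phase) pair of one frame."""
        if not -self.n_frames <= index < self.n_frames:
            raise IndexError(f"frame index {index} out of range [0, {self.n_frames})")
        return self.magnitude[index], self.phase[index]


#: Default integer codes of the tissue compartments.
DEFAULT_LABELS = {"background": 0, "phantom": 1, "skin_interface": 2, "gel_pad": 3}


@dataclass
class ROILabelMap:
    """Labeled pixel regions: tissue compartments plus thermometry ROIs.

    The tissue compartments (phantom, skin interface, gel pad, background)
    partition the frame and live in one integer label image. The referenceless
    thermometry ROIs — ``inner_roi`` (the heated region) and ``outer_roi``
    (the surrounding baseline annulus) — overlay the phantom compartment and
    are therefore stored as separate boolean masks; they must be disjoint.
    """

    labels: np.ndarray
    registry: dict = field(default_factory=lambda: dict(DEFAULT_LABELS))
    inner_roi: np.ndarray | None = None
    outer_roi: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label image must be integer coded")
        for name in ("inner_roi", "outer_roi"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != self.labels.shape:
                    raise GeometryError(f"{name} shape {m.shape} != label shape {self.labels.shape}")
                setattr(self, name, m)
        if self.inner_roi is not None and self.outer_roi is not None:
            if np.any(self.inner_roi & self.outer_roi):
                raise MaskError("inner_roi and outer_roi must be disjoint")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of a named region; errors if absent or empty."""
        if name in ("inner_roi", "outer_roi"):
            m = getattr(self, name)
            if m is None:
                raise MaskError(f"{name} was never defined on this label map")
        elif name in self.registry:
            m = self.labels == self.registry[name]
        else:
            known = sorted(self.registry) + ["inner_roi", "outer_roi"]
            raise MaskError(f"unknown region {name!r}; known regions: {', '.join(known)}")
        if not m.any():
            raise MaskError(f"region {name!r} is empty")
        return m

    def has_region(self, name: str) -> bool:
        try:
            self.mask(name)
        except MaskError:
            return False
        return True
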