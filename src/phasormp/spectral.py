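"""Domain types for emission spectra and lambda stacks.

A spectrum lives on a uniform wavelength grid (:class:`WavelengthAxis`);
a lambda stack (:class:`SpectralImage`) attaches one spectrum to every
pixel. Intensities are always stored as floating point, whatever the
integer depth of the acquisition, so the downstream pipeline is agnostic
to photon-count scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySpectrumError

__all__ = [
    "WavelengthAxis",
    "EmissionSpectrum",
    "SpectralImage",
    "normalize_spectrum",
    "spectral_center_of_mass",
]


@dataclass(frozen=True)
class WavelengthAxis:
    """Uniform wavelength grid: channel ``k`` sits at ``start + k * step`` nm.

    Non-uniform grids are rejected by construction: only ``start``,
    ``step`` and ``count`` are stored. ``span`` is the amplitude
    ``(count - 1) * step`` covered by the grid, which is the default
    period used by the phasor transform.
    """

    start: float
    step: float
    count: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"axis step must be > 0, got {self.step}")
        if self.count < 2:
            raise ValueError(f"axis needs at least 2 channels, got {self.count}")

    @property
    def stop(self) -> float:
        return self.start + (self.count - 1) * self.step

    @property
    def span(self) -> float:
        """Amplitude of the spectral range, ``(count - 1) * step`` nm."""
        return (self.count - 1) * self.step

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.count)

    @property
    def offsets(self) -> np.ndarray:
        """Channel offsets from the axis start; what enters the phasor phase."""
        return self.step * np.arange(self.count)


def _as_intensities(values, count: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.shape[0] != count:
        raise ValueError(
            f"intensities must be a 1-D vector of length {count}, got shape {arr.shape}"
        )
    if np.any(arr < 0):
        raise ValueError("intensities must be nonnegative")
    if not np.all(np.isfinite(arr)):
        raise ValueError("intensities must be finite")
    return arr


@dataclass(frozen=True)
class EmissionSpectrum:
    """Nonnegative intensities I(lambda) on a :class:`WavelengthAxis`."""

    axis: WavelengthAxis
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intensities", _as_intensities(self.intensities, self.axis.count)
        )

    @property
    def total(self) -> float:
        return float(self.intensities.sum())

    @property
    def is_empty(self) -> bool:
        return self.total == 0.0

    def __add__(self, other: "EmissionSpectrum") -> "EmissionSpectrum":
        if other.axis != self.axis:
            raise ValueError("cannot add spectra on different axes")
        return EmissionSpectrum(self.axis, self.intensities + other.intensities)

    def scaled(self, factor: float) -> "EmissionSpectrum":
        if factor < 0:
            raise ValueError("scale factor must be nonnegative")
        return EmissionSpectrum(self.axis, self.intensities * factor)


def normalize_spectrum(s: EmissionSpectrum, mode: str = "max") -> EmissionSpectrum:
    """Rescale a spectrum so its peak is 1 (``max``) or its sum is 1 (``area``)."""
    if s.is_empty:
        raise EmptySpectrumError("cannot normalize a spectrum with zero total intensity")
    if mode == "max":
        return EmissionSpectrum(s.axis, s.intensities / s.intensities.max())
    if mode == "area":
        return EmissionSpectrum(s.axis, s.intensities / s.total)
    raise ValueError(f"unknown normalization mode {mode!r}; expected 'max' or 'area'")


def spectral_center_of_mass(s: EmissionSpectrum) -> float:
    """Intensity-weighted mean wavelength, in nm."""
    if s.is_empty:
        raise EmptySpectrumError("center of mass undefined for an empty spectrum")
    return float(np.dot(s.axis.wavelengths, s.intensities) / s.total)


class SpectralImage:
    """(height, width, channels) lambda stack with a shared wavelength axis.

    ``voxels`` are stored channel-last as float64. ``pixel_size`` (um per
    pixel) is optional metadata carried through to particle measurements.
    """

    def __init__(
        self,
        axis: WavelengthAxis,
        voxels: np.ndarray,
        pixel_size: float | None = None,
    ) -> None:
        voxels = np.asarray(voxels, dtype=float)
        if voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D (h, w, channels), got {voxels.ndim}-D")
        if voxels.shape[2] != axis.count:
            raise ValueError(
                f"channel dimension {voxels.shape[2]} does not match axis count {axis.count}"
            )
        if np.any(voxels < 0):
            raise ValueError("voxels must be nonnegative (clamp on load)")
        if pixel_size is not None and pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
        self.axis = axis
        self.voxels = voxels
        self.pixel_size = pixel_size

    @property
    def height(self) -> int:
        return self.voxels.shape[0]

    @property
    def width(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def total_intensity(self) -> np.ndarray:
        """Per-pixel summed intensity map, shape (height, width)."""
        return self.voxels.sum(axis=2)

    def spectrum_at(self, y: int, x: int) -> EmissionSpectrum:
        return EmissionSpectrum(self.axis, self.voxels[y, x])
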