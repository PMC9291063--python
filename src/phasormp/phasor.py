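"""Spectral phasor transform and its image-wise application.

A spectrum is mapped to the normalized real/imaginary parts of its first
Fourier harmonic:

    X = sum_k I_k cos(2 pi n d_k / L) / sum_k I_k
    Y = sum_k I_k sin(2 pi n d_k / L) / sum_k I_k

where ``d_k`` is the channel offset from the axis start and ``L`` the
amplitude of the spectral range (the axis span by default, overridable).
Using offsets rather than absolute wavelengths makes the transform
independent of the wavelength origin. The formulas are implemented
verbatim in standard math orientation (counterclockwise-increasing
angle); the conventional clockwise-with-redshift presentation is applied
only in the plot renderer by inverting the displayed Y axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptySpectrumError
from .spectral import EmissionSpectrum, SpectralImage

__all__ = [
    "Phasor",
    "PhasorImage",
    "compute_phasor",
    "phasor_image",
    "combine_phasors",
    "unwrapped_angle",
    "phasor_image_to_csv",
    "phasor_image_to_tiff",
    "plot_phasor",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Phasor:
    """A point in phasor space with its total-intensity weight."""

    x: float
    y: float
    weight: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("phasor weight must be nonnegative")

    @property
    def angle(self) -> float:
        """atan2(Y, X), radians in (-pi, pi]."""
        return float(np.arctan2(self.y, self.x))

    @property
    def modulus(self) -> float:
        return float(np.hypot(self.x, self.y))


def unwrapped_angle(p: Phasor) -> float:
    """Phasor angle mapped to [0, 2 pi); increases monotonically with red shift."""
    return float(np.mod(np.arctan2(p.y, p.x), 2.0 * np.pi))


def _phase(axis_offsets: np.ndarray, harmonic: int, span: float) -> np.ndarray:
    return 2.0 * np.pi * harmonic * axis_offsets / span


def compute_phasor(
    s: EmissionSpectrum, harmonic: int = 1, span: float | None = None
) -> Phasor:
    """First-harmonic spectral phasor of a single spectrum.

    ``span`` defaults to the axis span ``(count - 1) * step``; pass an
    explicit value to pin the period independently of the axis endpoints.
    Harmonics above 1 are accepted but considered experimental.
    """
    if harmonic < 1:
        raise ValueError(f"harmonic must be >= 1, got {harmonic}")
    if s.is_empty:
        raise EmptySpectrumError("phasor undefined for a spectrum with zero total intensity")
    if harmonic > 1:
        log.warning("harmonic n=%d is experimental; the reference analysis uses n=1", harmonic)
    L = float(span) if span is not None else s.axis.span
    if L <= 0:
        raise ValueError(f"span must be > 0, got {L}")
    phase = _phase(s.axis.offsets, harmonic, L)
    total = s.total
    x = float(np.dot(s.intensities, np.cos(phase)) / total)
    y = float(np.dot(s.intensities, np.sin(phase)) / total)
    return Phasor(x, y, total)


class PhasorImage:
    """Per-pixel phasor maps with a validity mask.

    X and Y are finite exactly where ``valid_mask`` is true; masked pixels
    hold NaN so they can never silently leak into downstream statistics.
    """

    def __init__(
        self,
        x: np.ndarray,
        y: np.ndarray,
        weight: np.ndarray,
        valid_mask: np.ndarray,
        pixel_size: float | None = None,
    ) -> None:
        x, y, weight = (np.asarray(a, dtype=float) for a in (x, y, weight))
        valid_mask = np.asarray(valid_mask, dtype=bool)
        if not (x.shape == y.shape == weight.shape == valid_mask.shape):
            raise ValueError("x, y, weight, valid_mask must share one shape")
        if x.ndim != 2:
            raise ValueError("phasor maps must be 2-D")
        self.x = x
        self.y = y
        self.weight = weight
        self.valid_mask = valid_mask
        self.pixel_size = pixel_size

    @property
    def height(self) -> int:
        return self.x.shape[0]

    @property
    def width(self) -> int:
        return self.x.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape

    def valid_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, Y, weight) arrays over valid pixels only."""
        m = self.valid_mask
        return self.x[m], self.y[m], self.weight[m]


def otsu_background_threshold(total: np.ndarray) -> float:
    """Otsu threshold on the per-pixel total-intensity image."""
    from skimage.filters import threshold_otsu

    if np.ptp(total) == 0:
        return float(total.ravel()[0])
    return float(threshold_otsu(total))


def phasor_image(
    img: SpectralImage,
    harmonic: int = 1,
    background_threshold: float | str | None = "otsu",
    span: float | None = None,
) -> PhasorImage:
    """Per-pixel phasor transform of a lambda stack.

    Pixels whose total intensity is at or below ``background_threshold``
    are masked invalid. The default threshold is Otsu's value on the
    total-intensity image (the acquisition papers rarely state a
    background criterion); pass a number for an absolute cutoff.
    """
    if harmonic < 1:
        raise ValueError(f"harmonic must be >= 1, got {harmonic}")
    total = img.total_intensity()
    if background_threshold is None:
        thr = 0.0
    elif isinstance(background_threshold, str):
        if background_threshold != "otsu":
            raise ValueError(f"unknown threshold mode {background_threshold!r}")
        thr = otsu_background_threshold(total)
    else:
        thr = float(background_threshold)
        if thr < 0:
            raise ValueError("background threshold must be >= 0")
    valid = total > thr

    L = float(span) if span is not None else img.axis.span
    phase = _phase(img.axis.offsets, harmonic, L)
    # einsum over the channel axis: numerators of the phasor sums per pixel
    num_x = img.voxels @ np.cos(phase)
    num_y = img.voxels @ np.sin(phase)
    x = np.full(total.shape, np.nan)
    y = np.full(total.shape, np.nan)
    np.divide(num_x, total, out=x, where=valid)
    np.divide(num_y, total, out=y, where=valid)
    if not valid.any():
        log.warning(
            "phasor_image: no pixel exceeds background threshold %.4g; all pixels masked", thr
        )
    return PhasorImage(x, y, total, valid, pixel_size=img.pixel_size)


def combine_phasors(parts: list[Phasor]) -> Phasor:
    """Intensity-weighted centroid of phasors.

    By linearity of the transform this equals the phasor of the summed
    spectra exactly, which is what makes contribution estimates simple
    vector algebra.
    """
    if not parts:
        raise ValueError("combine_phasors needs at least one phasor")
    w = np.array([p.weight for p in parts])
    total = float(w.sum())
    if total == 0:
        raise EmptySpectrumError("combined phasor undefined for zero total weight")
    x = float(np.dot(w, [p.x for p in parts]) / total)
    y = float(np.dot(w, [p.y for p in parts]) / total)
    return Phasor(x, y, total)


def phasor_image_to_csv(pim: PhasorImage, path: str | Path) -> Path:
    """Write valid pixels as CSV rows ``x,y,X,Y,weight`` (x, y are pixel indices)."""
    import pandas as pd

    ys, xs = np.nonzero(pim.valid_mask)
    df = pd.DataFrame(
        {
            "x": xs,
            "y": ys,
            "X": pim.x[ys, xs],
            "Y": pim.y[ys, xs],
            "weight": pim.weight[ys, xs],
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def phasor_image_to_tiff(pim: PhasorImage, path: str | Path) -> Path:
    """Write a 3-page float32 TIFF holding the X, Y and weight maps."""
    import tifffile

    path = Path(path)
    stack = np.stack([pim.x, pim.y, pim.weight]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path


def plot_phasor(
    pim: PhasorImage,
    path: str | Path,
    bins: int = 200,
    cursors=None,
) -> Path:
    """Render a 2-D histogram phasor plot with the unit circle.

    The displayed Y axis is inverted so that a red shift of the spectrum
    moves the cloud clockwise, matching the conventional presentation.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y, w = pim.valid_points()
    fig, ax = plt.subplots(figsize=(5, 5))
    if x.size:
        ax.hist2d(x, y, bins=bins, range=[[-1, 1], [-1, 1]], weights=w, cmin=1e-300)
    theta = np.linspace(0, 2 * np.pi, 400)
    ax.plot(np.cos(theta), np.sin(theta), "k-", lw=0.8)
    if cursors:
        for c in cursors:
            circ = plt.Circle(c.center, c.radius, fill=False, color=c.color, lw=1.5)
            ax.add_patch(circ)
            ax.annotate(c.label, c.center, color=c.color, fontsize=8, ha="center")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(1.05, -1.05)  # inverted: clockwise red shift
    ax.set_xlabel("X")
    ax.set_ylabel("Y")
    ax.set_aspect("equal")
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
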