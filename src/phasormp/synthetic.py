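"""Synthetic polymer emission spectra and lambda-stack scenes with ground truth.

The default reference spectra are SYNTHETIC STAND-INS: sums of Gaussians
whose peak positions are invented to be qualitatively consistent with
solvatochromic-dye staining of common polymers — polyolefins show two
peaks between 450 and 520 nm, polystyrene and PET a single broader peak
above 520 nm, with PET the reddest and broadest. No published numeric
emission maxima exist for these defaults; edit the YAML reference file to
substitute measured ones.

Scenes place non-overlapping elliptical particles, each carrying its
class spectrum scaled by a per-particle brightness, optionally under a
uniform background and shot (Poisson) plus Gaussian read noise. Every
scene ships with its ground-truth label map and particle table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .classify import CLASS_COLORS, LabelMap, ParticleTable, PARTICLE_COLUMNS
from .spectral import EmissionSpectrum, SpectralImage, WavelengthAxis, normalize_spectrum

__all__ = [
    "PolymerReference",
    "NoiseModel",
    "SceneSpec",
    "DEFAULT_AXIS",
    "default_references",
    "make_reference_spectrum",
    "generate_scene",
    "render_rgb_preview",
    "load_references_yaml",
    "save_references_yaml",
]

#: Default fixture axis: 420-740 nm.
DEFAULT_AXIS = WavelengthAxis(start=420.0, step=2.5, count=129)


@dataclass(frozen=True)
class PolymerReference:
    """Synthetic emission model of one polymer class: a sum of Gaussian peaks."""

    name: str
    peaks: tuple[tuple[float, float, float], ...]  # (center nm, sigma nm, amplitude)
    dielectric_range: tuple[float, float] = (0.0, 0.0)
    display_color: tuple[float, float, float] = (0.7, 0.7, 0.7)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ConfigurationError(f"reference {self.name!r} has no peaks")
        for center, sigma, amp in self.peaks:
            if sigma <= 0 or amp <= 0:
                raise ConfigurationError(
                    f"reference {self.name!r}: sigma and amplitude must be > 0"
                )


def default_references() -> list[PolymerReference]:
    """Load the editable stand-in reference library shipped with the package.

    Defaults are invented, polarity-ordered PP -> PET; dielectric constants
    are standard handbook ranges. See ``data/polymer_references.yaml``.
    """
    from importlib.resources import files

    path = files("phasormp").joinpath("data/polymer_references.yaml")
    return load_references_yaml(path)


def make_reference_spectrum(ref: PolymerReference, axis: WavelengthAxis) -> EmissionSpectrum:
    """Evaluate a reference as a max-normalized sum of Gaussians on ``axis``."""
    wl = axis.wavelengths
    for center, _, _ in ref.peaks:
        if not (axis.start <= center <= axis.stop):
            raise ConfigurationError(
                f"reference {ref.name!r}: peak at {center} nm outside axis "
                f"[{axis.start}, {axis.stop}] nm"
            )
    curve = np.zeros(axis.count)
    for center, sigma, amp in ref.peaks:
        curve += amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return normalize_spectrum(EmissionSpectrum(axis, curve), mode="max")


@dataclass(frozen=True)
class NoiseModel:
    """Shot noise (variance = mean, photon-counting style) plus optional
    Gaussian read noise."""

    poisson: bool = True
    gaussian_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ConfigurationError("gaussian_sd must be >= 0")


@dataclass(frozen=True)
class ParticleSpec:
    """One requested particle; position/size sampled when unset."""

    polymer: str
    size: float | None = None  # mean radius, pixels
    position: tuple[float, float] | None = None  # (x, y), pixels


@dataclass
class SceneSpec:
    """Recipe for a synthetic lambda stack.

    Either list explicit ``particles`` or give ``n_particles`` plus
    ``class_mix`` (target fractions summing to 1) and let the generator
    sample classes. ``brightness`` is the expected total photon count per
    particle pixel; ``background_level`` the expected count per channel in
    background. A fixed ``seed`` makes the output bit-identical.
    """

    width: int = 256
    height: int = 256
    axis: WavelengthAxis = DEFAULT_AXIS
    particles: list[ParticleSpec] | None = None
    n_particles: int = 20
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"PP": 0.2, "LDPE": 0.2, "HDPE": 0.2, "PS": 0.2, "PET": 0.2}
    )
    size_range: tuple[float, float] = (4.0, 12.0)
    brightness: float = 2000.0
    brightness_jitter: float = 0.3
    background_level: float = 0.0
    noise: NoiseModel = NoiseModel(poisson=False)
    pixel_size: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ConfigurationError("scene dimensions must be positive")
        if self.particles is None:
            total = sum(self.class_mix.values())
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ConfigurationError(
                    f"class_mix fractions must sum to 1, got {total}"
                )
        if self.size_range[0] < 1:
            raise ConfigurationError("particle sizes must be >= 1 pixel")
        if self.background_level < 0 or self.brightness <= 0:
            raise ConfigurationError("brightness must be > 0 and background >= 0")


def _sample_classes(spec: SceneSpec, rng: np.random.Generator) -> list[str]:
    """Deterministic class roster as close to class_mix as integer counts allow."""
    names = sorted(spec.class_mix)
    quotas = {c: spec.class_mix[c] * spec.n_particles for c in names}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = spec.n_particles - sum(counts.values())
    remainders = sorted(names, key=lambda c: (-(quotas[c] - counts[c]), c))
    for c in remainders[:short]:
        counts[c] += 1
    roster = [c for c in names for _ in range(counts[c])]
    rng.shuffle(roster)
    return roster


def _ellipse_mask(
    h: int, w: int, cx: float, cy: float, rx: float, ry: float, theta: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


MAX_PLACEMENT_TRIES = 200


def generate_scene(
    spec: SceneSpec, refs: list[PolymerReference] | None = None
) -> tuple[SpectralImage, LabelMap, ParticleTable]:
    """Build a lambda stack plus its ground-truth label map and particle table.

    Particles are placed by rejection sampling with a one-pixel margin so
    they never touch; after ``MAX_PLACEMENT_TRIES`` failures per particle
    the generator raises, reporting achieved vs requested counts.
    """
    refs = refs if refs is not None else default_references()
    by_name = {r.name: r for r in refs}
    rng = np.random.default_rng(spec.seed)

    if spec.particles is not None:
        roster = [p.polymer for p in spec.particles]
        requested = list(spec.particles)
    else:
        roster = _sample_classes(spec, rng)
        requested = [ParticleSpec(polymer=c) for c in roster]
    missing = sorted(set(roster) - set(by_name))
    if missing:
        raise ConfigurationError(f"classes {missing} not present in the reference list")

    class_names = tuple(dict.fromkeys(by_name))  # reference order
    shapes = {
        name: normalize_spectrum(make_reference_spectrum(by_name[name], spec.axis), "area")
        for name in set(roster)
    }

    h, w = spec.height, spec.width
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    voxels = np.zeros((h, w, spec.axis.count))
    rows = []
    from scipy.ndimage import binary_dilation

    for pid, pspec in enumerate(requested, start=1):
        placed = False
        for _ in range(MAX_PLACEMENT_TRIES):
            mean_r = (
                pspec.size
                if pspec.size is not None
                else rng.uniform(*spec.size_range)
            )
            rx = mean_r * rng.uniform(0.7, 1.3)
            ry = mean_r * rng.uniform(0.7, 1.3)
            theta = rng.uniform(0, math.pi)
            if pspec.position is not None:
                cx, cy = pspec.position
            elif rx >= (w - 1) / 2 or ry >= (h - 1) / 2:
                continue  # cannot fit in the frame; counts as a failed try
            else:
                cx = rng.uniform(rx, w - 1 - rx)
                cy = rng.uniform(ry, h - 1 - ry)
            mask = _ellipse_mask(h, w, cx, cy, rx, ry, theta)
            if not mask.any():
                continue
            grown = binary_dilation(mask, iterations=1)
            if (grown & occupied).any():
                continue
            brightness = spec.brightness * rng.uniform(
                1 - spec.brightness_jitter, 1 + spec.brightness_jitter
            )
            voxels[mask] += brightness * shapes[pspec.polymer].intensities
            ci = class_names.index(pspec.polymer) + 1
            labels[mask] = ci
            occupied |= grown
            area = int(mask.sum())
            eq_d = 2.0 * math.sqrt(area / math.pi)
            px = spec.pixel_size
            rows.append(
                {
                    "particle_id": pid,
                    "class": pspec.polymer,
                    "area_px": area,
                    "area_um2": area * px**2 if px else np.nan,
                    "centroid_x": cx,
                    "centroid_y": cy,
                    "eq_diameter_px": eq_d,
                    "eq_diameter_um": eq_d * px if px else np.nan,
                    "tile": "",
                }
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"particle placement failed: placed {pid - 1} of "
                f"{len(requested)} requested particles within "
                f"{MAX_PLACEMENT_TRIES} tries each"
            )

    voxels += spec.background_level
    if spec.noise.poisson:
        voxels = rng.poisson(voxels).astype(float)
    if spec.noise.gaussian_sd > 0:
        voxels = voxels + rng.normal(0.0, spec.noise.gaussian_sd, size=voxels.shape)
    voxels = np.clip(voxels, 0.0, None)

    img = SpectralImage(spec.axis, voxels, pixel_size=spec.pixel_size)
    gt = LabelMap(labels, class_names, pixel_size=spec.pixel_size)
    table = ParticleTable(
        pd.DataFrame(rows, columns=PARTICLE_COLUMNS), pixel_size=spec.pixel_size
    )
    return img, gt, table


def _wavelength_to_rgb(wl: np.ndarray) -> np.ndarray:
    """Approximate visible-light RGB per wavelength (nm), rows normalized."""
    wl = np.asarray(wl, dtype=float)
    r = np.zeros_like(wl)
    g = np.zeros_like(wl)
    b = np.zeros_like(wl)
    m = (wl >= 380) & (wl < 440)
    r[m] = -(wl[m] - 440) / 60
    b[m] = 1.0
    m = (wl >= 440) & (wl < 490)
    g[m] = (wl[m] - 440) / 50
    b[m] = 1.0
    m = (wl >= 490) & (wl < 510)
    g[m] = 1.0
    b[m] = -(wl[m] - 510) / 20
    m = (wl >= 510) & (wl < 580)
    r[m] = (wl[m] - 510) / 70
    g[m] = 1.0
    m = (wl >= 580) & (wl < 645)
    r[m] = 1.0
    g[m] = -(wl[m] - 645) / 65
    m = wl >= 645
    r[m] = 1.0
    return np.column_stack([r, g, b])


def render_rgb_preview(img: SpectralImage) -> np.ndarray:
    """Approximate true-color rendering of a lambda stack.

    Each channel contributes its wavelength's RGB weighted by intensity;
    the result is scaled to [0, 1] by the brightest pixel. A zero image
    renders black. Deterministic.
    """
    lut = _wavelength_to_rgb(img.axis.wavelengths)  # (channels, 3)
    rgb = img.voxels @ lut
    peak = rgb.max()
    if peak > 0:
        rgb = rgb / peak
    return np.clip(rgb, 0.0, 1.0)


def save_references_yaml(refs: list[PolymerReference], path: str | Path) -> Path:
    data = [
        {
            "name": r.name,
            "peaks": [
                {"center": float(c), "sigma": float(s), "amplitude": float(a)}
                for c, s, a in r.peaks
            ],
            "dielectric_range": [float(r.dielectric_range[0]), float(r.dielectric_range[1])],
            "display_color": [float(v) for v in r.display_color],
            "synthetic_standin": True,  # not measured emission maxima
        }
        for r in refs
    ]
    path = Path(path)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def load_references_yaml(path: str | Path) -> list[PolymerReference]:
    data = yaml.safe_load(Path(path).read_text())
    refs = []
    for entry in data:
        refs.append(
            PolymerReference(
                name=str(entry["name"]),
                peaks=tuple(
                    (float(p["center"]), float(p["sigma"]), float(p["amplitude"]))
                    for p in entry["peaks"]
                ),
                dielectric_range=tuple(entry.get("dielectric_range", (0.0, 0.0))),
                display_color=tuple(entry.get("display_color", (0.7, 0.7, 0.7))),
            )
        )
    return refs
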