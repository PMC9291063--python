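"""Cursor-based phasor segmentation, particle extraction, and composition
quantification.

Circular cursors select phasor clouds; each valid pixel whose phasor
falls inside a cursor is labeled with that cursor's class, producing a
selection map back in image space. Connected components of the map are
the detected particles; their per-class areas or counts yield the
composition fractions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, UnitError
from .phasor import Phasor, PhasorImage, unwrapped_angle

__all__ = [
    "Cursor",
    "LabelMap",
    "ParticleTable",
    "classify_pixels",
    "auto_cursors",
    "extract_particles",
    "composition_fractions",
    "mosaic_aggregate",
    "load_cursors_yaml",
    "save_cursors_yaml",
]

log = logging.getLogger(__name__)

#: Display colors of the conventional class code (polyolefins blue/green,
#: polystyrene yellow, PET red).
CLASS_COLORS = {
    "PP": (0.0, 0.3, 1.0),
    "LDPE": (0.0, 0.8, 0.4),
    "HDPE": (0.0, 0.6, 0.2),
    "PE": (0.0, 0.7, 0.3),
    "LDPE/HDPE": (0.0, 0.7, 0.3),
    "PS": (1.0, 0.9, 0.0),
    "PET": (1.0, 0.1, 0.1),
}

DEFAULT_CURSOR_RADIUS = 0.08
PARTICLE_COLUMNS = [
    "particle_id",
    "class",
    "area_px",
    "area_um2",
    "centroid_x",
    "centroid_y",
    "eq_diameter_px",
    "eq_diameter_um",
    "tile",
]


@dataclass(frozen=True)
class Cursor:
    """Circular selector in phasor space."""

    label: str
    center: tuple[float, float]
    radius: float = DEFAULT_CURSOR_RADIUS
    color: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError(f"cursor {self.label!r}: radius must be > 0")
        cx, cy = self.center
        if not (-1 <= cx <= 1 and -1 <= cy <= 1):
            raise ConfigurationError(
                f"cursor {self.label!r}: center {self.center} outside [-1, 1]^2"
            )

    def contains(self, x, y) -> np.ndarray:
        return (np.asarray(x) - self.center[0]) ** 2 + (
            np.asarray(y) - self.center[1]
        ) ** 2 <= self.radius**2


@dataclass
class LabelMap:
    """Per-pixel class index map; 0 is background/unclassified.

    Index ``i + 1`` corresponds to ``classes[i]``.
    """

    labels: np.ndarray
    classes: tuple[str, ...]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if self.labels.max(initial=0) > len(self.classes):
            raise ValueError("label index exceeds the declared class list")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def class_mask(self, label: str) -> np.ndarray:
        return self.labels == (self.classes.index(label) + 1)


@dataclass
class ParticleTable:
    """Connected-component measurements, one row per detected particle."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PARTICLE_COLUMNS))
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        missing = set(PARTICLE_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"particle table missing columns: {sorted(missing)}")
        ids = self.frame["particle_id"]
        if ids.duplicated().any():
            raise ValueError("particle_id values must be unique")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def is_empty(self) -> bool:
        return len(self.frame) == 0

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, pixel_size: float | None = None) -> "ParticleTable":
        df = pd.read_csv(path)
        for col in PARTICLE_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col != "tile" else ""
        return cls(df[PARTICLE_COLUMNS], pixel_size=pixel_size)


def classify_pixels(pim: PhasorImage, cursors: list[Cursor]) -> LabelMap:
    """Assign each valid pixel to the cursor containing its phasor.

    A pixel inside several overlapping cursors goes to the nearest cursor
    center; exact ties go to the first cursor in list order. Pixels
    outside all cursors, or invalid, stay 0.
    """
    if not cursors:
        raise ConfigurationError("need at least one cursor")
    labels_seen = [c.label for c in cursors]
    if len(set(labels_seen)) != len(labels_seen):
        raise ConfigurationError(f"duplicate cursor labels: {labels_seen}")

    h, w = pim.shape
    dist2 = np.full((len(cursors), h, w), np.inf)
    valid = pim.valid_mask
    for i, c in enumerate(cursors):
        d2 = (pim.x - c.center[0]) ** 2 + (pim.y - c.center[1]) ** 2
        inside = np.zeros((h, w), dtype=bool)
        inside[valid] = d2[valid] <= c.radius**2
        dist2[i][inside] = d2[inside]
    any_inside = np.isfinite(dist2).any(axis=0)
    # argmin returns the first index on ties, which is the stated tie-break
    winner = np.argmin(dist2, axis=0)
    labels = np.where(any_inside, winner + 1, 0).astype(np.int32)
    return LabelMap(labels, tuple(labels_seen), pixel_size=pim.pixel_size)


def auto_cursors(
    pim: PhasorImage,
    k: int,
    radius: float = DEFAULT_CURSOR_RADIUS,
    seed: int = 0,
) -> list[Cursor]:
    """Place ``k`` cursors on weight-weighted k-means centroids of the cloud.

    Deterministic for a fixed seed; cursors are returned sorted by
    unwrapped phasor angle (blue to red) and labeled ``auto_0 .. auto_{k-1}``.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    x, y, wgt = pim.valid_points()
    if x.size < k:
        raise ConfigurationError(
            f"only {x.size} valid pixels available for {k} requested cursors"
        )
    from sklearn.cluster import KMeans

    pts = np.column_stack([x, y])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(pts, sample_weight=wgt)
    centers = km.cluster_centers_
    order = np.argsort(
        [unwrapped_angle(Phasor(cx, cy, 1.0)) for cx, cy in centers]
    )
    cursors = []
    for rank, idx in enumerate(order):
        cx, cy = centers[idx]
        cursors.append(
            Cursor(
                label=f"auto_{rank}",
                center=(float(np.clip(cx, -1, 1)), float(np.clip(cy, -1, 1))),
                radius=radius,
            )
        )
    return cursors


def extract_particles(
    lm: LabelMap,
    min_particle_size: int = 4,
    connectivity: int = 8,
    tile: str = "",
) -> ParticleTable:
    """Connected components per class, filtered by ``min_particle_size``.

    Components are computed independently per class so touching particles
    of different polymers stay separate. Micron-based columns are filled
    when ``pixel_size`` metadata is present, NaN otherwise.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    from skimage.measure import label as cc_label, regionprops

    skimage_conn = 1 if connectivity == 4 else 2
    px = lm.pixel_size
    rows = []
    pid = 0
    for ci, cname in enumerate(lm.classes, start=1):
        mask = lm.labels == ci
        if not mask.any():
            continue
        comp = cc_label(mask, connectivity=skimage_conn)
        for region in regionprops(comp):
            if region.area < min_particle_size:
                continue
            pid += 1
            eq_d_px = 2.0 * math.sqrt(region.area / math.pi)
            cy, cx = region.centroid
            rows.append(
                {
                    "particle_id": pid,
                    "class": cname,
                    "area_px": int(region.area),
                    "area_um2": region.area * px**2 if px else np.nan,
                    "centroid_x": cx,
                    "centroid_y": cy,
                    "eq_diameter_px": eq_d_px,
                    "eq_diameter_um": eq_d_px * px if px else np.nan,
                    "tile": tile,
                }
            )
    frame = pd.DataFrame(rows, columns=PARTICLE_COLUMNS)
    return ParticleTable(frame, pixel_size=px)


def composition_fractions(pt: ParticleTable, basis: str = "pixel_area") -> dict[str, float]:
    """Per-class fraction of the detected material.

    ``basis='pixel_area'`` weighs classes by summed particle area;
    ``basis='particle_count'`` by number of particles. Fractions sum to 1
    over the detected classes. An empty table yields an empty map with a
    logged warning.
    """
    if basis not in ("pixel_area", "particle_count"):
        raise ValueError(f"basis must be 'pixel_area' or 'particle_count', got {basis!r}")
    if pt.is_empty:
        log.warning("composition_fractions: empty particle table; returning no fractions")
        return {}
    if basis == "pixel_area":
        sizes = pt.frame.groupby("class")["area_px"].sum()
    else:
        sizes = pt.frame.groupby("class")["particle_id"].count()
    total = float(sizes.sum())
    return {str(c): float(v) / total for c, v in sizes.items()}


def mosaic_aggregate(tables: list[ParticleTable]) -> ParticleTable:
    """Pool per-tile particle tables into one, re-keying particle ids.

    All tables must agree on pixel_size metadata (or all lack it);
    otherwise areas would mix incompatible units.
    """
    if not tables:
        return ParticleTable()
    sizes = {t.pixel_size for t in tables}
    if len(sizes) > 1:
        raise UnitError(f"tiles disagree on pixel_size: {sorted(sizes, key=str)}")
    frames = []
    offset = 0
    for i, t in enumerate(tables):
        if t.is_empty:
            continue
        df = t.frame.copy()
        df["particle_id"] = np.arange(offset + 1, offset + 1 + len(df))
        df.loc[df["tile"].isin(["", np.nan]) | df["tile"].isna(), "tile"] = f"tile_{i}"
        offset += len(df)
        frames.append(df)
    if not frames:
        return ParticleTable(pixel_size=tables[0].pixel_size)
    out = pd.concat(frames, ignore_index=True)[PARTICLE_COLUMNS]
    return ParticleTable(out, pixel_size=tables[0].pixel_size)


def save_cursors_yaml(cursors: list[Cursor], path: str | Path) -> Path:
    data = [
        {
            "label": c.label,
            "center": [float(c.center[0]), float(c.center[1])],
            "radius": float(c.radius),
            "color": [float(v) for v in c.color],
        }
        for c in cursors
    ]
    path = Path(path)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def load_cursors_yaml(path: str | Path) -> list[Cursor]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise ConfigurationError(f"{path}: cursor YAML must be a list")
    cursors = []
    for entry in data:
        cursors.append(
            Cursor(
                label=str(entry["label"]),
                center=(float(entry["center"][0]), float(entry["center"][1])),
                radius=float(entry.get("radius", DEFAULT_CURSOR_RADIUS)),
                color=tuple(entry.get("color", (0.5, 0.5, 0.5))),
            )
        )
    return cursors


def labelmap_to_rgb(lm: LabelMap, colors: dict[str, tuple] | None = None) -> np.ndarray:
    """Render a LabelMap as an RGB float image using the class color code."""
    colors = {**CLASS_COLORS, **(colors or {})}
    rgb = np.zeros((lm.height, lm.width, 3))
    for i, cname in enumerate(lm.classes, start=1):
        col = colors.get(cname, (0.7, 0.7, 0.7))
        rgb[lm.labels == i] = col
    return rgb


def save_labelmap(lm: LabelMap, path: str | Path, legend_path: str | Path | None = None) -> Path:
    """Write the selection map as a color PNG plus a JSON legend."""
    import imageio.v3 as iio
    import json

    rgb = (labelmap_to_rgb(lm) * 255).astype(np.uint8)
    path = Path(path)
    iio.imwrite(path, rgb)
    if legend_path is not None:
        legend = {
            str(i + 1): {"class": c, "color": list(CLASS_COLORS.get(c, (0.7, 0.7, 0.7)))}
            for i, c in enumerate(lm.classes)
        }
        Path(legend_path).write_text(json.dumps(legend, indent=2, sort_keys=True))
    return path
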