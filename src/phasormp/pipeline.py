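"""End-to-end orchestration: lambda stacks -> phasors -> labels -> particles
-> composition report, plus a synthetic benchmark harness."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .classify import (
    Cursor,
    LabelMap,
    ParticleTable,
    classify_pixels,
    auto_cursors,
    composition_fractions,
    extract_particles,
    mosaic_aggregate,
    save_cursors_yaml,
    save_labelmap,
)
from .errors import ConfigurationError
from .phasor import (
    compute_phasor,
    phasor_image,
    phasor_image_to_csv,
    phasor_image_to_tiff,
    plot_phasor,
)
from .spectral import WavelengthAxis
from .synthetic import (
    PolymerReference,
    SceneSpec,
    default_references,
    generate_scene,
    make_reference_spectrum,
)

__all__ = [
    "PipelineConfig",
    "reference_cursors",
    "run_pipeline",
    "run_synthetic_benchmark",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Fully serializable run configuration; written beside the outputs so
    every result can be reproduced."""

    axis_start: float | None = None
    axis_step: float | None = None
    channels: int | None = None
    harmonic: int = 1
    threshold: float | str = "otsu"  # "otsu" or an absolute intensity
    cursors_yaml: str | None = None
    auto_k: int | None = None
    cursor_radius: float = 0.08
    min_particle_size: int = 4
    connectivity: int = 8
    basis: str = "pixel_area"
    seed: int = 0
    out_dir: str = "phasormp_out"

    def axis(self) -> WavelengthAxis | None:
        if self.axis_start is None or self.axis_step is None or self.channels is None:
            return None
        return WavelengthAxis(self.axis_start, self.axis_step, self.channels)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def reference_cursors(
    refs: list[PolymerReference] | None = None,
    axis: WavelengthAxis | None = None,
    radius: float = 0.08,
    merge_pe: bool = True,
    harmonic: int = 1,
) -> list[Cursor]:
    """Cursors centered on each reference spectrum's phasor.

    With ``merge_pe`` (the default) LDPE and HDPE collapse into one
    "LDPE/HDPE" cursor centered between their phasors, since their clouds
    overlap in image data; strict mode keeps them separate for
    bulk-spectrum work.
    """
    from .phasor import combine_phasors

    refs = refs if refs is not None else default_references()
    if axis is None:
        from .synthetic import DEFAULT_AXIS

        axis = DEFAULT_AXIS
    phasors = {
        r.name: compute_phasor(make_reference_spectrum(r, axis), harmonic=harmonic)
        for r in refs
    }
    cursors: list[Cursor] = []
    names = list(phasors)
    pe_names = [n for n in names if n in ("LDPE", "HDPE")]
    for name in names:
        if merge_pe and name in pe_names:
            continue
        p = phasors[name]
        cursors.append(Cursor(label=name, center=(p.x, p.y), radius=radius))
    if merge_pe and pe_names:
        merged = combine_phasors([dataclasses.replace(phasors[n], weight=1.0) for n in pe_names])
        cursors.append(
            Cursor(label="LDPE/HDPE", center=(merged.x, merged.y), radius=radius * 1.5)
        )
    return cursors


def _resolve_cursors(config: PipelineConfig, pim) -> list[Cursor]:
    from .classify import load_cursors_yaml

    if config.cursors_yaml:
        return load_cursors_yaml(config.cursors_yaml)
    if config.auto_k:
        return auto_cursors(
            pim, config.auto_k, radius=config.cursor_radius, seed=config.seed
        )
    raise ConfigurationError("config must set either cursors_yaml or auto_k")


def run_pipeline(config: PipelineConfig, inputs: list[str | Path]) -> dict:
    """Run phasor -> classify -> quantify over one or more tiles.

    Writes per-tile phasor maps, selection maps and particle tables plus
    an aggregate JSON + Markdown report under ``config.out_dir``; returns
    the report dict. Deterministic given config and seed.
    """
    if not inputs:
        raise ConfigurationError("no input images supplied")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")

    axis = config.axis()
    tables: list[ParticleTable] = []
    tile_reports = []
    cursors: list[Cursor] | None = None
    for i, inp in enumerate(inputs):
        inp = Path(inp)
        tile = inp.stem
        log.info("stage phasor: tile %s", tile)
        img = pio.load_spectral_image(inp, axis_spec=axis)
        pim = phasor_image(
            img, harmonic=config.harmonic, background_threshold=config.threshold
        )
        phasor_image_to_tiff(pim, out / f"{tile}_phasor.tif")
        phasor_image_to_csv(pim, out / f"{tile}_phasor.csv")
        if cursors is None:
            cursors = _resolve_cursors(config, pim)
            save_cursors_yaml(cursors, out / "cursors_used.yaml")
        plot_phasor(pim, out / f"{tile}_phasorplot.png", cursors=cursors)
        log.info("stage classify: tile %s", tile)
        lm = classify_pixels(pim, cursors)
        save_labelmap(lm, out / f"{tile}_selection.png", out / f"{tile}_legend.json")
        log.info("stage quantify: tile %s", tile)
        pt = extract_particles(
            lm,
            min_particle_size=config.min_particle_size,
            connectivity=config.connectivity,
            tile=tile,
        )
        pt.to_csv(out / f"{tile}_particles.csv")
        tables.append(pt)
        tile_reports.append(
            {
                "tile": tile,
                "n_particles": len(pt),
                "valid_pixels": int(pim.valid_mask.sum()),
            }
        )

    aggregate = mosaic_aggregate(tables)
    aggregate.to_csv(out / "particles_aggregate.csv")
    report = {
        "n_tiles": len(inputs),
        "tiles": tile_reports,
        "n_particles": len(aggregate),
        "fractions_by_area": composition_fractions(aggregate, "pixel_area")
        if not aggregate.is_empty
        else {},
        "fractions_by_count": composition_fractions(aggregate, "particle_count")
        if not aggregate.is_empty
        else {},
        "basis_default": config.basis,
        "class_areas_px": {
            str(c): int(v)
            for c, v in aggregate.frame.groupby("class")["area_px"].sum().items()
        }
        if not aggregate.is_empty
        else {},
        "class_counts": {
            str(c): int(v)
            for c, v in aggregate.frame.groupby("class")["particle_id"].count().items()
        }
        if not aggregate.is_empty
        else {},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _write_markdown_report(report, out / "report.md")
    return report


def _write_markdown_report(report: dict, path: Path) -> None:
    lines = [
        "# Composition report",
        "",
        f"Tiles analyzed: {report['n_tiles']}",
        f"Particles detected: {report['n_particles']}",
        "",
        "| class | area fraction | count fraction | area (px) | count |",
        "|---|---|---|---|---|",
    ]
    for cname in sorted(report["fractions_by_area"]):
        lines.append(
            "| {c} | {fa:.4f} | {fc:.4f} | {a} | {n} |".format(
                c=cname,
                fa=report["fractions_by_area"][cname],
                fc=report["fractions_by_count"].get(cname, 0.0),
                a=report["class_areas_px"].get(cname, 0),
                n=report["class_counts"].get(cname, 0),
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _merge_pe_label(name: str) -> str:
    return "LDPE/HDPE" if name in ("LDPE", "HDPE", "LDPE/HDPE") else name


def pixel_accuracy(
    predicted: LabelMap, truth: LabelMap, merge_pe: bool = True
) -> float:
    """Fraction of pixels (background included) with matching class labels."""
    if predicted.labels.shape != truth.labels.shape:
        raise ValueError("label maps differ in shape")

    def names(lm: LabelMap) -> np.ndarray:
        arr = np.array(["" ] + [(_merge_pe_label(c) if merge_pe else c) for c in lm.classes])
        return arr[lm.labels]

    return float(np.mean(names(predicted) == names(truth)))


def ground_truth_fractions(truth: LabelMap, merge_pe: bool = True) -> dict[str, float]:
    """Per-class fraction of particle pixels in a ground-truth label map."""
    counts: dict[str, int] = {}
    for i, cname in enumerate(truth.classes, start=1):
        n = int((truth.labels == i).sum())
        if n == 0:
            continue
        key = _merge_pe_label(cname) if merge_pe else cname
        counts[key] = counts.get(key, 0) + n
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()}


def run_synthetic_benchmark(
    scene_spec: SceneSpec,
    config: PipelineConfig,
    replicates: int = 5,
    seed: int = 0,
    merge_pe: bool = True,
) -> pd.DataFrame:
    """Repeatedly generate a scene, run the pipeline in memory, and score
    recovery against ground truth.

    Returns one row per replicate with pixel accuracy and per-class
    fraction errors, plus a confusion matrix serialized as JSON in the
    ``confusion`` column. Classification uses cursors centered on the
    reference phasors (merged polyethylene by default).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    refs = default_references()
    cursors = reference_cursors(
        refs, axis=scene_spec.axis, radius=config.cursor_radius, merge_pe=merge_pe,
        harmonic=config.harmonic,
    )
    rows = []
    for r in range(replicates):
        spec_r = dataclasses.replace(scene_spec, seed=seed + r)
        img, gt, _ = generate_scene(spec_r, refs)
        pim = phasor_image(
            img, harmonic=config.harmonic, background_threshold=config.threshold
        )
        lm = classify_pixels(pim, cursors)
        acc = pixel_accuracy(lm, gt, merge_pe=merge_pe)
        pt = extract_particles(
            lm, min_particle_size=config.min_particle_size,
            connectivity=config.connectivity,
        )
        frac = composition_fractions(pt, "pixel_area")
        if merge_pe:
            merged: dict[str, float] = {}
            for c, v in frac.items():
                merged[_merge_pe_label(c)] = merged.get(_merge_pe_label(c), 0.0) + v
            frac = merged
        gt_frac = ground_truth_fractions(gt, merge_pe=merge_pe)
        errors = {
            c: abs(frac.get(c, 0.0) - gt_frac.get(c, 0.0))
            for c in set(frac) | set(gt_frac)
        }
        confusion = _confusion(lm, gt, merge_pe)
        rows.append(
            {
                "replicate": r,
                "seed": seed + r,
                "pixel_accuracy": acc,
                "max_fraction_error": max(errors.values()) if errors else 0.0,
                **{f"frac_err_{c}": e for c, e in sorted(errors.items())},
                "confusion": json.dumps(confusion, sort_keys=True),
            }
        )
    return pd.DataFrame(rows)


def _confusion(predicted: LabelMap, truth: LabelMap, merge_pe: bool) -> dict:
    def names(lm: LabelMap) -> np.ndarray:
        arr = np.array(
            ["background"]
            + [(_merge_pe_label(c) if merge_pe else c) for c in lm.classes]
        )
        return arr[lm.labels]

    p, t = names(predicted).ravel(), names(truth).ravel()
    out: dict[str, dict[str, int]] = {}
    for tv in np.unique(t):
        sel = t == tv
        sub: dict[str, int] = {}
        for pv in np.unique(p[sel]):
            sub[str(pv)] = int(np.sum(p[sel] == pv))
        out[str(tv)] = sub
    return out
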