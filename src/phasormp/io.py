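"""File I/O: multi-page TIFF lambda stacks with YAML axis sidecars, bulk
spectrum CSVs, and FTIR peak-list CSVs."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError
from .spectral import EmissionSpectrum, SpectralImage, WavelengthAxis

__all__ = [
    "load_spectral_image",
    "save_spectral_image",
    "sidecar_path",
    "read_axis_sidecar",
    "write_axis_sidecar",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

log = logging.getLogger(__name__)


def sidecar_path(tiff_path: Path) -> Path:
    return Path(tiff_path).with_suffix(".axis.yaml")


def write_axis_sidecar(path: Path, axis: WavelengthAxis) -> None:
    data = {"start_nm": float(axis.start), "step_nm": float(axis.step), "count": int(axis.count)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_axis_sidecar(path: Path) -> WavelengthAxis:
    data = yaml.safe_load(Path(path).read_text())
    try:
        return WavelengthAxis(
            start=float(data["start_nm"]),
            step=float(data["step_nm"]),
            count=int(data["count"]),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"axis sidecar {path} is missing start_nm/step_nm/count") from exc


def _read_pages(path: Path) -> np.ndarray:
    """Read a multi-page TIFF or a directory of per-channel TIFFs.

    Returns a (channels, h, w) array in page / filename order.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"})
        if not files:
            raise FormatError(f"directory {path} contains no TIFF files")
        pages = [tifffile.imread(f) for f in files]
        stack = np.stack(pages, axis=0)
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None, :, :]
    if stack.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D stack, got shape {stack.shape}")
    return np.asarray(stack)


def load_spectral_image(
    path: str | Path,
    axis_spec: WavelengthAxis | None = None,
    pixel_size: float | None = None,
) -> SpectralImage:
    """Load a lambda stack (one TIFF page per wavelength channel).

    The wavelength axis comes from ``axis_spec`` or, if omitted, from the
    ``<stem>.axis.yaml`` sidecar next to the file. A page-count mismatch
    with the axis raises :class:`FormatError` naming both counts; negative
    pixels are clamped to zero with a logged warning count.
    """
    path = Path(path)
    stack = _read_pages(path)
    if axis_spec is None:
        sc = sidecar_path(path) if path.is_file() else path / "axis.yaml"
        if not sc.exists():
            raise FormatError(f"no axis_spec given and sidecar {sc} not found")
        axis_spec = read_axis_sidecar(sc)
    if stack.shape[0] != axis_spec.count:
        raise FormatError(
            f"{path}: stack has {stack.shape[0]} channel pages but the axis "
            f"declares {axis_spec.count} channels"
        )
    voxels = np.moveaxis(stack.astype(float), 0, 2)
    n_neg = int(np.count_nonzero(voxels < 0))
    if n_neg:
        log.warning("%s: clamped %d negative-valued voxels to 0", path, n_neg)
        voxels = np.clip(voxels, 0.0, None)
    img = SpectralImage(axis_spec, voxels, pixel_size=pixel_size)
    log.info(
        "loaded %s: %dx%d pixels, %d channels (%.1f-%.1f nm, step %.2f nm)",
        path, img.width, img.height, axis_spec.count,
        axis_spec.start, axis_spec.stop, axis_spec.step,
    )
    return img


def save_spectral_image(img: SpectralImage, path: str | Path) -> Path:
    """Write a lambda stack as a multi-page float32 TIFF plus axis sidecar."""
    path = Path(path)
    stack = np.moveaxis(img.voxels, 2, 0).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    write_axis_sidecar(sidecar_path(path), img.axis)
    return path


def read_spectrum_csv(path: str | Path) -> EmissionSpectrum:
    """Read a bulk spectrum from a 2-column CSV (``wavelength_nm,intensity``).

    The wavelength column must form a uniform, strictly increasing grid.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower() for c in df.columns}
    if not {"wavelength_nm", "intensity"} <= cols:
        raise FormatError(f"{path}: expected columns 'wavelength_nm,intensity', got {list(df.columns)}")
    df.columns = [c.strip().lower() for c in df.columns]
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    inten = df["intensity"].to_numpy(dtype=float)
    if len(wl) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    steps = np.diff(wl)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path}: wavelength grid must be uniform and increasing")
    axis = WavelengthAxis(start=float(wl[0]), step=float(steps[0]), count=len(wl))
    return EmissionSpectrum(axis, np.clip(inten, 0.0, None))


def write_spectrum_csv(s: EmissionSpectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"wavelength_nm": s.axis.wavelengths, "intensity": s.intensities}
    ).to_csv(path, index=False)
    return path
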