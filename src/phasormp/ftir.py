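"""Polymer identification from ATR-FTIR peak lists.

The built-in reference table holds the characteristic infrared absorption
peaks (cm^-1) of the five common packaging polymers; LDPE and HDPE share
an identical peak list and therefore always tie. Matching is greedy
nearest one-to-one so a single broad observed band cannot satisfy several
reference peaks at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FtirReference",
    "MatchResult",
    "DEFAULT_FTIR_TABLE",
    "default_ftir_references",
    "match_peaks",
    "is_inconclusive",
    "detect_peaks",
    "load_ftir_references_csv",
    "save_ftir_references_csv",
]

#: Characteristic IR absorption peaks (cm^-1) per polymer class.
DEFAULT_FTIR_TABLE: dict[str, tuple[float, ...]] = {
    "PP": (2915.0, 1455.0, 1377.0, 997.0, 982.0),
    "LDPE": (2915.0, 2845.0, 1462.0, 717.0),
    "HDPE": (2915.0, 2845.0, 1462.0, 717.0),
    "PS": (3024.0, 2847.0, 1492.0, 1451.0, 694.0),
    "PET": (1713.0, 1241.0, 1094.0, 720.0),
}

DEFAULT_TOLERANCE = 5.0  # cm^-1; absorbs peak-picking jitter at ~2 cm^-1 resolution


@dataclass(frozen=True)
class FtirReference:
    name: str
    peaks: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"reference {self.name!r} has no peaks")


def default_ftir_references() -> list[FtirReference]:
    return [FtirReference(name, peaks) for name, peaks in DEFAULT_FTIR_TABLE.items()]


@dataclass(frozen=True)
class MatchResult:
    """Score of one reference against the observed peak list.

    ``rank`` is 1-based; references with identical (score, matched) share
    a rank, so an exact tie appears as several rank-1 rows.
    """

    name: str
    matched: int
    total: int
    score: float
    rank: int
    matched_peaks: tuple[float, ...]
    unmatched_observed: tuple[float, ...]


def _greedy_match(
    observed: np.ndarray, ref_peaks: tuple[float, ...], tolerance: float
) -> tuple[list[float], set[int]]:
    """Greedy nearest-first one-to-one assignment of observed to reference peaks."""
    pairs = []
    for ri, rp in enumerate(ref_peaks):
        for oi, op in enumerate(observed):
            d = abs(op - rp)
            if d <= tolerance:
                pairs.append((d, ri, oi))
    pairs.sort()
    used_ref: set[int] = set()
    used_obs: set[int] = set()
    matched = []
    for _, ri, oi in pairs:
        if ri in used_ref or oi in used_obs:
            continue
        used_ref.add(ri)
        used_obs.add(oi)
        matched.append(ref_peaks[ri])
    return matched, used_obs


def match_peaks(
    observed: list[float],
    refs: list[FtirReference] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[MatchResult]:
    """Rank polymer references by the fraction of their peaks seen in ``observed``.

    score = matched / total reference peaks; ranking is descending by
    score, then matched count. Exact ties share a rank. All-zero scores
    mean the ranking is inconclusive (see :func:`is_inconclusive`).
    """
    if not observed:
        raise ValueError("no peaks supplied")
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance}")
    refs = refs if refs is not None else default_ftir_references()
    obs = np.asarray(observed, dtype=float)

    scored = []
    for ref in refs:
        matched, used_obs = _greedy_match(obs, ref.peaks, tolerance)
        unmatched = tuple(
            float(obs[i]) for i in range(len(obs)) if i not in used_obs
        )
        scored.append(
            (
                len(matched) / len(ref.peaks),
                len(matched),
                ref.name,
                tuple(sorted(matched, reverse=True)),
                unmatched,
            )
        )
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))

    results = []
    rank = 0
    prev_key = None
    for i, (score, matched, name, mpeaks, unmatched) in enumerate(scored):
        key = (score, matched)
        if key != prev_key:
            rank = i + 1
            prev_key = key
        results.append(
            MatchResult(
                name=name,
                matched=matched,
                total=len(next(r for r in refs if r.name == name).peaks),
                score=score,
                rank=rank,
                matched_peaks=mpeaks,
                unmatched_observed=unmatched,
            )
        )
    return results


def is_inconclusive(results: list[MatchResult]) -> bool:
    """True when no reference matched any observed peak."""
    return all(r.score == 0.0 for r in results)


def detect_peaks(
    wavenumbers: np.ndarray,
    intensities: np.ndarray,
    prominence: float = 0.05,
) -> list[float]:
    """Pick local maxima from a raw absorbance curve.

    ``prominence`` is relative to the intensity range. Peaks come back in
    descending intensity order. Works with either ascending or descending
    wavenumber axes.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if wn.size != inten.size:
        raise ValueError("wavenumbers and intensities must have the same length")
    if wn.size < 3:
        raise ValueError(f"need at least 3 points to detect peaks, got {wn.size}")
    if not (0 < prominence <= 1):
        raise ValueError(f"prominence must be in (0, 1], got {prominence}")
    if wn[0] > wn[-1]:  # FTIR convention often lists descending wavenumbers
        wn, inten = wn[::-1], inten[::-1]

    from scipy.signal import find_peaks

    rng = float(np.ptp(inten))
    if rng == 0:
        return []
    idx, _ = find_peaks(inten, prominence=prominence * rng)
    order = np.argsort(inten[idx])[::-1]
    return [float(wn[i]) for i in idx[order]]


def load_ftir_references_csv(path: str | Path) -> list[FtirReference]:
    """Read references from CSV rows ``class,peaks`` with ;-separated peaks."""
    df = pd.read_csv(path)
    refs = []
    for _, row in df.iterrows():
        peaks = tuple(float(p) for p in str(row["peaks"]).split(";") if p.strip())
        refs.append(FtirReference(str(row["class"]), peaks))
    return refs


def save_ftir_references_csv(refs: list[FtirReference], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "class": [r.name for r in refs],
            "peaks": [";".join(f"{p:g}" for p in r.peaks) for r in refs],
        }
    ).to_csv(path, index=False)
    return path
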