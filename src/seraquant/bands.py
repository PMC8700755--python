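"""Stable-band detection and per-band feature extraction.

Calibration rests on two scalar features per absorption band of the
preprocessed spectrum: the peak absorbance H (AU, maximum inside the band
window) and the band area S (AU*cm^-1, trapezoidal integral over the same
window).  Bands are detected once, on a set of spectra spanning the dilution
series, kept only if present in most spectra, and their integration windows
(flanking local minima of the mean spectrum) are frozen so every sample is
measured identically.  Band indices count 1..n by ascending centre
wavenumber, which makes feature ids like ``H20`` or ``S49`` stable keys.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .spectra import Spectrum, SpectrumError

__all__ = [
    "BandDescriptor",
    "BandError",
    "detect_bands",
    "band_absorbance",
    "band_area",
    "build_feature_matrix",
]

#: Cross-spectrum peak matching tolerance: two 4 cm^-1 resolution elements.
MATCH_TOLERANCE = 8.0


class BandError(ValueError):
    """Raised for band-detection or band-window failures."""


@dataclass(frozen=True)
class BandDescriptor:
    """One absorption band: ordinal index, centre and integration window (cm^-1)."""

    index: int
    center: float
    window_low: float
    window_high: float

    def __post_init__(self) -> None:
        if not (self.window_low < self.center < self.window_high):
            raise BandError(
                f"band {self.index}: window ({self.window_low}, {self.window_high}) "
                f"must bracket the centre {self.center}"
            )

    @property
    def absorbance_id(self) -> str:
        return f"H{self.index}"

    @property
    def area_id(self) -> str:
        return f"S{self.index}"


def _common_grid(spectra: Sequence[Spectrum]) -> np.ndarray:
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid):
            raise BandError("band detection requires spectra on a common wavenumber grid")
    return grid


def detect_bands(
    spectra: Sequence[Spectrum],
    min_prominence: float,
    min_presence: float = 0.8,
) -> list[BandDescriptor]:
    """Find bands present in at least ``min_presence`` of the spectra.

    Peaks are local maxima with prominence >= ``min_prominence`` (AU, on the
    scale of the supplied spectra).  Peak positions are matched across
    spectra within +-8 cm^-1; each surviving band's centre is the grid point
    nearest the median matched position, and its window runs between the
    flanking local minima of the mean spectrum (grid ends count as minima).
    """
    if len(spectra) == 0:
        raise BandError("no spectra supplied to detect_bands")
    if not (0.0 < min_presence <= 1.0):
        raise BandError(f"min_presence must be in (0, 1], got {min_presence}")
    grid = _common_grid(spectra)

    # all peak positions tagged by the spectrum they came from
    positions: list[tuple[float, int]] = []
    for si, s in enumerate(spectra):
        pk, _ = find_peaks(s.absorbance, prominence=min_prominence)
        positions.extend((float(grid[i]), si) for i in pk)
    if not positions:
        raise BandError("no peaks found at the requested prominence")
    positions.sort()

    # greedy 1-D clustering: a new cluster starts when the gap from the
    # running cluster median exceeds the matching tolerance
    clusters: list[list[tuple[float, int]]] = []
    for pos, si in positions:
        if clusters and pos - float(np.median([p for p, _ in clusters[-1]])) <= MATCH_TOLERANCE:
            clusters[-1].append((pos, si))
        else:
            clusters.append([(pos, si)])

    n = len(spectra)
    mean_a = np.mean([s.absorbance for s in spectra], axis=0)
    minima = _local_minima(mean_a)

    bands: list[BandDescriptor] = []
    centers_kept: list[float] = []
    for cl in clusters:
        present = len({si for _, si in cl})
        if present / n < min_presence:
            continue
        center_pos = float(np.median([p for p, _ in cl]))
        ci = int(np.argmin(np.abs(grid - center_pos)))
        left = minima[minima < ci]
        right = minima[minima > ci]
        lo = int(left[-1]) if left.size else 0
        hi = int(right[0]) if right.size else grid.size - 1
        if lo == ci or hi == ci:
            continue  # centre sits on a grid edge; not a usable band
        centers_kept.append(float(grid[ci]))
        bands.append((float(grid[ci]), float(grid[lo]), float(grid[hi])))
    if not bands:
        raise BandError("no bands satisfied the presence criterion")
    bands.sort(key=lambda b: b[0])
    return [
        BandDescriptor(index=i + 1, center=c, window_low=lo, window_high=hi)
        for i, (c, lo, hi) in enumerate(bands)
    ]


def _local_minima(a: np.ndarray) -> np.ndarray:
    """Indices of local minima of ``a``, with both endpoints included."""
    interior, _ = find_peaks(-a)
    return np.unique(np.concatenate(([0], interior, [a.size - 1])))


def _window_indices(s: Spectrum, band: BandDescriptor) -> np.ndarray:
    w = s.wavenumbers
    if band.window_low < w[0] or band.window_high > w[-1]:
        raise BandError(
            f"band {band.index} ({band.center:g} cm^-1): window "
            f"({band.window_low:g}, {band.window_high:g}) outside spectrum span "
            f"({w[0]:g}, {w[-1]:g})"
        )
    lo = int(np.searchsorted(w, band.window_low, side="left"))
    hi = int(np.searchsorted(w, band.window_high, side="right"))
    idx = np.arange(lo, hi)
    if idx.size < 2:
        raise BandError(f"band {band.index}: window contains fewer than 2 grid points")
    return idx


def band_absorbance(s: Spectrum, band: BandDescriptor) -> float:
    """Peak absorbance H: maximum within the band window (AU)."""
    idx = _window_indices(s, band)
    return float(np.max(s.absorbance[idx]))


def band_area(s: Spectrum, band: BandDescriptor) -> float:
    """Band area S: trapezoidal integral over the band window (AU*cm^-1)."""
    idx = _window_indices(s, band)
    return float(np.trapezoid(s.absorbance[idx], s.wavenumbers[idx]))


def build_feature_matrix(
    samples: Sequence[Spectrum], bands: Sequence[BandDescriptor]
) -> pd.DataFrame:
    """Per-sample H/S feature table: one row per spectrum, columns H<i>, S<i>.

    Row labels come from ``meta['sample_id']`` when present.  All features
    are homogeneous of degree 1 in absorbance.
    """
    if len(samples) == 0:
        raise BandError("no sample spectra supplied")
    if len(bands) == 0:
        raise BandError("no bands supplied")
    ids = []
    for i, s in enumerate(samples):
        ids.append(str(s.meta.get("sample_id", f"sample{i}")))
    cols: list[str] = []
    for b in bands:
        cols.extend([b.absorbance_id, b.area_id])
    values = np.empty((len(samples), len(cols)))
    for r, s in enumerate(samples):
        c = 0
        for b in bands:
            values[r, c] = band_absorbance(s, b)
            values[r, c + 1] = band_area(s, b)
            c += 2
    fm = pd.DataFrame(values, index=pd.Index(ids, name="sample"), columns=cols)
    if not np.all(np.isfinite(fm.to_numpy())):
        raise BandError("non-finite feature values")
    return fm


def bands_to_frame(bands: Sequence[BandDescriptor]) -> pd.DataFrame:
    """Serialisable table of band definitions (index, center, window)."""
    return pd.DataFrame(
        {
            "index": [b.index for b in bands],
            "center": [b.center for b in bands],
            "window_low": [b.window_low for b in bands],
            "window_high": [b.window_high for b in bands],
        }
    )


def bands_from_frame(df: pd.DataFrame) -> list[BandDescriptor]:
    return [
        BandDescriptor(int(r["index"]), float(r["center"]), float(r["window_low"]), float(r["window_high"]))
        for _, r in df.iterrows()
    ]
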