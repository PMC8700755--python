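"""Reading, validation and preprocessing of dried-film mid-IR absorbance spectra.

A :class:`Spectrum` is a pair of equally long arrays — wavenumber (cm^-1,
strictly increasing) and absorbance (AU) — plus free-form metadata.  The
preprocessing chain applied before any feature extraction is, in order:

1. average replicate scans recorded for the same film,
2. two-point linear baseline subtraction,
3. excision of the atmospheric CO2 window by straight-line interpolation,
4. vector normalisation (unit Euclidean norm over a stated range).

Each step is exposed as a pure function; :func:`preprocess` chains them and
records the applied settings in the output metadata.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "WavenumberRange",
    "PreprocessConfig",
    "SpectrumError",
    "read_spectrum",
    "write_spectrum",
    "average_replicates",
    "baseline_correct_two_point",
    "vector_normalize",
    "excise_straight_line",
    "preprocess",
]

#: Default atmospheric CO2 asymmetric-stretch window excised from every
#: spectrum (cm^-1).  The gas-phase doublet sits near 2349 cm^-1.
DEFAULT_CO2_REGION = (2280.0, 2400.0)

#: Nominal acquisition range of the instrument class this package targets.
DEFAULT_ACQUISITION_RANGE = (500.0, 4000.0)


class SpectrumError(ValueError):
    """Raised for malformed spectra or invalid preprocessing requests."""


@dataclass(frozen=True)
class WavenumberRange:
    """Closed wavenumber interval [low, high] in cm^-1."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.high):
            raise SpectrumError(
                f"invalid wavenumber range: low={self.low} must be < high={self.high}"
            )

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high


@dataclass
class Spectrum:
    """One absorbance spectrum on a strictly increasing wavenumber grid.

    Descending input grids are silently re-sorted to ascending (the original
    orientation is the caller's business to record in ``meta``); duplicated
    or otherwise non-monotonic grids are rejected.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1:
            raise SpectrumError("wavenumbers and absorbance must be 1-D arrays")
        if w.size != a.size:
            raise SpectrumError(
                f"length mismatch: {w.size} wavenumbers vs {a.size} absorbances"
            )
        if w.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(a))):
            raise SpectrumError("non-finite values in spectrum")
        d = np.diff(w)
        if np.all(d < 0):  # descending input: re-sort
            w, a = w[::-1], a[::-1].copy()
            d = np.diff(w)
        if not np.all(d > 0):
            raise SpectrumError("wavenumbers must be strictly monotonic (no duplicates)")
        self.wavenumbers = w
        self.absorbance = a

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def span(self) -> WavenumberRange:
        return WavenumberRange(float(self.wavenumbers[0]), float(self.wavenumbers[-1]))

    def nearest_index(self, x: float) -> int:
        """Index of the grid point nearest ``x``; ties go to lower wavenumber."""
        w = self.wavenumbers
        i = int(np.searchsorted(w, x))
        if i == 0:
            return 0
        if i >= w.size:
            return w.size - 1
        # distance to the point below wins on a tie
        return i - 1 if (x - w[i - 1]) <= (w[i] - x) else i

    def slice_indices(self, rng: WavenumberRange) -> np.ndarray:
        """Indices of grid points inside [rng.low, rng.high]."""
        w = self.wavenumbers
        lo = int(np.searchsorted(w, rng.low, side="left"))
        hi = int(np.searchsorted(w, rng.high, side="right"))
        return np.arange(lo, hi)

    def with_absorbance(self, a: np.ndarray, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.wavenumbers.copy(), np.asarray(a, dtype=float), meta)


# ---------------------------------------------------------------------------
# I/O: two-column CSV and a minimal JCAMP-DX dialect
# ---------------------------------------------------------------------------

def _read_csv_spectrum(path: Path) -> Spectrum:
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(";", ",").replace("\t", ",").split(",") if p != ""]
            if len(parts) < 2:
                raise SpectrumError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1:  # optional header
                    continue
                raise SpectrumError(f"{path}:{lineno}: non-numeric row {line!r}")
    if len(rows) < 2:
        raise SpectrumError(f"{path}: fewer than 2 data points")
    w = np.array([r[0] for r in rows])
    a = np.array([r[1] for r in rows])
    descending = bool(w.size > 1 and w[0] > w[-1])
    meta = {"source": str(path), "source_orientation": "descending" if descending else "ascending"}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return Spectrum(w, a, meta)


def _read_jcamp_spectrum(path: Path) -> Spectrum:
    """Minimal JCAMP-DX reader: AFFN-encoded ##XYDATA=(X++(Y..Y)) or ##XYPOINTS.

    Compressed ordinate forms (SQZ/DIF/DUP) are not supported and raise.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None  # None | "xydata" | "xypoints"
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XYDATA":
                mode = "xydata"
                continue
            if key == "XYPOINTS":
                mode = "xypoints"
                continue
            if key == "END":
                mode = None
                continue
            fields[key] = val
            mode = None
        elif mode is not None:
            data_lines.append((mode, line))
    if not data_lines:
        raise SpectrumError(f"{path}: no XYDATA/XYPOINTS block found")
    xfac = float(fields.get("XFACTOR", "1"))
    yfac = float(fields.get("YFACTOR", "1"))
    xs: list[float] = []
    ys: list[float] = []
    for mode, line in data_lines:
        for ch in line:
            if ch.isalpha() and ch.upper() not in "E":
                raise SpectrumError(
                    f"{path}: compressed JCAMP ordinate forms (SQZ/DIF/DUP) are not supported"
                )
        toks = [t for t in line.replace(",", " ").replace(";", " ").split() if t]
        vals = [float(t) for t in toks]
        if mode == "xypoints":
            for x, y in zip(vals[0::2], vals[1::2]):
                xs.append(x * xfac)
                ys.append(y * yfac)
        else:  # (X++(Y..Y)): first token is X of the first Y on this line
            if len(vals) < 2:
                raise SpectrumError(f"{path}: malformed XYDATA line {line!r}")
            x0 = vals[0] * xfac
            yline = vals[1:]
            if len(yline) > 1:
                # per-line abscissa spacing from declared grid
                if "DELTAX" in fields:
                    dx = float(fields["DELTAX"]) * xfac
                elif {"FIRSTX", "LASTX", "NPOINTS"} <= fields.keys():
                    n = int(float(fields["NPOINTS"]))
                    dx = (float(fields["LASTX"]) - float(fields["FIRSTX"])) * xfac / max(n - 1, 1)
                else:
                    raise SpectrumError(f"{path}: cannot infer DELTAX for XYDATA")
            else:
                dx = 0.0
            for k, y in enumerate(yline):
                xs.append(x0 + k * dx)
                ys.append(y * yfac)
    if len(xs) < 2:
        raise SpectrumError(f"{path}: fewer than 2 data points")
    descending = xs[0] > xs[-1]
    return Spectrum(
        np.array(xs),
        np.array(ys),
        {"source": str(path), "source_orientation": "descending" if descending else "ascending"},
    )


def read_spectrum(path, format: str | None = None) -> Spectrum:
    """Read a spectrum from CSV (two numeric columns) or JCAMP-DX.

    ``format`` is ``"csv"`` or ``"jcamp-dx"``; when omitted it is inferred
    from the file extension (.jdx/.dx/.jcamp -> JCAMP, else CSV).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcamp-dx" if path.suffix.lower() in {".jdx", ".dx", ".jcamp"} else "csv"
    if format == "csv":
        return _read_csv_spectrum(path)
    if format in {"jcamp-dx", "jcamp", "jdx"}:
        return _read_jcamp_spectrum(path)
    raise SpectrumError(f"unknown spectrum format {format!r}")


def write_spectrum(path, s: Spectrum, sidecar_meta: bool = True) -> None:
    """Write the two-column CSV dialect ``read_spectrum`` consumes.

    Floats are written with ``repr`` so a read-back is bit-identical.  Meta
    goes to a ``<name>.csv.meta.json`` sidecar unless disabled.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write("wavenumber_cm-1,absorbance\n")
    for w, a in zip(s.wavenumbers.tolist(), s.absorbance.tolist()):
        buf.write(f"{w!r},{a!r}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    if sidecar_meta and s.meta:
        serialisable = {k: v for k, v in s.meta.items() if _json_ok(v)}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(serialisable, indent=2, sort_keys=True), encoding="utf-8"
        )


def _json_ok(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# Preprocessing steps
# ---------------------------------------------------------------------------

def average_replicates(replicates: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra sharing an identical grid."""
    if len(replicates) == 0:
        raise SpectrumError("cannot average an empty replicate list")
    first = replicates[0]
    for r in replicates[1:]:
        if r.wavenumbers.shape != first.wavenumbers.shape or not np.array_equal(
            r.wavenumbers, first.wavenumbers
        ):
            raise SpectrumError("replicates do not share an identical wavenumber grid")
    mean = np.mean([r.absorbance for r in replicates], axis=0)
    return first.with_absorbance(mean, n_replicates=len(replicates))


def baseline_correct_two_point(
    s: Spectrum, left: float | None = None, right: float | None = None
) -> Spectrum:
    """Subtract the straight line through the spectrum at two anchor points.

    Anchors default to the first and last grid points.  Anchor absorbances are
    taken at the nearest grid points (ties toward lower wavenumber); the
    corrected spectrum is exactly zero at both anchors.
    """
    w = s.wavenumbers
    if left is None:
        left = float(w[0])
    if right is None:
        right = float(w[-1])
    if not (left < right):
        raise SpectrumError(f"baseline anchors must satisfy left < right, got {left}, {right}")
    if left < w[0] or right > w[-1]:
        raise SpectrumError(
            f"baseline anchors ({left}, {right}) outside grid span ({w[0]}, {w[-1]})"
        )
    i, j = s.nearest_index(left), s.nearest_index(right)
    if i == j:
        raise SpectrumError("baseline anchors resolve to the same grid point")
    xi, xj = w[i], w[j]
    yi, yj = s.absorbance[i], s.absorbance[j]
    line = yi + (yj - yi) * (w - xi) / (xj - xi)
    return s.with_absorbance(s.absorbance - line, baseline_anchors=(float(xi), float(xj)))


def vector_normalize(s: Spectrum, range: WavenumberRange | None = None) -> Spectrum:
    """Scale the whole spectrum so the Euclidean norm over ``range`` is 1."""
    if range is None:
        range = s.span
    idx = s.slice_indices(range)
    if idx.size == 0:
        raise SpectrumError(f"normalisation range {range} does not overlap the grid")
    norm = float(np.linalg.norm(s.absorbance[idx]))
    if norm <= 0.0:
        raise SpectrumError("zero Euclidean norm within the normalisation range")
    return s.with_absorbance(
        s.absorbance / norm, normalization_range=(range.low, range.high), normalization_norm=norm
    )


def excise_straight_line(s: Spectrum, region: WavenumberRange) -> Spectrum:
    """Replace the interior of ``region`` with the chord between its edges.

    Used to delete the atmospheric CO2 doublet.  The nearest grid points at
    the region boundaries anchor the chord; points outside are untouched.
    """
    w = s.wavenumbers
    if region.low < w[0] or region.high > w[-1]:
        raise SpectrumError(f"excision region {region} outside grid span {s.span}")
    i, j = s.nearest_index(region.low), s.nearest_index(region.high)
    if j - i < 2:  # no interior points: nothing to replace
        return s.with_absorbance(s.absorbance.copy(), excised_region=(region.low, region.high))
    a = s.absorbance.copy()
    a[i : j + 1] = np.interp(w[i : j + 1], [w[i], w[j]], [a[i], a[j]])
    return s.with_absorbance(a, excised_region=(region.low, region.high))


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the fixed preprocessing chain.

    ``baseline_left``/``baseline_right`` of ``None`` mean the grid endpoints;
    ``normalize_range`` of ``None`` means the full grid span.
    """

    baseline_left: float | None = None
    baseline_right: float | None = None
    co2_region: tuple[float, float] = DEFAULT_CO2_REGION
    normalize_range: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "baseline_left": self.baseline_left,
            "baseline_right": self.baseline_right,
            "co2_region": list(self.co2_region),
            "normalize_range": None if self.normalize_range is None else list(self.normalize_range),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PreprocessConfig":
        nr = d.get("normalize_range")
        return cls(
            baseline_left=d.get("baseline_left"),
            baseline_right=d.get("baseline_right"),
            co2_region=tuple(d.get("co2_region", DEFAULT_CO2_REGION)),
            normalize_range=None if nr is None else tuple(nr),
        )


def preprocess(replicates: Sequence[Spectrum], config: PreprocessConfig | None = None) -> Spectrum:
    """Average -> baseline-correct -> excise CO2 -> vector-normalise.

    The order is fixed and recorded in the output ``meta['preprocess_order']``.
    """
    cfg = config or PreprocessConfig()
    s = average_replicates(replicates)
    s = baseline_correct_two_point(s, cfg.baseline_left, cfg.baseline_right)
    lo, hi = cfg.co2_region
    span = s.span
    if lo > span.low and hi < span.high:
        s = excise_straight_line(s, WavenumberRange(lo, hi))
    nr = None if cfg.normalize_range is None else WavenumberRange(*cfg.normalize_range)
    s = vector_normalize(s, nr)
    s.meta["preprocess_order"] = ["average", "baseline", "co2_excision", "vector_normalize"]
    return s
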