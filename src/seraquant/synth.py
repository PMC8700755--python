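"""Synthetic dried-film serum FTIR dilution studies with known ground truth.

The generator emulates the calibration design this package targets: a stock
control-serum solution certified for a 38-analyte panel, diluted 2, 3, 5, 7
and 10x (each level measured in triplicate), acquired at 500-4000 cm^-1 on a
4 cm^-1 grid.  Each spectrum is a Beer-Lambert mixture of Gaussian bands:

    A(v) = sum_b amp_b * exp(-(v - c_b)^2 / (2 sigma_b^2))
           + linear baseline drift + white Gaussian noise,

    amp_b = const_b + sum_i loading_{b,i} * concentration_i.

Bands fall in two classes.  *Analyte bands* have concentration loadings, so
their amplitude scales with the dilution in lockstep.  *Background bands*
(the free-OH region above 3700 cm^-1, from the film/substrate rather than
solutes) have a fixed amplitude; they are what makes vector-normalised
spectra still carry dilution information, and ratios of analyte-band to
background-band features are exactly proportional to concentration.

The 49-band library places 15 fixed template centres at positions typical of
serum films (amide I/II, CH stretches, phosphate, the free-OH pair, ...) and
fills the rest with seeded random bands; by construction band index 2 is
616 cm^-1, 20 is 1717, 42 is 3750 and 49 is 3903, matching the feature names
the packaged reference composite uses.

The lockstep design (all analytes share one dilution factor) is the
structural assumption the whole method exploits; ``analyte_jitter_sd``
deliberately breaks it to show how accuracy degrades once concentration
ratios vary between samples, as they do in real sera.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .model import ConcentrationPanel, PanelDefinition
from .spectra import Spectrum

__all__ = [
    "SyntheticBand",
    "StudyDesign",
    "SynthError",
    "default_stock_panel",
    "make_band_library",
    "simulate_spectrum",
    "simulate_sample",
    "simulate_dilution_study",
    "default_grid",
]

#: Acquisition grid: 500-4000 cm^-1 at 4 cm^-1 steps (876 points).
GRID_LOW, GRID_HIGH, GRID_STEP = 500.0, 4000.0, 4.0

#: Analyte-band template centres (cm^-1) with stock amplitudes (AU) and
#: widths (cm^-1): positions typical of dried-serum spectra (phenyl ring,
#: carbohydrate CO, phosphate, COO-, CH2/CH3, amide II/I, C=O, OH stretch).
TEMPLATE_BANDS = [
    # (center, stock amplitude, sigma)
    (616.0, 0.45, 12.0),
    (1080.0, 0.50, 14.0),
    (1171.0, 0.40, 12.0),
    (1242.0, 0.45, 14.0),
    (1394.0, 0.55, 12.0),
    (1453.0, 0.60, 14.0),
    (1536.0, 0.80, 18.0),
    (1650.0, 1.00, 22.0),
    (1717.0, 0.40, 11.0),
    (2872.0, 0.30, 10.0),
    (2920.0, 0.38, 10.0),
    (2957.0, 0.33, 9.0),
    (3280.0, 0.90, 28.0),
]

#: Background (film/substrate free-OH) template centres: fixed amplitude,
#: independent of solute concentrations.
BACKGROUND_TEMPLATES = [(3750.0, 0.40, 5.0), (3903.0, 0.35, 5.0)]

#: No synthetic band is placed inside the CO2 window that preprocessing
#: excises, with margin.
CO2_EXCLUSION = (2260.0, 2420.0)

N_BANDS_DEFAULT = 49


class SynthError(ValueError):
    """Raised for invalid synthetic-study requests."""


@dataclass(frozen=True)
class SyntheticBand:
    """One Gaussian band of the simulator's library.

    ``loadings`` maps analyte id to absorbance per concentration unit;
    ``constant_amplitude`` > 0 marks a background band whose amplitude does
    not depend on the sample.
    """

    center: float
    sigma: float
    loadings: tuple[tuple[str, float], ...] = ()
    constant_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise SynthError(f"band at {self.center}: sigma must be > 0")
        has_loading = any(v > 0 for _, v in self.loadings)
        if not has_loading and not (self.constant_amplitude > 0):
            raise SynthError(
                f"band at {self.center}: needs a positive loading or constant amplitude"
            )

    @property
    def is_background(self) -> bool:
        return self.constant_amplitude > 0

    def amplitude(self, concentrations) -> float:
        amp = self.constant_amplitude
        for a, l in self.loadings:
            amp += l * float(concentrations[a])
        return amp


@dataclass
class StudyDesign:
    """Dilution-study layout and noise model.

    Defaults are the calibration conditions this package assumes: stock
    diluted 2/3/5/7/10x in triplicate, additive white noise of 1e-4 AU
    (a clean bench instrument), no baseline drift.
    """

    stock: ConcentrationPanel
    dilution_factors: tuple[float, ...] = (2.0, 3.0, 5.0, 7.0, 10.0)
    replicates: int = 3
    noise_sd: float = 1e-4
    drift_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.dilution_factors)
        if len(set(f)) != len(f):
            raise SynthError("dilution factors must be distinct")
        if any(x <= 1.0 for x in f):
            raise SynthError("dilution factors must all exceed 1")
        if self.replicates < 1:
            raise SynthError("replicates must be >= 1")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise SynthError("noise_sd and drift_amplitude must be >= 0")
        self.dilution_factors = f


def default_grid() -> np.ndarray:
    return np.arange(GRID_LOW, GRID_HIGH + GRID_STEP / 2, GRID_STEP)


def default_stock_panel(panel: PanelDefinition, sample_id: str = "stock") -> ConcentrationPanel:
    """Stock concentrations implied by the panel's calibration ranges.

    The ranges span a 2x..10x dilution of the stock, so range_high is
    stock/2: the stock sits at twice the upper range bound.
    """
    return ConcentrationPanel(sample_id, {a.id: 2.0 * a.range_high for a in panel.analytes})


# ---------------------------------------------------------------------------
# Band library
# ---------------------------------------------------------------------------

def _place_fillers(rng, n, low, high, taken, min_sep, exclusions=()):
    """Rejection-sample n centres in [low, high] keeping min_sep from ``taken``.

    If the packing is tight for a given draw sequence, the separation is
    relaxed in 10% steps (down to 60%) rather than failing; band widths are
    derived from realised gaps afterwards, so peaks stay resolvable.
    """
    for relax in (1.0, 0.9, 0.8, 0.7, 0.6):
        sep = min_sep * relax
        placed: list[float] = []
        for _ in range(50000):
            if len(placed) == n:
                return sorted(placed)
            c = float(rng.uniform(low, high))
            if any(lo <= c <= hi for lo, hi in exclusions):
                continue
            if all(abs(c - t) >= sep for t in taken + placed):
                placed.append(c)
        if len(placed) == n:
            return sorted(placed)
    raise SynthError("could not place filler bands; loosen the spacing rules")


def _stratified_positions(rng, n, low, high, jitter):
    """n jittered, evenly spaced interior positions of (low, high)."""
    base = low + (high - low) * (np.arange(1, n + 1)) / (n + 1)
    return sorted(float(b + rng.uniform(-jitter, jitter)) for b in base)


def make_band_library(
    panel: PanelDefinition, n_bands: int = N_BANDS_DEFAULT, seed: int = 0
) -> list[SyntheticBand]:
    """Build a deterministic 49-band serum-like library for ``panel``.

    Fillers are distributed so the template centres land on fixed indices:
    one filler below 616 cm^-1 (616 is band 2), ten between 616 and 1717
    (1717 is band 20), seventeen between 1717 and 3500 cm^-1 (3750 is band
    42) and six background fillers between 3750 and 3903 cm^-1 (3903 is
    band 49).  Every analyte receives at
    least one positive loading; loading magnitudes are normalised so a
    band's amplitude at stock concentration equals its template amplitude.
    """
    n_templates = len(TEMPLATE_BANDS) + len(BACKGROUND_TEMPLATES)
    if n_bands < n_templates:
        raise SynthError(f"n_bands must be >= {n_templates}")
    if n_bands != N_BANDS_DEFAULT:
        # index bookkeeping below assumes the canonical 49-band layout
        raise SynthError("only the canonical 49-band library layout is supported")
    rng = np.random.default_rng(seed)
    stock = default_stock_panel(panel)

    template_centers = [c for c, _, _ in TEMPLATE_BANDS] + [c for c, _, _ in BACKGROUND_TEMPLATES]
    low_filler = _place_fillers(rng, 1, 540.0, 576.0, template_centers, 40.0)
    finger_fillers = _place_fillers(
        rng, 10, 656.0, 1678.0, template_centers + low_filler, 44.0
    )
    upper_fillers = _place_fillers(
        rng, 17, 1760.0, 3500.0, template_centers + low_filler + finger_fillers, 48.0,
        exclusions=[CO2_EXCLUSION],
    )
    main_fillers = sorted(finger_fillers + upper_fillers)
    high_fillers = _stratified_positions(rng, 6, 3750.0, 3903.0, jitter=2.5)

    entries = []  # (center, amplitude, sigma, background?)
    for c in low_filler:
        sigma = float(rng.uniform(4.0, min(8.0, (c - GRID_LOW) / 7.0)))
        entries.append((c, float(rng.uniform(0.10, 0.30)), sigma, False))
    for c, amp, sigma in TEMPLATE_BANDS:
        entries.append((c, amp, sigma, False))
    for c in main_fillers:
        all_centers = template_centers + low_filler + [x for x in main_fillers if x != c]
        gap = min(abs(c - t) for t in all_centers)
        cap = min(30.0, gap / 3.0, (c - GRID_LOW) / 7.0, (GRID_HIGH - c) / 7.0)
        sigma = float(rng.uniform(6.0, max(6.5, cap)))
        entries.append((c, float(rng.uniform(0.05, 0.50)), sigma, False))
    for c, amp, sigma in BACKGROUND_TEMPLATES:
        entries.append((c, amp, sigma, True))
    for c in high_fillers:
        entries.append((c, float(rng.uniform(0.15, 0.35)), float(rng.uniform(4.0, 5.5)), True))
    entries.sort(key=lambda e: e[0])

    # distribute analyte loadings over the concentration-dependent bands
    analyte_ids = panel.ids
    conc_band_pos = [i for i, e in enumerate(entries) if not e[3]]
    assignment: dict[int, list[str]] = {i: [] for i in conc_band_pos}
    for i in conc_band_pos:
        k = int(rng.integers(1, 5))
        chosen = rng.choice(analyte_ids, size=min(k, len(analyte_ids)), replace=False)
        assignment[i] = [str(a) for a in chosen]
    covered = {a for ids in assignment.values() for a in ids}
    for a in analyte_ids:
        if a not in covered:
            assignment[int(rng.choice(conc_band_pos))].append(a)

    library: list[SyntheticBand] = []
    for i, (c, amp, sigma, bg) in enumerate(entries):
        if bg:
            library.append(SyntheticBand(center=c, sigma=sigma, constant_amplitude=amp))
        else:
            ids = assignment[i]
            fracs = rng.dirichlet(np.ones(len(ids)))
            loadings = tuple(
                (a, float(f * amp / stock[a])) for a, f in zip(ids, fracs)
            )
            library.append(SyntheticBand(center=c, sigma=sigma, loadings=loadings))
    return library


# ---------------------------------------------------------------------------
# Spectrum and study simulation
# ---------------------------------------------------------------------------

def noiseless_absorbance(concentrations, library, grid: np.ndarray | None = None) -> np.ndarray:
    """Beer-Lambert mixture of the library's Gaussian bands (no noise/drift)."""
    v = default_grid() if grid is None else grid
    a = np.zeros_like(v)
    for b in library:
        amp = b.amplitude(concentrations)
        if amp != 0.0:
            a += amp * np.exp(-((v - b.center) ** 2) / (2.0 * b.sigma**2))
    return a


def _spectrum_rng(design: StudyDesign, sample_id: str, replicate: int):
    key = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng([design.seed & 0x7FFFFFFF, key, replicate])


def simulate_spectrum(
    panel: ConcentrationPanel,
    library: list[SyntheticBand],
    design: StudyDesign,
    replicate: int = 0,
) -> Spectrum:
    """One replicate acquisition of ``panel``: bands + drift + white noise.

    Reproducible: the noise stream is derived from (design.seed, sample id,
    replicate index) only.
    """
    grid = default_grid()
    a = noiseless_absorbance(panel.values, library, grid)
    rng = _spectrum_rng(design, panel.sample_id, replicate)
    if design.drift_amplitude > 0:
        u0, u1 = rng.uniform(-1.0, 1.0, size=2) * design.drift_amplitude
        a = a + u0 + (u1 - u0) * (grid - grid[0]) / (grid[-1] - grid[0])
    if design.noise_sd > 0:
        a = a + rng.normal(0.0, design.noise_sd, size=grid.size)
    return Spectrum(
        grid,
        a,
        meta={
            "sample_id": panel.sample_id,
            "replicate": replicate,
            "synthetic": True,
        },
    )


def _level_panel(design: StudyDesign, factor: float, jitter_sd: float) -> ConcentrationPanel:
    sample_id = f"dil{factor:g}"
    values = {a: v / factor for a, v in design.stock.values.items()}
    if jitter_sd > 0:
        rng = np.random.default_rng(
            [design.seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode()) ^ 0x5EED, 7]
        )
        for a in values:
            values[a] *= float(np.exp(rng.normal(0.0, jitter_sd)))
    return ConcentrationPanel(sample_id, values)


def simulate_sample(
    library: list[SyntheticBand],
    design: StudyDesign,
    factor: float,
    analyte_jitter_sd: float = 0.0,
) -> tuple[list[Spectrum], ConcentrationPanel]:
    """Replicate spectra and ground-truth panel for one dilution factor."""
    if factor <= 1.0:
        raise SynthError("dilution factor must exceed 1")
    panel = _level_panel(design, factor, analyte_jitter_sd)
    spectra = [
        simulate_spectrum(panel, library, design, replicate=r)
        for r in range(design.replicates)
    ]
    for s in spectra:
        s.meta["dilution_factor"] = factor
    return spectra, panel


def simulate_dilution_study(
    design: StudyDesign,
    library: list[SyntheticBand],
    include_stock: bool = False,
    analyte_jitter_sd: float = 0.0,
) -> tuple[list[Spectrum], list[ConcentrationPanel]]:
    """The full study: every dilution level in replicate, ordered (level, rep).

    With ``analyte_jitter_sd`` = 0 the concentration vectors of all levels
    are exactly proportional (lockstep); a positive jitter multiplies each
    level/analyte concentration by an independent lognormal factor, breaking
    the proportionality the way real sera do.
    """
    spectra: list[Spectrum] = []
    panels: list[ConcentrationPanel] = []
    if include_stock:
        panel = ConcentrationPanel("stock", dict(design.stock.values))
        for r in range(design.replicates):
            spectra.append(simulate_spectrum(panel, library, design, replicate=r))
        panels.append(panel)
    for f in design.dilution_factors:
        s, p = simulate_sample(library, design, f, analyte_jitter_sd)
        spectra.extend(s)
        panels.append(p)
    return spectra, panels
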