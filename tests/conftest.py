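"""Shared fixtures: synthetic spectra helpers and a session-scoped
noiseless calibration study (the expensive end-to-end pieces are reused)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import seraquant as sq


def gaussian_spectrum(
    center: float = 1650.0,
    amplitude: float = 1.0,
    sigma: float = 10.0,
    lo: float = 500.0,
    hi: float = 4000.0,
    step: float = 1.0,
    slope: float = 0.0,
    intercept: float = 0.0,
    meta: dict | None = None,
) -> sq.Spectrum:
    w = np.arange(lo, hi + step / 2, step)
    a = amplitude * np.exp(-((w - center) ** 2) / (2 * sigma**2)) + slope * w + intercept
    return sq.Spectrum(w, a, meta or {})


@pytest.fixture(scope="session")
def panel() -> sq.PanelDefinition:
    return sq.reference_panel()


@pytest.fixture(scope="session")
def library(panel):
    return sq.make_band_library(panel, seed=1)


@pytest.fixture(scope="session")
def noiseless_study(panel, library):
    design = sq.StudyDesign(stock=sq.default_stock_panel(panel), noise_sd=0.0, seed=1)
    spectra, truth = sq.simulate_dilution_study(design, library)
    groups: dict[str, list[sq.Spectrum]] = {}
    for s in spectra:
        groups.setdefault(str(s.meta["sample_id"]), []).append(s)
    return design, spectra, truth, groups


@pytest.fixture(scope="session")
def calibrated(panel, library, noiseless_study):
    design, _, truth, groups = noiseless_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, info = sq.calibrate(groups, truth, panel)
    return model, info, design
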