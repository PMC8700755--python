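"""End-to-end orchestration: calibrate, predict, and internal-consistency
validation of the packaged reference calibration, with manifest-tracked
provenance.

The stages always run in the same order — preprocess replicates, detect
stable bands, extract H/S features, search the composite feature, fit the
per-analyte coefficients and the global bias — and a run is fully determined
by its configuration (one seed drives all randomness), so rerunning a config
reproduces the model file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import BandDescriptor, build_feature_matrix, detect_bands
from .model import (
    CalibrationModel,
    ConcentrationPanel,
    ModelError,
    PanelDefinition,
    PredictionReport,
    estimate_bias,
    fit_scale_coefficients,
    fit_shared_composite_value,
    implied_composite_values,
    load_model,
    panels_to_frame,
    predict_panel,
    reference_coefficients,
    reference_panel,
    reference_validation,
    save_model,
    score_predictions,
    REFERENCE_DELTA,
)
from .search import SearchConfig, build_composite
from .spectra import PreprocessConfig, Spectrum, preprocess, read_spectrum
from .synth import StudyDesign, default_stock_panel, make_band_library, simulate_dilution_study

__all__ = [
    "ConfigError",
    "RunManifest",
    "calibrate",
    "run_calibrate",
    "run_predict",
    "predict_from_spectra",
    "validate_reference",
]

logger = logging.getLogger(__name__)

#: Peak prominence used for band detection, as a fraction of the median
#: spectrum maximum (preprocessed scale).
DEFAULT_PROMINENCE_FRACTION = 0.005
DEFAULT_MIN_PRESENCE = 0.8


class ConfigError(ValueError):
    """Raised when a run configuration is missing or malformed."""


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    fingerprints: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "fingerprints": self.fingerprints,
            "timings": self.timings,
            "outputs": self.outputs,
            "version": self.version,
        }

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _sha256_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(
    replicates_by_sample: Mapping[str, Sequence[Spectrum]],
    truth: Sequence[ConcentrationPanel],
    panel: PanelDefinition,
    search_cfg: SearchConfig | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
    min_presence: float = DEFAULT_MIN_PRESENCE,
    reference_analyte: str | None = None,
) -> tuple[CalibrationModel, dict]:
    """Fit a calibration from replicate spectra and known concentrations.

    ``replicates_by_sample`` keys must match the truth panels' sample ids.
    Returns the model and an info dict (band count, screened features,
    selected terms, in-sample max Delta%).
    """
    search_cfg = search_cfg or SearchConfig()
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    truth = list(truth)
    if not truth:
        raise ConfigError("calibration needs at least one truth panel")
    missing = [p.sample_id for p in truth if p.sample_id not in replicates_by_sample]
    if missing:
        raise ConfigError(f"no spectra supplied for samples: {missing}")

    processed: list[Spectrum] = []
    for p in truth:
        s = preprocess(list(replicates_by_sample[p.sample_id]), preprocess_cfg)
        s.meta["sample_id"] = p.sample_id
        processed.append(s)
    logger.info("preprocessed %d samples", len(processed))

    peak_scale = float(np.median([np.max(np.abs(s.absorbance)) for s in processed]))
    bands = detect_bands(
        processed, min_prominence=prominence_fraction * peak_scale, min_presence=min_presence
    )
    logger.info("detected %d stable bands", len(bands))

    fm = build_feature_matrix(processed, bands)
    truth_df = panels_to_frame(truth)
    stability, rel_sem = _feature_stability(
        replicates_by_sample, truth, preprocess_cfg, bands, fm
    )
    composite, search_info = build_composite(
        fm,
        truth_df,
        search_cfg,
        reference_analyte=reference_analyte,
        stability=stability,
        feature_rel_sem=rel_sem,
    )

    K = composite.evaluate_matrix(fm)
    coeffs = fit_scale_coefficients(K, truth)
    raw_pred = np.outer(K, [coeffs[a] for a in truth_df.columns])
    delta = estimate_bias(raw_pred, truth_df.to_numpy(dtype=float))
    # the bias stage only corrects a systematic overprediction; a tiny
    # negative estimate (underprediction) is clamped to zero
    delta = float(max(0.0, delta))

    model = CalibrationModel(
        composite=composite,
        coefficients=coeffs,
        bias=delta,
        panel=panel,
        bands=bands,
        preprocess=preprocess_cfg,
        provenance={
            "search": search_info,
            "n_samples": len(truth),
            "n_bands": len(bands),
            "tool_version": __version__,
        },
    )

    corrected = raw_pred * (1.0 - delta)
    rel = np.abs(corrected - truth_df.to_numpy()) / truth_df.to_numpy()
    info = dict(search_info)
    info.update(
        {
            "n_bands": len(bands),
            "delta": delta,
            "in_sample_max_rel_error": float(rel.max()),
            "in_sample_max_delta_pct": float(100.0 * rel.max()),
        }
    )
    return model, info


def _feature_stability(
    replicates_by_sample: Mapping[str, Sequence[Spectrum]],
    truth: Sequence[ConcentrationPanel],
    preprocess_cfg: PreprocessConfig,
    bands: Sequence[BandDescriptor],
    fm: pd.DataFrame,
) -> tuple[pd.Series | None, pd.DataFrame | None]:
    """Per-feature noise from replicate scatter.

    Each replicate is preprocessed on its own and measured with the frozen
    band windows; the within-sample scatter estimates the feature's noise
    after replicate averaging.  Returns (snr, rel_sem):

    * snr — cross-sample spread of the averaged feature over its pooled
      replicate standard error (larger = more reproducible band);
    * rel_sem — per-sample relative standard error of each averaged
      feature, used to propagate measurement noise through candidate terms.

    Needs >= 2 replicates somewhere, else (None, None).
    """
    if max(len(replicates_by_sample[p.sample_id]) for p in truth) < 2:
        return None, None
    per_sample_var: list[np.ndarray] = []
    for p in truth:
        reps = list(replicates_by_sample[p.sample_id])
        singles = [preprocess([r], preprocess_cfg) for r in reps]
        vals = np.array(
            [build_feature_matrix([s], list(bands)).to_numpy()[0] for s in singles]
        )
        if len(reps) > 1:
            per_sample_var.append(vals.var(axis=0, ddof=1) / len(reps))
    sem = np.sqrt(np.mean(per_sample_var, axis=0))
    spread = fm.to_numpy().std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        snr = np.where(sem > 0, spread / sem, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(sem[None, :] / fm.to_numpy())
    rel = np.where(np.isfinite(rel), rel, 0.0)
    return (
        pd.Series(snr, index=fm.columns),
        pd.DataFrame(rel, index=fm.index, columns=fm.columns),
    )


def _require(cfg: Mapping, key: str, where: str = "config"):
    if key not in cfg:
        raise ConfigError(f"{where} is missing required field {key!r}")
    return cfg[key]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {config} did not parse to a mapping")
        return loaded
    return dict(config)


def _panel_from_csv(path) -> PanelDefinition:
    from .model import Analyte

    df = pd.read_csv(path)
    for col in ("analyte", "name", "units", "range_low", "range_high"):
        if col not in df.columns:
            raise ConfigError(f"panel table {path} is missing column {col!r}")
    return PanelDefinition(
        [
            Analyte(r["analyte"], r["name"], r["units"], float(r["range_low"]), float(r["range_high"]))
            for _, r in df.iterrows()
        ]
    )


def run_calibrate(config, out_dir=None) -> tuple[CalibrationModel, RunManifest]:
    """Config-driven calibration; writes model.json and manifest.json.

    The config (YAML mapping or dict) either names measured spectra::

        samples:                    # replicate files per sample
          - id: dil2
            replicates: [a.csv, b.csv, c.csv]
        truth: truth.csv            # samples x analytes concentrations
        panel: panel.csv            # analyte, name, units, range_low, range_high

    or requests a synthetic study::

        synthetic:
          noise_sd: 1.0e-4
          dilution_factors: [2, 3, 5, 7, 10]
          replicates: 3

    plus optional ``seed``, ``search``, ``preprocess``, ``detection`` and
    ``reference_analyte`` sections.  Any stage failure aborts the run; no
    partial model file is left behind.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    search_cfg = SearchConfig(seed=seed, **cfg.get("search", {}))
    preprocess_cfg = PreprocessConfig.from_dict(cfg.get("preprocess", {}))
    det = cfg.get("detection", {})
    manifest = RunManifest(config=cfg)

    t0 = time.perf_counter()
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        panel = reference_panel() if "panel" not in cfg else _panel_from_csv(cfg["panel"])
        jitter = float(syn.pop("analyte_jitter_sd", 0.0))
        design = StudyDesign(stock=default_stock_panel(panel), seed=seed, **syn)
        library = make_band_library(panel, seed=seed)
        spectra, truth = simulate_dilution_study(design, library, analyte_jitter_sd=jitter)
        groups: dict[str, list[Spectrum]] = {}
        for s in spectra:
            groups.setdefault(str(s.meta["sample_id"]), []).append(s)
        manifest.fingerprints["synthetic_design"] = _sha256_obj(
            {"design": syn, "seed": seed, "jitter": jitter}
        )
    else:
        samples = _require(cfg, "samples")
        truth_path = _require(cfg, "truth")
        panel = _panel_from_csv(_require(cfg, "panel"))
        groups = {}
        for entry in samples:
            sid = _require(entry, "id", where="samples entry")
            paths = _require(entry, "replicates", where=f"sample {sid!r}")
            groups[str(sid)] = [read_spectrum(p) for p in paths]
            for p in paths:
                manifest.fingerprints[str(p)] = _sha256_file(p)
        tdf = pd.read_csv(truth_path, index_col=0)
        truth = [ConcentrationPanel(str(i), row.to_dict()) for i, row in tdf.iterrows()]
        manifest.fingerprints[str(truth_path)] = _sha256_file(truth_path)
    manifest.timings["load_s"] = round(time.perf_counter() - t0, 6)

    t1 = time.perf_counter()
    model, info = calibrate(
        groups,
        truth,
        panel,
        search_cfg=search_cfg,
        preprocess_cfg=preprocess_cfg,
        prominence_fraction=float(det.get("prominence_fraction", DEFAULT_PROMINENCE_FRACTION)),
        min_presence=float(det.get("min_presence", DEFAULT_MIN_PRESENCE)),
        reference_analyte=cfg.get("reference_analyte"),
    )
    manifest.timings["calibrate_s"] = round(time.perf_counter() - t1, 6)
    manifest.config["_info"] = {
        k: v for k, v in info.items() if isinstance(v, (int, float, str, list))
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model_path = out / "model.json"
        save_model(model, model_path)
        manifest.outputs.append(str(model_path))
        manifest.fingerprints["model.json"] = _sha256_file(model_path)
        manifest.write(out / "manifest.json")
        manifest.outputs.append(str(out / "manifest.json"))
    return model, manifest


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_from_spectra(
    model: CalibrationModel,
    replicates: Sequence[Spectrum],
    truth: ConcentrationPanel | None = None,
) -> PredictionReport:
    """Predict the whole panel from one sample's replicate spectra.

    Replicates are preprocessed with the model's recorded settings, the
    model's frozen band windows are measured, and the composite feature is
    evaluated.  A spectrum that does not cover a needed band window raises a
    BandError naming the band.
    """
    from .bands import band_absorbance, band_area

    s = preprocess(list(replicates), model.preprocess)
    needed = set(model.composite.feature_ids())
    features: dict[str, float] = {}
    for b in model.bands:
        if b.absorbance_id in needed:
            features[b.absorbance_id] = band_absorbance(s, b)
        if b.area_id in needed:
            features[b.area_id] = band_area(s, b)
    missing = needed - features.keys()
    if missing:
        raise ModelError(
            f"model bands do not provide features {sorted(missing)}; "
            "was the model saved without its band table?"
        )
    pred = predict_panel(model, features)
    if truth is not None:
        return score_predictions(pred, truth, model.panel)
    rows = [
        {
            "analyte": a.id,
            "name": a.name,
            "units": a.units,
            "predicted": pred.values[a.id],
        }
        for a in model.panel.analytes
    ]
    return PredictionReport(pd.DataFrame(rows))


def run_predict(model_path, spectra_paths: Sequence, truth_path=None) -> PredictionReport:
    """Load a model and predict from replicate spectrum files."""
    model = load_model(model_path)
    replicates = [read_spectrum(p) for p in spectra_paths]
    truth = None
    if truth_path is not None:
        tdf = pd.read_csv(truth_path, index_col=0)
        truth = ConcentrationPanel(str(tdf.index[0]), tdf.iloc[0].to_dict())
    return predict_from_spectra(model, replicates, truth)


# ---------------------------------------------------------------------------
# Reference-calibration consistency checks
# ---------------------------------------------------------------------------

def validate_reference() -> dict:
    """Internal-consistency numbers of the packaged reference calibration.

    * ``implied_k_cv_pct`` — coefficient of variation of the per-analyte
      implied composite values K_i = found_i / (C_i (1 - delta)); one shared
      K generated every prediction, so the spread reflects table rounding.
    * ``max_rel_error_pct`` — worst relative error when a single K, fitted by
      relative least squares to the true test concentrations of analytes
      printed with >= 4 units (full 4-digit precision), predicts those
      analytes.
    * ``delta_pct_matches`` — the published 2-decimal Delta% entries that are
      exactly reproduced from their own printed true/found pair (some rows
      are not self-consistent after rounding; they are reported, not hidden).
    """
    val = reference_validation().set_index("analyte")
    coefs = reference_coefficients()

    ki = implied_composite_values("test_found")
    cv_pct = 100.0 * float(ki.std(ddof=1) / ki.mean())

    truth = val["test_true"]
    k_hat = fit_shared_composite_value(truth, coefs, min_true=4.0)
    sel = truth[truth >= 4.0]
    pred = pd.Series({a: coefs[a] * (1.0 - REFERENCE_DELTA) * k_hat for a in sel.index})
    rel_err_pct = (100.0 * (pred - sel).abs() / sel)

    from .model import _round_half_up

    recomputed = {
        a: _round_half_up(100.0 * abs(r["test_true"] - r["test_found"]) / r["test_true"])
        for a, r in val.iterrows()
    }
    matches = {a: bool(abs(recomputed[a] - val.loc[a, "delta_pct"]) < 5e-9) for a in val.index}

    return {
        "implied_k_cv_pct": cv_pct,
        "implied_k_mean": float(ki.mean()),
        "fitted_k": k_hat,
        "max_rel_error_pct": float(rel_err_pct.max()),
        "n_analytes_ge_4": int(sel.size),
        "delta_pct_recomputed": recomputed,
        "delta_pct_matches": matches,
        "n_delta_pct_matches": int(sum(matches.values())),
    }
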