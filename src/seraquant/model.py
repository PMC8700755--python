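"""Calibration model: per-analyte scale coefficients, bias correction,
prediction and scoring for the 38-analyte serum panel.

Every analyte concentration is predicted from the single composite feature K
as  B_i = C_i * K * (1 - delta),  where C_i is a per-analyte scale
coefficient (closed-form least squares against the calibration samples) and
delta is one global multiplicative bias correction estimated by relative
least squares, so that analytes measured in large units do not dominate.

A published reference calibration for a certified bovine control-serum panel
(38 coefficients, delta = 0.054, the canonical three-term composite over
H20, H49, S2, S42, S49, and the panel's concentration ranges together with
its validation true/found table) ships with the package and is loadable via
:func:`reference_model`, :func:`reference_panel` and
:func:`reference_validation`.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BandDescriptor
from .search import CompositeFeature, MonomialTerm, evaluate_composite
from .spectra import PreprocessConfig

__all__ = [
    "Analyte",
    "PanelDefinition",
    "ConcentrationPanel",
    "CalibrationModel",
    "PredictionReport",
    "ModelError",
    "fit_scale_coefficients",
    "estimate_bias",
    "predict_panel",
    "score_predictions",
    "save_model",
    "load_model",
    "reference_panel",
    "reference_coefficients",
    "reference_validation",
    "reference_model",
    "reference_composite",
]

#: Global bias of the packaged reference calibration: predictions before
#: correction run ~5.7% high, hence the multiplicative factor (1 - 0.054).
REFERENCE_DELTA = 0.054


class ModelError(ValueError):
    """Raised for invalid calibration inputs or a corrupted model file."""


@dataclass(frozen=True)
class Analyte:
    id: str
    name: str
    units: str
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if not (self.range_low < self.range_high):
            raise ModelError(f"{self.id}: range_low must be < range_high")
        if not self.units:
            raise ModelError(f"{self.id}: units must be nonempty")


@dataclass
class PanelDefinition:
    """Ordered list of analytes with units and calibration concentration ranges."""

    analytes: list[Analyte]

    def __post_init__(self) -> None:
        ids = [a.id for a in self.analytes]
        if len(set(ids)) != len(ids):
            raise ModelError("duplicate analyte ids in panel definition")

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.analytes]

    def __len__(self) -> int:
        return len(self.analytes)

    def get(self, analyte_id: str) -> Analyte:
        for a in self.analytes:
            if a.id == analyte_id:
                return a
        raise KeyError(analyte_id)


@dataclass
class ConcentrationPanel:
    """One sample's concentration vector, keyed by analyte id."""

    sample_id: str
    values: dict

    def __post_init__(self) -> None:
        self.values = {str(k): float(v) for k, v in self.values.items()}
        for k, v in self.values.items():
            if not (v > 0 and np.isfinite(v)):
                raise ModelError(f"{self.sample_id}: concentration {k} must be > 0, got {v}")

    def __getitem__(self, analyte_id: str) -> float:
        return self.values[analyte_id]

    def scaled(self, factor: float, sample_id: str | None = None) -> "ConcentrationPanel":
        return ConcentrationPanel(
            sample_id or self.sample_id, {k: v * factor for k, v in self.values.items()}
        )


def panels_to_frame(panels: Sequence[ConcentrationPanel]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict({p.sample_id: p.values for p in panels}, orient="index")
    df.index.name = "sample"
    return df


@dataclass
class CalibrationModel:
    """Everything needed to turn a preprocessed spectrum into 38 concentrations."""

    composite: CompositeFeature
    coefficients: dict
    bias: float
    panel: PanelDefinition
    bands: list[BandDescriptor] = field(default_factory=list)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = {str(k): float(v) for k, v in self.coefficients.items()}
        missing = set(self.panel.ids) - set(self.coefficients)
        if missing:
            raise ModelError(f"coefficients missing for analytes: {sorted(missing)}")
        for k, v in self.coefficients.items():
            if not (v > 0 and np.isfinite(v)):
                raise ModelError(f"coefficient for {k} must be > 0, got {v}")
        if not (0.0 <= self.bias < 0.5):
            raise ModelError(f"bias delta must lie in [0, 0.5), got {self.bias}")


@dataclass
class PredictionReport:
    """Per-analyte predictions, optional truth, and relative errors in percent."""

    table: pd.DataFrame  # columns: analyte, name, units, predicted[, true, delta_pct]

    @property
    def max_delta_pct(self) -> float:
        if "delta_pct" not in self.table.columns:
            raise ModelError("report has no truth values to score against")
        return float(self.table["delta_pct"].max())


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_scale_coefficients(
    K_values: Sequence[float], panels: Sequence[ConcentrationPanel]
) -> dict:
    """Closed-form per-analyte C_i minimising sum_s (C*K_s - B_is)^2.

    C_i = sum_s K_s B_is / sum_s K_s^2.
    """
    K = np.asarray(K_values, dtype=float)
    if K.size == 0 or len(panels) != K.size:
        raise ModelError("K values and panels must be equally many and nonempty")
    if np.all(K == 0.0):
        raise ModelError("all K values are zero")
    ids = set(panels[0].values)
    for p in panels[1:]:
        if set(p.values) != ids:
            raise ModelError("panels do not share a common analyte set")
    denom = float(K @ K)
    out = {}
    for a in sorted(ids):
        b = np.array([p[a] for p in panels])
        out[a] = float(K @ b) / denom
    return out


def estimate_bias(predicted, truth) -> float:
    """Global bias delta = 1 - f*, with f* the relative-LS shrinkage factor.

    f* minimises sum ((f * pred - true) / true)^2 over all entries; in closed
    form f* = sum(r) / sum(r^2) with r = pred / true.  A calibration that
    systematically overpredicts by 5.7% yields delta = 0.054.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.size == 0:
        raise ModelError("cannot estimate bias from empty input")
    if p.shape != t.shape:
        raise ModelError("predicted and truth shapes differ")
    if np.any(t <= 0):
        raise ModelError("truth values must be > 0")
    r = p / t
    f = float(r.sum() / (r @ r))
    return 1.0 - f


# ---------------------------------------------------------------------------
# Prediction and scoring
# ---------------------------------------------------------------------------

def predict_panel(model: CalibrationModel, features: Mapping[str, float]) -> ConcentrationPanel:
    """B_i = C_i * K * (1 - delta) for every panel analyte.

    Emits a warning when the implied concentrations fall outside the panel's
    calibration ranges (the model is only claimed valid inside them).
    """
    K = evaluate_composite(model.composite, features)
    factor = K * (1.0 - model.bias)
    values = {}
    out_of_range = []
    for a in model.panel.analytes:
        v = model.coefficients[a.id] * factor
        values[a.id] = v
        if not (a.range_low <= v <= a.range_high):
            out_of_range.append(a.id)
    if out_of_range:
        warnings.warn(
            f"predictions outside the calibration range for {len(out_of_range)} "
            f"analytes (e.g. {out_of_range[0]}); the calibration is only valid "
            "inside its concentration ranges",
            stacklevel=2,
        )
    if K == 0.0:
        # all predictions are exactly zero; bypass the >0 panel invariant
        p = ConcentrationPanel.__new__(ConcentrationPanel)
        p.sample_id = "prediction"
        p.values = values
        return p
    return ConcentrationPanel("prediction", values)


def _round_half_up(x: float, places: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))


def score_predictions(
    pred: ConcentrationPanel,
    truth: ConcentrationPanel,
    panel: PanelDefinition | None = None,
) -> PredictionReport:
    """Relative errors Delta% = 100*|true - pred|/true, 2-decimal half-up."""
    shared = [a for a in pred.values if a in truth.values]
    if not shared:
        raise ModelError("predictions and truth share no analytes")
    if panel is not None:
        shared = [a for a in panel.ids if a in shared]
    rows = []
    for a in shared:
        t = truth[a]
        if t <= 0:
            raise ModelError(f"truth for {a} must be > 0")
        p = pred.values[a]
        rows.append(
            {
                "analyte": a,
                "name": panel.get(a).name if panel else a,
                "units": panel.get(a).units if panel else "",
                "predicted": p,
                "true": t,
                "delta_pct": _round_half_up(100.0 * abs(t - p) / t),
            }
        )
    return PredictionReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Serialisation (JSON; floats via repr round-trip bit-exactly)
# ---------------------------------------------------------------------------

def _model_to_dict(model: CalibrationModel) -> dict:
    return {
        "format": "seraquant-calibration",
        "version": 1,
        "composite": {
            "terms": [dict(t.exponents) for t in model.composite.terms],
            "weights": [float(w) for w in model.composite.weights],
            "scale": float(model.composite.scale),
        },
        "coefficients": model.coefficients,
        "bias": model.bias,
        "panel": [
            {
                "id": a.id,
                "name": a.name,
                "units": a.units,
                "range_low": a.range_low,
                "range_high": a.range_high,
            }
            for a in model.panel.analytes
        ],
        "bands": [
            {
                "index": b.index,
                "center": b.center,
                "window_low": b.window_low,
                "window_high": b.window_high,
            }
            for b in model.bands
        ],
        "preprocess": model.preprocess.to_dict(),
        "provenance": model.provenance,
    }


def save_model(model: CalibrationModel, path) -> None:
    Path(path).write_text(
        json.dumps(_model_to_dict(model), indent=2, sort_keys=True), encoding="utf-8"
    )


def load_model(path) -> CalibrationModel:
    try:
        d = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ModelError(f"corrupted model file {path}: {e}") from e
    if d.get("format") != "seraquant-calibration":
        raise ModelError(f"{path} is not a calibration model file")
    try:
        comp = CompositeFeature(
            terms=[MonomialTerm(t) for t in d["composite"]["terms"]],
            weights=np.array(d["composite"]["weights"], dtype=float),
            scale=float(d["composite"].get("scale", 1.0)),
        )
        panel = PanelDefinition(
            [
                Analyte(p["id"], p["name"], p["units"], p["range_low"], p["range_high"])
                for p in d["panel"]
            ]
        )
        bands = [
            BandDescriptor(b["index"], b["center"], b["window_low"], b["window_high"])
            for b in d.get("bands", [])
        ]
        return CalibrationModel(
            composite=comp,
            coefficients=d["coefficients"],
            bias=float(d["bias"]),
            panel=panel,
            bands=bands,
            preprocess=PreprocessConfig.from_dict(d.get("preprocess", {})),
            provenance=d.get("provenance", {}),
        )
    except KeyError as e:
        raise ModelError(f"model file {path} is missing field {e}") from e


# ---------------------------------------------------------------------------
# Packaged reference calibration
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("seraquant.data").joinpath(name)


def reference_panel() -> PanelDefinition:
    """The certified 38-analyte control-serum panel with calibration ranges."""
    df = pd.read_csv(_data_path("panel_reference.csv"))
    return PanelDefinition(
        [
            Analyte(r["analyte"], r["name"], r["units"], float(r["range_low"]), float(r["range_high"]))
            for _, r in df.iterrows()
        ]
    )


def reference_coefficients() -> dict:
    """The published per-analyte scale coefficients C_i."""
    df = pd.read_csv(_data_path("panel_coefficients.csv"))
    return {r["analyte"]: float(r["coefficient"]) for _, r in df.iterrows()}


def reference_validation() -> pd.DataFrame:
    """Published validation table: true/found test concentrations and Delta%."""
    return pd.read_csv(_data_path("panel_reference.csv"))


def reference_composite() -> CompositeFeature:
    """The canonical three-ratio-term composite over H20, H49, S2, S42, S49.

    Stored with equal simplex weights and scale 3, which is numerically
    identical to the plain unit-weight sum of the three terms.
    """
    terms = [
        MonomialTerm({"H20": 2, "S2": -2}),
        MonomialTerm({"H20": 1, "H49": 1, "S42": 1, "S2": -1, "S49": -1}),
        MonomialTerm({"H49": 2, "H20": -1, "S42": -1, "S49": -1}),
    ]
    return CompositeFeature(terms=terms, weights=np.full(3, 1.0 / 3.0), scale=3.0)


def reference_model() -> CalibrationModel:
    """The packaged published calibration (coefficients, delta = 0.054)."""
    return CalibrationModel(
        composite=reference_composite(),
        coefficients=reference_coefficients(),
        bias=REFERENCE_DELTA,
        panel=reference_panel(),
        provenance={"source": "packaged reference calibration"},
    )


def implied_composite_values(
    column: str = "test_found", delta: float = REFERENCE_DELTA
) -> pd.Series:
    """Per-analyte implied K_i = value_i / (C_i * (1 - delta)).

    Since every analyte is predicted from one shared K, the implied values
    should agree across the panel up to the rounding of the published tables;
    their coefficient of variation is the internal-consistency check.
    """
    val = reference_validation().set_index("analyte")[column]
    coef = pd.Series(reference_coefficients())
    return (val / (coef * (1.0 - delta))).rename("implied_K")


def fit_shared_composite_value(
    truth: Mapping[str, float] | pd.Series,
    coefficients: Mapping[str, float] | None = None,
    delta: float = REFERENCE_DELTA,
    min_true: float = 0.0,
) -> float:
    """Single K minimising the relative LS misfit of C_i*K*(1-delta) to truth.

    With a_i = C_i (1-delta) / true_i the minimiser is sum(a)/sum(a^2).
    ``min_true`` restricts the fit to analytes whose printed true value is at
    least that large (coarsely printed small values carry rounding error).
    """
    coefs = dict(coefficients or reference_coefficients())
    t = pd.Series(dict(truth), dtype=float)
    t = t[t >= min_true]
    if t.empty:
        raise ModelError("no analytes left after the min_true filter")
    a = np.array([coefs[k] * (1.0 - delta) / t[k] for k in t.index])
    return float(a.sum() / (a @ a))
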