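"""Composite-feature construction: correlation screening, ratio-term
enumeration and simplex-constrained weight fitting.

The calibration signal is a single scalar K per sample, built in three
stages from the band features H<i>/S<i>:

1. *Primary screening* keeps features whose absolute Pearson correlation
   with every analyte concentration is high.  Because multiplying a feature
   by a constant, or adding/subtracting features, cannot improve a Pearson
   correlation while multiplication and division can, the search space is
   restricted to signed-integer-exponent monomials ("ratio terms") of the
   screened features.
2. *Term screening* keeps ratio terms whose sample vector correlates with
   every analyte above ``r_threshold`` (default 0.999).
3. *Weight fitting* combines a small number of retained terms into
   K = scale * sum_t w_t * term_t with weights on the probability simplex
   (w >= 0, sum w = 1).  The quadratic program is solved by a reduced-
   gradient / active-set iteration with exact line searches, which converges
   finitely for this convex objective.

Any global scale of K is irrelevant — it is absorbed by the per-analyte
coefficients fitted afterwards — so the subset search ranks candidate terms
scale-invariantly.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonomialTerm",
    "CompositeFeature",
    "SearchConfig",
    "SearchError",
    "TermEvaluationError",
    "pearson_correlation",
    "screen_primary_features",
    "enumerate_ratio_terms",
    "screen_terms",
    "fit_term_weights",
    "evaluate_composite",
    "build_composite",
]

logger = logging.getLogger(__name__)


class SearchError(ValueError):
    """Raised for invalid search inputs or a failed search."""


class TermEvaluationError(ZeroDivisionError):
    """Raised when a ratio term hits a zero denominator or missing feature."""


# ---------------------------------------------------------------------------
# Terms and composites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonomialTerm:
    """Product of features raised to signed integer exponents.

    ``exponents`` is stored as a tuple of (feature_id, exponent) pairs sorted
    by feature id with zero exponents dropped, so terms hash and compare by
    value.  ``MonomialTerm({"H20": 2, "S2": -2})`` is H20^2 / S2^2.
    """

    exponents: tuple[tuple[str, int], ...]

    def __init__(self, exponents: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = dict(exponents)
        cleaned = tuple(sorted((f, int(e)) for f, e in items.items() if int(e) != 0))
        if not cleaned:
            raise SearchError("a monomial term needs at least one nonzero exponent")
        object.__setattr__(self, "exponents", cleaned)

    @property
    def total_degree(self) -> int:
        return sum(abs(e) for _, e in self.exponents)

    @property
    def max_exponent(self) -> int:
        return max(abs(e) for _, e in self.exponents)

    def features(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.exponents)

    def evaluate(self, features: Mapping[str, float]) -> float:
        out = 1.0
        for f, e in self.exponents:
            if f not in features:
                raise TermEvaluationError(f"feature {f!r} missing while evaluating {self}")
            v = float(features[f])
            if e < 0 and v == 0.0:
                raise TermEvaluationError(f"zero denominator: {f} = 0 in term {self}")
            out *= v**e
        return out

    def evaluate_matrix(self, fm: pd.DataFrame) -> np.ndarray:
        """Evaluate the term for every row of a feature matrix."""
        out = np.ones(len(fm))
        for f, e in self.exponents:
            if f not in fm.columns:
                raise TermEvaluationError(f"feature {f!r} missing while evaluating {self}")
            col = fm[f].to_numpy(dtype=float)
            if e < 0 and np.any(col == 0.0):
                bad = fm.index[np.nonzero(col == 0.0)[0][0]]
                raise TermEvaluationError(
                    f"zero denominator: {f} = 0 for sample {bad!r} in term {self}"
                )
            out = out * col**e
        return out

    def __str__(self) -> str:
        num = [f if e == 1 else f"{f}^{e}" for f, e in self.exponents if e > 0]
        den = [f if e == -1 else f"{f}^{-e}" for f, e in self.exponents if e < 0]
        s = "*".join(num) if num else "1"
        return s + ("/(" + "*".join(den) + ")" if den else "")


@dataclass
class CompositeFeature:
    """K = scale * sum_t weights[t] * terms[t], weights on the simplex.

    The explicit positive ``scale`` lets the same object represent both a
    weighted average (scale 1) and a plain unit-weight sum of terms (scale =
    number of terms, equal weights); the downstream per-analyte coefficients
    absorb either convention.
    """

    terms: list[MonomialTerm]
    weights: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.terms) == 0:
            raise SearchError("a composite feature needs at least one term")
        if self.weights.shape != (len(self.terms),):
            raise SearchError("weights and terms must have equal length")
        if np.any(self.weights < -1e-12):
            raise SearchError("weights must be nonnegative")
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise SearchError("weights must sum to 1")
        if not (self.scale > 0.0 and np.isfinite(self.scale)):
            raise SearchError("scale must be a positive finite number")
        self.weights = np.clip(self.weights, 0.0, None)

    def evaluate(self, features: Mapping[str, float]) -> float:
        return self.scale * float(
            sum(w * t.evaluate(features) for w, t in zip(self.weights, self.terms))
        )

    def evaluate_matrix(self, fm: pd.DataFrame) -> np.ndarray:
        cols = np.column_stack([t.evaluate_matrix(fm) for t in self.terms])
        return self.scale * cols @ self.weights

    def feature_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for t in self.terms:
            for f in t.features():
                if f not in out:
                    out.append(f)
        return tuple(sorted(out))


def evaluate_composite(cf: CompositeFeature, features: Mapping[str, float]) -> float:
    """Evaluate K for one sample's feature map."""
    return cf.evaluate(features)


@dataclass
class SearchConfig:
    """Knobs of the composite-feature search.

    r_threshold
        Signed Pearson bound a ratio term must beat against every analyte.
    primary_r_threshold
        Absolute Pearson bound for the stage-1 feature screen.  Raw band
        features are screened far more loosely than terms: after vector
        normalisation their dilution response is monotone but curved, and
        observed stage-1 correlations on real dried-film series range from
        about 0.77 to 0.999.
    max_primary_features
        Cap on screened features after collinearity de-duplication.
    max_degree / total_degree_cap
        Per-feature and total absolute exponent bounds of enumerated terms.
    max_terms
        Largest number of terms combined into K.
    max_candidate_terms
        Size of the top-ranked term pool over which subsets are searched
        exhaustively.
    seed
        Only used for optional randomised restarts; the search itself is
        deterministic.
    """

    r_threshold: float = 0.999
    primary_r_threshold: float = 0.75
    max_primary_features: int = 8
    max_degree: int = 2
    total_degree_cap: int = 5
    max_terms: int = 3
    max_candidate_terms: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_threshold < 1.0):
            raise SearchError("r_threshold must be in (0, 1)")
        if not (0.0 < self.primary_r_threshold < 1.0):
            raise SearchError("primary_r_threshold must be in (0, 1)")
        if self.max_degree < 1:
            raise SearchError("max_degree must be >= 1")
        if self.total_degree_cap < 1:
            raise SearchError("total_degree_cap must be >= 1")
        if self.max_terms < 1:
            raise SearchError("max_terms must be >= 1")


# ---------------------------------------------------------------------------
# Stage 1: feature screening
# ---------------------------------------------------------------------------

def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SearchError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise SearchError("Pearson correlation needs at least 3 points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise SearchError("Pearson correlation is undefined for a constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def _targets_frame(targets) -> pd.DataFrame:
    """Accept a DataFrame (samples x analytes) or a list of ConcentrationPanel."""
    if isinstance(targets, pd.DataFrame):
        return targets
    rows = {p.sample_id: p.values for p in targets}
    return pd.DataFrame.from_dict(rows, orient="index")


def screen_primary_features(
    fm: pd.DataFrame,
    targets,
    cfg: SearchConfig | None = None,
    stability: pd.Series | None = None,
) -> list[str]:
    """Stage 1: features with |r| >= primary_r_threshold against every analyte.

    On a vector-normalised dilution series every band feature responds to
    dilution in one of two ways: features of analyte bands increase with
    concentration, features of bands the solutes do not feed (film and
    substrate background) decrease.  Ratios across the two classes are what
    make an informative composite, so the screen keeps the strongest
    features of *each* sign class — up to ``max_primary_features`` in total.

    ``stability`` is an optional per-feature signal-to-noise score (larger
    is better, e.g. cross-sample spread over replicate scatter); when given
    it ranks features within a class, preferring the most reproducible
    bands.  Without it, and on ties, the worst absolute correlation ranks.
    Constant feature columns are dropped with a warning.
    """
    cfg = cfg or SearchConfig()
    tf = _targets_frame(targets)
    if len(tf) != len(fm):
        raise SearchError(
            f"feature matrix has {len(fm)} samples but targets have {len(tf)}"
        )
    if not fm.index.equals(tf.index):
        if set(fm.index) != set(tf.index):
            raise SearchError("feature matrix and target samples do not align")
        tf = tf.loc[fm.index]
    if len(fm) < 3:
        raise SearchError("primary screening needs at least 3 samples")

    increasing: list[tuple[float, float, str]] = []
    decreasing: list[tuple[float, float, str]] = []
    for col in fm.columns:
        x = fm[col].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            warnings.warn(f"dropping constant feature column {col!r}", stacklevel=2)
            continue
        rs = [pearson_correlation(x, tf[a].to_numpy(dtype=float)) for a in tf.columns]
        worst = min(abs(r) for r in rs)
        if worst >= cfg.primary_r_threshold:
            snr = float(stability.get(col, np.inf)) if stability is not None else np.inf
            (increasing if np.mean(rs) > 0 else decreasing).append((snr, worst, col))
    key = lambda t: (-t[0], -t[1], t[2])
    increasing.sort(key=key)
    decreasing.sort(key=key)

    half = max(1, cfg.max_primary_features // 2)
    kept = [c for *_, c in increasing[:half]] + [c for *_, c in decreasing[:half]]
    # fill remaining slots from whichever class has spares
    spares = [c for *_, c in increasing[half:]] + [c for *_, c in decreasing[half:]]
    kept.extend(spares[: cfg.max_primary_features - len(kept)])
    logger.info("primary screen kept %d of %d features: %s", len(kept), fm.shape[1], kept)
    return kept


# ---------------------------------------------------------------------------
# Stage 2: term enumeration and screening
# ---------------------------------------------------------------------------

def enumerate_ratio_terms(features: Sequence[str], cfg: SearchConfig | None = None) -> list[MonomialTerm]:
    """All distinct signed-exponent monomials over ``features``.

    Per-feature exponents lie in [-max_degree, +max_degree], the total
    absolute degree is capped by ``total_degree_cap``, and the empty monomial
    is excluded.  Order is canonical: features sorted lexicographically,
    exponent vectors in lexicographic order.
    """
    cfg = cfg or SearchConfig()
    feats = sorted(set(features))
    if not feats:
        raise SearchError("no features to enumerate terms over")
    terms: list[MonomialTerm] = []
    rng = range(-cfg.max_degree, cfg.max_degree + 1)

    def rec(i: int, budget: int, acc: list[tuple[str, int]]) -> None:
        if i == len(feats):
            if acc:
                terms.append(MonomialTerm(dict(acc)))
            return
        for e in rng:
            if abs(e) > budget:
                continue
            if e != 0:
                acc.append((feats[i], e))
                rec(i + 1, budget - abs(e), acc)
                acc.pop()
            else:
                rec(i + 1, budget, acc)

    rec(0, cfg.total_degree_cap, [])
    return terms


def screen_terms(
    terms: Sequence[MonomialTerm],
    fm: pd.DataFrame,
    targets,
    cfg: SearchConfig | None = None,
) -> list[MonomialTerm]:
    """Stage 2: terms whose sample vector has r > r_threshold with every analyte.

    The correlation is signed — a term anti-proportional to concentration is
    rejected even though its reciprocal would pass.  Terms that evaluate to a
    constant vector are skipped.
    """
    cfg = cfg or SearchConfig()
    tf = _targets_frame(targets)
    if not fm.index.equals(tf.index):
        tf = tf.loc[fm.index]
    t_cols = {a: tf[a].to_numpy(dtype=float) for a in tf.columns}
    kept: list[MonomialTerm] = []
    for term in terms:
        v = term.evaluate_matrix(fm)
        if not np.all(np.isfinite(v)) or np.ptp(v) == 0.0:
            continue
        if all(pearson_correlation(v, y) > cfg.r_threshold for y in t_cols.values()):
            kept.append(term)
    return kept


# ---------------------------------------------------------------------------
# Stage 3: simplex-constrained least squares (reduced-gradient solver)
# ---------------------------------------------------------------------------

def _simplex_lsq(A: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int | None = None):
    """Minimise ||A w - y||^2 subject to w >= 0 and sum(w) = 1.

    Primal active-set reduced-gradient iteration: on the current working set
    the equality-constrained problem is solved exactly through its KKT
    system; infeasible steps are cut at the first blocking bound (exact line
    search — the objective is quadratic, so the constrained Newton step needs
    no backtracking), and bound multipliers decide which zeroed weight may
    re-enter.  Finite convergence for this convex QP.

    Returns (w, objective).
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n, t = A.shape
    if y.shape != (n,):
        raise SearchError("target length does not match the term matrix")
    if t == 1:
        w = np.array([1.0])
        r = A[:, 0] - y
        return w, float(r @ r)
    G = 2.0 * A.T @ A  # Hessian
    c = 2.0 * A.T @ y
    if max_iter is None:
        max_iter = 10 * t * t + 200

    def solve_eq(active: np.ndarray) -> np.ndarray:
        """Equality-constrained minimiser over the working set (KKT, min-norm)."""
        k = int(active.sum())
        idx = np.nonzero(active)[0]
        K = np.zeros((k + 1, k + 1))
        K[:k, :k] = G[np.ix_(idx, idx)]
        K[:k, k] = 1.0
        K[k, :k] = 1.0
        rhs = np.concatenate([c[idx], [1.0]])
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        w = np.zeros(t)
        w[idx] = sol[:k]
        return w

    def objective(w: np.ndarray) -> float:
        r = A @ w - y
        return float(r @ r)

    w = np.full(t, 1.0 / t)
    active = np.ones(t, dtype=bool)
    for _ in range(max_iter):
        w_star = solve_eq(active)
        if np.all(w_star[active] >= -1e-12):
            w_new = np.clip(w_star, 0.0, None)
            s = w_new.sum()
            w_new = w_new / s if s > 0 else np.full(t, 1.0 / t)
            # optimality over zeroed weights: bound multiplier = g_j - lambda
            g = G @ w_new - c
            lam = float(np.mean(g[active])) if active.any() else 0.0
            inactive = ~active
            viol = inactive & (g - lam < -1e-10 * max(1.0, abs(lam)))
            w = w_new
            if not viol.any():
                break
            active[np.argmin(np.where(viol, g - lam, np.inf))] = True
        else:
            # exact line search from w toward w_star, cut at first bound
            d = w_star - w
            neg = d < -1e-15
            with np.errstate(divide="ignore", invalid="ignore"):
                alphas = np.where(neg, -w / d, np.inf)
            j = int(np.argmin(alphas))
            alpha = float(min(1.0, max(0.0, alphas[j])))
            w = w + alpha * d
            w[j] = 0.0
            active[j] = False
            if not active.any():  # numerical corner: restart from a vertex
                active[int(np.argmax(w_star))] = True
                w = np.zeros(t)
                w[active] = 1.0
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    return w, objective(w)


def fit_term_weights(
    terms: Sequence[MonomialTerm],
    fm: pd.DataFrame,
    target: Sequence[float],
    cfg: SearchConfig | None = None,
) -> CompositeFeature:
    """Fit simplex weights so sum_t w_t * term_t(sample) tracks ``target``.

    The returned composite has scale 1; its value at the fitted weights
    minimises the least-squares deviation from the target over the simplex.
    """
    cfg = cfg or SearchConfig()
    terms = list(terms)
    if not terms:
        raise SearchError("no terms to fit weights over")
    y = np.asarray(target, dtype=float)
    A = np.column_stack([t.evaluate_matrix(fm) for t in terms])
    if not np.all(np.isfinite(A)):
        raise SearchError("non-finite term values during weight fitting")
    if any(np.ptp(A[:, j]) == 0.0 and np.all(A[:, j] == 0.0) for j in range(A.shape[1])):
        raise SearchError("degenerate all-zero term column")
    w, _ = _simplex_lsq(A, y)
    return CompositeFeature(terms=terms, weights=w, scale=1.0)


# ---------------------------------------------------------------------------
# Full stage 1-3 pipeline
# ---------------------------------------------------------------------------

def build_composite(
    fm: pd.DataFrame,
    targets,
    cfg: SearchConfig | None = None,
    reference_analyte: str | None = None,
    stability: pd.Series | None = None,
    feature_rel_sem: pd.DataFrame | None = None,
) -> tuple[CompositeFeature, dict]:
    """Run screening, enumeration and weight fitting; return (composite, info).

    The fitting target is the reference analyte's concentration rescaled to
    unit mean (all analytes are proportional on a lockstep dilution design,
    so the choice only fixes a scale, which the coefficient stage absorbs).
    Candidate terms are first normalised to unit sample mean so the subset
    search compares them scale-invariantly; the normalisations are folded
    back into the returned composite's weights and scale.

    Term subsets are scored by leave-one-out prediction error plus, when
    ``feature_rel_sem`` (per-sample relative standard error of each feature,
    estimable from replicate scatter) is available, the delta-method
    variance the features' measurement noise propagates into the composite.
    The in-sample objective alone would reward both fitting sample noise
    and stacking high exponents on noisy features; neither improves
    prediction of new samples.
    """
    cfg = cfg or SearchConfig()
    tf = _targets_frame(targets)
    if not fm.index.equals(tf.index):
        tf = tf.loc[fm.index]
    if reference_analyte is None:
        reference_analyte = str(tf.columns[0])
    if reference_analyte not in tf.columns:
        raise SearchError(f"reference analyte {reference_analyte!r} not in targets")
    y = tf[reference_analyte].to_numpy(dtype=float)
    tau = y / y.mean()

    feats = screen_primary_features(fm, tf, cfg, stability=stability)
    if not feats:
        raise SearchError(
            "no features passed primary screening; lower primary_r_threshold "
            "or check the dilution design"
        )
    candidates = enumerate_ratio_terms(feats, cfg)
    retained = screen_terms(candidates, fm, tf, cfg)
    if not retained:
        raise SearchError("no ratio terms passed the r_threshold screen")

    # unit-mean term columns -> scale-invariant ranking and subset search
    cols, scales, pool_terms = [], [], []
    for term in retained:
        v = term.evaluate_matrix(fm)
        m = float(v.mean())
        if m <= 0:
            continue
        cols.append(v / m)
        scales.append(m)
        pool_terms.append(term)
    U = np.column_stack(cols)

    resid = np.sum((U - tau[:, None]) ** 2, axis=0)
    order = np.argsort(resid, kind="stable")
    # drop near-duplicate columns so the pool is diverse
    pool: list[int] = []
    for j in order:
        if len(pool) >= cfg.max_candidate_terms:
            break
        if all(np.max(np.abs(U[:, j] - U[:, k])) > 1e-10 for k in pool):
            pool.append(int(j))

    n = U.shape[0]
    use_loo = n >= 4
    if feature_rel_sem is not None:
        feature_rel_sem = feature_rel_sem.loc[fm.index]

    def loo_score(cols: np.ndarray) -> float:
        err = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            w_i, _ = _simplex_lsq(cols[keep], tau[keep])
            err += float((cols[i] @ w_i - tau[i]) ** 2)
        return err

    def noise_score(subset: tuple[int, ...], w: np.ndarray) -> float:
        """Delta-method variance of K = sum w_t U_t from feature noise,
        summed over samples (features independent, terms correlated
        through shared features)."""
        if feature_rel_sem is None:
            return 0.0
        var = np.zeros(n)
        feats = sorted({f for j in subset for f in pool_terms_by_col[j].features()})
        for f in feats:
            dK = np.zeros(n)
            for wt, j in zip(w, subset):
                e = dict(pool_terms_by_col[j].exponents).get(f, 0)
                if e:
                    dK += wt * U[:, j] * e
            var += (dK * feature_rel_sem[f].to_numpy(dtype=float)) ** 2
        return float(var.sum())

    pool_terms_by_col = {j: pool_terms[j] for j in pool}
    best = None  # (score, objective, size, subset, weights)
    for size in range(1, min(cfg.max_terms, len(pool)) + 1):
        for subset in itertools.combinations(pool, size):
            cols = U[:, subset]
            w, obj = _simplex_lsq(cols, tau)
            score = (loo_score(cols) if use_loo else obj) + noise_score(subset, w)
            key = (score, obj, size, subset)
            if best is None or key < best[:4]:
                best = (score, obj, size, subset, w)
    assert best is not None
    _, obj, _, subset, w = best
    sel_terms = [pool_terms[j] for j in subset]
    sel_scales = np.array([scales[j] for j in subset])

    # fold unit-mean normalisation back: K = sum_t (w_t/m_t) * raw_term_t
    v = w / sel_scales
    total = float(v.sum())
    composite = CompositeFeature(terms=sel_terms, weights=v / total, scale=total)
    info = {
        "reference_analyte": reference_analyte,
        "primary_features": feats,
        "n_candidate_terms": len(candidates),
        "n_retained_terms": len(retained),
        "selected_terms": [str(t) for t in sel_terms],
        "objective": obj,
    }
    logger.info(
        "composite search: %d candidates -> %d retained -> %d selected (objective %.3e)",
        len(candidates), len(retained), len(sel_terms), obj,
    )
    return composite, info
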