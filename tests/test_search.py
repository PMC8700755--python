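"""Composite-feature search: correlation screening, term enumeration and
the simplex-constrained weight fit, each checked against independent
oracles (hand computation, brute-force enumeration, grid search)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seraquant as sq
from seraquant.search import SearchError, TermEvaluationError, _simplex_lsq


class TestPearson:
    def test_perfect_affine(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert sq.pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert sq.pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # product-moment formula by hand: cov=1.5, sx^2=1, sy^2=7/3
        assert sq.pearson_correlation([1, 2, 3], [1, 2, 4]) == pytest.approx(
            3 / np.sqrt(2 * 42 / 9), abs=1e-10
        )
        assert sq.pearson_correlation([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820, abs=5e-5)

    def test_invalid_inputs(self):
        with pytest.raises(SearchError):
            sq.pearson_correlation([1, 2], [1, 2])
        with pytest.raises(SearchError):
            sq.pearson_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(SearchError):
            sq.pearson_correlation([1, 2, 3], [1, 2])

    @settings(deadline=None, database=None, derandomize=True, max_examples=40)
    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-50, max_value=50),
    )
    def test_invariant_under_positive_affine_maps(self, a, b):
        """The rationale for searching only x and / combinations."""
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r0 = sq.pearson_correlation(x, y)
        assert sq.pearson_correlation(a * x + b, y) == pytest.approx(r0, abs=1e-9)


class TestMonomialTerm:
    def test_canonical_form_and_equality(self):
        t1 = sq.MonomialTerm({"H20": 2, "S2": -2, "H49": 0})
        t2 = sq.MonomialTerm({"S2": -2, "H20": 2})
        assert t1 == t2
        assert t1.total_degree == 4
        assert str(t1) == "H20^2/(S2^2)"

    def test_evaluate(self):
        t = sq.MonomialTerm({"a": 1, "b": -1})
        assert t.evaluate({"a": 6.0, "b": 2.0}) == pytest.approx(3.0)
        with pytest.raises(TermEvaluationError):
            t.evaluate({"a": 6.0, "b": 0.0})
        with pytest.raises(TermEvaluationError):
            t.evaluate({"a": 6.0})


def brute_force_terms(features, max_degree, cap):
    """Independent enumeration oracle: raw product over exponent grids."""
    out = set()
    for exps in itertools.product(range(-max_degree, max_degree + 1), repeat=len(features)):
        if any(exps) and sum(abs(e) for e in exps) <= cap:
            out.add(tuple(sorted((f, e) for f, e in zip(features, exps) if e)))
    return out


class TestEnumerateTerms:
    def test_single_feature_degree_one(self):
        cfg = sq.SearchConfig(max_degree=1, total_degree_cap=1)
        terms = sq.enumerate_ratio_terms(["x"], cfg)
        assert {str(t) for t in terms} == {"x", "1/(x)"}

    def test_two_features_count_twelve(self):
        cfg = sq.SearchConfig(max_degree=2, total_degree_cap=2)
        assert len(sq.enumerate_ratio_terms(["a", "b"], cfg)) == 12

    @pytest.mark.parametrize("nfeat", [1, 2, 3])
    @pytest.mark.parametrize("cap", [1, 2, 3, 4])
    def test_matches_brute_force(self, nfeat, cap):
        feats = ["a", "b", "c"][:nfeat]
        for max_degree in (1, 2):
            cfg = sq.SearchConfig(max_degree=max_degree, total_degree_cap=cap)
            terms = sq.enumerate_ratio_terms(feats, cfg)
            assert {t.exponents for t in terms} == brute_force_terms(feats, max_degree, cap)
            assert len(terms) == len(set(terms))  # distinct

    def test_canonical_composite_terms_enumerated(self):
        """The three published ratio terms over H20,H49,S2,S42,S49 appear."""
        cfg = sq.SearchConfig(max_degree=2, total_degree_cap=5)
        terms = set(sq.enumerate_ratio_terms(["H20", "H49", "S2", "S42", "S49"], cfg))
        for ref in sq.reference_composite().terms:
            assert ref in terms

    def test_deterministic_order(self):
        cfg = sq.SearchConfig(max_degree=2, total_degree_cap=3)
        a = sq.enumerate_ratio_terms(["b", "a"], cfg)
        b = sq.enumerate_ratio_terms(["a", "b"], cfg)
        assert a == b


def lockstep_fixture(n=5, seed=0):
    """Feature matrix + proportional two-analyte targets on a dilution grid."""
    d = 1.0 / np.array([2.0, 3.0, 5.0, 7.0, 10.0])[:n]
    rng = np.random.default_rng(seed)
    fm = pd.DataFrame(
        {
            "F1": 3.0 * d,          # proportional to concentration
            "F2": 0.7 * np.ones(n) + 0.0 * d,  # constant -> dropped
            "F3": 1.3 / (d + 0.2),  # anti-monotone (background-like)
            "F4": rng.normal(10, 0.1, n),  # noise feature
        },
        index=[f"dil{i}" for i in range(n)],
    )
    targets = pd.DataFrame({"B1": 40 * d, "B2": 7 * d}, index=fm.index)
    return fm, targets


class TestScreening:
    def test_proportional_feature_selected_noise_rejected(self):
        fm, targets = lockstep_fixture()
        with pytest.warns(UserWarning, match="constant"):
            kept = sq.screen_primary_features(fm, targets)
        assert "F1" in kept
        assert "F3" in kept  # anti-correlated background class
        assert "F4" not in kept

    def test_pure_noise_rejected_under_null(self):
        """P(|r| > 0.999 with n=6) is ~0 for independent noise."""
        rng = np.random.default_rng(7)
        d = 1.0 / np.array([2, 3, 4, 5, 7, 10.0])
        hits = 0
        for _ in range(500):
            x = rng.normal(size=6)
            if abs(sq.pearson_correlation(x, d)) > 0.999:
                hits += 1
        assert hits == 0

    def test_term_screen_signed(self):
        fm, targets = lockstep_fixture()
        cfg = sq.SearchConfig()
        good = sq.MonomialTerm({"F1": 1})
        bad = sq.MonomialTerm({"F1": -1})
        kept = sq.screen_terms([good, bad], fm, targets, cfg)
        assert kept == [good]

    def test_retained_set_invariant_to_analyte_relabeling(self):
        fm, targets = lockstep_fixture()
        cfg = sq.SearchConfig(max_degree=1, total_degree_cap=2)
        terms = sq.enumerate_ratio_terms(["F1", "F3"], cfg)
        kept1 = sq.screen_terms(terms, fm, targets, cfg)
        relabeled = targets.rename(columns={"B1": "B2", "B2": "B1"})
        kept2 = sq.screen_terms(terms, fm, relabeled, cfg)
        assert kept1 == kept2

    def test_misaligned_samples_rejected(self):
        fm, targets = lockstep_fixture()
        targets.index = ["x0", "x1", "x2", "x3", "x4"]
        with pytest.raises(SearchError):
            sq.screen_primary_features(fm, targets)


def grid_search_simplex(A, y, step=1e-3):
    """Brute-force oracle over the 2-simplex at the given resolution."""
    g = np.arange(0.0, 1.0 + step / 2, step)
    w1, w2 = np.meshgrid(g, g, indexing="ij")
    keep = (w1 + w2) <= 1.0 + 1e-12
    W = np.column_stack([w1[keep], w2[keep], 1.0 - w1[keep] - w2[keep]])
    R = W @ A.T - y
    return float(np.min(np.sum(R * R, axis=1)))


class TestWeightFit:
    def test_single_term_weight_is_one(self):
        fm, targets = lockstep_fixture()
        cf = sq.fit_term_weights([sq.MonomialTerm({"F1": 1})], fm, targets["B1"].to_numpy())
        assert cf.weights.tolist() == [1.0]

    def test_two_terms_exact_recovery(self):
        """Term 1 equals the target, term 2 is orthogonal noise -> w ~ [1, 0]."""
        rng = np.random.default_rng(1)
        y = 1.0 / np.array([2, 3, 5, 7, 10.0])
        noise = rng.normal(size=5)
        noise -= noise @ y / (y @ y) * y  # orthogonalise
        fm = pd.DataFrame({"T1": y, "T2": 5.0 + noise}, index=[f"s{i}" for i in range(5)])
        cf = sq.fit_term_weights(
            [sq.MonomialTerm({"T1": 1}), sq.MonomialTerm({"T2": 1})], fm, y
        )
        assert cf.weights[0] == pytest.approx(1.0, abs=1e-6)
        assert cf.weights[1] == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        A = rng.uniform(0.5, 2.0, size=(7, 3))
        y = rng.uniform(0.5, 2.0, size=7)
        w, obj = _simplex_lsq(A, y)
        assert w.min() >= 0 and w.sum() == pytest.approx(1.0, abs=1e-9)
        assert obj <= grid_search_simplex(A, y) + 1e-6

    def test_no_vertex_beats_the_mixture(self):
        rng = np.random.default_rng(9)
        A = rng.uniform(0.5, 2.0, size=(6, 4))
        y = A @ np.array([0.4, 0.3, 0.2, 0.1]) + rng.normal(0, 0.05, 6)
        _, obj = _simplex_lsq(A, y)
        for j in range(4):
            r = A[:, j] - y
            assert obj <= float(r @ r) + 1e-10


class TestEvaluateComposite:
    def test_all_ones(self):
        ref = sq.reference_composite()  # weights 1/3, scale 3 (unit-weight sum)
        feats = {f: 1.0 for f in ["H20", "H49", "S2", "S42", "S49"]}
        assert sq.evaluate_composite(ref, feats) == pytest.approx(3.0)
        # as a plain weighted average (scale 1) the same terms give K = 1
        avg = sq.CompositeFeature(ref.terms, np.full(3, 1 / 3), scale=1.0)
        assert sq.evaluate_composite(avg, feats) == pytest.approx(1.0)

    def test_weighted_mean(self):
        terms = [sq.MonomialTerm({c: 1}) for c in "abc"]
        cf = sq.CompositeFeature(terms, np.array([0.5, 0.5, 0.0]))
        assert cf.evaluate({"a": 2.0, "b": 3.0, "c": 4.0}) == pytest.approx(2.5)

    def test_zero_denominator_raises(self):
        cf = sq.reference_composite()
        feats = {"H20": 0.0, "H49": 1.0, "S2": 1.0, "S42": 1.0, "S49": 1.0}
        with pytest.raises(TermEvaluationError, match="H20"):
            sq.evaluate_composite(cf, feats)

    def test_simplex_invariants_enforced(self):
        terms = [sq.MonomialTerm({"a": 1})]
        with pytest.raises(SearchError):
            sq.CompositeFeature(terms * 2, np.array([0.7, 0.7]))
        with pytest.raises(SearchError):
            sq.CompositeFeature(terms, np.array([-0.2]))


def test_full_search_on_lockstep_data_tracks_concentration():
    """K fitted on noiseless lockstep features correlates with concentration
    essentially perfectly."""
    fm, targets = lockstep_fixture()
    fm = fm.drop(columns=["F2", "F4"])
    composite, info = sq.build_composite(fm, targets)
    K = composite.evaluate_matrix(fm)
    r = sq.pearson_correlation(K, targets["B1"].to_numpy())
    assert r > 0.999999
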