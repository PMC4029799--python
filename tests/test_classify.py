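"""Naive Bayes screeners, LOOCV, the weighted score and subset search.

The LOOCV path and the exhaustive search are each checked against
independent brute-force oracles implemented here with plain loops.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import wfc
from wfc.classify import (
    ConfusionCounts,
    SubsetSearchScreener,
    TissueGaussianNB,
    exhaustive_search,
    loo_predict,
    loocv,
    restrict_pool,
    score,
)
from wfc.features import feature_ids


class TestGaussianNB:
    def test_hand_arithmetic_two_class(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        y = np.array([0, 0, 1, 1])
        m = TissueGaussianNB().fit(X, y)
        assert m.theta_.ravel() == pytest.approx([1.0, 11.0])
        assert m.var_.ravel() == pytest.approx([1.0, 1.0])  # population variance

    def test_priors_from_class_frequencies(self):
        X = np.zeros((10, 1)) + np.arange(10)[:, None]
        y = np.array([0] * 6 + [1] * 4)
        m = TissueGaussianNB().fit(X, y)
        assert m.class_prior_ == pytest.approx([0.6, 0.4])

    def test_duplicated_table_same_parameters(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        y = rng.random(20) < 0.5
        a = TissueGaussianNB().fit(X, y)
        b = TissueGaussianNB().fit(np.vstack([X, X]), np.concatenate([y, y]))
        assert np.allclose(a.theta_, b.theta_)
        assert np.allclose(a.var_, b.var_)
        assert np.allclose(a.class_prior_, b.class_prior_)

    def test_midpoint_decision_boundary(self):
        # equal variances and priors: boundary at the midpoint 5
        X = np.array([[-1.0], [1.0], [9.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        m = TissueGaussianNB().fit(X, y)
        assert m.predict([[2.0]])[0] == 0
        assert m.predict([[7.0]])[0] == 1

    def test_tie_goes_to_suspicious(self):
        X = np.array([[-1.0], [1.0], [9.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        m = TissueGaussianNB().fit(X, y)
        assert m.predict([[5.0]])[0] == 1  # exactly on the boundary

    def test_uninformative_feature_does_not_change_decision(self):
        rng = np.random.default_rng(1)
        X1 = np.concatenate([rng.normal(0, 1, 20), rng.normal(6, 1, 20)])[:, None]
        noise = np.tile(rng.standard_normal(20), 2)[:, None]  # identical per class
        y = np.array([0] * 20 + [1] * 20)
        m1 = TissueGaussianNB().fit(X1, y)
        m2 = TissueGaussianNB().fit(np.hstack([X1, noise]), y)
        q = np.linspace(-3, 9, 25)[:, None]
        q2 = np.hstack([q, np.zeros_like(q)])
        assert np.array_equal(m1.predict(q), m2.predict(q2))

    def test_small_class_errors(self):
        with pytest.raises(ValueError):
            TissueGaussianNB().fit(np.zeros((3, 1)) + np.arange(3)[:, None], [0, 0, 1])

    def test_matches_sklearn_gaussian_nb(self):
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(5)
        X = rng.standard_normal((80, 3)) + np.where(rng.random(80) < 0.5, 0, 2)[:, None]
        y = rng.random(80) < 0.4
        ours = TissueGaussianNB().fit(X, y)
        theirs = GaussianNB().fit(X, y)
        assert np.array_equal(ours.predict(X), theirs.predict(X))


def _naive_loocv(X, y):
    """Independent oracle: per-fold Gaussian NB with explicit loops."""
    X, y = np.asarray(X, float), np.asarray(y, bool)
    n = len(y)
    preds = np.zeros(n, bool)
    floor = np.maximum(1e-9 * X.var(axis=0), 1e-12)
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        Xi, yi = X[keep], y[keep]
        post = []
        for cls in (False, True):
            sel = Xi[yi == cls]
            mu, var = sel.mean(0), np.maximum(sel.var(0), floor)
            ll = -0.5 * np.sum(np.log(2 * np.pi * var) + (X[i] - mu) ** 2 / var)
            post.append(np.log(len(sel) / (n - 1)) + ll)
        preds[i] = post[1] >= post[0]
    return preds


class TestLOOCV:
    def test_perfect_separation_classifies_all(self):
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(50, 0.1, 10)])[:, None]
        labels = ["normal"] * 10 + ["mass_benign"] * 10
        df = pd.DataFrame({"haar:M-a1": X.ravel(), "label": labels})
        c = loocv(df, ["haar:M-a1"])
        assert (c.ntp, c.ntn, c.nfp, c.nfn) == (10, 10, 0, 0)

    def test_counts_conserve_n_and_deterministic(self, small_table):
        c1 = loocv(small_table, ["haar:K-d1", "haar:S-d1"])
        c2 = loocv(small_table, ["haar:K-d1", "haar:S-d1"])
        assert c1.n == len(small_table)
        assert (c1.ntp, c1.ntn, c1.nfp, c1.nfn) == (c2.ntp, c2.ntn, c2.nfp, c2.nfn)

    def test_vectorized_path_equals_naive_refit_oracle(self):
        rng = np.random.default_rng(3)
        n = 50
        y = rng.random(n) < 0.45
        X = rng.standard_normal((n, 3)) + np.where(y, 0.8, 0.0)[:, None]
        assert np.array_equal(loo_predict(X, y), _naive_loocv(X, y))

    def test_two_sample_class_degenerate_folds_handled(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1], [5.2], [4.9]])
        labels = ["mass_benign"] * 2 + ["normal"] * 4
        df = pd.DataFrame({"haar:M-a1": X.ravel(), "label": labels})
        c = loocv(df, ["haar:M-a1"])
        assert c.n == 6  # no fold crashes even though one class has 2 samples


class TestScore:
    def test_limit_cases(self):
        c = ConfusionCounts(ntp=7, ntn=3, nfp=2, nfn=1)
        assert score(c, w=1.0) == 7
        assert score(c, w=0.0) == 3

    def test_weighted_arithmetic(self):
        c = ConfusionCounts(ntp=644, ntn=390, nfp=0, nfn=0)
        assert score(c, w=0.995) == pytest.approx(642.73)

    def test_monotone_in_counts(self):
        base = score(ConfusionCounts(10, 10, 0, 0), w=0.995)
        assert score(ConfusionCounts(11, 10, 0, 0), w=0.995) > base
        assert score(ConfusionCounts(10, 11, 0, 0), w=0.995) > base


class TestRestrictPool:
    def test_pool_is_64_of_one_basis_and_two_moments(self):
        pool = restrict_pool(feature_ids("bior2.2"), "bior2.2", ("M", "S"))
        assert len(pool) == 64
        assert all(f.basis == "bior2.2" and f.moment in ("M", "S") for f in pool)
        assert all(f.map in ("a", "h", "v", "d") for f in pool)  # raw excluded

    def test_disjoint_moment_pairs(self):
        a = set(restrict_pool(feature_ids("haar"), "haar", ("SD", "K")))
        b = set(restrict_pool(feature_ids("haar"), "haar", ("M", "S")))
        assert not (a & b)

    def test_union_over_pairs_covers_128(self):
        pools = [
            restrict_pool(feature_ids("haar"), "haar", pair)
            for pair in combinations(("M", "SD", "S", "K"), 2)
        ]
        assert len(set().union(*pools)) == 128

    def test_identical_pair_rejected(self):
        with pytest.raises(ValueError):
            restrict_pool(feature_ids("haar"), "haar", ("M", "M"))


def _bruteforce_search(table, pool, target, max_k, w):
    """Independent re-enumeration using the naive LOOCV oracle."""
    from wfc.labels import target_vector

    y = target_vector(table["label"], target)
    pool = sorted(pool, key=lambda f: f.encode())
    best = None
    for k in range(1, max_k + 1):
        for subset in combinations(pool, k):
            X = table[[f.encode() for f in subset]].to_numpy()
            pred = _naive_loocv(X, y)
            ntp = int((pred & y).sum())
            ntn = int((~pred & ~y).sum())
            s = w * ntp + (1 - w) * ntn
            key = (s, ntn)
            if best is None or key > best[0]:
                best = (key, subset)
    return best


class TestExhaustiveSearch:
    def test_perfectly_separating_singleton_selected(self, toy_gaussian_table):
        pool = [wfc.FeatureId.decode(c) for c in toy_gaussian_table.columns
                if c not in ("image_id", "label")][:5] + [wfc.FeatureId.decode("haar:S-d2")]
        res = exhaustive_search(toy_gaussian_table, pool, target="any", max_k=3)
        assert res.feature_set == (wfc.FeatureId.decode("haar:S-d2"),)
        assert res.counts.nfn == 0 and res.counts.nfp == 0

    def test_equals_bruteforce_reenumeration(self, toy_gaussian_table):
        pool = [wfc.FeatureId.decode(c) for c in toy_gaussian_table.columns
                if c not in ("image_id", "label")]
        assert len(pool) == 10
        res = exhaustive_search(toy_gaussian_table, pool, target="any", max_k=2)
        (bscore, bntn), bset = _bruteforce_search(
            toy_gaussian_table, pool, "any", 2, 0.995
        )
        assert res.score == pytest.approx(bscore)
        assert res.counts.ntn == bntn
        assert res.feature_set == bset

    def test_pool_order_invariance(self, toy_gaussian_table):
        pool = [wfc.FeatureId.decode(c) for c in toy_gaussian_table.columns
                if c not in ("image_id", "label")]
        a = exhaustive_search(toy_gaussian_table, pool, max_k=2)
        b = exhaustive_search(toy_gaussian_table, pool[::-1], max_k=2)
        assert a.feature_set == b.feature_set and a.score == b.score

    def test_superset_pool_never_scores_lower(self, small_table):
        ids = feature_ids("haar")
        pool_small = restrict_pool(ids, "haar", ("S", "K"))[:10]
        pool_big = restrict_pool(ids, "haar", ("S", "K"))[:20]
        a = exhaustive_search(small_table, pool_small, max_k=2)
        b = exhaustive_search(small_table, pool_big, max_k=2)
        assert b.score >= a.score


class TestScreenerEstimator:
    def test_fit_predict_round_trip(self, toy_gaussian_table):
        scr = SubsetSearchScreener(basis="haar", moments=("S", "K"), max_k=2)
        scr.fit(toy_gaussian_table)
        preds = scr.predict(toy_gaussian_table)
        assert preds.dtype == bool and len(preds) == len(toy_gaussian_table)
        # the separating feature must be in the chosen subset
        assert "haar:S-d2" in [f.encode() for f in scr.best_feature_set_]

    def test_sklearn_params_clone(self):
        from sklearn.base import clone

        scr = SubsetSearchScreener(basis="db2", moments=("M", "S"), w=0.9)
        assert clone(scr).get_params()["w"] == 0.9


def test_searched_single_basis_screener_is_highly_sensitive():
    """End-to-end separability: on a balanced 200-phantom cohort the
    searched single-basis classifier recovers nearly all abnormalities."""
    from wfc.pipeline import phantom_feature_table

    table = phantom_feature_table(
        n=200, prevalence=0.5, seed=1, bases=["bior2.2"],
        template=wfc.PhantomSpec(image_size=512), size=512,
    )
    res = wfc.search_basis(table, "bior2.2", moments="auto", target="any")
    assert res.sensitivity >= 0.95
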