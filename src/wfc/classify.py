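"""Naive Bayes screening classifiers and exhaustive feature-subset search.

A screener is a Gaussian naive Bayes model over 1-3 wavelet-moment
features, separating images into *normal* vs *suspicious* (or, for tuned
classifiers, one lesion type vs everything else).  Evaluation is
leave-one-out cross-validation (LOOCV): each image is predicted by a
model fit on all the others.

Feature subsets are chosen by exhaustively scoring every combination of
one, two or three features from a restricted 64-feature pool (one basis,
two of the four moment types, the 32 wavelet maps) with the weighted
count score

    s = w * NTP + (1 - w) * NTN,        w = 0.995 by default,

which prioritizes sensitivity: in a triage tool, images called normal
leave the queue, so false negatives are the costly error.  Ties on the
score are broken by the higher true-negative count, then by feature-id
order.

The LOOCV inner loop is exact but vectorized: per-fold class statistics
are obtained by downdating the full-sample sums, so scoring one subset
costs a handful of array operations rather than n model fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import MOMENTS, FeatureId, feature_ids
from .labels import target_vector

__all__ = [
    "ConfusionCounts",
    "TissueGaussianNB",
    "fit_gaussian_nb",
    "predict_table",
    "loocv",
    "loo_predict",
    "score",
    "restrict_pool",
    "SearchResult",
    "exhaustive_search",
    "SubsetSearchScreener",
]

#: Relative variance floor: per-feature class variances are clipped at
#: VAR_FLOOR_FRAC times the feature's variance over all samples.
VAR_FLOOR_FRAC = 1e-9
_VAR_FLOOR_ABS = 1e-12


@dataclass(frozen=True)
class ConfusionCounts:
    """Aggregate true/false positive/negative counts of one evaluation."""

    ntp: int
    ntn: int
    nfp: int
    nfn: int

    def __post_init__(self):
        if min(self.ntp, self.ntn, self.nfp, self.nfn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.ntp + self.ntn + self.nfp + self.nfn

    @property
    def sensitivity(self) -> float:
        return self.ntp / (self.ntp + self.nfn)

    @property
    def specificity(self) -> float:
        return self.ntn / (self.ntn + self.nfp)

    @property
    def classification_rate(self) -> float:
        return (self.ntp + self.ntn) / self.n


def score(counts: ConfusionCounts, w: float = 0.995) -> float:
    """Weighted selection score ``w*NTP + (1-w)*NTN``."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    return w * counts.ntp + (1.0 - w) * counts.ntn


class TissueGaussianNB(BaseEstimator, ClassifierMixin):
    """Gaussian naive Bayes with population variances and a suspicious tie rule.

    Class-conditional densities are independent univariate Gaussians with
    empirical (population, divide-by-n) means and variances and empirical
    class priors.  Posterior ties go to the positive (suspicious) class:
    in a triage setting ambiguity must not discharge an image.

    Fitted attributes: ``classes_`` (negative, positive), ``theta_`` and
    ``var_`` of shape (2, n_features), ``class_prior_``.
    """

    def __init__(self, var_floor_frac: float = VAR_FLOOR_FRAC):
        self.var_floor_frac = var_floor_frac

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2D with one row per label")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("exactly two classes required")
        floor = np.maximum(self.var_floor_frac * X.var(axis=0), _VAR_FLOOR_ABS)
        theta, var, prior = [], [], []
        for c in classes:
            sel = X[y == c]
            if sel.shape[0] < 2:
                raise ValueError(f"class {c!r} has fewer than 2 samples")
            theta.append(sel.mean(axis=0))
            v = sel.var(axis=0)
            if np.any(v < floor):
                warnings.warn("zero-variance feature in a class; variance floored")
            var.append(np.maximum(v, floor))
            prior.append(sel.shape[0] / X.shape[0])
        self.classes_ = classes
        self.theta_ = np.array(theta)
        self.var_ = np.array(var)
        self.class_prior_ = np.array(prior)
        self.n_features_in_ = X.shape[1]
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape}")
        jll = np.empty((X.shape[0], 2))
        for k in range(2):
            ll = -0.5 * (
                np.log(2 * np.pi * self.var_[k])
                + (X - self.theta_[k]) ** 2 / self.var_[k]
            ).sum(axis=1)
            jll[:, k] = np.log(self.class_prior_[k]) + ll
        return jll

    def predict(self, X):
        jll = self._joint_log_likelihood(X)
        # tie -> positive (suspicious) class, i.e. classes_[1]
        return self.classes_[(jll[:, 1] >= jll[:, 0]).astype(int)]


def _columns(feature_set: Sequence) -> List[str]:
    return [f.encode() if isinstance(f, FeatureId) else str(f) for f in feature_set]


def fit_gaussian_nb(table: pd.DataFrame, feature_set: Sequence, target: str = "any"):
    """Fit a :class:`TissueGaussianNB` on a feature table.

    ``target`` names the positive partition of the five-way labels
    (``'any'``, ``'calcification'`` or ``'mass'``).  Returns the fitted
    model; its feature order is recorded in ``feature_ids_``.
    """
    cols = _columns(feature_set)
    y = target_vector(table["label"], target)
    model = TissueGaussianNB().fit(table[cols].to_numpy(), y)
    model.feature_ids_ = tuple(cols)
    model.target_ = target
    return model


def predict_table(model, table: pd.DataFrame) -> np.ndarray:
    """Boolean suspicious/positive predictions for each table row."""
    missing = [c for c in model.feature_ids_ if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks features {missing}")
    return model.predict(table[list(model.feature_ids_)].to_numpy()).astype(bool)


# ---------------------------------------------------------------------------
# vectorized leave-one-out machinery


def _loo_loglik(X: np.ndarray, y: np.ndarray):
    """Per-fold per-class per-feature Gaussian log-densities.

    Returns ``ll`` of shape (2, n, p) where ``ll[c, i, f]`` is the log
    density of sample i's feature f under class c's Gaussian fit on all
    samples except i, and ``logprior`` of shape (2, n).  Class index 1 is
    the positive class.  Folds whose training split empties a class get
    ``-inf`` for that class, which reduces to predicting from the priors
    of the remaining data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    n, p = X.shape
    floor = np.maximum(VAR_FLOOR_FRAC * X.var(axis=0), _VAR_FLOOR_ABS)
    X2 = X * X
    ll = np.empty((2, n, p))
    logprior = np.empty((2, n))
    with np.errstate(divide="ignore"):
        for c, sel in enumerate((~y, y)):
            n_c = int(sel.sum())
            s = X[sel].sum(axis=0)
            q = X2[sel].sum(axis=0)
            is_c = sel.astype(float)[:, None]
            n_prime = n_c - sel.astype(int)            # (n,)
            S = s[None, :] - is_c * X                  # (n, p)
            Q = q[None, :] - is_c * X2
            denom = np.maximum(n_prime, 1)[:, None].astype(float)
            mean = S / denom
            var = np.maximum(Q / denom - mean * mean, floor[None, :])
            ll[c] = -0.5 * (np.log(2 * np.pi * var) + (X - mean) ** 2 / var)
            ll[c, n_prime == 0, :] = -np.inf
            logprior[c] = np.log(n_prime / (n - 1.0))
    return ll, logprior


def loo_predict(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out predictions: sample i scored by a model fit without i."""
    ll, logprior = _loo_loglik(X, y)
    post = logprior + ll.sum(axis=2)
    return post[1] >= post[0]  # tie -> suspicious


def _counts(pred: np.ndarray, y: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        ntp=int((pred & y).sum()),
        ntn=int((~pred & ~y).sum()),
        nfp=int((pred & ~y).sum()),
        nfn=int((~pred & y).sum()),
    )


def loocv(table: pd.DataFrame, feature_set: Sequence, target: str = "any") -> ConfusionCounts:
    """LOOCV confusion counts for one feature subset.

    Each of the n samples is predicted by a model trained on the other
    n-1; counts aggregate all n held-out predictions (so they sum to n).
    Deterministic: no randomness is involved.
    """
    y = target_vector(table["label"], target)
    if min(y.sum(), (~y).sum()) < 2:
        raise ValueError("need at least 2 samples in each class")
    X = table[_columns(feature_set)].to_numpy()
    return _counts(loo_predict(X, y), y)


# ---------------------------------------------------------------------------
# restricted pools and exhaustive search


def restrict_pool(all_features: Sequence[FeatureId], basis: str, moment_pair) -> List[FeatureId]:
    """The 64-feature pool: one basis, two moment types, 32 wavelet maps.

    Raw-image features are excluded (the pool spans the 4 maps x 8
    levels only).
    """
    pair = tuple(moment_pair)
    if len(pair) != 2 or pair[0] == pair[1]:
        raise ValueError("moment_pair must be two distinct moments")
    for m in pair:
        if m not in MOMENTS:
            raise ValueError(f"unknown moment {m!r}; expected one of {MOMENTS}")
    from .decompose import canonical_basis_name

    basis = canonical_basis_name(basis)
    pool = [
        f
        for f in all_features
        if f.basis == basis and f.moment in pair and f.map != "raw"
    ]
    return pool


@dataclass
class SearchResult:
    """Outcome of an exhaustive subset search."""

    feature_set: Tuple[FeatureId, ...]
    score: float
    counts: ConfusionCounts
    w: float
    target: str
    moment_pair: Optional[Tuple[str, str]] = None

    @property
    def sensitivity(self) -> float:
        return self.counts.sensitivity

    @property
    def specificity(self) -> float:
        return self.counts.specificity


def exhaustive_search(
    table: pd.DataFrame,
    pool: Sequence[FeatureId],
    target: str = "any",
    max_k: int = 3,
    w: float = 0.995,
) -> SearchResult:
    """Evaluate every 1..max_k-feature subset of ``pool`` by LOOCV.

    Returns the argmax of the weighted score; ties break to the higher
    true-negative count, then to the lexicographically first feature-id
    tuple.  The result is independent of the order the pool is given in.
    """
    if len(pool) == 0:
        raise ValueError("empty feature pool")
    pool = sorted(pool, key=lambda f: f.sort_key())
    y = target_vector(table["label"], target)
    if min(y.sum(), (~y).sum()) < 2:
        raise ValueError("need at least 2 samples in each class")
    X = table[[f.encode() for f in pool]].to_numpy()
    ll, logprior = _loo_loglik(X, y)
    n = X.shape[0]
    npos, nneg = int(y.sum()), int(n - y.sum())

    best = None  # (score, ntn, subset_indices, counts)
    for k in range(1, max_k + 1):
        for idx in combinations(range(len(pool)), k):
            post = logprior + ll[:, :, idx].sum(axis=2)
            pred = post[1] >= post[0]
            ntp = int((pred & y).sum())
            ntn = int((~pred & ~y).sum())
            s = w * ntp + (1.0 - w) * ntn
            if best is None or (s, ntn) > (best[0], best[1]):
                best = (s, ntn, idx, ntp)
    s, ntn, idx, ntp = best
    counts = ConfusionCounts(ntp=ntp, ntn=ntn, nfp=nneg - ntn, nfn=npos - ntp)
    return SearchResult(
        feature_set=tuple(pool[i] for i in idx),
        score=s,
        counts=counts,
        w=w,
        target=target,
    )


_MOMENT_PAIRS = tuple(combinations(MOMENTS, 2))


def search_basis(
    table: pd.DataFrame,
    basis: str,
    moments="auto",
    target: str = "any",
    max_k: int = 3,
    w: float = 0.995,
) -> SearchResult:
    """Search one basis, either with a fixed moment pair or over all six pairs."""
    ids = feature_ids(basis)
    pairs = _MOMENT_PAIRS if moments == "auto" else (tuple(moments),)
    best = None
    for pair in pairs:
        pool = [f for f in restrict_pool(ids, basis, pair) if f.encode() in table.columns]
        if not pool:
            continue
        res = exhaustive_search(table, pool, target, max_k, w)
        res.moment_pair = pair
        if best is None:
            best = res
            continue
        cur, top = (res.score, res.counts.ntn), (best.score, best.counts.ntn)
        if cur > top or (
            cur == top
            and tuple(f.encode() for f in res.feature_set)
            < tuple(f.encode() for f in best.feature_set)
        ):
            best = res
    if best is None:
        raise ValueError(f"table has no features for basis {basis!r}")
    return best


class SubsetSearchScreener(BaseEstimator, ClassifierMixin):
    """Classifier that picks its own 1-3 feature subset by exhaustive search.

    ``fit`` runs the LOOCV-scored search over the restricted pool of the
    given basis (and moment pair, or all six pairs when ``moments='auto'``),
    then fits the final naive Bayes model on all training rows with the
    winning subset.  ``X`` is a feature table (DataFrame) containing the
    codec-named feature columns plus a ``label`` column used to derive the
    training partition; ``y`` may be omitted (it is implied by ``label``
    and ``target``).

    Fitted attributes: ``best_feature_set_``, ``search_result_``,
    ``model_``, ``classes_``.
    """

    def __init__(self, basis: str = "haar", moments="auto", target: str = "any",
                 max_k: int = 3, w: float = 0.995):
        self.basis = basis
        self.moments = moments
        self.target = target
        self.max_k = max_k
        self.w = w

    def fit(self, X: pd.DataFrame, y=None):
        res = search_basis(X, self.basis, self.moments, self.target, self.max_k, self.w)
        self.search_result_ = res
        self.best_feature_set_ = res.feature_set
        self.model_ = fit_gaussian_nb(X, res.feature_set, self.target)
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict_table(self.model_, X)
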