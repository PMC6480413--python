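"""Multinomial naive Bayes over present symptoms.

The classifier scores a cause c for a record by

    P(c | record)  ∝  P(c) * prod_{s : record[s]=1} P(s | c)

i.e. the product runs over the symptoms *reported present* only; an
absent symptom contributes no factor (the multinomial event model on a
bag of present symptoms, not the Bernoulli model). Class priors are the
training cause fractions; the conditional for symptom s given cause c is
the smoothed share of s among all present-symptom reports in class c:

    P(s | c) = (count(s present in c) + alpha) / (total present in c + alpha*S)

Accumulation is done in log space with a single final normalisation so
that surveys with a couple of hundred symptoms cannot underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import VADataset

__all__ = [
    "MultinomialVANB",
    "RankedPrediction",
    "fit_nbc",
    "posterior",
    "classify_ranked",
]


@dataclass(frozen=True)
class RankedPrediction:
    """Full descending-probability cause ordering for one death record."""

    record_id: str
    ordered_causes: tuple
    scores: tuple

    def __post_init__(self):
        if len(self.ordered_causes) != len(set(self.ordered_causes)):
            raise ValueError("ranking repeats a cause")
        s = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def rank_of(self, cause) -> int:
        """1-based rank of ``cause`` in this prediction."""
        return self.ordered_causes.index(cause) + 1

    def top(self, k: int = 1) -> tuple:
        return self.ordered_causes[:k]


def _validate_binary_matrix(X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X))
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.isin(np.unique(X), (0, 1)).all():
        raise ValueError("X entries must be 0 or 1")
    return X.astype(np.float64)


class MultinomialVANB(BaseEstimator, ClassifierMixin):
    """Multinomial naive Bayes for binary VA symptom matrices.

    Parameters
    ----------
    alpha : float, default=1.0
        Additive (Laplace) smoothing pseudo-count, >= 0. With
        ``alpha=0`` a symptom never seen in a class zeroes that class's
        posterior; this is permitted but logged.
    classes : sequence, optional
        Cause labels in the order used for tie-breaking and output
        columns. Defaults to sorted unique labels of ``y``. Ranking
        ties are broken by this order, deterministically.

    Attributes
    ----------
    classes_ : ndarray of shape (M,)
        Cause labels in score-column order.
    class_prior_ : ndarray of shape (M,)
        Training fraction of each cause; sums to 1.
    feature_prob_ : ndarray of shape (M, S)
        Smoothed P(symptom | cause); each row sums to 1 when alpha > 0.
    """

    def __init__(self, alpha: float = 1.0, classes=None):
        self.alpha = alpha
        self.classes = classes

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        X = _validate_binary_matrix(X)
        y = np.asarray(y, dtype=object)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if self.classes is None:
            classes = np.array(sorted(set(y.tolist())), dtype=object)
        else:
            classes = np.asarray(list(self.classes), dtype=object)
            extra = set(y.tolist()) - set(classes.tolist())
            if extra:
                raise ValueError(f"labels outside declared classes: {sorted(extra)}")
        if len(classes) < 2:
            raise ValueError("need at least two causes to classify")

        n, S = X.shape
        M = len(classes)
        priors = np.empty(M)
        cond = np.empty((M, S))
        for i, c in enumerate(classes):
            mask = y == c
            n_c = int(mask.sum())
            if n_c == 0:
                raise ValueError(f"cause {c!r} has no training records")
            priors[i] = n_c / n
            counts = X[mask].sum(axis=0)
            denom = counts.sum() + self.alpha * S
            if denom == 0:
                # class whose records report no symptoms, alpha=0
                cond[i] = 0.0
            else:
                cond[i] = (counts + self.alpha) / denom
        self.classes_ = classes
        self.class_prior_ = priors
        self.feature_prob_ = cond
        self.n_features_in_ = S
        if self.alpha == 0 and np.any(cond == 0):
            warnings.warn(
                "alpha=0 with unseen symptoms: some posteriors can be exactly zero",
                stacklevel=2,
            )
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        check_is_fitted(self, "feature_prob_")
        X = _validate_binary_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"record length {X.shape[1]} != trained symptom count "
                f"{self.n_features_in_}"
            )
        with np.errstate(divide="ignore"):
            log_cond = np.log(self.feature_prob_)
            log_prior = np.log(self.class_prior_)
        # only present symptoms contribute factors
        jll = X @ log_cond.T + log_prior
        return jll

    def predict_log_proba(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        norm = logsumexp(jll, axis=1, keepdims=True)
        out = jll - norm
        # all-zero scores (alpha=0 pathologies) -> uniform with a warning
        dead = ~np.isfinite(norm).ravel()
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} record(s) had zero posterior mass under "
                "every cause; returning a uniform posterior",
                stacklevel=2,
            )
            out[dead] = -np.log(len(self.classes_))
        return out

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax with ties broken by class order (np.argmax is first-max)
        return self.classes_[np.argmax(proba, axis=1)]

    def predict_ranked(self, X, record_ids=None) -> list:
        """Full descending-posterior cause ranking per record.

        Ties are broken by position in ``classes_`` (stable sort).
        """
        proba = self.predict_proba(X)
        return rank_scores(proba, self.classes_, record_ids)

    # -- persistence -----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "feature_prob_")
        return {
            "type": "nbc",
            "alpha": self.alpha,
            "classes": self.classes_.tolist(),
            "class_prior": self.class_prior_.tolist(),
            "feature_prob": self.feature_prob_.tolist(),
            "symptom_names": getattr(self, "symptom_names_", None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultinomialVANB":
        model = cls(alpha=d["alpha"], classes=d["classes"])
        model.classes_ = np.asarray(d["classes"], dtype=object)
        model.class_prior_ = np.asarray(d["class_prior"], dtype=float)
        model.feature_prob_ = np.asarray(d["feature_prob"], dtype=float)
        model.n_features_in_ = model.feature_prob_.shape[1]
        if d.get("symptom_names"):
            model.symptom_names_ = list(d["symptom_names"])
        return model


def rank_scores(scores: np.ndarray, classes, record_ids=None) -> list:
    """Turn an (N, M) score matrix into RankedPredictions.

    Causes are ordered by descending score; exact ties keep the order
    of ``classes`` (stable mergesort on the negated scores).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    classes = list(classes)
    if record_ids is None:
        record_ids = [str(i) for i in range(scores.shape[0])]
    out = []
    for rid, row in zip(record_ids, scores):
        order = np.argsort(-row, kind="stable")
        out.append(
            RankedPrediction(
                record_id=str(rid),
                ordered_causes=tuple(classes[j] for j in order),
                scores=tuple(row[order]),
            )
        )
    return out


# -- functional wrappers over the estimator ------------------------------

def fit_nbc(ds: VADataset, alpha: float = 1.0) -> MultinomialVANB:
    """Train a multinomial NB on a VADataset (cause order = ds.causes)."""
    model = MultinomialVANB(alpha=alpha, classes=ds.causes).fit(ds.X, ds.y)
    model.symptom_names_ = list(ds.symptom_names)
    return model


def posterior(model: MultinomialVANB, record) -> np.ndarray:
    """Normalised posterior P(cause | record) for one binary record."""
    record = np.asarray(record).reshape(1, -1)
    return model.predict_proba(record)[0]


def classify_ranked(model: MultinomialVANB, record, record_id="0") -> RankedPrediction:
    """Rank all causes for one record by descending posterior."""
    record = np.asarray(record).reshape(1, -1)
    return model.predict_ranked(record, record_ids=[record_id])[0]
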