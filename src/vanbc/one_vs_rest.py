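"""One-against-all ensemble of binary naive Bayes classifiers.

A dataset with M causes is decomposed into M binary datasets: in the
i-th, records of cause C_i are labelled positive and everything else
negative, and a binary multinomial NB is fitted to each. At prediction
time each member reports its positive-class posterior for the record,
and causes are ranked by that score in descending order. Scores are
deliberately *not* renormalised across members — each is a valid
two-class posterior and the ensemble compares them directly. The
negative class mixes many causes; no reweighting is applied.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import VADataset
from .naive_bayes import MultinomialVANB, RankedPrediction, rank_scores

__all__ = ["OneVsRestVANB", "fit_oaa", "predict_ranked", "predict_batch"]

_POS, _NEG = "positive", "negative"


class OneVsRestVANB(BaseEstimator, ClassifierMixin):
    """One-vs-rest ensemble of binary multinomial NB members.

    Parameters
    ----------
    alpha : float, default=1.0
        Smoothing pseudo-count passed to every binary member.
    classes : sequence, optional
        Cause order for members, tie-breaking and output columns;
        defaults to sorted unique labels of ``y``.

    Attributes
    ----------
    classes_ : ndarray of shape (M,)
    estimators_ : list of M fitted binary MultinomialVANB members;
        member i is trained with cause ``classes_[i]`` as positive.
    """

    def __init__(self, alpha: float = 1.0, classes=None):
        self.alpha = alpha
        self.classes = classes

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y, dtype=object)
        if self.classes is None:
            classes = np.array(sorted(set(y.tolist())), dtype=object)
        else:
            classes = np.asarray(list(self.classes), dtype=object)
            extra = set(y.tolist()) - set(classes.tolist())
            if extra:
                raise ValueError(f"labels outside declared classes: {sorted(extra)}")
        if len(classes) < 2:
            raise ValueError("need at least two causes")
        members = []
        for c in classes:
            y_bin = np.where(y == c, _POS, _NEG).astype(object)
            if (y_bin == _POS).sum() == 0:
                raise ValueError(f"cause {c!r} has no records; cannot train its member")
            if (y_bin == _NEG).sum() == 0:
                raise ValueError(f"cause {c!r} covers every record; rest class empty")
            member = MultinomialVANB(alpha=self.alpha, classes=[_POS, _NEG])
            members.append(member.fit(X, y_bin))
        self.classes_ = classes
        self.estimators_ = members
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """(N, M) matrix of member positive-class posteriors.

        Column i is P(positive | record) under member i. Rows need not
        sum to 1: no cross-member calibration is performed.
        """
        check_is_fitted(self, "estimators_")
        X = np.atleast_2d(np.asarray(X))
        cols = [m.predict_proba(X)[:, 0] for m in self.estimators_]
        return np.column_stack(cols)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_ranked(self, X, record_ids=None) -> list:
        """Causes ranked by descending member score, ties by class order."""
        return rank_scores(self.decision_function(X), self.classes_, record_ids)

    # -- persistence -----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "estimators_")
        return {
            "type": "oaa",
            "alpha": self.alpha,
            "classes": self.classes_.tolist(),
            "members": [m.to_dict() for m in self.estimators_],
            "symptom_names": getattr(self, "symptom_names_", None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OneVsRestVANB":
        model = cls(alpha=d["alpha"], classes=d["classes"])
        model.classes_ = np.asarray(d["classes"], dtype=object)
        model.estimators_ = [MultinomialVANB.from_dict(m) for m in d["members"]]
        model.n_features_in_ = model.estimators_[0].n_features_in_
        if d.get("symptom_names"):
            model.symptom_names_ = list(d["symptom_names"])
        return model


# -- functional wrappers -------------------------------------------------

def fit_oaa(ds: VADataset, alpha: float = 1.0) -> OneVsRestVANB:
    """Train the one-against-all ensemble on a VADataset."""
    model = OneVsRestVANB(alpha=alpha, classes=ds.causes).fit(ds.X, ds.y)
    model.symptom_names_ = list(ds.symptom_names)
    return model


def predict_ranked(model, record, record_id="0") -> RankedPrediction:
    """Ranked causes for a single binary symptom vector."""
    record = np.asarray(record).reshape(1, -1)
    return model.predict_ranked(record, record_ids=[record_id])[0]


def predict_batch(model, ds: VADataset) -> list:
    """One RankedPrediction per record of ``ds``, in order.

    The dataset's symptom names must match the training layout; a
    mismatch reports the symmetric difference.
    """
    trained = getattr(model, "symptom_names_", None)
    if trained is not None and list(trained) != list(ds.symptom_names):
        diff = set(trained) ^ set(ds.symptom_names)
        raise ValueError(f"symptom mismatch between model and dataset: {sorted(diff)}")
    if ds.n_symptoms != model.n_features_in_:
        raise ValueError(
            f"dataset has {ds.n_symptoms} symptoms, model expects {model.n_features_in_}"
        )
    return model.predict_ranked(ds.X, record_ids=ds.record_ids)
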