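"""Assessment metrics for verbal-autopsy cause assignment.

Individual-level agreement is measured by sensitivity (per-cause recall,
TP/(TP+FN)) and by the partially chance-corrected concordance

    PCCC(k) = (S - k/n) / (1 - k/n),

where S is the fraction of records whose true cause lies within the top
k of n ranked causes; PCCC is 0 at chance level and 1 for perfect
assignment (it can be negative below chance). Population-level agreement
uses CSMF accuracy,

    1 - sum_j |CSMF_true_j - CSMF_pred_j| / (2 * (1 - min_j CSMF_true_j)),

which compares predicted and observed cause-specific mortality
fractions and is bounded in [0, 1].

All three are reported *cumulatively by rank*: a record counts as
correctly assigned at depth k when its true cause appears anywhere in
its top k ranked causes, so e.g. 60% at rank 1 plus 15% new hits at
rank 2 gives a cumulative 75% at rank 2.

Cumulative CSMF accuracy at k > 1 uses an "effective assignment": a
record is credited with its true cause when that cause is in its top k,
otherwise with its rank-1 cause. The per-depth accuracy of that
assignment is not guaranteed monotone (crediting a true cause that is
already over-predicted can worsen the predicted CSMF), so the reported
cumulative value at rank k is the running maximum over depths 1..k —
the best population-level agreement achievable using up to k ranks.
This reduces to the standard definition at k = 1 and is non-decreasing
by construction; only the k = 1 case has a standard definition, and the
choice is documented as an interpretation in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "RankTally",
    "sensitivity",
    "pccc",
    "csmf_accuracy",
    "csmf_from_labels",
    "confusion_counts",
    "EvaluationResult",
    "evaluate_ranked",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single cause."""

    cause: object
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class RankTally:
    """Fraction S of records whose true cause is within the top k of n."""

    S: float
    k: int
    n: int

    def __post_init__(self):
        if not 0.0 <= self.S <= 1.0:
            raise ValueError("S must lie in [0, 1]")
        if not 1 <= self.k <= self.n:
            raise ValueError("need 1 <= k <= n")


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN (reported missing) when the cause has no records."""
    denom = counts.TP + counts.FN
    if denom == 0:
        return math.nan
    return counts.TP / denom


def pccc(tally: RankTally) -> float:
    """Partially chance-corrected concordance at depth k.

    Corrects the top-k hit fraction S for the k/n probability of a
    chance hit. Undefined at k = n (every ranking trivially contains
    the truth), which raises.
    """
    if tally.k >= tally.n:
        raise ValueError("PCCC is undefined for k >= n")
    chance = tally.k / tally.n
    return (tally.S - chance) / (1.0 - chance)


def csmf_accuracy(true_csmf, pred_csmf) -> float:
    """Population-level agreement between two cause-fraction vectors.

    Both vectors must share cause order and sum to 1. Returns values in
    [0, 1]; the denominator 2*(1 - min(true)) normalises by the worst
    possible total absolute error, so the bound is tight.
    """
    t = np.asarray(true_csmf, dtype=float)
    p = np.asarray(pred_csmf, dtype=float)
    if t.shape != p.shape:
        raise ValueError("CSMF vectors must have identical shape")
    for name, v in (("true", t), ("pred", p)):
        if (v < -1e-12).any() or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} CSMF must be non-negative and sum to 1")
    denom = 2.0 * (1.0 - t.min())
    if denom == 0.0:
        raise ValueError("true CSMF concentrated on a single cause; accuracy undefined")
    return 1.0 - np.abs(t - p).sum() / denom


def csmf_from_labels(labels, causes) -> np.ndarray:
    """Empirical cause fractions of ``labels`` over the ordered ``causes``."""
    labels = np.asarray(labels, dtype=object)
    counts = np.array([(labels == c).sum() for c in causes], dtype=float)
    if counts.sum() == 0:
        raise ValueError("no labels")
    return counts / counts.sum()


def confusion_counts(true_labels, pred_labels, cause) -> ConfusionCounts:
    """One-vs-rest confusion counts of ``cause`` from aligned label vectors."""
    t = np.asarray(true_labels, dtype=object) == cause
    p = np.asarray(pred_labels, dtype=object) == cause
    return ConfusionCounts(
        cause=cause,
        TP=int((t & p).sum()),
        FP=int((~t & p).sum()),
        FN=int((t & ~p).sum()),
        TN=int((~t & ~p).sum()),
    )


@dataclass
class EvaluationResult:
    """Cumulative per-rank metrics plus per-cause rank-1 sensitivity.

    ``per_rank`` has one row per depth k = 1..max_rank with columns
    rank, sensitivity, pccc, csmf_accuracy (pccc is NaN at k = n, where
    it is undefined). ``per_cause_rank1`` maps cause -> rank-1
    sensitivity; causes absent from the test truths are excluded.
    """

    per_rank: pd.DataFrame
    per_cause_rank1: dict = field(default_factory=dict)
    n_records: int = 0
    n_causes: int = 0

    def metric_at(self, metric: str, rank: int) -> float:
        row = self.per_rank.loc[self.per_rank["rank"] == rank, metric]
        if row.empty:
            raise KeyError(f"rank {rank} not evaluated")
        return float(row.iloc[0])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format report: columns metric, rank, cause, value."""
        rows = []
        for _, r in self.per_rank.iterrows():
            k = int(r["rank"])
            for m in ("sensitivity", "pccc", "csmf_accuracy"):
                rows.append({"metric": m, "rank": k, "cause": "", "value": r[m]})
        for cause, v in self.per_cause_rank1.items():
            rows.append(
                {"metric": "sensitivity_per_cause", "rank": 1, "cause": str(cause), "value": v}
            )
        return pd.DataFrame(rows, columns=["metric", "rank", "cause", "value"])

    def to_json_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_causes": self.n_causes,
            "per_rank": self.per_rank.to_dict(orient="records"),
            "per_cause_rank1": {str(k): v for k, v in self.per_cause_rank1.items()},
        }


def evaluate_ranked(predictions, truths, max_rank: int | None = None) -> EvaluationResult:
    """Cumulative sensitivity / PCCC / CSMF accuracy from ranked predictions.

    Parameters
    ----------
    predictions : list of RankedPrediction
        Full cause rankings, aligned with ``truths``.
    truths : sequence
        True cause per record.
    max_rank : int, optional
        Deepest rank to report; defaults to the number of causes M.

    Notes
    -----
    The cause universe is the union of ranked causes and true labels —
    normally exactly the training cause list. Cumulative CSMF accuracy
    at depth k uses the effective assignment (true cause if within top
    k, else the rank-1 cause).
    """
    truths = np.asarray(list(truths), dtype=object)
    if len(predictions) != len(truths):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(truths)} truths"
        )
    if len(predictions) == 0:
        raise ValueError("nothing to evaluate")
    causes = list(predictions[0].ordered_causes)
    for p in predictions:
        if set(p.ordered_causes) != set(causes):
            raise ValueError("predictions rank different cause sets")
    extra = set(truths.tolist()) - set(causes)
    if extra:
        raise ValueError(f"true labels outside ranked causes: {sorted(extra)}")

    M = len(causes)
    if max_rank is None:
        max_rank = M
    if not 1 <= max_rank <= M:
        raise ValueError(f"max_rank must lie in 1..{M}")

    N = len(truths)
    true_rank = np.array([p.rank_of(t) for p, t in zip(predictions, truths)])
    rank1 = np.array([p.ordered_causes[0] for p in predictions], dtype=object)
    true_csmf = csmf_from_labels(truths, causes)

    rows = []
    best_csmf_acc = -math.inf
    for k in range(1, max_rank + 1):
        hit = true_rank <= k
        S = hit.mean()
        p_k = pccc(RankTally(S=S, k=k, n=M)) if k < M else math.nan
        effective = np.where(hit, truths, rank1)
        pred_csmf = csmf_from_labels(effective, causes)
        # cumulative = best agreement achievable within the top k ranks
        best_csmf_acc = max(best_csmf_acc, csmf_accuracy(true_csmf, pred_csmf))
        rows.append(
            {
                "rank": k,
                "sensitivity": float(S),
                "pccc": p_k,
                "csmf_accuracy": best_csmf_acc,
            }
        )

    per_cause = {}
    for c in causes:
        cc = confusion_counts(truths, rank1, c)
        s = sensitivity(cc)
        if not math.isnan(s):  # causes with no true records are excluded
            per_cause[c] = s

    return EvaluationResult(
        per_rank=pd.DataFrame(rows),
        per_cause_rank1=per_cause,
        n_records=N,
        n_causes=M,
    )
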