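"""Experimental harness: stratified cross-validation, Dirichlet test-set
resampling, and Wilcoxon signed-rank comparison of paired metric series.

The cross-validation protocol partitions each dataset into k folds by
stratified sampling — every fold carries (up to integer rounding) the
same cause proportions as the whole dataset — then trains on k-1 parts,
ranks causes on the held-out part, scores cumulative sensitivity, PCCC
and CSMF accuracy at each rank, and reports across-fold means.

The Dirichlet experiment perturbs the cause composition of a test set:
a cause distribution is drawn from a Dirichlet, per-cause record counts
from a multinomial over it, and records are resampled with replacement
within each cause — modelling the realistic situation where deployed
data has a different cause mix than the training data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import clone

from .dataset import VADataset
from .metrics import evaluate_ranked

__all__ = [
    "FoldPlan",
    "PairedSeries",
    "CVResult",
    "stratified_kfold",
    "run_cv",
    "dirichlet_resample_test",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class FoldPlan:
    """Stratified fold assignment: fold index per record."""

    k: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def stratified_kfold(ds: VADataset, k: int, seed: int = 0) -> FoldPlan:
    """Partition records into k folds, stratified by cause.

    Within each cause the records are shuffled (seeded) and dealt
    round-robin, remainders going to the lowest-index folds, so fold
    sizes per cause differ by at most one record. Causes with fewer
    than k records simply miss some folds.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > ds.n_records:
        raise ValueError(f"k={k} exceeds the {ds.n_records} records available")
    rng = np.random.default_rng(seed)
    assignments = np.full(ds.n_records, -1, dtype=int)
    for cause in ds.causes:
        idx = np.flatnonzero(ds.y == cause)
        rng.shuffle(idx)
        for j, rec in enumerate(idx):
            assignments[rec] = j % k
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass
class CVResult:
    """Per-fold and mean evaluation results for one classifier."""

    algorithm: str
    fold_results: list
    mean_per_rank: pd.DataFrame

    def mean_metric_at(self, metric: str, rank: int) -> float:
        row = self.mean_per_rank.loc[self.mean_per_rank["rank"] == rank, metric]
        if row.empty:
            raise KeyError(f"rank {rank} not evaluated")
        return float(row.iloc[0])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format report: algorithm, fold ('mean' row included),
        rank, metric, value."""
        rows = []
        for f, res in enumerate(self.fold_results):
            for _, r in res.per_rank.iterrows():
                for m in ("sensitivity", "pccc", "csmf_accuracy"):
                    rows.append(
                        {
                            "algorithm": self.algorithm,
                            "fold": str(f),
                            "rank": int(r["rank"]),
                            "metric": m,
                            "value": r[m],
                        }
                    )
        for _, r in self.mean_per_rank.iterrows():
            for m in ("sensitivity", "pccc", "csmf_accuracy"):
                rows.append(
                    {
                        "algorithm": self.algorithm,
                        "fold": "mean",
                        "rank": int(r["rank"]),
                        "metric": m,
                        "value": r[m],
                    }
                )
        return pd.DataFrame(rows, columns=["algorithm", "fold", "rank", "metric", "value"])


def run_cv(
    ds: VADataset,
    algorithms: dict,
    k: int = 10,
    max_rank: int | None = None,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation of ranked classifiers.

    Parameters
    ----------
    ds : VADataset
    algorithms : dict of name -> unfitted estimator
        Each estimator must expose ``fit(X, y)`` and
        ``predict_ranked(X, record_ids)`` (the NB and one-vs-rest
        classifiers here do; any conforming object works).
    k : int, default=10
    max_rank : int, optional
        Deepest rank scored; defaults to the cause count.
    seed : int
        Seeds the stratified shuffle; the procedure is deterministic
        given (ds, seed, hyperparameters).

    Returns
    -------
    dict of name -> CVResult
    """
    if max_rank is None:
        max_rank = ds.n_causes
    plan = stratified_kfold(ds, k=k, seed=seed)
    out: dict = {}
    for name, proto in algorithms.items():
        fold_results = []
        for fold in range(k):
            tr = ds.subset(plan.train_indices(fold))
            te = ds.subset(plan.test_indices(fold))
            missing = [c for c in ds.causes if c not in tr.causes]
            if missing:
                raise ValueError(
                    f"fold {fold}: training part lacks cause(s) {missing}; "
                    "use fewer folds or more data"
                )
            model = clone(proto)
            try:
                model.set_params(classes=list(ds.causes))
            except ValueError:
                pass  # estimator without an explicit class-order knob
            model.fit(tr.X, tr.y)
            preds = model.predict_ranked(te.X, record_ids=te.record_ids)
            fold_results.append(evaluate_ranked(preds, te.y, max_rank=max_rank))
        mean = (
            pd.concat([r.per_rank for r in fold_results])
            .groupby("rank", as_index=False)
            .mean()
        )
        out[name] = CVResult(algorithm=name, fold_results=fold_results, mean_per_rank=mean)
    return out


def dirichlet_resample_test(
    test: VADataset,
    concentration=None,
    seed: int = 0,
    max_retries: int = 100,
) -> VADataset:
    """Resample a test set with replacement under a Dirichlet cause mix.

    A CSMF is drawn from Dirichlet(concentration) over the test set's
    causes, per-cause counts from Multinomial(N, CSMF), and that many
    records are drawn with replacement from each cause's records. The
    output has the same size N and contains only copies of input
    records. If a positive count lands on a cause with no records in
    the test set (impossible here, since the cause list is the observed
    one, but kept for custom cause lists) the draw is retried.

    Parameters
    ----------
    concentration : array-like of shape (M,), optional
        Positive Dirichlet weights per cause; default is the symmetric
        uninformative choice of 1 per cause.
    """
    M = test.n_causes
    if concentration is None:
        concentration = np.ones(M)
    concentration = np.asarray(concentration, dtype=float)
    if concentration.shape != (M,) or (concentration <= 0).any():
        raise ValueError("concentration must be positive and one weight per cause")
    rng = np.random.default_rng(seed)
    N = test.n_records
    cause_indices = {c: np.flatnonzero(test.y == c) for c in test.causes}

    for _ in range(max_retries):
        csmf = rng.dirichlet(concentration)
        counts = rng.multinomial(N, csmf)
        if all(
            counts[i] == 0 or len(cause_indices[c]) > 0
            for i, c in enumerate(test.causes)
        ):
            break
    else:
        raise RuntimeError("could not draw a cause mix supported by the test set")

    picked = []
    for i, c in enumerate(test.causes):
        if counts[i] > 0:
            picked.append(rng.choice(cause_indices[c], size=counts[i], replace=True))
    idx = np.concatenate(picked)
    rng.shuffle(idx)
    present = set(test.y[idx].tolist())
    return VADataset(
        record_ids=[f"r{j}_{test.record_ids[i]}" for j, i in enumerate(idx)],
        symptom_names=list(test.symptom_names),
        X=test.X[idx],
        y=test.y[idx],
        causes=[c for c in test.causes if c in present],
    )


@dataclass(frozen=True)
class PairedSeries:
    """Aligned metric observations for two classifiers.

    Typically one observation per (dataset, rank) cell — e.g. five
    ranks by seven datasets gives 35 paired values.
    """

    labels: tuple
    a_values: np.ndarray
    b_values: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a_values, dtype=float)
        b = np.asarray(self.b_values, dtype=float)
        if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
            raise ValueError("need two equal-length 1-D series")
        if len(self.labels) != len(a):
            raise ValueError("labels must align with values")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("missing values not allowed")
        object.__setattr__(self, "a_values", a)
        object.__setattr__(self, "b_values", b)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    z: float  # NaN in exact mode
    p_value: float
    n_nonzero: int
    mode: str


def wilcoxon_signed_rank(series: PairedSeries, mode: str = "normal_approx") -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped; ties in |difference| receive
    mid-ranks. ``exact`` mode enumerates all 2^m sign patterns (m <=
    20); ``normal_approx`` uses

        Z = (W+ - m(m+1)/4) / sqrt(m(m+1)(2m+1)/24)

    without continuity correction and p = 2 * (1 - Phi(|Z|)).
    """
    d = series.a_values - series.b_values
    d = d[d != 0]
    m = len(d)
    if m == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())

    if mode == "exact":
        if m > 20:
            raise ValueError("exact enumeration limited to m <= 20 differences")
        # null distribution of W+ by full sign enumeration
        total = 2**m
        patterns = (np.arange(total, dtype=np.uint32)[:, None] >> np.arange(m)) & 1
        w_vals = patterns.astype(np.uint8) @ ranks
        mean_w = m * (m + 1) / 4.0
        # two-tailed: as or more extreme in distance from the mean
        obs_dev = abs(w_plus - mean_w)
        p = float(np.mean(np.abs(w_vals - mean_w) >= obs_dev - 1e-12))
        return WilcoxonResult(w_plus, math.nan, p, m, "exact")
    if mode == "normal_approx":
        mu = m * (m + 1) / 4.0
        sigma = math.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
        z = (w_plus - mu) / sigma
        p = 2.0 * float(norm.sf(abs(z)))
        return WilcoxonResult(w_plus, z, p, m, "normal_approx")
    raise ValueError(f"unknown mode {mode!r}")
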