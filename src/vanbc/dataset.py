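"""Container for binary verbal-autopsy (VA) datasets.

A VA dataset is a deaths-by-symptoms binary matrix: one row per death
record, one column per yes/no survey item (1 = symptom reported present),
plus a single categorical cause-of-death label per record. This is the
exchange object every other module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VADataset"]


def _first_appearance_unique(values) -> list:
    seen: dict = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return list(seen)


@dataclass
class VADataset:
    """Binary symptom matrix with one cause-of-death label per record.

    Parameters
    ----------
    record_ids : list of str
        Unique identifier per death record (row).
    symptom_names : list of str
        Unique name per binary symptom (column).
    X : ndarray of shape (n_records, n_symptoms)
        Binary matrix; entry 1 means the symptom was reported "Yes".
    y : ndarray of shape (n_records,)
        Cause-of-death label per record.
    causes : list of str, optional
        Ordered unique cause labels. Defaults to order of first
        appearance in ``y``. Every cause must occur in ``y``.
    """

    record_ids: list
    symptom_names: list
    X: np.ndarray
    y: np.ndarray
    causes: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=object)
        self.record_ids = [str(r) for r in self.record_ids]
        self.symptom_names = [str(s) for s in self.symptom_names]
        if self.causes is None:
            self.causes = _first_appearance_unique(self.y)
        else:
            self.causes = list(self.causes)
        self.validate()
        self.X = self.X.astype(np.int8, copy=False)

    # -- basic shape accessors -------------------------------------------
    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def n_symptoms(self) -> int:
        return self.X.shape[1]

    @property
    def n_causes(self) -> int:
        return len(self.causes)

    def validate(self) -> None:
        """Raise ``ValueError`` on any structural invariant violation."""
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, s = self.X.shape
        if n < 1 or s < 1:
            raise ValueError("dataset needs at least one record and one symptom")
        if len(self.record_ids) != n:
            raise ValueError("record_ids length does not match X rows")
        if len(self.symptom_names) != s:
            raise ValueError("symptom_names length does not match X columns")
        if len(set(self.record_ids)) != n:
            raise ValueError("duplicate record_ids")
        if len(set(self.symptom_names)) != s:
            raise ValueError("duplicate symptom_names")
        if len(self.y) != n:
            raise ValueError("y length does not match X rows")
        vals = np.unique(self.X)
        if not np.isin(vals, (0, 1)).all():
            bad = [v for v in vals.tolist() if v not in (0, 1)]
            raise ValueError(f"X entries must be 0 or 1; found {bad}")
        cause_set = set(self.causes)
        if len(cause_set) != len(self.causes):
            raise ValueError("duplicate cause labels")
        if len(self.causes) < 2:
            raise ValueError("need at least two causes")
        observed = set(self.y.tolist())
        missing = observed - cause_set
        if missing:
            raise ValueError(f"labels not in cause list: {sorted(missing)}")
        unseen = cause_set - observed
        if unseen:
            raise ValueError(f"causes with zero records: {sorted(unseen)}")

    # -- conversions ------------------------------------------------------
    def to_frame(self, cause_column: str = "cause", id_column: str = "id") -> pd.DataFrame:
        """Return the dataset as a tidy DataFrame (id, symptoms..., cause)."""
        df = pd.DataFrame(self.X, columns=self.symptom_names)
        df.insert(0, id_column, self.record_ids)
        df[cause_column] = self.y
        return df

    def subset(self, indices) -> "VADataset":
        """Row subset preserving cause order (causes absent from the subset
        are dropped from the cause list)."""
        indices = np.asarray(indices)
        y = self.y[indices]
        present = set(y.tolist())
        return VADataset(
            record_ids=[self.record_ids[i] for i in indices],
            symptom_names=list(self.symptom_names),
            X=self.X[indices],
            y=y,
            causes=[c for c in self.causes if c in present],
        )

    def cause_counts(self) -> pd.Series:
        """Deaths per cause, in cause order."""
        vc = pd.Series(self.y).value_counts()
        return vc.reindex(self.causes).astype(int)

    def csmf(self) -> np.ndarray:
        """Observed cause-specific mortality fractions, in cause order."""
        return self.cause_counts().to_numpy() / self.n_records

    def __eq__(self, other) -> bool:
        if not isinstance(other, VADataset):
            return NotImplemented
        return (
            self.record_ids == other.record_ids
            and self.symptom_names == other.symptom_names
            and self.causes == other.causes
            and np.array_equal(self.X, other.X)
            and np.array_equal(self.y, other.y)
        )
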