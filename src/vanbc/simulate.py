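"""Synthetic verbal-autopsy data generation.

The restricted study datasets (physician-coded VA surveys) cannot be
shipped, so this module generates structurally matched stand-ins:
binary symptom matrices with a controlled cause mix and per-cause
symptom prevalence profiles. Symptoms are conditionally independent
Bernoulli given the cause — exactly the naive Bayes assumption, which
makes parameter recovery well-posed — with an optional pairwise-copying
correlation knob to probe the violated-assumption regime.

Two families of presets are provided:

* separable data, where each cause owns a private "signature" symptom
  (present with probability ``signature_strength`` under its cause and
  at baseline otherwise), giving a known-answer regime for classifiers;
* imbalanced presets mirroring the published per-cause death counts and
  symptom counts of seven real VA study datasets (9–17 causes, 88–224
  symptoms, strong class imbalance), with random moderately overlapping
  symptom profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import VADataset

__all__ = [
    "SyntheticSpec",
    "generate",
    "make_separable_spec",
    "make_imbalanced_spec",
    "recover_parameters",
    "PRESETS",
]


# Per-cause death counts of the seven study datasets (None = cause absent)
# and their binary symptom counts. Cause order is the 17-group list.
_CAUSE_NAMES = (
    "Acute respiratory",
    "HIV/AIDS",
    "Diarrhoeal",
    "Pulmonary TB",
    "Other and unspecified infections",
    "Neoplasms",
    "Nutrition and endocrine",
    "Cardiovascular",
    "Chronic respiratory",
    "Liver cirrhosis",
    "Other non-communicable diseases",
    "Neonatal",
    "Road and transport injuries",
    "Other injuries",
    "Ill-defined",
    "Suicide",
    "Maternal",
)

_PRESET_COUNTS = {
    #                 symptom count, counts per 17-group cause (None = absent)
    "mds_child": (90, (3392, 5, 2711, 78, 2514, 96, 372, 18, 21, 112, 1345, 410, 95, 659, 397, None, None)),
    "agincourt": (88, (110, 2012, 66, 690, 432, 244, 70, 381, 27, 89, 221, None, 219, 366, 711, 125, 60)),
    "matlab_adult": (214, (11, None, 29, 43, 79, 352, 90, 714, 129, 100, 244, None, 49, 68, 35, 34, 23)),
    "phmrc_adult_global": (224, (304, None, 101, 177, 622, 497, None, 928, 84, 234, 697, None, 124, 471, None, 70, 345)),
    "phmrc_adult_india": (224, (81, None, 41, 21, 174, 19, None, 242, 52, 59, 125, None, 32, 218, None, 33, 136)),
    "phmrc_child_global": (133, (532, None, 256, None, 376, 28, None, 76, None, None, 186, None, 92, 324, 194, None, None)),
    "phmrc_child_india": (133, (141, None, 112, None, 187, 15, None, 25, None, None, 80, None, 64, 259, 65, None, None)),
}

PRESETS = tuple(sorted(_PRESET_COUNTS))


@dataclass
class SyntheticSpec:
    """Full generating recipe for one synthetic VA dataset.

    Parameters
    ----------
    causes : list of str
        Cause labels, length M.
    csmf : ndarray of shape (M,)
        Cause mix to draw record labels from; sums to 1.
    profile : ndarray of shape (M, S)
        Bernoulli prevalence of each symptom under each cause.
    N : int
        Number of records to generate.
    seed : int
        Generator seed; identical specs generate identical datasets.
    symptom_names : list of str, optional
        Defaults to s000, s001, ...
    signature_strength : float or None
        Provenance only: prevalence of each cause's private signature
        symptom if the profile was built by ``make_separable_spec``.
    rho : float, default=0.0
        Pairwise symptom copying: each odd column is overwritten by its
        left neighbour with this probability, breaking conditional
        independence while keeping marginals similar.
    """

    causes: list
    csmf: np.ndarray
    profile: np.ndarray
    N: int
    seed: int = 0
    symptom_names: list = field(default=None)  # type: ignore[assignment]
    signature_strength: float | None = None
    rho: float = 0.0

    def __post_init__(self):
        self.csmf = np.asarray(self.csmf, dtype=float)
        self.profile = np.asarray(self.profile, dtype=float)
        M = len(self.causes)
        if self.csmf.shape != (M,):
            raise ValueError("csmf length must match cause count")
        if (self.csmf < 0).any() or abs(self.csmf.sum() - 1.0) > 1e-9:
            raise ValueError("csmf must be non-negative and sum to 1")
        if self.profile.ndim != 2 or self.profile.shape[0] != M:
            raise ValueError("profile must be M x S")
        if ((self.profile < 0) | (self.profile > 1)).any():
            raise ValueError("profile entries must lie in [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.N < 1:
            raise ValueError("N must be positive")
        S = self.profile.shape[1]
        if self.symptom_names is None:
            self.symptom_names = [f"s{j:03d}" for j in range(S)]
        elif len(self.symptom_names) != S:
            raise ValueError("symptom_names length must match profile columns")

    @property
    def M(self) -> int:
        return len(self.causes)

    @property
    def S(self) -> int:
        return self.profile.shape[1]

    def to_dict(self) -> dict:
        return {
            "causes": list(self.causes),
            "csmf": self.csmf.tolist(),
            "profile": self.profile.tolist(),
            "N": int(self.N),
            "seed": int(self.seed),
            "symptom_names": list(self.symptom_names),
            "signature_strength": self.signature_strength,
            "rho": float(self.rho),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(
            causes=list(d["causes"]),
            csmf=np.asarray(d["csmf"], dtype=float),
            profile=np.asarray(d["profile"], dtype=float),
            N=int(d["N"]),
            seed=int(d["seed"]),
            symptom_names=list(d["symptom_names"]) if d.get("symptom_names") else None,
            signature_strength=d.get("signature_strength"),
            rho=float(d.get("rho", 0.0)),
        )


def generate(spec: SyntheticSpec, max_retries: int = 100, min_count: int = 1) -> VADataset:
    """Draw a VADataset from a SyntheticSpec (seeded, reproducible).

    Record causes are drawn from the spec's cause mix (redrawn up to
    ``max_retries`` times if some cause comes out with fewer than
    ``min_count`` records, so that the dataset invariant "every cause
    observed" holds), then symptom j of a cause-c record is
    Bernoulli(profile[c, j]).

    Parameters
    ----------
    min_count : int, default=1
        Minimum records per cause. Cross-validation consumers need at
        least 2 so every training part retains each cause.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    rng = np.random.default_rng(spec.seed)
    M, S, N = spec.M, spec.S, spec.N
    for _ in range(max_retries):
        cause_idx = rng.choice(M, size=N, p=spec.csmf)
        if np.bincount(cause_idx, minlength=M).min() >= min_count:
            break
    else:
        raise RuntimeError(
            f"a cause was drawn fewer than {min_count} times in "
            f"{max_retries} attempts; increase N or the smallest csmf entry"
        )
    X = (rng.random((N, S)) < spec.profile[cause_idx]).astype(np.int8)
    if spec.rho > 0:
        copy_mask = rng.random((N, S // 2)) < spec.rho
        for pair, j in enumerate(range(1, S, 2)):
            X[copy_mask[:, pair], j] = X[copy_mask[:, pair], j - 1]
    y = np.array([spec.causes[i] for i in cause_idx], dtype=object)
    return VADataset(
        record_ids=[f"d{i:06d}" for i in range(N)],
        symptom_names=list(spec.symptom_names),
        X=X,
        y=y,
        causes=list(spec.causes),
    )


def make_separable_spec(
    M: int = 15,
    N: int = 3000,
    seed: int = 0,
    signature_strength: float = 1.0,
    baseline: float = 0.0,
    extra_symptoms: int = 0,
    extra_prevalence: float = 0.3,
    csmf=None,
) -> SyntheticSpec:
    """Spec where cause c owns private signature symptom c.

    With ``signature_strength=1`` and ``baseline=0`` each record shows
    exactly its cause's signature symptom, so any consistent classifier
    recovers the cause perfectly. ``extra_symptoms`` adds shared
    noise columns with common prevalence ``extra_prevalence``.
    """
    if M < 2:
        raise ValueError("need at least two causes")
    S = M + extra_symptoms
    profile = np.full((M, S), float(baseline))
    np.fill_diagonal(profile[:, :M], float(signature_strength))
    if extra_symptoms:
        profile[:, M:] = float(extra_prevalence)
    if csmf is None:
        csmf = np.full(M, 1.0 / M)
    return SyntheticSpec(
        causes=[f"cause_{i:02d}" for i in range(M)],
        csmf=np.asarray(csmf, dtype=float),
        profile=profile,
        N=N,
        seed=seed,
        signature_strength=float(signature_strength),
    )


def make_imbalanced_spec(template: str, N: int = 2000, seed: int = 0) -> SyntheticSpec:
    """Spec whose cause mix mirrors a study dataset's death counts.

    The cause fractions are proportional to the published per-cause
    death counts of the named dataset (causes absent there are
    dropped), and the symptom count matches that dataset. Symptom
    profiles are random with substantial overlap, calibrated to the
    difficulty regime real VA data exhibits (top-rank sensitivity far
    below 1): every symptom has a shared baseline prevalence drawn from
    U(0.05, 0.25), and each cause elevates a small characteristic
    subset (5% of symptoms, drawn from a common pool covering 30% of
    symptoms so causes share markers) by +U(0.15, 0.35).
    """
    if template not in _PRESET_COUNTS:
        raise ValueError(
            f"unknown preset {template!r}; available: {', '.join(PRESETS)}"
        )
    S, counts = _PRESET_COUNTS[template]
    causes = [c for c, n in zip(_CAUSE_NAMES, counts) if n is not None]
    count_vec = np.array([n for n in counts if n is not None], dtype=float)
    csmf = count_vec / count_vec.sum()
    M = len(causes)

    rng = np.random.default_rng(seed)
    baseline = rng.uniform(0.05, 0.25, size=S)
    profile = np.tile(baseline, (M, 1))
    pool = rng.choice(S, size=max(3, int(S * 0.30)), replace=False)
    n_char = max(2, int(S * 0.05))
    for c in range(M):
        chars = rng.choice(pool, size=min(n_char, len(pool)), replace=False)
        profile[c, chars] = np.clip(
            baseline[chars] + rng.uniform(0.15, 0.35, size=len(chars)), 0.0, 0.95
        )
    return SyntheticSpec(
        causes=causes,
        csmf=csmf,
        profile=profile,
        N=N,
        seed=seed,
    )


def recover_parameters(ds: VADataset, alpha: float = 0.0):
    """Empirical generator estimates from a dataset.

    Returns ``(csmf_hat, profile_hat)`` aligned to ``ds.causes`` and
    ``ds.symptom_names``: class fractions and per-cause symptom
    frequencies ((count + alpha) / (n_c + 2*alpha), the Beta-smoothed
    Bernoulli rate). Useful for checking generated data against its
    spec and for split-half stability checks.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    M, S = ds.n_causes, ds.n_symptoms
    csmf_hat = ds.csmf()
    profile_hat = np.empty((M, S))
    for i, c in enumerate(ds.causes):
        rows = ds.X[ds.y == c]
        profile_hat[i] = (rows.sum(axis=0) + alpha) / (len(rows) + 2 * alpha)
    return csmf_hat, profile_hat
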