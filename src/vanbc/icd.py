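"""ICD-10 code grouping into the 17 broad cause-of-death categories.

Physician-assigned ICD-10 codes are collapsed into 17 broad cause
groups before training/evaluation. Range membership compares the
3-character code root — (letter block, 2-digit number) — so a bare
3-character range bound such as ``B20`` includes all of its 4-character
children (``B20.1``, ``B201``). A handful of codes sit in two groups in
the published table (e.g. D64, G40, R04, Q00–Q99 appear under both a
general group and Neonatal); the resolution policy is explicit and
configurable because the grouping is plausibly age-conditional.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "CauseGroup",
    "CauseGroupTable",
    "load_cause_groups",
    "map_icd10",
    "NEONATAL_GROUP",
]

NEONATAL_GROUP = 12

# 1-2 letter block, two digits, optional suffix ("B20", "B20.1", "B201", "ZZ21")
_ICD_RE = re.compile(r"^([A-Z]{1,2})(\d{2})(?:\.?[0-9A-Z]{0,2})$")


def _code_key(code: str):
    """Return the orderable (letters, number) root of an ICD-10 code."""
    m = _ICD_RE.match(code.strip().upper())
    if m is None:
        raise ValueError(f"not an ICD-10 code: {code!r}")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class CauseGroup:
    """One broad cause group and its inclusive ICD-10 code ranges."""

    number: int
    name: str
    ranges: tuple  # of ((letters, lo), (letters, hi)) pairs

    def contains(self, code: str) -> bool:
        key = _code_key(code)
        return any(lo <= key <= hi for lo, hi in self.ranges)


class CauseGroupTable:
    """Ordered collection of the broad cause groups.

    Parameters
    ----------
    groups : sequence of CauseGroup
        Group numbers must be unique; each range must satisfy lo <= hi.
    """

    def __init__(self, groups) -> None:
        self.groups = sorted(groups, key=lambda g: g.number)
        numbers = [g.number for g in self.groups]
        if len(set(numbers)) != len(numbers):
            raise ValueError("duplicate group numbers")
        for g in self.groups:
            for lo, hi in g.ranges:
                if lo > hi:
                    raise ValueError(
                        f"group {g.number}: inverted range {lo}..{hi}"
                    )

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    def group(self, number: int) -> CauseGroup:
        for g in self.groups:
            if g.number == number:
                return g
        raise KeyError(number)

    def name_of(self, number: int) -> str:
        return self.group(number).name

    def matching_groups(self, code: str) -> list:
        """All group numbers whose ranges contain ``code`` (ascending)."""
        return [g.number for g in self.groups if g.contains(code)]


def _parse_ranges(spec: str) -> tuple:
    out = []
    for part in spec.split(";"):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo_s, hi_s = (p.strip() for p in part.split("-", 1))
            lo = _code_key(lo_s)
            # tolerate "I26-28": bare numeric upper bound inherits the letters
            hi = (lo[0], int(hi_s)) if hi_s.isdigit() else _code_key(hi_s)
        else:
            lo = hi = _code_key(part)
        out.append((lo, hi))
    return tuple(out)


def load_cause_groups(path=None) -> CauseGroupTable:
    """Load a cause-group table from CSV.

    The CSV needs columns ``group_number``, ``group_name`` and
    ``icd_ranges`` (semicolon-separated ``start-end`` ranges or single
    codes). With no path, the packaged 17-group table is loaded.
    """
    if path is None:
        src = resources.files("vanbc").joinpath("data/cause_groups.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    groups = [
        CauseGroup(
            number=int(row.group_number),
            name=str(row.group_name),
            ranges=_parse_ranges(str(row.icd_ranges)),
        )
        for row in df.itertuples()
    ]
    return CauseGroupTable(groups)


def map_icd10(
    code: str,
    table: CauseGroupTable | None = None,
    policy: str = "lowest",
    age_days: float | None = None,
):
    """Map one ICD-10 code to its broad cause-group number.

    Parameters
    ----------
    code : str
        ICD-10 code (letter block + 2 digits, optional suffix).
    table : CauseGroupTable, optional
        Defaults to the packaged 17-group table.
    policy : {"lowest", "neonatal", "age"}
        Tie-break when the code belongs to several groups: ``lowest``
        returns the smallest group number; ``neonatal`` prefers the
        Neonatal group when it is among the matches; ``age`` applies the
        neonatal preference only when ``age_days`` <= 28.
    age_days : float, optional
        Age at death in days; only consulted by the ``age`` policy.

    Returns
    -------
    int or None
        The group number, or None when no range contains the code
        (an explicit "unmapped" result, not an exception). Ambiguous
        codes resolve per ``policy`` and emit a warning.
    """
    if table is None:
        table = load_cause_groups()
    matches = table.matching_groups(code)
    if not matches:
        return None
    if len(matches) == 1:
        return matches[0]

    if policy == "age":
        prefer_neonatal = age_days is not None and age_days <= 28
    elif policy == "neonatal":
        prefer_neonatal = True
    elif policy == "lowest":
        prefer_neonatal = False
    else:
        raise ValueError(f"unknown overlap policy: {policy!r}")

    if prefer_neonatal and NEONATAL_GROUP in matches:
        chosen = NEONATAL_GROUP
    else:
        chosen = min(m for m in matches)
    warnings.warn(
        f"ICD-10 code {code} matches groups {matches}; "
        f"policy {policy!r} chose {chosen}",
        stacklevel=2,
    )
    return chosen
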