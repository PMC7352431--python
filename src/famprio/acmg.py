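"""ACMG/AMP evidence combination into the five-tier classification.

The combining table ships as a packaged JSON rule file
(``data/acmg_rules.json``); the engine only counts evidence codes per
strength category and matches the count thresholds, so alternative
tables can be swapped in.  Conflicting pathogenic- and benign-side
evidence, like no evidence at all, yields "Uncertain significance".
"""

from __future__ import annotations

import json
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "ALL_CODES",
    "EvidenceSet",
    "combine_evidence",
    "load_rule_table",
]

PATHOGENIC = "Pathogenic"
LIKELY_PATHOGENIC = "Likely pathogenic"
VUS = "Uncertain significance"
LIKELY_BENIGN = "Likely benign"
BENIGN = "Benign"

CLASSIFICATIONS = (PATHOGENIC, LIKELY_PATHOGENIC, VUS, LIKELY_BENIGN, BENIGN)

ALL_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

_STRENGTH = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)(\d+)$")


class EvidenceSet(frozenset):
    """A set of ACMG evidence codes; unknown codes are rejected."""

    def __new__(cls, codes: Iterable[str] = ()):
        codes = frozenset(c.strip().upper() for c in codes if str(c).strip())
        unknown = codes - ALL_CODES
        if unknown:
            raise ValueError(f"unknown evidence code(s): {', '.join(sorted(unknown))}")
        return super().__new__(cls, codes)

    @classmethod
    def from_string(cls, text: str) -> "EvidenceSet":
        return cls(c for c in re.split(r"[,\s]+", text) if c)

    def counts(self) -> dict[str, int]:
        out = {"pvs": 0, "ps": 0, "pm": 0, "pp": 0, "ba": 0, "bs": 0, "bp": 0}
        for code in self:
            out[_STRENGTH.match(code).group(1).lower()] += 1
        return out


def load_rule_table(path: Optional[str | Path] = None) -> dict:
    if path is not None:
        raw = Path(path).read_text()
    else:
        raw = resources.files("famprio.data").joinpath("acmg_rules.json").read_text()
    table = json.loads(raw)
    for section in ("pathogenic", "likely_pathogenic", "benign", "likely_benign"):
        if section not in table:
            raise ValueError(f"rule table missing section {section!r}")
    return table


def _matches(counts: dict[str, int], rules: list[dict]) -> bool:
    return any(
        all(counts.get(cat, 0) >= n for cat, n in rule.items()) for rule in rules
    )


def combine_evidence(
    ev: EvidenceSet | Iterable[str], rule_table: Optional[dict] = None
) -> str:
    """Combine evidence codes into one of the five tiers.

    The strongest matching pathogenic-side and benign-side tiers are
    determined independently; if both sides match, the result is
    "Uncertain significance".
    """
    if not isinstance(ev, EvidenceSet):
        ev = EvidenceSet(ev)
    table = rule_table or load_rule_table()
    counts = ev.counts()

    path_tier = None
    if _matches(counts, table["pathogenic"]):
        path_tier = PATHOGENIC
    elif _matches(counts, table["likely_pathogenic"]):
        path_tier = LIKELY_PATHOGENIC

    benign_tier = None
    if _matches(counts, table["benign"]):
        benign_tier = BENIGN
    elif _matches(counts, table["likely_benign"]):
        benign_tier = LIKELY_BENIGN

    if path_tier and benign_tier:
        return VUS
    return path_tier or benign_tier or VUS
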