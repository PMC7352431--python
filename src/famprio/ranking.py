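"""Gene-level intolerance ranking of surviving candidates.

Intolerance evidence is used to *order* candidates, never to drop them.
The composite score is the mean of the available intolerance percentiles
(rescaled to 0-1; 0.5 when none are available) plus a normalized
variant-class component: pLI for truncating classes, a logistic squash
of the missense Z-score for missense variants.  Missing class scores are
neutral.  Weights are configurable; the combination itself is a
symmetric default, not a published formula.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .variants import AnnotatedVariant

__all__ = [
    "GeneIntoleranceRecord",
    "read_intolerance_table",
    "variant_class_score",
    "composite_rank",
]

PERCENTILE_SOURCES = ("esp6500", "exac", "local")

#: consequence classes scored with pLI (loss of function)
LOF_CLASSES = ("nonsense", "frameshift", "splice")


@dataclass(frozen=True)
class GeneIntoleranceRecord:
    gene: str
    intolerance_percentiles: dict[str, Optional[float]]
    pli: Optional[float] = None
    mis_z: Optional[float] = None

    def __post_init__(self) -> None:
        for src, pct in self.intolerance_percentiles.items():
            if pct is not None and not 0.0 <= pct <= 100.0:
                raise ValueError(f"percentile {pct} for {src} outside [0, 100]")
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"pLI {self.pli} outside [0, 1]")


def read_intolerance_table(path: str | Path) -> dict[str, GeneIntoleranceRecord]:
    """Read a TSV with columns gene, esp6500_pct, exac_pct, local_pct,
    pli, mis_z ('.' for missing)."""
    records = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            def parse(col):
                raw = row.get(col, ".")
                return None if raw in ("", ".") else float(raw)

            records[row["gene"]] = GeneIntoleranceRecord(
                gene=row["gene"],
                intolerance_percentiles={
                    "esp6500": parse("esp6500_pct"),
                    "exac": parse("exac_pct"),
                    "local": parse("local_pct"),
                },
                pli=parse("pli"),
                mis_z=parse("mis_z"),
            )
    return records


def variant_class_score(
    v: AnnotatedVariant, rec: Optional[GeneIntoleranceRecord]
) -> float:
    """pLI for truncating variants, missense Z for missense, neutral 0
    when the score (or the whole record) is missing."""
    if rec is None:
        return 0.0
    if v.consequence in LOF_CLASSES:
        return rec.pli if rec.pli is not None else 0.0
    if v.consequence == "missense":
        return rec.mis_z if rec.mis_z is not None else 0.0
    return 0.0


def _class_component(v: AnnotatedVariant, rec: Optional[GeneIntoleranceRecord]) -> float:
    raw = variant_class_score(v, rec)
    if v.consequence in LOF_CLASSES:
        return raw  # pLI is already on [0, 1]
    if v.consequence == "missense":
        return 1.0 / (1.0 + math.exp(-raw))  # Z-score squashed to (0, 1)
    return 0.0


def _percentile_component(rec: Optional[GeneIntoleranceRecord]) -> float:
    if rec is None:
        return 0.5
    pcts = [p for p in rec.intolerance_percentiles.values() if p is not None]
    if not pcts:
        return 0.5
    return sum(pcts) / len(pcts) / 100.0


def rank_score(
    v: AnnotatedVariant,
    rec: Optional[GeneIntoleranceRecord],
    percentile_weight: float = 1.0,
    class_weight: float = 1.0,
) -> float:
    return percentile_weight * _percentile_component(rec) + class_weight * _class_component(v, rec)


def composite_rank(
    candidates: Sequence[AnnotatedVariant],
    records: dict[str, GeneIntoleranceRecord],
    percentile_weight: float = 1.0,
    class_weight: float = 1.0,
) -> list[tuple[AnnotatedVariant, float]]:
    """Order candidates by descending composite score; never drops any.

    Ties (including all-missing intolerance data) break on (chrom, pos,
    ref, alt).  Output is a permutation of the input.
    """
    scored = [
        (v, rank_score(v, records.get(v.gene), percentile_weight, class_weight))
        for v in candidates
    ]
    scored.sort(key=lambda item: (-item[1], item[0].chrom, item[0].pos, item[0].ref, item[0].alt))
    return scored
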