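"""Quantification of the wet-lab readouts.

qPCR relative telomere length: the telomere-to-single-copy-gene ratio is
T/S = 2^-(mean Ct_telomere - mean Ct_albumin); replicate Cts are averaged
within a run, the run-level T/S values averaged across runs, and RTL is
the sample T/S divided by the T/S of a reference DNA pool.  No
amplification-efficiency correction is applied.

ChIP dot-blot enrichment: the immunoprecipitated signal divided by the
input signal after scaling the input lane up to the total chromatin it
represents (input_signal / input_fraction).

Group comparison is the classical two-sample equal-variance t-test,
two-tailed.
"""

from __future__ import annotations

import csv
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "ChipMeasurement",
    "ts_ratio",
    "relative_tl",
    "chip_enrichment",
    "compare_rtl_groups",
    "read_ct_table",
    "read_blot_table",
    "rtl_table",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct replicates for one sample: per-run replicate lists per target."""

    sample: str
    ct_telomere: tuple[tuple[float, ...], ...]
    ct_albumin: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.ct_telomere) != len(self.ct_albumin):
            raise ValueError(f"{self.sample}: run counts differ between targets")
        if not self.ct_telomere:
            raise ValueError(f"{self.sample}: no runs")
        for runs in (self.ct_telomere, self.ct_albumin):
            for cts in runs:
                for ct in cts:
                    if not math.isfinite(ct) or ct <= 0:
                        raise ValueError(f"{self.sample}: invalid Ct {ct}")

    @property
    def n_runs(self) -> int:
        return len(self.ct_telomere)


@dataclass(frozen=True)
class ChipMeasurement:
    sample: str
    antibody: str  # "target" or "IgG"
    chip_signal: float
    input_signal: float
    input_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.chip_signal < 0 or self.input_signal < 0:
            raise ValueError(f"{self.sample}: signals must be >= 0")
        if not 0.0 < self.input_fraction <= 1.0:
            raise ValueError(f"{self.sample}: input_fraction outside (0, 1]")


def ts_ratio(m: QpcrMeasurement) -> float:
    """T/S = 2^-dCt per run, averaged across runs."""
    per_run = []
    for tel, alb in zip(m.ct_telomere, m.ct_albumin):
        if not tel or not alb:
            raise ValueError(f"{m.sample}: a run is missing all Cts for a target")
        d_ct = sum(tel) / len(tel) - sum(alb) / len(alb)
        per_run.append(2.0 ** (-d_ct))
    return sum(per_run) / len(per_run)


def relative_tl(sample_ts: float, reference_ts: float) -> float:
    if not reference_ts > 0:
        raise ValueError(f"reference T/S must be positive, got {reference_ts}")
    return sample_ts / reference_ts


def chip_enrichment(m: ChipMeasurement) -> float:
    """ChIP signal over total input signal (input lane scaled up by the
    chromatin fraction it was loaded from)."""
    if m.input_signal <= 0:
        raise ValueError(f"{m.sample}: input signal must be positive")
    return m.chip_signal / (m.input_signal / m.input_fraction)


def compare_rtl_groups(
    group_a: Sequence[float], group_b: Sequence[float], tails: int = 2
):
    """Two-sample equal-variance Student's t-test on RTL values.

    Returns (t, p).  Degenerate input (zero pooled variance) raises.
    """
    if tails != 2:
        raise ValueError("only the two-tailed test is supported")
    a, b = list(group_a), list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    pooled = sum((x - sum(a) / len(a)) ** 2 for x in a) + sum(
        (x - sum(b) / len(b)) ** 2 for x in b
    )
    if pooled == 0.0:
        raise ValueError("zero pooled variance: t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# long-format table I/O
# ---------------------------------------------------------------------------


def read_ct_table(path: str | Path) -> list[QpcrMeasurement]:
    """Read a long TSV (sample, run, target, replicate, ct); target is
    'telomere' or 'albumin'."""
    by_sample: dict[str, dict[str, dict[str, list[tuple[int, float]]]]] = defaultdict(
        lambda: defaultdict(lambda: {"telomere": [], "albumin": []})
    )
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            target = row["target"]
            if target not in ("telomere", "albumin"):
                raise ValueError(f"unknown target {target!r}")
            by_sample[row["sample"]][row["run"]][target].append(
                (int(row["replicate"]), float(row["ct"]))
            )
    measurements = []
    for sample, runs in by_sample.items():
        tel, alb = [], []
        for run in sorted(runs):
            tel.append(tuple(ct for _, ct in sorted(runs[run]["telomere"])))
            alb.append(tuple(ct for _, ct in sorted(runs[run]["albumin"])))
        measurements.append(QpcrMeasurement(sample, tuple(tel), tuple(alb)))
    return measurements


def read_blot_table(path: str | Path) -> list[ChipMeasurement]:
    """Read a TSV (sample, antibody, chip_signal, input_signal,
    input_fraction)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ChipMeasurement(
                    sample=row["sample"],
                    antibody=row["antibody"],
                    chip_signal=float(row["chip_signal"]),
                    input_signal=float(row["input_signal"]),
                    input_fraction=float(row.get("input_fraction", 1.0)),
                )
            )
    return out


def rtl_table(
    measurements: Sequence[QpcrMeasurement], reference_sample: str
) -> dict[str, dict[str, float]]:
    """Per-sample T/S and RTL against the named reference sample."""
    ts = {m.sample: ts_ratio(m) for m in measurements}
    if reference_sample not in ts:
        raise ValueError(f"reference sample {reference_sample!r} not in table")
    ref = ts[reference_sample]
    return {s: {"ts": t, "rtl": relative_tl(t, ref)} for s, t in ts.items()}
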