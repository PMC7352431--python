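"""Annotated multi-sample variant tables: domain types and I/O.

Two on-disk dialects carry the same information:

* VCF 4.x with per-alt INFO keys (``CADD_PHRED``, ``GERP``, ``PHASTCONS``,
  ``PHYLOP``, ``MAF_1KG``, ``MAF_EXAC_NONTCGA``, ``GENE``, ``CSQ_CLASS``
  and one key per deleteriousness predictor, value D/T) plus FORMAT
  GT/DP.  Read with cyvcf2; multi-allelic records are split into one
  variant per alternate allele.
* a flat tab-separated table with one row per (variant, alt), genotype
  dosage columns ``gt_<member>`` and depth columns ``dp_<member>``.
  Missing values are written as ``.``.

Coordinates are 1-based as in VCF; no indel re-normalization is done.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .pedigree import Pedigree

__all__ = [
    "PREDICTOR_TOOLS",
    "CONSEQUENCES",
    "PredictorCalls",
    "AnnotatedVariant",
    "read_variant_table",
    "write_variant_table",
    "write_funnel_report",
]

#: the ten deleteriousness predictors, in canonical column order
PREDICTOR_TOOLS = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "MetaSVM",
    "MetaLR",
    "PROVEAN",
)

CONSEQUENCES = (
    "synonymous",
    "missense",
    "nonsense",
    "splice",
    "frameshift",
    "inframe_indel",
    "other",
)

MAF_SOURCES = ("thousand_genomes", "exac_nontcga")


class PredictorCalls:
    """Calls from the ten predictors: deleterious / tolerated / missing."""

    __slots__ = ("_calls",)

    def __init__(self, calls: Optional[dict[str, Optional[str]]] = None):
        calls = dict(calls or {})
        unknown = set(calls) - set(PREDICTOR_TOOLS)
        if unknown:
            raise ValueError(f"unknown predictor tool(s): {sorted(unknown)}")
        for tool, call in calls.items():
            if call not in ("deleterious", "tolerated", None):
                raise ValueError(f"invalid call {call!r} for {tool}")
        self._calls = {t: calls.get(t) for t in PREDICTOR_TOOLS}

    def __getitem__(self, tool: str) -> Optional[str]:
        return self._calls[tool]

    def __eq__(self, other) -> bool:
        return isinstance(other, PredictorCalls) and self._calls == other._calls

    def __repr__(self) -> str:
        short = {"deleterious": "D", "tolerated": "T", None: "."}
        return "PredictorCalls(" + "".join(short[self._calls[t]] for t in PREDICTOR_TOOLS) + ")"

    def as_dict(self) -> dict[str, Optional[str]]:
        return dict(self._calls)

    @property
    def n_available(self) -> int:
        return sum(1 for c in self._calls.values() if c is not None)

    @property
    def n_deleterious(self) -> int:
        return sum(1 for c in self._calls.values() if c == "deleterious")

    @classmethod
    def from_letters(cls, letters: str) -> "PredictorCalls":
        """Build from a 10-character D/T/. string in canonical tool order."""
        if len(letters) != len(PREDICTOR_TOOLS):
            raise ValueError("expected one letter per predictor tool")
        decode = {"D": "deleterious", "T": "tolerated", ".": None}
        return cls({t: decode[ch] for t, ch in zip(PREDICTOR_TOOLS, letters)})


@dataclass
class AnnotatedVariant:
    """One bi-allelic variant row with genotypes and annotations.

    ``genotypes`` maps member id -> alternate-allele dosage (0/1/2) or
    None; ``depth`` maps member id -> read depth.  Annotation scores are
    None when absent from the source table.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: Optional[float] = None
    genotypes: dict[str, Optional[int]] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)
    maf_sources: dict[str, Optional[float]] = field(default_factory=dict)
    cadd_phred: Optional[float] = None
    gerp: Optional[float] = None
    phastcons: Optional[float] = None
    phylop: Optional[float] = None
    predictor_calls: PredictorCalls = field(default_factory=PredictorCalls)
    gene: str = ""
    consequence: str = "other"
    caller_filter_pass: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for src, f in self.maf_sources.items():
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError(f"MAF {f} from {src} outside [0, 1]")
        if self.phastcons is not None and not 0.0 <= self.phastcons <= 1.0:
            raise ValueError(f"PhastCons {self.phastcons} outside [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_INFO_KEYS = {
    "cadd_phred": "CADD_PHRED",
    "gerp": "GERP",
    "phastcons": "PHASTCONS",
    "phylop": "PHYLOP",
}
_MAF_KEYS = {"thousand_genomes": "MAF_1KG", "exac_nontcga": "MAF_EXAC_NONTCGA"}
_TOOL_KEY = {t: t.upper() for t in PREDICTOR_TOOLS}


def read_variant_table(
    path: str | Path, dialect: str, ped: Pedigree
) -> list[AnnotatedVariant]:
    """Read an annotated variant table in the ``vcf`` or ``tsv`` dialect.

    Sample columns must all correspond to pedigree member ids; a
    mismatch raises ``ValueError`` listing the unmatched ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "vcf":
        return _read_vcf(path, ped)
    if dialect == "tsv":
        return _read_tsv(path, ped)
    raise ValueError(f"unknown dialect {dialect!r}")


def _check_samples(samples, ped: Pedigree, where: str) -> None:
    unmatched = [s for s in samples if s not in ped]
    if unmatched:
        raise ValueError(
            f"{where}: sample ids not in pedigree: {', '.join(unmatched)}"
        )


def _read_vcf(path: Path, ped: Pedigree) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    _check_samples(samples, ped, str(path))

    variants: list[AnnotatedVariant] = []
    for record in vcf:
        n_alt = len(record.ALT)
        for alt_idx, alt in enumerate(record.ALT):
            genotypes: dict[str, Optional[int]] = {}
            for sample, gt in zip(samples, record.genotypes):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):  # half-calls conservative-missing
                    genotypes[sample] = None
                else:
                    genotypes[sample] = sum(1 for a in alleles if a == alt_idx + 1)
            depth: dict[str, int] = {}
            dp_field = record.format("DP")
            if dp_field is not None:
                for sample, dp in zip(samples, dp_field[:, 0]):
                    if dp >= 0:  # htslib encodes missing as large negative
                        depth[sample] = int(dp)
            if not depth and record.INFO.get("DP") is not None:
                # record-level DP copied to every sample with a genotype
                depth = {s: int(record.INFO["DP"]) for s in samples}

            def info_per_alt(key):
                val = record.INFO.get(key)
                if val is None:
                    return None
                if isinstance(val, tuple):
                    val = val[alt_idx] if alt_idx < len(val) else None
                if isinstance(val, str):
                    parts = val.split(",")
                    val = parts[alt_idx] if n_alt > 1 and len(parts) == n_alt else val
                    if val in (".", ""):
                        return None
                return val

            numeric = {}
            for attr, key in _INFO_KEYS.items():
                raw = info_per_alt(key)
                numeric[attr] = None if raw is None else float(raw)
            mafs = {}
            for src, key in _MAF_KEYS.items():
                raw = info_per_alt(key)
                mafs[src] = None if raw is None else float(raw)
            calls = {}
            for tool, key in _TOOL_KEY.items():
                raw = info_per_alt(key)
                if raw in (None, "."):
                    calls[tool] = None
                elif raw in ("D", "deleterious"):
                    calls[tool] = "deleterious"
                elif raw in ("T", "tolerated"):
                    calls[tool] = "tolerated"
                else:
                    raise ValueError(
                        f"{path}: invalid predictor call {raw!r} for {key} "
                        f"at {record.CHROM}:{record.POS}"
                    )
            gene = info_per_alt("GENE") or ""
            csq = info_per_alt("CSQ_CLASS") or "other"
            variants.append(
                AnnotatedVariant(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    qual=record.QUAL,
                    genotypes=genotypes,
                    depth=depth,
                    maf_sources=mafs,
                    predictor_calls=PredictorCalls(calls),
                    gene=str(gene),
                    consequence=str(csq),
                    caller_filter_pass=record.FILTER is None,  # None == PASS
                    **numeric,
                )
            )
    return variants


_TSV_FIXED = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "qual",
    "filter_pass",
    "gene",
    "consequence",
    "maf_1kg",
    "maf_exac_nontcga",
    "cadd_phred",
    "gerp",
    "phastcons",
    "phylop",
]


def _read_tsv(path: Path, ped: Pedigree) -> list[AnnotatedVariant]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing_cols = [c for c in _TSV_FIXED if c not in header]
        if missing_cols:
            raise ValueError(f"{path}: missing columns {missing_cols}")
        gt_samples = [c[3:] for c in header if c.startswith("gt_")]
        _check_samples(gt_samples, ped, str(path))

        def parse(raw, conv):
            return None if raw in (None, "", ".") else conv(raw)

        variants = []
        for lineno, row in enumerate(reader, start=2):
            genotypes: dict[str, Optional[int]] = {}
            for s in gt_samples:
                raw = row.get(f"gt_{s}", ".")
                if raw in ("", "."):
                    genotypes[s] = None
                elif raw in ("0", "1", "2"):
                    genotypes[s] = int(raw)
                else:
                    raise ValueError(
                        f"{path}:{lineno}: malformed genotype {raw!r} for {s}"
                    )
            depth = {}
            for s in gt_samples:
                raw = row.get(f"dp_{s}")
                if raw not in (None, "", "."):
                    depth[s] = int(raw)
            calls = {}
            for tool in PREDICTOR_TOOLS:
                raw = row.get(tool, ".")
                calls[tool] = {
                    "D": "deleterious",
                    "T": "tolerated",
                    ".": None,
                    "": None,
                }.get(raw)
                if raw not in ("D", "T", ".", "", None):
                    raise ValueError(
                        f"{path}:{lineno}: invalid predictor call {raw!r}"
                    )
            variants.append(
                AnnotatedVariant(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    qual=parse(row["qual"], float),
                    genotypes=genotypes,
                    depth=depth,
                    maf_sources={
                        "thousand_genomes": parse(row["maf_1kg"], float),
                        "exac_nontcga": parse(row["maf_exac_nontcga"], float),
                    },
                    cadd_phred=parse(row["cadd_phred"], float),
                    gerp=parse(row["gerp"], float),
                    phastcons=parse(row["phastcons"], float),
                    phylop=parse(row["phylop"], float),
                    predictor_calls=PredictorCalls(calls),
                    gene=row["gene"],
                    consequence=row["consequence"],
                    caller_filter_pass=row["filter_pass"] == "1",
                )
            )
    return variants


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        if math.isnan(value):
            return "."
        return repr(value)  # repr round-trips float64
    return str(value)


def write_variant_table(
    variants: list[AnnotatedVariant],
    path: str | Path,
    dialect: str,
    ped: Pedigree,
) -> None:
    """Write variants in the ``tsv`` or ``vcf`` dialect.

    Sample columns are the pedigree's sample-available members in
    pedigree order.
    """
    samples = ped.genotyped_ids()
    if dialect == "tsv":
        _write_tsv(variants, Path(path), samples)
    elif dialect == "vcf":
        _write_vcf(variants, Path(path), samples)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_tsv(variants, path: Path, samples) -> None:
    header = (
        _TSV_FIXED
        + list(PREDICTOR_TOOLS)
        + [f"gt_{s}" for s in samples]
        + [f"dp_{s}" for s in samples]
    )
    letter = {"deleterious": "D", "tolerated": "T", None: "."}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for v in variants:
            row = [
                v.chrom,
                v.pos,
                v.ref,
                v.alt,
                _fmt(v.qual),
                "1" if v.caller_filter_pass else "0",
                v.gene,
                v.consequence,
                _fmt(v.maf_sources.get("thousand_genomes")),
                _fmt(v.maf_sources.get("exac_nontcga")),
                _fmt(v.cadd_phred),
                _fmt(v.gerp),
                _fmt(v.phastcons),
                _fmt(v.phylop),
            ]
            row += [letter[v.predictor_calls[t]] for t in PREDICTOR_TOOLS]
            row += [_fmt(v.genotypes.get(s)) for s in samples]
            row += [_fmt(v.depth.get(s)) for s in samples]
            writer.writerow(row)


_VCF_HEADER_INFO = (
    [
        ("MAF_1KG", "A", "Float", "Minor allele frequency, 1000 Genomes Phase 3"),
        ("MAF_EXAC_NONTCGA", "A", "Float", "Minor allele frequency, non-TCGA ExAC"),
        ("CADD_PHRED", "A", "Float", "Scaled PHRED-like CADD score"),
        ("GERP", "A", "Float", "GERP conservation score"),
        ("PHASTCONS", "A", "Float", "PhastCons conservation score"),
        ("PHYLOP", "A", "Float", "PhyloP conservation score"),
        ("GENE", "A", "String", "Gene symbol"),
        ("CSQ_CLASS", "A", "String", "Consequence class"),
    ]
    + [(t.upper(), "A", "String", f"{t} call (D/T)") for t in PREDICTOR_TOOLS]
)


def _write_vcf(variants, path: Path, samples) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=famprio"]
    seen: list[str] = []
    for v in variants:
        if v.chrom not in seen:
            seen.append(v.chrom)
    lines += [f"##contig=<ID={c}>" for c in seen]
    for key, number, vtype, desc in _VCF_HEADER_INFO:
        lines.append(
            f'##INFO=<ID={key},Number={number},Type={vtype},Description="{desc}">'
        )
    lines.append('##FILTER=<ID=caller_fail,Description="Failed caller internal filters">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    letter = {"deleterious": "D", "tolerated": "T", None: "."}
    for v in variants:
        info = []
        for key, value in [
            ("MAF_1KG", v.maf_sources.get("thousand_genomes")),
            ("MAF_EXAC_NONTCGA", v.maf_sources.get("exac_nontcga")),
            ("CADD_PHRED", v.cadd_phred),
            ("GERP", v.gerp),
            ("PHASTCONS", v.phastcons),
            ("PHYLOP", v.phylop),
        ]:
            if value is not None:
                info.append(f"{key}={_fmt(value)}")
        if v.gene:
            info.append(f"GENE={v.gene}")
        info.append(f"CSQ_CLASS={v.consequence}")
        for t in PREDICTOR_TOOLS:
            call = v.predictor_calls[t]
            if call is not None:
                info.append(f"{t.upper()}={letter[call]}")
        fields = [
            v.chrom,
            str(v.pos),
            ".",
            v.ref,
            v.alt,
            _fmt(v.qual),
            "PASS" if v.caller_filter_pass else "caller_fail",
            ";".join(info) or ".",
            "GT:DP",
        ]
        for s in samples:
            dp = v.depth.get(s)
            fields.append(f"{gt_str[v.genotypes.get(s)]}:{dp if dp is not None else '.'}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def write_funnel_report(report, out_dir: str | Path) -> None:
    """Write a finalized cascade report: funnel TSV with the per-variant
    decision trail appended, a candidate table and a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lines = ["stage\tsurviving"]
    lines += [f"{stage}\t{count}" for stage, count in report.stage_counts]
    lines.append("")
    lines.append("variant\t" + "\t".join(s for s, _ in report.stage_counts))
    for key in sorted(report.trail):
        decisions = report.trail[key]
        lines.append(
            key + "\t" + "\t".join(decisions[s] for s, _ in report.stage_counts)
        )
    (out_dir / "funnel.tsv").write_text("\n".join(lines) + "\n")

    cand_lines = ["rank\tvariant\tgene\tconsequence\trank_score\trescued"]
    for rank, (v, score) in enumerate(report.candidates, start=1):
        cand_lines.append(
            f"{rank}\t{v.key}\t{v.gene}\t{v.consequence}\t{score:.6f}"
            f"\t{'1' if v.key in report.rescued else '0'}"
        )
    (out_dir / "candidates.tsv").write_text("\n".join(cand_lines) + "\n")

    summary = {
        "n_input": report.n_input,
        "stages": {s: c for s, c in report.stage_counts},
        "n_candidates": len(report.candidates),
        "n_rescued": len(report.rescued),
        "candidates": [v.key for v, _ in report.candidates],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
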