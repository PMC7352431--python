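"""The prioritization funnel.

Default stage order: quality -> rarity -> segregation -> cadd ->
conservation -> vote.  Boundary semantics follow the source wording
literally: strict ``>`` for QUAL, coverage, CADD, GERP and PhastCons;
inclusive ``>=`` for PhyloP and for the consensus vote fraction; the
rarity gate removes variants strictly above the MAF ceiling, so a
frequency of exactly 0.1% is retained and novel variants (no frequency
in any source) always survive.

Variants in known cancer genes may be "rescued": they bypass the CADD,
conservation and vote stages but never quality, rarity or segregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .pedigree import Pedigree, classify_segregation
from .variants import AnnotatedVariant, PredictorCalls

__all__ = [
    "FilterConfig",
    "FunnelReport",
    "VoteResult",
    "quality_filter",
    "rarity_filter",
    "cadd_filter",
    "conservation_filter",
    "deleteriousness_vote",
    "rescue_check",
    "run_cascade",
]

DEFAULT_STAGES = ("quality", "rarity", "segregation", "cadd", "conservation", "vote")

#: consequence classes eligible for the consensus-vote stage by default
VOTE_CONSEQUENCES = ("missense", "nonsense", "splice")

#: protein-altering classes eligible for cancer-gene rescue
CODING_ALTERING = ("missense", "nonsense", "splice", "frameshift", "inframe_indel")


@dataclass(frozen=True)
class FilterConfig:
    qual_min: float = 20.0
    depth_min: float = 5.0
    maf_max: float = 0.001
    cadd_min: float = 10.0
    gerp_min: float = 2.0
    phastcons_min: float = 0.3
    phylop_min: float = 3.0
    consensus_fraction: float = 0.6
    min_predictor_calls: int = 5
    missing_cadd_fails: bool = True
    require_conservation_score: bool = True
    vote_consequences: tuple[str, ...] = VOTE_CONSEQUENCES
    rescue_genes: frozenset[str] = frozenset()
    stage_order: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        if not 0.0 < self.consensus_fraction <= 1.0:
            raise ValueError("consensus_fraction must be in (0, 1]")
        unknown = set(self.stage_order) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("rescue_genes",):
            if key in raw:
                raw[key] = frozenset(raw[key])
        for key in ("vote_consequences", "stage_order"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["rescue_genes"] = sorted(d["rescue_genes"])
        d["vote_consequences"] = list(d["vote_consequences"])
        d["stage_order"] = list(d["stage_order"])
        return d

    def with_rescue_genes(self, genes) -> "FilterConfig":
        return replace(self, rescue_genes=frozenset(genes))


def quality_filter(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Caller QUAL strictly above the floor, every available per-member
    depth strictly above the coverage floor, and caller filters passed."""
    if not v.caller_filter_pass:
        return False
    if v.qual is None or not v.qual > cfg.qual_min:
        return False
    depths = [d for m, d in v.depth.items() if v.genotypes.get(m) is not None]
    if depths and not min(depths) > cfg.depth_min:
        return False
    return True


def rarity_filter(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """True iff every available population frequency is <= the ceiling.

    Variants absent from all sources are novel and survive.
    """
    return all(
        f <= cfg.maf_max for f in v.maf_sources.values() if f is not None
    )


def cadd_filter(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    if v.cadd_phred is None:
        return not cfg.missing_cadd_fails
    return v.cadd_phred > cfg.cadd_min


def conservation_filter(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """All *available* conservation scores must clear their thresholds;
    with ``require_conservation_score`` at least one must be present."""
    checks = [
        (v.gerp, lambda s: s > cfg.gerp_min),
        (v.phastcons, lambda s: s > cfg.phastcons_min),
        (v.phylop, lambda s: s >= cfg.phylop_min),
    ]
    available = [ok(score) for score, ok in checks if score is not None]
    if not available:
        return not cfg.require_conservation_score
    return all(available)


@dataclass(frozen=True)
class VoteResult:
    passed: bool
    n_deleterious: int
    n_available: int


def deleteriousness_vote(calls: PredictorCalls, cfg: FilterConfig) -> VoteResult:
    """Consensus over the non-missing predictor calls.

    Passes when at least ``min_predictor_calls`` tools report and the
    deleterious fraction is at least ``consensus_fraction`` (6/10 passes,
    5/10 fails at the defaults).
    """
    n_avail = calls.n_available
    n_del = calls.n_deleterious
    passed = (
        n_avail >= cfg.min_predictor_calls
        and n_del / n_avail >= cfg.consensus_fraction
    )
    return VoteResult(passed, n_del, n_avail)


def rescue_check(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Lenient handling for protein-altering variants in listed genes."""
    return v.gene in cfg.rescue_genes and v.consequence in CODING_ALTERING


@dataclass
class FunnelReport:
    """Per-stage survivor counts plus the per-variant decision trail."""

    n_input: int = 0
    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    trail: dict[str, dict[str, str]] = field(default_factory=dict)
    candidates: list[tuple[AnnotatedVariant, float]] = field(default_factory=list)
    rescued: set[str] = field(default_factory=set)

    @property
    def candidate_keys(self) -> list[str]:
        return [v.key for v, _ in self.candidates]


#: stages a rescued variant bypasses (never quality/rarity/segregation)
RESCUABLE_STAGES = frozenset({"cadd", "conservation", "vote"})


def _stage_decision(v, stage, ped, cfg) -> bool:
    if stage == "quality":
        return quality_filter(v, cfg)
    if stage == "rarity":
        return rarity_filter(v, cfg)
    if stage == "segregation":
        return classify_segregation(v.genotypes, ped, "dominant").passed
    if stage == "cadd":
        return cadd_filter(v, cfg)
    if stage == "conservation":
        return conservation_filter(v, cfg)
    if stage == "vote":
        if v.consequence not in cfg.vote_consequences:
            return False
        return deleteriousness_vote(v.predictor_calls, cfg).passed
    raise ValueError(f"unknown stage {stage!r}")


def run_cascade(
    variants: Sequence[AnnotatedVariant],
    ped: Pedigree,
    cfg: Optional[FilterConfig] = None,
    intolerance: Optional[dict] = None,
) -> FunnelReport:
    """Apply every stage in ``cfg.stage_order`` and build the report.

    Candidates are the variants surviving all stages, ordered by the
    gene-intolerance composite rank (when an intolerance table is given)
    with (chrom, pos) tie-breaking.
    """
    cfg = cfg or FilterConfig()
    ped.require_cases()
    report = FunnelReport(n_input=len(variants))

    alive: list[AnnotatedVariant] = []
    trail: dict[str, dict[str, str]] = {v.key: {} for v in variants}
    survivors = list(variants)
    for stage in cfg.stage_order:
        next_survivors = []
        for v in survivors:
            rescued_here = stage in RESCUABLE_STAGES and rescue_check(v, cfg)
            if rescued_here:
                trail[v.key][stage] = "rescued"
                report.rescued.add(v.key)
                next_survivors.append(v)
                continue
            try:
                ok = _stage_decision(v, stage, ped, cfg)
            except ValueError:
                ok = False  # e.g. uninformative for segregation
            trail[v.key][stage] = "pass" if ok else "fail"
            if ok:
                next_survivors.append(v)
        # dead variants carry "not-applicable" for later stages
        survivors = next_survivors
        report.stage_counts.append((stage, len(survivors)))
    for v in variants:
        for stage in cfg.stage_order:
            trail[v.key].setdefault(stage, "not-applicable")
    report.trail = trail

    from .ranking import composite_rank

    report.candidates = composite_rank(survivors, intolerance or {})
    return report
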