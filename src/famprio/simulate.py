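"""Synthetic pedigree / variant-table generator.

Produces a two-generation family (one founder couple plus children with
configurable phenotype roles), one planted heterozygous dominant causal
variant transmitted from an untyped founder so that it satisfies every
cascade gate by construction, and background variants whose genotypes
are drawn independently of phenotype (Hardy-Weinberg founders with
optional gene-drop transmission to keep trios Mendelian-consistent) and
whose annotation scores come from configurable null/deleterious mixture
distributions tied together by a latent per-variant indicator.

Randomness uses one root seed; every variant gets its own deterministic
substream (``default_rng([seed, stream, index])``) so changing the
number of background variants never shifts earlier draws.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .pedigree import Member, Pedigree
from .variants import PREDICTOR_TOOLS, AnnotatedVariant, PredictorCalls

__all__ = [
    "SimulationConfig",
    "DEFAULT_CHILD_ROLES",
    "simulate_family",
    "plant_causal_variant",
    "simulate_background",
    "simulate_dataset",
]

#: child roles in the default two-generation template (9 children;
#: II-9 is an affected member without a DNA sample)
DEFAULT_CHILD_ROLES = {
    "II-1": "control",
    "II-2": "case",
    "II-3": "case",
    "II-4": "carrier",
    "II-5": "case",
    "II-6": "carrier",
    "II-7": "control",
    "II-8": "case",
    "II-9": "case",
}

_ROLE_CYCLE = ("case", "carrier", "control")


def _f32(x: float) -> float:
    """Round to the nearest float32 so values survive VCF (htslib stores
    QUAL and Float INFO fields in single precision) bit-identically."""
    return float(np.float32(x))


@dataclass
class SimulationConfig:
    seed: int = 0
    n_children: int = 9
    role_assignment: Optional[dict[str, str]] = None
    unsampled: tuple[str, ...] = ("I-2", "II-9")
    n_background_variants: int = 1000

    # background allele frequency: log10(af) ~ Uniform(*log10_af_range)
    log10_af_range: tuple[float, float] = (-5.0, -1.0)
    mendelian: bool = True

    # latent deleteriousness mixture for annotation scores
    p_latent_deleterious: float = 0.05
    cadd_null: tuple[float, float] = (3.0, 3.0)  # Normal(mean, sd), clipped at 0
    cadd_del: tuple[float, float] = (25.0, 5.0)
    gerp_null: tuple[float, float] = (0.0, 1.5)
    gerp_del: tuple[float, float] = (4.5, 1.0)
    phastcons_null: tuple[float, float] = (0.8, 4.0)  # Beta(a, b)
    phastcons_del: tuple[float, float] = (6.0, 1.2)
    phylop_null: tuple[float, float] = (0.5, 1.2)
    phylop_del: tuple[float, float] = (5.0, 1.5)
    predictor_concordance: float = 0.9
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "cadd": 0.05,
            "gerp": 0.10,
            "phastcons": 0.10,
            "phylop": 0.10,
            "predictor": 0.15,
            "maf_1kg": 0.10,
            "maf_exac": 0.10,
        }
    )
    qual_range: tuple[float, float] = (0.0, 100.0)
    depth_mean: float = 30.0
    p_caller_pass: float = 0.98
    consequence_probs: dict[str, float] = field(
        default_factory=lambda: {
            "synonymous": 0.40,
            "missense": 0.40,
            "nonsense": 0.02,
            "splice": 0.03,
            "frameshift": 0.02,
            "inframe_indel": 0.03,
            "other": 0.10,
        }
    )
    n_background_genes: int = 250
    causal_gene: str = "POT1"

    def __post_init__(self) -> None:
        if self.n_children < 0 or self.n_background_variants < 0:
            raise ValueError("counts must be >= 0")
        for p in (self.p_latent_deleterious, self.predictor_concordance, self.p_caller_pass):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for p in self.missing_rates.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missing rate {p} outside [0, 1]")
        total = sum(self.consequence_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"consequence probabilities sum to {total}, not 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
        for key, value in raw.items():
            if isinstance(value, list):
                raw[key] = tuple(value)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["unsampled"] = list(d["unsampled"])
        for key in ("log10_af_range", "qual_range") + tuple(
            k for k in d if k.endswith(("_null", "_del"))
        ):
            if isinstance(d[key], tuple):
                d[key] = list(d[key])
        return d


def _roman(n: int) -> str:
    return {1: "I", 2: "II"}[n]


def simulate_family(cfg: SimulationConfig) -> Pedigree:
    """Build the two-generation family template.

    Founders are I-1 (mother, intermediate phenotype) and I-2 (father,
    untyped).  Children II-1..II-n take roles from ``role_assignment``
    (default: the packaged 9-child template with 4 sampled cases, 3
    carriers and 2 controls) or cycle case/carrier/control.
    """
    unsampled = set(cfg.unsampled)
    members = [
        Member("I-1", "female", 1, role="carrier", sample_available="I-1" not in unsampled),
        Member("I-2", "male", 1, role="unknown", sample_available="I-2" not in unsampled),
    ]
    if cfg.role_assignment is not None:
        roles = dict(cfg.role_assignment)
    elif cfg.n_children == 9:
        roles = dict(DEFAULT_CHILD_ROLES)
    else:
        roles = {
            f"II-{i + 1}": _ROLE_CYCLE[i % 3] for i in range(cfg.n_children)
        }
    rng = np.random.default_rng([cfg.seed, 2])
    for i in range(cfg.n_children):
        cid = f"II-{i + 1}"
        members.append(
            Member(
                cid,
                "male" if rng.random() < 0.5 else "female",
                2,
                father="I-2",
                mother="I-1",
                role=roles.get(cid, "unknown"),
                sample_available=cid not in unsampled,
            )
        )
    return Pedigree(members, name="synthetic-family")


def plant_causal_variant(ped: Pedigree, cfg: SimulationConfig) -> AnnotatedVariant:
    """Plant a heterozygous dominant variant in founder I-2.

    Genotypes satisfy the role constraints exactly (cases dosage 1,
    controls 0, carriers a coin flip on the paternal allele); members
    without a sample are recorded as missing.  Annotations are drawn
    comfortably inside every gate: novel (no population frequency),
    high QUAL and depth, CADD/conservation above thresholds and at
    least 6 of 10 deleterious predictor calls.
    """
    sampled_cases = [
        m for m in ped.members_with_role("case") if m.sample_available
    ]
    if not sampled_cases:
        raise ValueError("cannot plant a causal variant: no sampled case")
    for m in ped:
        if m.father is None and m.id != "I-2" and m.role == "case":
            raise ValueError(
                f"role constraints unsatisfiable: founder {m.id} is a case "
                "but the variant is planted in I-2 only"
            )

    rng = np.random.default_rng([cfg.seed, 0])
    underlying: dict[str, int] = {}
    for m in ped:
        if m.father is None:
            underlying[m.id] = 1 if m.id == "I-2" else 0
        elif m.role == "case":
            underlying[m.id] = 1
        elif m.role == "control":
            underlying[m.id] = 0
        else:  # carrier / unknown children: paternal coin flip
            underlying[m.id] = int(rng.random() < 0.5)
    genotypes = {
        m.id: (underlying[m.id] if m.sample_available else None) for m in ped
    }

    qual = _f32(rng.uniform(60.0, 200.0))
    depth = {
        m: int(rng.poisson(cfg.depth_mean) + 10) for m in ped.genotyped_ids()
    }
    cadd = _f32(rng.uniform(20.0, 35.0))
    gerp = _f32(rng.uniform(3.0, 6.0))
    phastcons = _f32(rng.uniform(0.6, 0.99))
    phylop = _f32(rng.uniform(4.0, 8.0))
    n_deleterious = int(rng.integers(6, 11))
    order = rng.permutation(len(PREDICTOR_TOOLS))
    calls = {
        PREDICTOR_TOOLS[j]: ("deleterious" if rank < n_deleterious else "tolerated")
        for rank, j in enumerate(order)
    }
    return AnnotatedVariant(
        chrom="7",
        pos=124_503_601,
        ref="C",
        alt="A",
        qual=qual,
        genotypes=genotypes,
        depth=depth,
        maf_sources={"thousand_genomes": None, "exac_nontcga": None},
        cadd_phred=cadd,
        gerp=gerp,
        phastcons=phastcons,
        phylop=phylop,
        predictor_calls=PredictorCalls(calls),
        gene=cfg.causal_gene,
        consequence="missense",
        caller_filter_pass=True,
    )


_BASES = ("A", "C", "G", "T")


def simulate_background(ped: Pedigree, cfg: SimulationConfig) -> list[AnnotatedVariant]:
    """Null variants: genotypes independent of role, annotations from
    the configured mixture distributions."""
    return [
        _background_variant(ped, cfg, i) for i in range(cfg.n_background_variants)
    ]


def _background_variant(ped: Pedigree, cfg: SimulationConfig, index: int) -> AnnotatedVariant:
    rng = np.random.default_rng([cfg.seed, 1, index])
    af = _f32(10.0 ** rng.uniform(*cfg.log10_af_range))

    members = list(ped)
    underlying: dict[str, int] = {}
    if cfg.mendelian:
        for m in members:
            if m.father is None:
                underlying[m.id] = int(rng.binomial(2, af))
        for m in members:
            if m.father is not None:
                pa = int(rng.random() < underlying[m.father] / 2.0)
                ma = int(rng.random() < underlying[m.mother] / 2.0)
                underlying[m.id] = pa + ma
    else:
        for m in members:
            underlying[m.id] = int(rng.binomial(2, af))
    genotypes = {
        m.id: (underlying[m.id] if m.sample_available else None) for m in members
    }

    qual = _f32(rng.uniform(*cfg.qual_range))
    depth = {m: int(rng.poisson(cfg.depth_mean)) for m in ped.genotyped_ids()}
    caller_pass = bool(rng.random() < cfg.p_caller_pass)

    miss = cfg.missing_rates
    maf_1kg = None if rng.random() < miss["maf_1kg"] else af
    maf_exac = None if rng.random() < miss["maf_exac"] else af

    latent = rng.random() < cfg.p_latent_deleterious

    def normal_score(null_params, del_params, missing_key, floor=None):
        mean, sd = del_params if latent else null_params
        value = float(rng.normal(mean, sd))
        if floor is not None:
            value = max(floor, value)
        return None if rng.random() < miss[missing_key] else _f32(value)

    cadd = normal_score(cfg.cadd_null, cfg.cadd_del, "cadd", floor=0.0)
    gerp = normal_score(cfg.gerp_null, cfg.gerp_del, "gerp")
    a, b = cfg.phastcons_del if latent else cfg.phastcons_null
    phastcons_value = _f32(rng.beta(a, b))
    phastcons = None if rng.random() < miss["phastcons"] else phastcons_value
    phylop = normal_score(cfg.phylop_null, cfg.phylop_del, "phylop")

    p_del = cfg.predictor_concordance if latent else 1.0 - cfg.predictor_concordance
    calls = {}
    for tool in PREDICTOR_TOOLS:
        if rng.random() < miss["predictor"]:
            calls[tool] = None
        else:
            calls[tool] = "deleterious" if rng.random() < p_del else "tolerated"

    classes = sorted(cfg.consequence_probs)
    probs = np.array([cfg.consequence_probs[c] for c in classes])
    consequence = classes[int(rng.choice(len(classes), p=probs / probs.sum()))]
    gene = f"BG{int(rng.integers(cfg.n_background_genes)):04d}"

    ref, offset = _BASES[index % 4], _BASES[(index + 1) % 4]
    return AnnotatedVariant(
        chrom=str(1 + index % 22),
        pos=100_000 + index,
        ref=ref,
        alt=offset,
        qual=qual,
        genotypes=genotypes,
        depth=depth,
        maf_sources={"thousand_genomes": maf_1kg, "exac_nontcga": maf_exac},
        cadd_phred=cadd,
        gerp=gerp,
        phastcons=phastcons,
        phylop=phylop,
        predictor_calls=PredictorCalls(calls),
        gene=gene,
        consequence=consequence,
        caller_filter_pass=caller_pass,
    )


def simulate_dataset(cfg: SimulationConfig):
    """Family, planted causal variant and background variants.

    Returns ``(pedigree, variants)`` with the planted variant first.
    """
    ped = simulate_family(cfg)
    planted = plant_causal_variant(ped, cfg)
    background = simulate_background(ped, cfg)
    return ped, [planted] + background
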