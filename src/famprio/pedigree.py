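"""Pedigree structures, phenotype roles, and genotype co-segregation.

The central decision made here is :func:`classify_segregation`: under a
dominant model a variant segregates with disease when every genotyped
case carries at least one alternate allele and no genotyped control
carries any.  Members with an intermediate phenotype ("carrier" role) and
members with unknown role or missing genotype impose no constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "Member",
    "Pedigree",
    "GenotypeVector",
    "SegregationDecision",
    "MendelianViolation",
    "classify_segregation",
    "mendelian_consistency",
    "read_ped",
    "write_ped",
]

SEXES = ("male", "female", "unknown")
ROLES = ("case", "carrier", "control", "unknown")

#: alleles a parent of the given dosage can transmit (biallelic site)
_TRANSMISSIBLE = {0: (0,), 1: (0, 1), 2: (1,)}


@dataclass(frozen=True)
class Member:
    """One pedigree member.

    ``role`` is the phenotype label driving the segregation filter:
    ``case`` (affected), ``carrier`` (intermediate phenotype, may or may
    not carry), ``control`` (unaffected) or ``unknown``.
    """

    id: str
    sex: str = "unknown"
    generation: int = 1
    father: Optional[str] = None
    mother: Optional[str] = None
    role: str = "unknown"
    sample_available: bool = True

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"invalid sex {self.sex!r} for member {self.id!r}")
        if self.role not in ROLES:
            raise ValueError(f"invalid role {self.role!r} for member {self.id!r}")
        if self.generation < 1:
            raise ValueError(f"generation must be >= 1 for member {self.id!r}")
        if (self.father is None) != (self.mother is None):
            raise ValueError(
                f"member {self.id!r} must have zero or two parents"
            )


class Pedigree:
    """A named family: members indexed by id, with validated parent links."""

    def __init__(self, members: Iterable[Member], name: str = "family"):
        self.name = name
        self._members: dict[str, Member] = {}
        for m in members:
            if m.id in self._members:
                raise ValueError(f"duplicate member id {m.id!r}")
            self._members[m.id] = m
        for m in self._members.values():
            for pid in (m.father, m.mother):
                if pid is None:
                    continue
                if pid not in self._members:
                    raise ValueError(
                        f"parent {pid!r} of {m.id!r} not in pedigree"
                    )
                if self._members[pid].generation >= m.generation:
                    raise ValueError(
                        f"parent {pid!r} must be of earlier generation than {m.id!r}"
                    )

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self):
        return iter(self._members.values())

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._members

    def __getitem__(self, member_id: str) -> Member:
        return self._members[member_id]

    @property
    def member_ids(self) -> list[str]:
        return list(self._members)

    def members_with_role(self, role: str) -> list[Member]:
        return [m for m in self if m.role == role]

    def genotyped_ids(self) -> list[str]:
        """Ids of members for whom a DNA sample exists."""
        return [m.id for m in self if m.sample_available]

    def require_cases(self) -> None:
        if not self.members_with_role("case"):
            raise ValueError(
                f"pedigree {self.name!r} has no case members; "
                "segregation filtering is undefined"
            )


#: member id -> alternate-allele dosage (0, 1, 2) or None when missing
GenotypeVector = Mapping[str, Optional[int]]


def _check_genotypes(gv: GenotypeVector, ped: Pedigree) -> None:
    for mid, d in gv.items():
        if mid not in ped:
            raise ValueError(f"genotype for unknown member {mid!r}")
        if d is not None and d not in (0, 1, 2):
            raise ValueError(f"invalid dosage {d!r} for member {mid!r}")


@dataclass(frozen=True)
class SegregationDecision:
    passed: bool
    n_case_carriers: int
    n_control_carriers: int
    n_missing: int


def classify_segregation(
    gv: GenotypeVector, ped: Pedigree, model: str = "dominant"
) -> SegregationDecision:
    """Decide whether a genotype pattern co-segregates with disease.

    Under the (only supported) dominant model the variant passes iff
    every case with a non-missing genotype has dosage >= 1 and every
    control with a non-missing genotype has dosage 0.  Carriers,
    unknown-role members and missing genotypes are unconstrained;
    missing genotypes are counted in ``n_missing``.

    Raises ``ValueError`` if no case has a non-missing genotype (the
    variant is uninformative) or if the model is unsupported.
    """
    if model != "dominant":
        raise ValueError(f"unsupported inheritance model {model!r}")
    _check_genotypes(gv, ped)
    ped.require_cases()

    n_case_carriers = n_control_carriers = n_missing = 0
    n_case_typed = 0
    passed = True
    for member in ped:
        dosage = gv.get(member.id)
        if dosage is None:
            n_missing += 1
            continue
        if member.role == "case":
            n_case_typed += 1
            if dosage >= 1:
                n_case_carriers += 1
            else:
                passed = False
        elif member.role == "control":
            if dosage >= 1:
                n_control_carriers += 1
                passed = False
    if n_case_typed == 0:
        raise ValueError("uninformative variant: no case has a genotype")
    return SegregationDecision(passed, n_case_carriers, n_control_carriers, n_missing)


@dataclass(frozen=True)
class MendelianViolation:
    child: str
    father: str
    mother: str


def mendelian_consistency(
    gv: GenotypeVector, ped: Pedigree
) -> list[MendelianViolation]:
    """List trios whose genotypes violate Mendelian transmission.

    A child's dosage is a violation when it cannot be produced by any
    assignment of dosages to missing parents; missing child genotypes
    are never violations.
    """
    _check_genotypes(gv, ped)
    violations = []
    for member in ped:
        if member.father is None:
            continue
        child_d = gv.get(member.id)
        if child_d is None:
            continue
        f_opts = _dosage_options(gv.get(member.father))
        m_opts = _dosage_options(gv.get(member.mother))
        possible = {
            fa + ma
            for fd in f_opts
            for md in m_opts
            for fa in _TRANSMISSIBLE[fd]
            for ma in _TRANSMISSIBLE[md]
        }
        if child_d not in possible:
            violations.append(
                MendelianViolation(member.id, member.father, member.mother)
            )
    return violations


def _dosage_options(d: Optional[int]) -> tuple[int, ...]:
    return (0, 1, 2) if d is None else (d,)


# ---------------------------------------------------------------------------
# PED-like I/O: standard 6 columns plus a 7th phenotype-role column.
# ---------------------------------------------------------------------------

_SEX_CODE = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {v: k for k, v in _SEX_CODE.items()}
_ROLE_PHENOTYPE = {"case": "2", "carrier": "1", "control": "1", "unknown": "0"}


def read_ped(path: str | Path, name: Optional[str] = None) -> Pedigree:
    """Read a tab-separated extended PED file.

    Columns: family, id, father, mother, sex, phenotype, role
    [, sample_available].  "0" marks an unknown parent.  Generations are
    derived from parent links (founders are generation 1).
    """
    path = Path(path)
    rows = []
    fam = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 7:
            raise ValueError(f"{path}:{lineno}: expected >=7 columns, got {len(parts)}")
        fam = fam or parts[0]
        rows.append(parts)
    if not rows:
        raise ValueError(f"{path}: no pedigree rows")

    parents = {r[1]: (r[2], r[3]) for r in rows}

    def generation(mid: str, _seen=None) -> int:
        _seen = _seen or set()
        if mid in _seen:
            raise ValueError(f"pedigree cycle involving {mid!r}")
        f, m = parents.get(mid, ("0", "0"))
        if f == "0":
            return 1
        _seen = _seen | {mid}
        return 1 + max(generation(f, _seen), generation(m, _seen))

    members = []
    for r in rows:
        sample = True
        if len(r) >= 8:
            sample = r[7].strip() in ("1", "true", "True", "yes")
        members.append(
            Member(
                id=r[1],
                sex=_SEX_CODE.get(r[4], "unknown"),
                generation=generation(r[1]),
                father=None if r[2] == "0" else r[2],
                mother=None if r[3] == "0" else r[3],
                role=r[6].strip(),
                sample_available=sample,
            )
        )
    return Pedigree(members, name=name or fam or path.stem)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    lines = []
    for m in ped:
        lines.append(
            "\t".join(
                [
                    ped.name,
                    m.id,
                    m.father or "0",
                    m.mother or "0",
                    _SEX_TO_CODE[m.sex],
                    _ROLE_PHENOTYPE[m.role],
                    m.role,
                    "1" if m.sample_available else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
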