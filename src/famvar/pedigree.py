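"""Pedigree parsing and family-structure queries.

A multiplex-family cohort is described by a standard 6-column PED file
(FamID, IndID, FatherID, MotherID, Sex, Affection) plus a sidecar metadata
table that carries information the PED dialect cannot: which members were
actually sequenced, which families are consanguineous, and a free-text
diagnosis.  Affection is binary here: any affected diagnosis (the cohort
this models includes one obsessive-compulsive disorder case among the
schizophrenia cases) is coded affected; per-diagnosis labels live in the
sidecar only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from typing import Iterable

import pandas as pd

__all__ = [
    "Sex",
    "Affection",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "parse_ped",
    "write_ped",
    "apply_metadata",
    "load_pedigrees",
    "affected_members",
    "sequenced_controls",
    "pedigree_kinship",
    "expected_degree",
]


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_AFF_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED, "0": Affection.UNKNOWN}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_OUT = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}


class PedigreeError(ValueError):
    """Raised for malformed PED rows or structurally invalid pedigrees."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    affection: Affection
    sequenced: bool = True


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual]
    consanguineous: bool = False

    def __post_init__(self) -> None:
        self._by_id = {m.individual_id: m for m in self.members}

    def member(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    @property
    def member_ids(self) -> list[str]:
        return [m.individual_id for m in self.members]

    def sequenced_members(self) -> set[str]:
        return {m.individual_id for m in self.members if m.sequenced}

    def validate(self) -> None:
        """Check parent references and sex/parent-role consistency."""
        for m in self.members:
            for pid, role, want in (
                (m.father_id, "father", Sex.MALE),
                (m.mother_id, "mother", Sex.FEMALE),
            ):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"family {self.family_id}: {role} '{pid}' of "
                        f"'{m.individual_id}' is not a pedigree member"
                    )
                if parent.sex != want:
                    raise PedigreeError(
                        f"family {self.family_id}: {role} '{pid}' of "
                        f"'{m.individual_id}' has sex={parent.sex.value}"
                    )


def parse_ped(source: str | io.TextIOBase) -> list[Pedigree]:
    """Parse whitespace-delimited 6-column PED text into validated pedigrees.

    Missing parents are encoded ``0`` and map to None.  All individuals
    default to sequenced=True; use :func:`apply_metadata` to mark
    unsequenced members and consanguineous families from the sidecar table.
    """
    text = source.read() if hasattr(source, "read") else source
    families: dict[str, list[Individual]] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(f"PED line {lineno}: expected 6 columns, got {len(fields)}")
        fam, ind, father, mother, sex, aff = fields[:6]
        if (fam, ind) in seen:
            raise PedigreeError(f"PED line {lineno}: duplicate individual '{ind}' in family '{fam}'")
        seen.add((fam, ind))
        try:
            sex_e = _SEX_CODES[sex]
            aff_e = _AFF_CODES[aff]
        except KeyError as exc:
            raise PedigreeError(f"PED line {lineno}: bad sex/affection code {exc}") from None
        families.setdefault(fam, []).append(
            Individual(
                individual_id=ind,
                family_id=fam,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=sex_e,
                affection=aff_e,
            )
        )
    pedigrees = [Pedigree(family_id=fam, members=members) for fam, members in families.items()]
    for p in pedigrees:
        p.validate()
    return pedigrees


def write_ped(pedigrees: Iterable[Pedigree]) -> str:
    """Serialize pedigrees back to canonical 6-column PED text."""
    lines = []
    for p in pedigrees:
        for m in p.members:
            lines.append(
                " ".join(
                    [
                        p.family_id,
                        m.individual_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_OUT[m.sex],
                        _AFF_OUT[m.affection],
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def apply_metadata(pedigrees: list[Pedigree], metadata: pd.DataFrame) -> list[Pedigree]:
    """Apply the sidecar table (family_id, individual_id, sequenced,
    consanguineous, diagnosis) to parsed pedigrees.

    Returns new Pedigree objects; individuals absent from the sidecar keep
    sequenced=True.  A family is consanguineous if any of its sidecar rows
    sets consanguineous=1.
    """
    meta = metadata.set_index(["family_id", "individual_id"])
    out = []
    for p in pedigrees:
        members = []
        consang = p.consanguineous
        for m in p.members:
            key = (p.family_id, m.individual_id)
            if key in meta.index:
                row = meta.loc[key]
                members.append(replace(m, sequenced=bool(int(row["sequenced"]))))
                if int(row.get("consanguineous", 0)):
                    consang = True
            else:
                members.append(m)
        out.append(Pedigree(family_id=p.family_id, members=members, consanguineous=consang))
    return out


def load_pedigrees(ped_path: str, sidecar_path: str | None = None) -> list[Pedigree]:
    """Read a PED file plus optional sidecar metadata TSV from disk."""
    with open(ped_path) as fh:
        peds = parse_ped(fh.read())
    if sidecar_path is not None:
        meta = pd.read_csv(sidecar_path, sep="\t", dtype={"family_id": str, "individual_id": str})
        peds = apply_metadata(peds, meta)
    return peds


def affected_members(p: Pedigree) -> set[str]:
    """Sequenced members with affected status (any affected diagnosis)."""
    return {
        m.individual_id
        for m in p.members
        if m.sequenced and m.affection is Affection.AFFECTED
    }


def sequenced_controls(p: Pedigree) -> set[str]:
    """Sequenced members with unaffected status; unknown affection excluded."""
    return {
        m.individual_id
        for m in p.members
        if m.sequenced and m.affection is Affection.UNAFFECTED
    }


def pedigree_kinship(p: Pedigree, a: str, b: str) -> Fraction:
    """Expected kinship coefficient between two members from pedigree
    structure alone (founders assumed unrelated and non-inbred).

    Standard recursive definition: phi(x,x) = 1/2 (no inbreeding),
    phi(x,y) = (phi(father_x, y) + phi(mother_x, y)) / 2 where x is not an
    ancestor of y.
    """
    order = _topological_depth(p)

    def phi(x: str, y: str) -> Fraction:
        if order[x] < order[y]:
            x, y = y, x
        mx = p.member(x)
        if x == y:
            return Fraction(1, 2)
        fa = phi(mx.father_id, y) if mx.father_id else Fraction(0)
        mo = phi(mx.mother_id, y) if mx.mother_id else Fraction(0)
        return (fa + mo) / 2

    return phi(a, b)


def _topological_depth(p: Pedigree) -> dict[str, int]:
    depth: dict[str, int] = {}

    def d(ind_id: str) -> int:
        if ind_id in depth:
            return depth[ind_id]
        m = p.member(ind_id)
        parents = [pid for pid in (m.father_id, m.mother_id) if pid]
        depth[ind_id] = 0 if not parents else 1 + max(d(pid) for pid in parents)
        return depth[ind_id]

    for m in p.members:
        d(m.individual_id)
    return depth


def expected_degree(p: Pedigree, a: str, b: str) -> str:
    """Map pedigree kinship onto the discrete relationship degree scale
    used by the genotype-based classifier (duplicate_or_MZ, first, second,
    third, unrelated)."""
    phi = float(pedigree_kinship(p, a, b))
    if phi > 0.354:
        return "duplicate_or_MZ"
    if phi > 0.177:
        return "first"
    if phi > 0.0884:
        return "second"
    if phi > 0.0442:
        return "third"
    return "unrelated"
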