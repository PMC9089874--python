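"""Per-pedigree inheritance-pattern classification and candidate sets.

A filtered variant becomes a candidate in a family when its genotype
pattern matches one of four segregation classes:

* ``shared_het`` — carried by the affected members (at least two; by
  default every affected member with a usable call must carry it);
* ``de_novo`` — carried by an affected member whose parents are both
  sequenced, unaffected and homozygous-reference; families where the
  carrier's parent is itself affected are ineligible, since transmission
  from an affected parent is indistinguishable from sharing;
* ``homozygous_recessive`` — affected members homozygous for the
  alternate allele with no unaffected member homozygous;
* ``hemizygous_x`` — X-linked: affected males hemizygous, affected
  (carrier) females heterozygous, no unaffected male hemizygous.

When several predicates fire, precedence is
de_novo > hemizygous_x > homozygous_recessive > shared_het, so each
(variant, family) pair receives at most one class.

Two candidate sets are built: the *all* set over every pedigree, and the
*strict* set restricted to pedigrees with sequenced unaffected members,
additionally requiring that no such control carries a shared variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .pedigree import Affection, Pedigree, Sex, affected_members, sequenced_controls
from .variants import AnnotatedCohort, GT_HET, GT_HOMALT, GT_HOMREF, GT_MISSING

__all__ = [
    "SegregationClass", "GenotypeState", "CandidateVariant", "SegregationConfig",
    "genotype_state", "shared_among_affected", "is_de_novo",
    "is_recessive_homozygous", "is_hemizygous_candidate", "classify_variant",
    "build_candidate_sets", "summarize", "candidates_to_frame",
]


class SegregationClass(Enum):
    SHARED_HET = "shared_het"
    DE_NOVO = "de_novo"
    HOMOZYGOUS_RECESSIVE = "homozygous_recessive"
    HEMIZYGOUS_X = "hemizygous_x"


class GenotypeState(Enum):
    HOMREF = "homref"
    HET = "het"
    HOMALT = "homalt"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"


CARRIER_STATES = {GenotypeState.HET, GenotypeState.HOMALT, GenotypeState.HEMI_ALT}

# GRCh37 X pseudoautosomal regions (1-based, inclusive)
PAR1 = (60001, 2_699_520)
PAR2 = (154_931_044, 155_260_560)


def _is_x(chrom: str) -> bool:
    return chrom.removeprefix("chr") == "X"


def _in_par(pos: int) -> bool:
    return PAR1[0] <= pos <= PAR1[1] or PAR2[0] <= pos <= PAR2[1]


def genotype_state(gt: int, sex: Sex, chrom: str, pos: int) -> GenotypeState:
    """Sex- and chromosome-aware recoding of a diploid GT code.

    Male calls on non-pseudoautosomal X carrying any alternate allele are
    hemizygous-alt (callers often emit them diploid-coded); unknown sex on
    non-PAR X cannot be interpreted and recodes to missing.
    """
    if gt == GT_MISSING:
        return GenotypeState.MISSING
    if _is_x(chrom) and not _in_par(pos):
        if sex is Sex.MALE:
            return GenotypeState.HEMI_ALT if gt in (GT_HET, GT_HOMALT) else GenotypeState.HOMREF
        if sex is Sex.UNKNOWN:
            return GenotypeState.MISSING
    return {GT_HOMREF: GenotypeState.HOMREF, GT_HET: GenotypeState.HET,
            GT_HOMALT: GenotypeState.HOMALT}[gt]


@dataclass
class SegregationConfig:
    require_all_affected: bool = True  # False: any >= min_carriers affecteds
    min_carriers: int = 2


@dataclass(frozen=True)
class CandidateVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    family_id: str
    seg_class: SegregationClass
    carriers: frozenset[str]
    genes: frozenset[str]

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def _affected_states(states: dict[str, GenotypeState], p: Pedigree) -> dict[str, GenotypeState]:
    return {i: states[i] for i in affected_members(p) if i in states}


def _control_states(states: dict[str, GenotypeState], p: Pedigree) -> dict[str, GenotypeState]:
    return {i: states[i] for i in sequenced_controls(p) if i in states}


def shared_among_affected(states: dict[str, GenotypeState], p: Pedigree,
                          strict: bool = False,
                          cfg: SegregationConfig | None = None) -> bool:
    cfg = cfg or SegregationConfig()
    aff = _affected_states(states, p)
    carriers = {i for i, s in aff.items() if s in CARRIER_STATES}
    usable = {i for i, s in aff.items() if s is not GenotypeState.MISSING}
    if len(carriers) < cfg.min_carriers:
        return False
    if cfg.require_all_affected and carriers != usable:
        return False
    if strict:
        controls = _control_states(states, p)
        if any(s in CARRIER_STATES for s in controls.values()):
            return False
    return True


def is_de_novo(states: dict[str, GenotypeState], p: Pedigree) -> bool:
    """True when some affected member carries the allele while both of its
    parents are sequenced, unaffected and confidently homozygous-reference.
    A missing or QC-demoted parental call vetoes the call."""
    for ind_id, state in _affected_states(states, p).items():
        if state not in CARRIER_STATES:
            continue
        m = p.member(ind_id)
        if m.father_id is None or m.mother_id is None:
            continue
        parents_ok = True
        for pid in (m.father_id, m.mother_id):
            parent = p.member(pid)
            if (not parent.sequenced
                    or parent.affection is not Affection.UNAFFECTED
                    or states.get(pid) is not GenotypeState.HOMREF):
                parents_ok = False
                break
        if parents_ok:
            return True
    return False


def de_novo_carriers(states: dict[str, GenotypeState], p: Pedigree) -> frozenset[str]:
    out = set()
    for ind_id, state in _affected_states(states, p).items():
        if state not in CARRIER_STATES:
            continue
        m = p.member(ind_id)
        if m.father_id is None or m.mother_id is None:
            continue
        ok = all(
            p.member(pid).sequenced
            and p.member(pid).affection is Affection.UNAFFECTED
            and states.get(pid) is GenotypeState.HOMREF
            for pid in (m.father_id, m.mother_id)
        )
        if ok:
            out.add(ind_id)
    return frozenset(out)


def is_recessive_homozygous(states: dict[str, GenotypeState], p: Pedigree,
                            cfg: SegregationConfig | None = None) -> bool:
    cfg = cfg or SegregationConfig()
    aff = _affected_states(states, p)
    hom = {i for i, s in aff.items() if s is GenotypeState.HOMALT}
    usable = {i for i, s in aff.items() if s is not GenotypeState.MISSING}
    if len(hom) < cfg.min_carriers:
        return False
    if cfg.require_all_affected and hom != usable:
        return False
    controls = _control_states(states, p)
    if any(s is GenotypeState.HOMALT for s in controls.values()):
        return False
    return True


def is_hemizygous_candidate(states: dict[str, GenotypeState], p: Pedigree,
                            chrom: str, pos: int) -> bool:
    """X-linked hemizygous pattern: every usable affected male hemizygous
    (at least one), every usable affected female a heterozygous carrier,
    and no unaffected male hemizygous."""
    if not _is_x(chrom) or _in_par(pos):
        return False
    aff_males, aff_females = [], []
    for ind_id, s in _affected_states(states, p).items():
        if s is GenotypeState.MISSING:
            continue
        if p.member(ind_id).sex is Sex.MALE:
            aff_males.append(s)
        elif p.member(ind_id).sex is Sex.FEMALE:
            aff_females.append(s)
    if not aff_males or any(s is not GenotypeState.HEMI_ALT for s in aff_males):
        return False
    if any(s is not GenotypeState.HET for s in aff_females):
        return False
    for ind_id, s in _control_states(states, p).items():
        if p.member(ind_id).sex is Sex.MALE and s is GenotypeState.HEMI_ALT:
            return False
    return True


def classify_variant(states: dict[str, GenotypeState], p: Pedigree,
                     chrom: str, pos: int, strict: bool = False,
                     cfg: SegregationConfig | None = None) -> SegregationClass | None:
    """Single class per (variant, family) under fixed precedence;
    None when no predicate fires."""
    cfg = cfg or SegregationConfig()
    if is_de_novo(states, p):
        return SegregationClass.DE_NOVO
    if is_hemizygous_candidate(states, p, chrom, pos):
        return SegregationClass.HEMIZYGOUS_X
    if not _is_x(chrom) or _in_par(pos):
        if is_recessive_homozygous(states, p, cfg):
            return SegregationClass.HOMOZYGOUS_RECESSIVE
    if shared_among_affected(states, p, strict=strict, cfg=cfg):
        return SegregationClass.SHARED_HET
    return None


def _variant_states(cohort: AnnotatedCohort, i: int, p: Pedigree) -> dict[str, GenotypeState]:
    t = cohort.table
    row = t.sites.iloc[i]
    states = {}
    for m in p.members:
        if not m.sequenced or m.individual_id not in t.samples:
            continue
        j = t.sample_index(m.individual_id)
        states[m.individual_id] = genotype_state(
            int(t.gt[i, j]), m.sex, str(row.chrom), int(row.pos)
        )
    return states


def build_candidate_sets(
    cohort: AnnotatedCohort,
    pedigrees: list[Pedigree],
    cfg: SegregationConfig | None = None,
) -> tuple[list[CandidateVariant], list[CandidateVariant]]:
    """Classify every filtered variant in every pedigree.

    Returns (all_set, strict_set): the strict set covers only pedigrees
    with sequenced unaffected members and applies the control-exclusion
    rule to shared variants.
    """
    cfg = cfg or SegregationConfig()
    ann = cohort.annotations
    gene_col = "candidate_genes" if "candidate_genes" in ann.columns else "genes"
    all_set: list[CandidateVariant] = []
    strict_set: list[CandidateVariant] = []
    for i in range(cohort.table.n_sites):
        row = cohort.table.sites.iloc[i]
        genes = frozenset(str(ann[gene_col].iloc[i]).split(","))
        for p in pedigrees:
            states = _variant_states(cohort, i, p)
            if not states:
                continue
            for strict, target in ((False, all_set), (True, strict_set)):
                if strict and not sequenced_controls(p):
                    continue
                seg = classify_variant(states, p, str(row.chrom), int(row.pos),
                                       strict=strict, cfg=cfg)
                if seg is None:
                    continue
                if seg is SegregationClass.DE_NOVO:
                    carriers = de_novo_carriers(states, p)
                else:
                    carriers = frozenset(
                        i_ for i_, s in _affected_states(states, p).items()
                        if s in CARRIER_STATES
                    )
                target.append(
                    CandidateVariant(
                        chrom=str(row.chrom), pos=int(row.pos),
                        ref=str(row.ref), alt=str(row.alt),
                        family_id=p.family_id, seg_class=seg,
                        carriers=carriers, genes=genes,
                    )
                )
    return all_set, strict_set


def summarize(candidates: list[CandidateVariant]) -> dict:
    """Unique-variant and unique-gene counts plus per-class and per-family
    breakdowns.  A variant planted in two families counts once in the
    variant total; genes are the union over candidates' gene sets."""
    keys = {c.key for c in candidates}
    genes: set[str] = set()
    per_class: dict[str, int] = {}
    per_family: dict[str, int] = {}
    for c in candidates:
        genes |= c.genes
        per_class[c.seg_class.value] = per_class.get(c.seg_class.value, 0) + 1
        per_family[c.family_id] = per_family.get(c.family_id, 0) + 1
    return {
        "n_variants": len(keys),
        "n_genes": len(genes),
        "per_class": dict(sorted(per_class.items())),
        "per_family": dict(sorted(per_family.items())),
        "n_candidate_entries": len(candidates),
    }


def candidates_to_frame(candidates: list[CandidateVariant]) -> pd.DataFrame:
    rows = [
        {
            "family_id": c.family_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "genes": ",".join(sorted(c.genes)),
            "seg_class": c.seg_class.value,
            "carriers": ",".join(sorted(c.carriers)),
        }
        for c in candidates
    ]
    df = pd.DataFrame(rows, columns=["family_id", "chrom", "pos", "ref", "alt",
                                     "genes", "seg_class", "carriers"])
    return df.sort_values(["family_id", "chrom", "pos", "ref", "alt"]).reset_index(drop=True)
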