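"""Synthetic multiplex-family cohort generator.

Emulates the inputs of a family-based exome study end to end: a
multi-sample VCF with GT:AD:DP:GQ calls and a VQSR-style FILTER column,
a 6-column PED file with a sidecar metadata table, per-variant and
per-gene annotation TSVs, an in-house detection-count table, and a GMT
gene-set file — together with a ground-truth table recording the intended
fate of every planted variant.

The default cohort mirrors the study design this package targets: 14
families, 39 sequenced members (30 affected — one of them with a
non-schizophrenia psychiatric diagnosis — and 9 unaffected), exactly one
consanguineous family, and seven families carrying sequenced unaffected
controls.  Background sites are independent autosomal biallelic variants
with founder genotypes drawn in Hardy-Weinberg proportions and offspring
genotypes by Mendelian transmission (no linkage); planted variants of the
four segregation classes and one decoy per filter rule are injected with
genotypes realising their class.  Read depths are overdispersed
(shifted negative binomial) so allele-ratio boundary cases arise
naturally at background sites.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import variants as vs
from .pedigree import Affection, Individual, Pedigree, Sex
from .variants import GT_HET, GT_HOMALT, GT_HOMREF, GT_MISSING, VariantTable

__all__ = ["SimConfig", "Bundle", "simulate_cohort", "default_pedigrees",
           "add_genotype_noise", "mendelian_violations"]

# ---------------------------------------------------------------------------
# cohort structure
# ---------------------------------------------------------------------------

# (individual_id, father, mother, sex, affection, sequenced); "0" = none.
# A=affected, U=unaffected+sequenced, X=unknown+unsequenced.
_M, _F = "1", "2"
_FAMILY_TABLE: dict[str, list[tuple]] = {
    # fam: [(id, fa, mo, sex, aff, seq)]
    "F01": [("F01F", "0", "0", _M, "X", 0), ("F01M", "0", "0", _F, "U", 1),
            ("F01C1", "F01F", "F01M", _M, "A", 1), ("F01C2", "F01F", "F01M", _F, "A", 1)],
    "F02": [("F02F", "0", "0", _M, "X", 0), ("F02M", "0", "0", _F, "X", 0),
            ("F02C1", "F02F", "F02M", _M, "A", 1), ("F02C2", "F02F", "F02M", _F, "A", 1)],
    "F03": [("F03F", "0", "0", _M, "X", 0), ("F03M", "0", "0", _F, "X", 0),
            ("F03C1", "F03F", "F03M", _M, "A", 1), ("F03C2", "F03F", "F03M", _F, "A", 1)],
    "F04": [("F04F", "0", "0", _M, "U", 1), ("F04M", "0", "0", _F, "U", 1),
            ("N0673", "F04F", "F04M", _M, "A", 1), ("N0674", "F04F", "F04M", _F, "A", 1)],
    "F05": [("F05F", "0", "0", _M, "X", 0), ("F05M", "0", "0", _F, "U", 1),
            ("F05C1", "F05F", "F05M", _M, "A", 1), ("F05C2", "F05F", "F05M", _F, "A", 1)],
    "F06": [("F06F", "0", "0", _M, "X", 0), ("F06M", "0", "0", _F, "X", 0),
            ("F06C1", "F06F", "F06M", _M, "A", 1), ("F06C2", "F06F", "F06M", _F, "A", 1)],
    "F07": [("F07F", "0", "0", _M, "X", 0), ("F07M", "0", "0", _F, "X", 0),
            ("F07C1", "F07F", "F07M", _M, "A", 1), ("F07C2", "F07F", "F07M", _F, "A", 1)],
    "F08": [("F08F", "0", "0", _M, "X", 0), ("F08M", "0", "0", _F, "X", 0),
            ("F08C1", "F08F", "F08M", _M, "A", 1), ("F08C2", "F08F", "F08M", _F, "A", 1)],
    "F09": [("F09F", "0", "0", _M, "X", 0), ("F09M", "0", "0", _F, "X", 0),
            ("F09C1", "F09F", "F09M", _M, "A", 1), ("F09C2", "F09F", "F09M", _F, "A", 1)],
    "F10": [("F10F", "0", "0", _M, "U", 1), ("F10M", "0", "0", _F, "U", 1),
            ("N0688", "F10F", "F10M", _M, "A", 1), ("N0689", "F10F", "F10M", _F, "A", 1)],
    "F11": [("F11F", "0", "0", _M, "X", 0), ("F11M", "0", "0", _F, "U", 1),
            ("F11C1", "F11F", "F11M", _M, "A", 1), ("F11C2", "F11F", "F11M", _F, "A", 1)],
    "F12": [("F12F", "0", "0", _M, "X", 0), ("F12M", "0", "0", _F, "X", 0),
            ("F12C1", "F12F", "F12M", _M, "A", 1), ("F12C2", "F12F", "F12M", _F, "A", 1)],
    # F13: affected mother (the non-SCZ diagnosis), two affected sons,
    # unaffected father — the X-linked carrier-mother constellation.
    "F13": [("F13F", "0", "0", _M, "U", 1), ("N1010", "0", "0", _F, "A", 1),
            ("N0812", "F13F", "N1010", _M, "A", 1), ("N0813", "F13F", "N1010", _M, "A", 1)],
    "F14": [("F14F", "0", "0", _M, "X", 0), ("F14M", "0", "0", _F, "U", 1),
            ("F14C1", "F14F", "F14M", _M, "A", 1), ("F14C2", "F14F", "F14M", _F, "A", 1),
            ("F14C3", "F14F", "F14M", _M, "A", 1)],
}

CONSANGUINEOUS_FAMILY = "F10"
_DIAGNOSES = {"N1010": "OCD"}

# families whose planted shared variants enter through the unsequenced
# parent (controls stay non-carriers -> survive strict filtering), then
# the one family whose sequenced control carries the allele
_SHARED_FAMILIES = ["F01", "F02", "F03", "F05", "F06", "F07", "F08", "F09",
                    "F11", "F14", "F04"]
_DE_NOVO_SLOTS = [("F04", "N0674"), ("F04", "N0673"), ("F10", "N0688"), ("F10", "N0689")]

_SHARED_GENES = ["CACNA1E", "RYR2", "ANK3", "NRXN1", "KCNQ1", "SHANK1",
                 "STIM2", "ITPR1", "CACNB1", "CACNA1G", "AKT1", "RYR1",
                 "ANK2", "AKAP6", "HOMER1", "WNK2"]
_DE_NOVO_GENES = ["CACNA1C", "PODNL1", "DLL3", "ODC1", "SAPCD2"]
_HOMOZYGOUS_GENES = ["CNTN6", "LOXHD1"]
_HEMIZYGOUS_GENES = ["MAOB", "RYR3"]

DECOY_RULES = ["common_af", "synonymous_nonsplice", "high_rvis", "low_brain_nx",
               "segdup", "vqsr_fail", "low_dp", "inhouse_common"]
_DECOY_FATES = {
    "common_af": "dropped-by-frequency",
    "synonymous_nonsplice": "dropped-by-consequence",
    "high_rvis": "dropped-by-gene_constraints",
    "low_brain_nx": "dropped-by-gene_constraints",
    "segdup": "dropped-by-site_qc",
    "vqsr_fail": "dropped-by-site_qc",
    "low_dp": "dropped-by-genotype_qc",
    "inhouse_common": "dropped-by-inhouse",
}

AF_DATABASES = ("1000G_ALL", "ExAC_ALL", "ExAC_EAS", "HGVD", "jMorp")


@dataclass
class SimConfig:
    seed: int = 0
    n_families: int = 14
    n_background_sites: int = 20_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_shared_het: int = 11
    n_de_novo: int = 3
    n_homozygous: int = 1
    n_hemizygous: int = 1
    decoys_per_rule: int = 1
    genotype_error_rate: float = 0.0
    depth_shift: int = 10     # minimum depth of the shifted neg-binomial
    depth_nb_n: float = 5.0   # neg-binomial shape
    depth_nb_mean: float = 50.0  # mean of the overdispersed component

    def __post_init__(self) -> None:
        if not (1 <= self.n_families <= len(_FAMILY_TABLE)):
            raise ValueError("n_families must be in [1, 14]")
        for name in ("n_shared_het", "n_de_novo", "n_homozygous", "n_hemizygous",
                     "decoys_per_rule"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.genotype_error_rate <= 1.0):
            raise ValueError("genotype_error_rate must be in [0, 1]")


class SimulationConfigError(ValueError):
    """Planting is impossible under the requested family structure."""


@dataclass
class Bundle:
    out_dir: str
    vcf_path: str
    ped_path: str
    sidecar_path: str
    annotation_path: str
    gene_path: str
    inhouse_path: str
    gmt_path: str
    truth_path: str
    manifest_path: str
    truth: pd.DataFrame
    noise_ledger: pd.DataFrame | None = None
    noise_ledger_path: str | None = None


def default_pedigrees(n_families: int = 14) -> list[Pedigree]:
    """The cohort structure as Pedigree objects (sequenced flags applied)."""
    peds = []
    for fam, rows in list(_FAMILY_TABLE.items())[:n_families]:
        members = [
            Individual(
                individual_id=i, family_id=fam,
                father_id=None if fa == "0" else fa,
                mother_id=None if mo == "0" else mo,
                sex=Sex.MALE if sex == _M else Sex.FEMALE,
                affection={"A": Affection.AFFECTED, "U": Affection.UNAFFECTED,
                           "X": Affection.UNKNOWN}[aff],
                sequenced=bool(seq),
            )
            for i, fa, mo, sex, aff, seq in rows
        ]
        peds.append(Pedigree(family_id=fam, members=members,
                             consanguineous=fam == CONSANGUINEOUS_FAMILY))
    return peds


def _ped_text(pedigrees: list[Pedigree]) -> str:
    from .pedigree import write_ped
    return write_ped(pedigrees)


def _sidecar_frame(pedigrees: list[Pedigree]) -> pd.DataFrame:
    rows = []
    for p in pedigrees:
        for m in p.members:
            rows.append({
                "family_id": p.family_id,
                "individual_id": m.individual_id,
                "sequenced": int(m.sequenced),
                "consanguineous": int(p.consanguineous),
                "diagnosis": _DIAGNOSES.get(
                    m.individual_id,
                    "SCZ" if m.affection is Affection.AFFECTED else
                    ("healthy" if m.affection is Affection.UNAFFECTED else "unknown"),
                ),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted-variant bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class _Planted:
    chrom: str
    pos: int
    ref: str
    alt: str
    family: str
    gene: str
    seg_class: str      # intended class (decoys use their violated pattern)
    fate: str           # "pass" or "dropped-by-<rule>"
    in_all: bool
    in_strict: bool
    genotypes: dict[str, int]          # individual -> GT code, others homref
    consequence: str = "nonsynonymous"
    splice_site: bool = False
    segdup: bool = False
    filter_status: str = "pass"
    af: dict[str, float | None] = field(default_factory=dict)
    inhouse_count: int = 0
    low_depth: bool = False
    rule: str = ""  # violated rule, decoys only

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def _affected_ids(fam: str) -> list[str]:
    return [r[0] for r in _FAMILY_TABLE[fam] if r[4] == "A" and r[5]]


def _rare_af(rng: np.random.Generator) -> dict[str, float | None]:
    """Sub-1% frequencies across the five databases; some entries null
    (never observed) to exercise the null-passes rule."""
    out: dict[str, float | None] = {}
    for db in AF_DATABASES:
        u = rng.random()
        if u < 0.4:
            out[db] = None
        elif u < 0.7:
            out[db] = 0.0
        else:
            out[db] = round(float(rng.uniform(1e-5, 0.009)), 6)
    return out


def _shared_genotypes(fam: str, n_families: int) -> tuple[dict[str, int], bool]:
    """Heterozygous sharing among all affected members.  Returns the
    genotype map and whether the variant survives strict filtering
    (i.e. no sequenced control carries it)."""
    rows = _FAMILY_TABLE[fam]
    genos = {i: GT_HET for i in _affected_ids(fam)}
    sequenced_controls = [r[0] for r in rows if r[4] == "U" and r[5]]
    unsequenced_parents = [r[0] for r in rows if not r[5]]
    if unsequenced_parents:
        # transmit through an unsequenced parent; sequenced controls clean
        genos[unsequenced_parents[0]] = GT_HET
        strict_ok = bool(sequenced_controls)
    else:
        # both parents sequenced: the transmitting parent is a carrier
        # control, which strict filtering must reject
        father = rows[0][0]
        genos[father] = GT_HET
        strict_ok = False
    return genos, strict_ok


def _build_planted(cfg: SimConfig, rng: np.random.Generator) -> list[_Planted]:
    fams = set(list(_FAMILY_TABLE)[:cfg.n_families])
    planted: list[_Planted] = []
    control_fams = {"F01", "F04", "F05", "F10", "F11", "F13", "F14"}

    def gene_name(pool: list[str], idx: int, prefix: str) -> str:
        return pool[idx] if idx < len(pool) else f"{prefix}{idx:03d}"

    # shared het
    shared_fams = [f for f in _SHARED_FAMILIES if f in fams]
    if cfg.n_shared_het and not shared_fams:
        raise SimulationConfigError("no family available for shared-het planting")
    for i in range(cfg.n_shared_het):
        fam = shared_fams[i % len(shared_fams)]
        genos, strict_ok = _shared_genotypes(fam, cfg.n_families)
        chrom = str((i % 12) + 1)
        planted.append(_Planted(
            chrom=chrom, pos=50_000_000 + i * 1_000, ref="A", alt="G",
            family=fam, gene=gene_name(_SHARED_GENES, i, "SHGENE"),
            seg_class="shared_het", fate="pass", in_all=True,
            in_strict=strict_ok and fam in control_fams,
            genotypes=genos, af=_rare_af(rng),
        ))

    # de novo
    slots = [(f, c) for f, c in _DE_NOVO_SLOTS if f in fams]
    if cfg.n_de_novo and not slots:
        raise SimulationConfigError(
            "de novo planting needs a family with both parents sequenced and unaffected")
    for i in range(cfg.n_de_novo):
        fam, child = slots[i % len(slots)]
        planted.append(_Planted(
            chrom=str(13 + (i % 9)), pos=60_000_000 + i * 1_000, ref="C", alt="T",
            family=fam, gene=gene_name(_DE_NOVO_GENES, i, "DNGENE"),
            seg_class="de_novo", fate="pass", in_all=True,
            in_strict=fam in control_fams,
            genotypes={child: GT_HET}, af=_rare_af(rng),
        ))

    # homozygous recessive (consanguineous family: children hom, parents het)
    if cfg.n_homozygous and "F10" not in fams:
        raise SimulationConfigError("homozygous planting needs the consanguineous family")
    for i in range(cfg.n_homozygous):
        genos = {c: GT_HOMALT for c in _affected_ids("F10")}
        genos["F10F"] = GT_HET
        genos["F10M"] = GT_HET
        planted.append(_Planted(
            chrom="3", pos=70_000_000 + i * 1_000, ref="T", alt="G",
            family="F10", gene=gene_name(_HOMOZYGOUS_GENES, i, "HOMGENE"),
            seg_class="homozygous_recessive", fate="pass", in_all=True,
            in_strict=True, genotypes=genos, af=_rare_af(rng),
        ))

    # hemizygous X (affected sons hemizygous, carrier mother het)
    if cfg.n_hemizygous and "F13" not in fams:
        raise SimulationConfigError(
            "hemizygous planting needs a family with affected males and their mother")
    for i in range(cfg.n_hemizygous):
        genos = {"N0812": GT_HOMALT, "N0813": GT_HOMALT, "N1010": GT_HET,
                 "F13F": GT_HOMREF}
        planted.append(_Planted(
            chrom="X", pos=43_000_000 + i * 1_000, ref="C", alt="T",
            family="F13", gene=gene_name(_HEMIZYGOUS_GENES, i, "HEMIGENE"),
            seg_class="hemizygous_x", fate="pass", in_all=True,
            in_strict=True, genotypes=genos, af=_rare_af(rng),
        ))

    # decoys: one shared-het pattern per violated rule, planted in F02
    # (falls back to the first available shared family)
    decoy_fam = "F02" if "F02" in fams else shared_fams[0] if shared_fams else None
    if cfg.decoys_per_rule and decoy_fam is None:
        raise SimulationConfigError("no family available for decoy planting")
    di = 0
    for rep in range(cfg.decoys_per_rule):
        for rule in DECOY_RULES:
            genos, _ = _shared_genotypes(decoy_fam, cfg.n_families)
            p = _Planted(
                chrom=str((di % 10) + 5), pos=80_000_000 + di * 1_000, ref="G", alt="A",
                family=decoy_fam, gene=f"DECOYGENE{di:02d}",
                seg_class="shared_het", fate=_DECOY_FATES[rule],
                in_all=False, in_strict=False, genotypes=genos,
                af=_rare_af(rng), rule=rule,
            )
            if rule == "common_af":
                p.af = dict(p.af)
                p.af["1000G_ALL"] = 0.05
            elif rule == "synonymous_nonsplice":
                p.consequence = "synonymous"
                p.splice_site = False
            elif rule == "segdup":
                p.segdup = True
            elif rule == "vqsr_fail":
                p.filter_status = "fail"
            elif rule == "low_dp":
                p.low_depth = True
            elif rule == "inhouse_common":
                p.inhouse_count = 25
            # high_rvis / low_brain_nx handled via the gene table
            planted.append(p)
            di += 1
    return planted


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig, out_dir: str) -> Bundle:
    """Generate the full input bundle under ``out_dir``.

    Byte-reproducible for a fixed config: the same seed yields identical
    files.  Returns a :class:`Bundle` with all paths and the truth table.
    """
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(out_dir, exist_ok=True)
    pedigrees = default_pedigrees(cfg.n_families)

    individuals: list[Individual] = [m for p in pedigrees for m in p.members]
    ind_index = {m.individual_id: k for k, m in enumerate(individuals)}
    sequenced = [m.individual_id for m in individuals if m.sequenced]
    n_ind = len(individuals)

    # --- background autosomal sites: founders HWE, offspring Mendelian ---
    n_bg = cfg.n_background_sites
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=n_bg)
    bg_gt = np.zeros((n_bg, n_ind), dtype=np.int8)
    for p in pedigrees:
        founders = [m for m in p.members if m.father_id is None and m.mother_id is None]
        nonfounders = [m for m in p.members if m not in founders]
        for m in founders:
            bg_gt[:, ind_index[m.individual_id]] = rng.binomial(2, maf).astype(np.int8)
        # parents precede children in the family tables
        for m in nonfounders:
            fa = bg_gt[:, ind_index[m.father_id]]
            mo = bg_gt[:, ind_index[m.mother_id]]
            child = ((rng.random(n_bg) < fa / 2.0).astype(np.int8)
                     + (rng.random(n_bg) < mo / 2.0).astype(np.int8))
            bg_gt[:, ind_index[m.individual_id]] = child

    chrom_bg = np.array([str(c % 22 + 1) for c in range(n_bg)])
    # positions unique per chromosome, well below the planted ranges
    pos_bg = 1_000_000 + (np.arange(n_bg) // 22) * 137

    # --- planted sites ---
    planted = _build_planted(cfg, rng)
    n_pl = len(planted)
    pl_gt = np.zeros((n_pl, n_ind), dtype=np.int8)
    for i, p in enumerate(planted):
        for ind_id, g in p.genotypes.items():
            if ind_id in ind_index:
                pl_gt[i, ind_index[ind_id]] = g

    # --- assemble site table ---
    sites = pd.DataFrame({
        "chrom": np.concatenate([chrom_bg, [p.chrom for p in planted]]),
        "pos": np.concatenate([pos_bg, [p.pos for p in planted]]).astype(np.int64),
        "ref": ["A"] * n_bg + [p.ref for p in planted],
        "alt": ["G"] * n_bg + [p.alt for p in planted],
        "filter_status": ["pass"] * n_bg + [p.filter_status for p in planted],
    })
    gt_all = np.vstack([bg_gt, pl_gt])

    order = np.lexsort((sites["pos"].to_numpy(), _chrom_rank(sites["chrom"])))
    sites = sites.iloc[order].reset_index(drop=True)
    gt_all = gt_all[order]
    inv = np.empty(len(order), dtype=np.int64)
    inv[order] = np.arange(len(order))
    planted_rows = {int(inv[n_bg + i]): p for i, p in enumerate(planted)}

    # --- depths / qualities ---
    n_sites = len(sites)
    n_seq = len(sequenced)
    seq_idx = np.array([ind_index[s] for s in sequenced])
    gt = gt_all[:, seq_idx]

    nb_p = cfg.depth_nb_n / (cfg.depth_nb_n + cfg.depth_nb_mean)
    dp = cfg.depth_shift + rng.negative_binomial(cfg.depth_nb_n, nb_p,
                                                 size=(n_sites, n_seq)).astype(np.int32)
    gq = rng.integers(60, 100, size=(n_sites, n_seq), dtype=np.int64).astype(np.int32)
    ad_alt = np.zeros((n_sites, n_seq), dtype=np.int32)
    het = gt == GT_HET
    ad_alt[het] = rng.binomial(dp[het], 0.5).astype(np.int32)
    ad_alt[gt == GT_HOMALT] = dp[gt == GT_HOMALT]
    ad_ref = dp - ad_alt

    # planted sites get confident calls (the planted pattern must stand or
    # fall on the segregation rules, not on sampling accidents)
    for row, p in planted_rows.items():
        dp[row, :] = rng.integers(40, 80, size=n_seq)
        gq[row, :] = rng.integers(80, 100, size=n_seq)
        g = gt[row, :]
        a = np.zeros(n_seq, dtype=np.int32)
        hh = g == GT_HET
        a[hh] = np.round(dp[row, hh] * rng.uniform(0.4, 0.6, size=int(hh.sum()))).astype(np.int32)
        a[g == GT_HOMALT] = dp[row, g == GT_HOMALT]
        ad_alt[row, :] = a
        ad_ref[row, :] = dp[row, :] - a
        if p.low_depth:
            dp[row, :] = 5

    table = VariantTable(
        samples=sequenced, sites=sites, gt=gt,
        ad_ref=ad_ref, ad_alt=ad_alt, dp=dp, gq=gq,
    )

    # --- write files ---
    paths = {name: os.path.join(out_dir, fn) for name, fn in [
        ("vcf", "cohort.vcf"), ("ped", "cohort.ped"), ("sidecar", "sidecar.tsv"),
        ("ann", "variant_annotations.tsv"), ("gene", "gene_annotations.tsv"),
        ("inhouse", "inhouse_counts.tsv"), ("gmt", "gene_sets.gmt"),
        ("truth", "truth.tsv"), ("manifest", "manifest.json"),
    ]}
    vs.write_vcf(table, paths["vcf"])
    with open(paths["ped"], "w") as fh:
        fh.write(_ped_text(pedigrees))
    _sidecar_frame(pedigrees).to_csv(paths["sidecar"], sep="\t", index=False)

    ann = _annotation_frame(chrom_bg, pos_bg, maf, planted, order)
    ann.to_csv(paths["ann"], sep="\t", index=False, na_rep=".")
    gene_df = _gene_frame(ann, planted, rng)
    gene_df.to_csv(paths["gene"], sep="\t", index=False)
    inhouse = _inhouse_frame(sites, planted_rows, rng)
    inhouse.to_csv(paths["inhouse"], sep="\t", index=False)
    with open(paths["gmt"], "w") as fh:
        fh.write(_gmt_text(gene_df, rng))

    truth = pd.DataFrame([
        {
            "chrom": p.chrom, "pos": p.pos, "ref": p.ref, "alt": p.alt,
            "family_id": p.family, "gene": p.gene, "seg_class": p.seg_class,
            "fate": p.fate, "in_all": p.in_all, "in_strict": p.in_strict,
        }
        for p in planted
    ], columns=["chrom", "pos", "ref", "alt", "family_id", "gene",
                "seg_class", "fate", "in_all", "in_strict"])
    truth.to_csv(paths["truth"], sep="\t", index=False)

    manifest = {"seed": cfg.seed, "config": _config_echo(cfg)}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    bundle = Bundle(
        out_dir=out_dir, vcf_path=paths["vcf"], ped_path=paths["ped"],
        sidecar_path=paths["sidecar"], annotation_path=paths["ann"],
        gene_path=paths["gene"], inhouse_path=paths["inhouse"],
        gmt_path=paths["gmt"], truth_path=paths["truth"],
        manifest_path=paths["manifest"], truth=truth,
    )
    if cfg.genotype_error_rate > 0:
        bundle = add_genotype_noise(bundle, cfg.genotype_error_rate,
                                    seed=cfg.seed + 1)
    return bundle


def _config_echo(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["maf_range"] = list(d["maf_range"])
    return d


def _chrom_rank(chroms: pd.Series) -> np.ndarray:
    rank = {str(c): c for c in range(1, 23)}
    rank.update({"X": 23, "Y": 24})
    return chroms.map(lambda c: rank.get(str(c).removeprefix("chr"), 99)).to_numpy()


def _annotation_frame(chrom_bg: np.ndarray, pos_bg: np.ndarray, maf: np.ndarray,
                      planted: list[_Planted], order: np.ndarray) -> pd.DataFrame:
    """One annotation row per site, in VCF site order.  Background sites
    are common variants (database AF = simulated MAF) spread over
    ~n_background/10 background genes; a third are protein-altering so the
    frequency filter does real work."""
    n_bg = len(chrom_bg)
    bg_consequences = np.array(["synonymous", "nonsynonymous", "other"])
    f = np.round(maf, 6)
    bg = pd.DataFrame({
        "chrom": chrom_bg,
        "pos": pos_bg.astype(np.int64),
        "ref": "A", "alt": "G",
        "genes": [f"BG{b // 10:05d}" for b in range(n_bg)],
        "consequence": bg_consequences[np.arange(n_bg) % 3],
        "splice_site": 0, "segdup": 0,
        **{f"af_{db}": f for db in AF_DATABASES},
    })
    pl = pd.DataFrame([
        {
            "chrom": p.chrom, "pos": p.pos, "ref": p.ref, "alt": p.alt,
            "genes": p.gene, "consequence": p.consequence,
            "splice_site": int(p.splice_site), "segdup": int(p.segdup),
            **{f"af_{db}": p.af.get(db) for db in AF_DATABASES},
        }
        for p in planted
    ], columns=list(bg.columns))
    ann = pd.concat([bg, pl], ignore_index=True) if len(pl) else bg
    return ann.iloc[order].reset_index(drop=True)


def _gene_frame(ann: pd.DataFrame, planted: list[_Planted],
                rng: np.random.Generator) -> pd.DataFrame:
    bg_genes = sorted({g for gs in ann["genes"] for g in str(gs).split(",")
                       if g.startswith("BG")})
    rows = [
        {"gene": g,
         "rvis_percentile": round(float(rng.uniform(0, 100)), 2),
         "brain_nx": round(float(rng.uniform(0, 5)), 3)}
        for g in bg_genes
    ]
    seen = set(bg_genes)
    for p in planted:
        if p.gene in seen:
            continue
        seen.add(p.gene)
        if p.rule == "high_rvis":
            rvis, nx = 85.0, 3.0
        elif p.rule == "low_brain_nx":
            rvis, nx = 5.0, 0.1
        else:
            rvis, nx = round(float(rng.uniform(1, 20)), 2), round(float(rng.uniform(1.5, 4.0)), 3)
        rows.append({"gene": p.gene, "rvis_percentile": rvis, "brain_nx": nx})
    return pd.DataFrame(rows, columns=["gene", "rvis_percentile", "brain_nx"])


def _inhouse_frame(sites: pd.DataFrame, planted_rows: dict[int, _Planted],
                   rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    # sprinkle sub-threshold detection counts over background sites
    n_sites = len(sites)
    picks = rng.choice(n_sites, size=min(500, n_sites), replace=False)
    counts = rng.integers(1, 20, size=len(picks))
    planted_set = set(planted_rows)
    for idx, c in zip(picks, counts):
        if int(idx) in planted_set:
            continue
        rows.append({"chrom": sites["chrom"].iloc[int(idx)],
                     "pos": int(sites["pos"].iloc[int(idx)]),
                     "ref": sites["ref"].iloc[int(idx)],
                     "alt": sites["alt"].iloc[int(idx)],
                     "detection_count": int(c)})
    for i, p in planted_rows.items():
        if p.inhouse_count > 0:
            rows.append({"chrom": p.chrom, "pos": p.pos, "ref": p.ref,
                         "alt": p.alt, "detection_count": p.inhouse_count})
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "detection_count"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _gmt_text(gene_df: pd.DataFrame, rng: np.random.Generator) -> str:
    calcium = ["CACNA1C", "CACNA1E", "CACNA1G", "CACNB1", "RYR1", "RYR2",
               "ITPR1", "STIM2"]
    present = [g for g in calcium if g in set(gene_df["gene"])]
    lines = ["SIM:CA\tcalcium channel-like activity\t" + "\t".join(present or calcium)]
    bg = [g for g in gene_df["gene"] if g.startswith("BG")]
    for i in range(9):
        members = sorted(rng.choice(bg, size=min(20, len(bg)), replace=False)) if bg else []
        lines.append(f"SIM:RND{i}\trandom background set {i}\t" + "\t".join(members))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# genotype noise
# ---------------------------------------------------------------------------

def add_genotype_noise(bundle: Bundle, rate: float, seed: int,
                       kinds: tuple[str, ...] = ("dp", "gq", "gt", "ad"),
                       out_dir: str | None = None) -> Bundle:
    """Perturb per-call fields at the given per-call rate and rewrite the
    VCF, recording every perturbed call in a noise ledger.

    Kinds: ``dp`` depth to 5, ``gq`` quality to 5, ``gt`` genotype flip
    (het<->homref, homalt->het), ``ad`` allele-ratio skew.  rate=0 returns
    an identical bundle (no calls touched).
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out_dir = out_dir or bundle.out_dir
    os.makedirs(out_dir, exist_ok=True)
    table = vs.read_vcf(bundle.vcf_path)
    n, m = table.gt.shape
    hit = rng.random((n, m)) < rate
    which = rng.integers(0, len(kinds), size=(n, m))
    ledger_rows = []
    for i, j in zip(*np.nonzero(hit)):
        kind = kinds[int(which[i, j])]
        site = table.sites.iloc[int(i)]
        sample = table.samples[int(j)]
        old_gt = int(table.gt[i, j])
        if kind == "dp":
            old, new = int(table.dp[i, j]), 5
            table.dp[i, j] = new
        elif kind == "gq":
            old, new = int(table.gq[i, j]), 5
            table.gq[i, j] = new
        elif kind == "gt":
            old = old_gt
            new = {GT_HET: GT_HOMREF, GT_HOMREF: GT_HET,
                   GT_HOMALT: GT_HET, GT_MISSING: GT_MISSING}[old_gt]
            table.gt[i, j] = new
            if new == GT_HET:
                half = max(1, int(table.dp[i, j]) // 2)
                table.ad_alt[i, j] = half
                table.ad_ref[i, j] = max(0, int(table.dp[i, j]) - half)
            elif new == GT_HOMREF:
                table.ad_alt[i, j] = 0
                table.ad_ref[i, j] = max(0, int(table.dp[i, j]))
        else:  # ad skew: alt support collapses below the ratio threshold
            old = int(table.ad_alt[i, j])
            dp = max(int(table.dp[i, j]), 1)
            new = max(0, dp // 10)
            table.ad_alt[i, j] = new
            table.ad_ref[i, j] = dp - new
        ledger_rows.append({
            "chrom": site.chrom, "pos": int(site.pos), "ref": site.ref,
            "alt": site.alt, "sample": sample, "field": kind,
            "old": old, "new": new,
        })
    ledger = pd.DataFrame(ledger_rows, columns=["chrom", "pos", "ref", "alt",
                                                "sample", "field", "old", "new"])
    vcf_path = os.path.join(out_dir, "cohort.vcf")
    vs.write_vcf(table, vcf_path)
    ledger_path = os.path.join(out_dir, "noise_ledger.tsv")
    ledger.to_csv(ledger_path, sep="\t", index=False)
    return replace(bundle, out_dir=out_dir, vcf_path=vcf_path,
                   noise_ledger=ledger, noise_ledger_path=ledger_path)


# ---------------------------------------------------------------------------
# independent consistency checks (used by the test-suite oracles)
# ---------------------------------------------------------------------------

def mendelian_violations(table: VariantTable, pedigrees: list[Pedigree]) -> list[tuple[int, str]]:
    """Scan fully sequenced autosomal trios for transmission violations.

    Returns (site row, child id) pairs where the child's genotype is
    impossible given both parents' called genotypes.  X sites and trios
    with any missing call are skipped; this is deliberately independent
    of the segregation classifier.
    """
    auto = table.sites["chrom"].isin({str(c) for c in range(1, 23)}).to_numpy()
    idx = {s: k for k, s in enumerate(table.samples)}
    trios = []
    for p in pedigrees:
        for m in p.members:
            if (m.sequenced and m.father_id and m.mother_id
                    and m.individual_id in idx
                    and p.member(m.father_id).sequenced and m.father_id in idx
                    and p.member(m.mother_id).sequenced and m.mother_id in idx):
                trios.append((m.individual_id, m.father_id, m.mother_id))
    out = []
    for child, fa, mo in trios:
        c, f, g = (table.gt[:, idx[child]], table.gt[:, idx[fa]], table.gt[:, idx[mo]])
        called = (c >= 0) & (f >= 0) & (g >= 0) & auto
        # allele counts transmissible from a parent with genotype x: x==0 -> {0},
        # x==1 -> {0,1}, x==2 -> {1}
        lo = (f == 2).astype(np.int8) + (g == 2).astype(np.int8)
        hi = (f >= 1).astype(np.int8) + (g >= 1).astype(np.int8)
        bad = called & ((c < lo) | (c > hi))
        for row in np.nonzero(bad)[0]:
            out.append((int(row), child))
    return out
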