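"""Variant table: multi-sample VCF input, multiallelic splitting, and the
join against variant- and gene-level annotation tables.

The in-memory container is a :class:`VariantTable`: a sites DataFrame
(one row per biallelic record after splitting) plus dense per-call numpy
matrices (GT code, AD ref/alt, DP, GQ) aligned site-by-sample.  Dense
matrices keep genotype QC and kinship estimation vectorised; the cohorts
this targets (tens of samples, tens of thousands of exonic sites) fit in
memory trivially.

Genotype codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.  A genotype
composed of *other* ALT alleles at a split multiallelic site is recoded to
hom-ref for the kept allele's record and flagged in ``other_alt`` — such a
call carries neither the kept allele nor REF certainty, and is never
counted as a carrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GT_HOMREF",
    "GT_HET",
    "GT_HOMALT",
    "GT_MISSING",
    "VariantTable",
    "AnnotatedCohort",
    "read_vcf",
    "write_vcf",
    "read_annotations",
    "read_gene_annotations",
    "read_inhouse_counts",
    "join_annotations",
    "variant_key",
]

GT_HOMREF = 0
GT_HET = 1
GT_HOMALT = 2
GT_MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "filter_status"]


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class VariantTable:
    """Biallelic variant records with dense per-sample call matrices."""

    samples: list[str]
    sites: pd.DataFrame  # columns: chrom, pos, ref, alt, filter_status
    gt: np.ndarray       # (n_sites, n_samples) int8
    ad_ref: np.ndarray   # int32, -1 = missing
    ad_alt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    other_alt: np.ndarray = field(default=None)  # bool, flagged recodes

    def __post_init__(self) -> None:
        n = len(self.sites)
        m = len(self.samples)
        if self.other_alt is None:
            self.other_alt = np.zeros((n, m), dtype=bool)
        for name in ("gt", "ad_ref", "ad_alt", "dp", "gq", "other_alt"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, m)}")
        keys = self.keys()
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant key {dup!r}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def keys(self) -> pd.Series:
        s = self.sites
        return (
            s["chrom"].astype(str)
            + ":" + s["pos"].astype(str)
            + ":" + s["ref"] + ":" + s["alt"]
        )

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def subset_sites(self, mask: np.ndarray | pd.Series) -> "VariantTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return VariantTable(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            gt=self.gt[idx].copy(),
            ad_ref=self.ad_ref[idx].copy(),
            ad_alt=self.ad_alt[idx].copy(),
            dp=self.dp[idx].copy(),
            gq=self.gq[idx].copy(),
            other_alt=self.other_alt[idx].copy(),
        )

    def copy(self) -> "VariantTable":
        return self.subset_sites(np.ones(self.n_sites, dtype=bool))


def read_vcf(path: str) -> VariantTable:
    """Read a VCF 4.x file into a :class:`VariantTable`, splitting
    multiallelic sites into one record per ALT allele.

    Requires GT in FORMAT; AD/DP/GQ are optional and missing values are
    encoded -1.  Per-allele AD decomposition at split sites keeps the REF
    depth and the allele's own depth.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    m = len(samples)
    rows: list[tuple] = []
    gt_rows: list[np.ndarray] = []
    adr_rows: list[np.ndarray] = []
    ada_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    oa_rows: list[np.ndarray] = []

    for rec in vcf:
        filt = rec.FILTER  # None means PASS in cyvcf2
        if filt is None or filt == "PASS":
            status = "pass"
        elif filt == ".":
            status = "other"
        else:
            status = "fail"

        # allele index per haplotype: (m, ploidy+1) with phase col last
        g = np.asarray(rec.genotype.array())
        alleles = g[:, :-1]
        ad = rec.format("AD")
        dp = rec.format("DP")
        gq = rec.format("GQ")
        dp_v = _int_vector(dp, m)
        gq_v = _int_vector(gq, m)

        for ai, alt in enumerate(rec.ALT, start=1):
            gt_v = np.full(m, GT_MISSING, dtype=np.int8)
            oa_v = np.zeros(m, dtype=bool)
            # cyvcf2 pads mixed-ploidy genotypes with -2; -1 is a missing allele
            ploidy_v = np.sum(alleles > -2, axis=1)
            called = ~np.any(alleles == -1, axis=1) & (ploidy_v > 0)
            n_this = np.sum(alleles == ai, axis=1)
            n_ref = np.sum(alleles == 0, axis=1)
            homalt = called & (n_this == ploidy_v)
            het = called & (n_this > 0) & (n_this < ploidy_v) & (n_this + n_ref == ploidy_v)
            homref = called & (n_this == 0) & (n_ref == ploidy_v)
            gt_v[homalt] = GT_HOMALT
            gt_v[het] = GT_HET
            gt_v[homref] = GT_HOMREF
            # any genotype involving a different ALT allele (e.g. 1/2 or
            # 2/2 seen from allele 1's record) carries neither the kept
            # allele "cleanly" nor REF: recode hom-ref, flag, never a carrier
            other = called & ~(homalt | het | homref)
            gt_v[other] = GT_HOMREF
            oa_v[other] = True

            if ad is not None and ad.shape[1] > ai:
                adr_v = _clean_counts(ad[:, 0])
                ada_v = _clean_counts(ad[:, ai])
            else:
                adr_v = np.full(m, -1, dtype=np.int32)
                ada_v = np.full(m, -1, dtype=np.int32)

            rows.append((rec.CHROM, rec.POS, rec.REF, alt, status))
            gt_rows.append(gt_v)
            adr_rows.append(adr_v)
            ada_rows.append(ada_v)
            dp_rows.append(dp_v)
            gq_rows.append(gq_v)
            oa_rows.append(oa_v)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    n = len(sites)

    def stack(rows_: list[np.ndarray], dtype) -> np.ndarray:
        if n == 0:
            return np.zeros((0, m), dtype=dtype)
        return np.vstack(rows_).astype(dtype)

    return VariantTable(
        samples=samples,
        sites=sites,
        gt=stack(gt_rows, np.int8),
        ad_ref=stack(adr_rows, np.int32),
        ad_alt=stack(ada_rows, np.int32),
        dp=stack(dp_rows, np.int32),
        gq=stack(gq_rows, np.int32),
        other_alt=stack(oa_rows, bool),
    )


def _int_vector(arr, m: int) -> np.ndarray:
    if arr is None:
        return np.full(m, -1, dtype=np.int32)
    v = np.asarray(arr).reshape(m, -1)[:, 0].astype(np.int64)
    v = np.where((v < 0) | (v > 10**8), -1, v)
    return v.astype(np.int32)


def _clean_counts(col) -> np.ndarray:
    v = np.asarray(col).astype(np.int64)
    v = np.where((v < 0) | (v > 10**8), -1, v)
    return v.astype(np.int32)


_GT_STRINGS = {GT_HOMREF: "0/0", GT_HET: "0/1", GT_HOMALT: "1/1", GT_MISSING: "./."}

VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FILTER=<ID=PASS,Description="All filters passed">',
    '##FILTER=<ID=VQSRTrancheSNP99.90to100.00,Description="VQSR tranche failure">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
]


def write_vcf(table: VariantTable, path: str, *, assembly: str = "GRCh37") -> None:
    """Write a biallelic VariantTable as plain-text VCF 4.2.

    Sites are written in chromosome/position order as stored.  Calls with
    missing AD/DP/GQ print '.' in those subfields.
    """
    lines = list(VCF_HEADER_LINES)
    lines.insert(1, f"##reference={assembly}")
    seen: list[str] = []
    for c in table.sites["chrom"]:
        if c not in seen:
            seen.append(c)
    lines.extend(f"##contig=<ID={c}>" for c in seen)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples)
    )
    sites = table.sites
    filt_map = {"pass": "PASS", "fail": "VQSRTrancheSNP99.90to100.00", "other": "."}
    for i in range(table.n_sites):
        row = sites.iloc[i]
        calls = []
        for j in range(len(table.samples)):
            gt = _GT_STRINGS[int(table.gt[i, j])]
            adr, ada = int(table.ad_ref[i, j]), int(table.ad_alt[i, j])
            ad = f"{adr},{ada}" if adr >= 0 and ada >= 0 else "."
            dp = str(int(table.dp[i, j])) if table.dp[i, j] >= 0 else "."
            gq = str(int(table.gq[i, j])) if table.gq[i, j] >= 0 else "."
            calls.append(f"{gt}:{ad}:{dp}:{gq}")
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t"
            f"{filt_map[row.filter_status]}\t.\tGT:AD:DP:GQ\t" + "\t".join(calls)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


CONSEQUENCES = {
    "synonymous",
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "inframe_indel",
    "splicing",
    "other",
}


def read_annotations(path: str) -> pd.DataFrame:
    """Read the per-variant annotation TSV.

    Expected header: chrom pos ref alt genes consequence splice_site segdup
    af_<dbname>...  ``genes`` is comma-separated; AF columns may contain '.'
    for "not observed in that database" (kept as NaN; the rarity filter
    treats NaN as frequency 0).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["."])
    required = {"chrom", "pos", "ref", "alt", "genes", "consequence", "splice_site", "segdup"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    bad = set(df["consequence"]) - CONSEQUENCES
    if bad:
        raise ValueError(f"unknown consequence values: {sorted(bad)}")
    df["splice_site"] = df["splice_site"].astype(int).astype(bool)
    df["segdup"] = df["segdup"].astype(int).astype(bool)
    df["key"] = [
        variant_key(c, p, r, a)
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    if df["key"].duplicated().any():
        dup = df.loc[df["key"].duplicated(), "key"].iloc[0]
        raise ValueError(f"duplicate annotation key {dup!r}")
    return df


def read_gene_annotations(path: str) -> pd.DataFrame:
    """Read the per-gene TSV: gene, rvis_percentile, brain_nx."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "rvis_percentile", "brain_nx"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene TSV missing columns: {sorted(missing)}")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene in gene annotation TSV")
    return df.set_index("gene")


def read_inhouse_counts(path: str) -> dict[str, int]:
    """Read the in-house cohort detection-count TSV keyed like variants."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        variant_key(c, p, r, a): int(n)
        for c, p, r, a, n in zip(df["chrom"], df["pos"], df["ref"], df["alt"], df["detection_count"])
    }


@dataclass
class AnnotatedCohort:
    """A variant table joined with its annotation rows (aligned site-wise)
    plus the gene-level annotation table."""

    table: VariantTable
    annotations: pd.DataFrame       # aligned to table.sites, same row order
    gene_annotations: pd.DataFrame  # indexed by gene symbol
    n_unannotated: int = 0

    def subset_sites(self, mask: np.ndarray) -> "AnnotatedCohort":
        mask = np.asarray(mask)
        return AnnotatedCohort(
            table=self.table.subset_sites(mask),
            annotations=self.annotations.loc[mask].reset_index(drop=True),
            gene_annotations=self.gene_annotations,
            n_unannotated=self.n_unannotated,
        )

    def genes_of(self, i: int) -> list[str]:
        return str(self.annotations["genes"].iloc[i]).split(",")

    def af_columns(self) -> list[str]:
        return [c for c in self.annotations.columns if c.startswith("af_")]


def join_annotations(
    table: VariantTable,
    annotations: pd.DataFrame,
    gene_annotations: pd.DataFrame,
) -> AnnotatedCohort:
    """Left-join variants with the annotation table on (chrom,pos,ref,alt).

    Variants lacking an annotation row are dropped from downstream filtering
    and counted in ``n_unannotated`` (lossless: kept + dropped = input).
    """
    keys = table.keys()
    ann = annotations.set_index("key")
    present = keys.isin(ann.index).to_numpy()
    kept = table.subset_sites(present)
    aligned = ann.loc[keys[present]].reset_index()
    return AnnotatedCohort(
        table=kept,
        annotations=aligned,
        gene_annotations=gene_annotations,
        n_unannotated=int((~present).sum()),
    )
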