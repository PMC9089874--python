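"""Hand-built mini-fixtures for the published variant classes.

These encode, as runnable inputs, the variant constellations a
multiplex-family pipeline must reproduce: fifteen loss-of-function
shared candidates, five de novo calls (three in a quartet with sequenced
unaffected parents, two in an affected mother whose own parents were
sequenced), one homozygous recessive variant in a consanguineous sibship,
and one X-linked hemizygous variant segregating from a heterozygous
carrier mother to two affected sons.  Positions, gene symbols and
population allele frequencies are the published GRCh37 values; pedigree
shapes are synthetic reconstructions chosen to realise each class.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import variants as vs
from .segregation import CandidateVariant, SegregationClass
from .simulate import AF_DATABASES, Bundle
from .variants import GT_HET, GT_HOMALT, GT_HOMREF, VariantTable

__all__ = ["table1_candidates", "table2_fixture", "table3_gmt_strict",
           "table3_gmt_all"]

# ---------------------------------------------------------------------------
# loss-of-function shared candidates (15 variants, 15 genes)
# ---------------------------------------------------------------------------

_TABLE1 = [
    ("F01", "20:48479568", "frameshift_indel", "SLC9A8"),
    ("F03", "19:56000877", "frameshift_indel", "SSC5D"),
    ("F06", "10:26785321", "splicing", "APBB1IP"),
    ("F07", "19:33167791", "frameshift_indel", "RGS9BP"),
    ("F08", "1:60306057", "frameshift_indel", "HOOK1"),
    ("F08", "16:3165404", "stopgain", "ZNF205"),
    ("F09", "2:84932821", "stopgain", "DNAH6"),
    ("F10", "2:80085187", "stopgain", "CTNNA2"),
    ("F10", "18:6898571", "stoploss", "ARHGAP28"),
    ("F10", "7:12384097", "splicing", "VWDE"),
    ("F11", "17:18150343", "stopgain", "FLII"),
    ("F11", "19:33134477", "splicing", "ANKRD27"),
    ("F14", "4:186357227", "frameshift_indel", "C4orf47"),
    ("F14", "8:29043913", "frameshift_indel", "KIF13B"),
    ("F14", "16:74694876", "frameshift_indel", "RFWD3"),
]


def table1_candidates() -> list[CandidateVariant]:
    """The loss-of-function candidate list as CandidateVariant objects
    (shared heterozygous class; REF/ALT alleles are placeholders since
    only positions and genes are published)."""
    out = []
    for fam, locus, consequence, gene in _TABLE1:
        chrom, pos = locus.split(":")
        if consequence == "frameshift_indel":
            ref, alt = "AT", "A"
        else:
            ref, alt = "G", "T"
        out.append(CandidateVariant(
            chrom=chrom, pos=int(pos), ref=ref, alt=alt, family_id=fam,
            seg_class=SegregationClass.SHARED_HET,
            carriers=frozenset(), genes=frozenset({gene}),
        ))
    return out


# ---------------------------------------------------------------------------
# de novo / homozygous / hemizygous constellation
# ---------------------------------------------------------------------------

# (chrom, pos, ref, alt, gene, consequence, af per ExAC_ALL/ExAC_EAS/
#  1000G_ALL/HGVD/jMorp, section, genotype map)
_TABLE2 = [
    ("12", 2224447, "C", "T", "CACNA1C", "nonsynonymous",
     (0, 0, 0, 0, 0), "de_novo", {"N0674": GT_HET}),
    ("19", 14046846, "G", "A", "PODNL1", "nonsynonymous",
     (0, 0, 0, 0, 0), "de_novo", {"N0674": GT_HET}),
    ("19", 39993536, "G", "T", "DLL3", "nonsynonymous",
     (0, 0, 0, 0, 0), "de_novo", {"N0673": GT_HET}),
    ("2", 10582149, "C", "T", "ODC1", "nonsynonymous",
     (0.000022, 0.0002, 0, 0, 0), "de_novo", {"N1010": GT_HET}),
    ("9", 139964552, "CACT", "C", "SAPCD2", "inframe_indel",
     (0, 0, 0, 0, 0), "de_novo", {"N1010": GT_HET}),
    ("3", 1363404, "T", "G", "CNTN6", "nonsynonymous",
     (0.000011, 0.0002, 0, 0.0016, 0.002), "homozygous_recessive",
     {"N0688": GT_HOMALT, "N0689": GT_HOMALT, "F10F": GT_HET, "F10M": GT_HET}),
    ("X", 43662605, "C", "T", "MAOB", "nonsynonymous",
     (0.0004, 0, 0.00052, 0.00042, 0), "hemizygous_x",
     # sons hemizygous (diploid-coded), carrier mother het; her own het is
     # inherited from the carrier grandmother, so it is not de novo
     {"N0812": GT_HOMALT, "N0813": GT_HOMALT, "N1010": GT_HET, "GM13": GT_HET}),
]

_AF_ORDER = ("ExAC_ALL", "ExAC_EAS", "1000G_ALL", "HGVD", "jMorp")

_FIXTURE_PED = """\
F04 F04F 0 0 1 1
F04 F04M 0 0 2 1
F04 N0673 F04F F04M 1 2
F04 N0674 F04F F04M 2 2
F10 F10F 0 0 1 1
F10 F10M 0 0 2 1
F10 N0688 F10F F10M 1 2
F10 N0689 F10F F10M 2 2
F13 GF13 0 0 1 1
F13 GM13 0 0 2 1
F13 F13F 0 0 1 1
F13 N1010 GF13 GM13 2 2
F13 N0812 F13F N1010 1 2
F13 N0813 F13F N1010 1 2
"""

_FIXTURE_SAMPLES = ["F04F", "F04M", "N0673", "N0674",
                    "F10F", "F10M", "N0688", "N0689",
                    "GF13", "GM13", "F13F", "N1010", "N0812", "N0813"]


def table2_fixture(out_dir: str) -> Bundle:
    """Write the seven-variant fixture bundle under ``out_dir``.

    Running the pipeline on it must classify five de novo, one homozygous
    recessive and one X-linked hemizygous candidate, all passing the
    frequency filter at their published allele frequencies.
    """
    os.makedirs(out_dir, exist_ok=True)
    n, m = len(_TABLE2), len(_FIXTURE_SAMPLES)
    sample_idx = {s: j for j, s in enumerate(_FIXTURE_SAMPLES)}
    gt = np.zeros((n, m), dtype=np.int8)
    for i, row in enumerate(_TABLE2):
        for ind, g in row[8].items():
            gt[i, sample_idx[ind]] = g
    dp = np.full((n, m), 60, dtype=np.int32)
    gq = np.full((n, m), 99, dtype=np.int32)
    ad_alt = np.zeros((n, m), dtype=np.int32)
    ad_alt[gt == GT_HET] = 30
    ad_alt[gt == GT_HOMALT] = 60
    ad_ref = dp - ad_alt

    sites = pd.DataFrame(
        [(r[0], r[1], r[2], r[3], "pass") for r in _TABLE2],
        columns=["chrom", "pos", "ref", "alt", "filter_status"],
    )
    table = VariantTable(samples=list(_FIXTURE_SAMPLES), sites=sites, gt=gt,
                         ad_ref=ad_ref, ad_alt=ad_alt, dp=dp, gq=gq)

    paths = {name: os.path.join(out_dir, fn) for name, fn in [
        ("vcf", "cohort.vcf"), ("ped", "cohort.ped"), ("sidecar", "sidecar.tsv"),
        ("ann", "variant_annotations.tsv"), ("gene", "gene_annotations.tsv"),
        ("inhouse", "inhouse_counts.tsv"), ("gmt", "gene_sets.gmt"),
        ("truth", "truth.tsv"), ("manifest", "manifest.json"),
    ]}
    vs.write_vcf(table, paths["vcf"])
    with open(paths["ped"], "w") as fh:
        fh.write(_FIXTURE_PED)
    sidecar = pd.DataFrame([
        {"family_id": fam, "individual_id": ind, "sequenced": 1,
         "consanguineous": int(fam == "F10"),
         "diagnosis": "OCD" if ind in {"N1010", "N0812", "N0813"} else "SCZ"}
        for fam, ind in [(l.split()[0], l.split()[1]) for l in _FIXTURE_PED.splitlines()]
    ])
    sidecar.to_csv(paths["sidecar"], sep="\t", index=False)

    ann_rows = []
    for r in _TABLE2:
        afs = dict(zip(_AF_ORDER, r[6]))
        ann_rows.append({
            "chrom": r[0], "pos": r[1], "ref": r[2], "alt": r[3],
            "genes": r[4], "consequence": r[5], "splice_site": 0, "segdup": 0,
            **{f"af_{db}": afs[db] for db in AF_DATABASES},
        })
    pd.DataFrame(ann_rows).to_csv(paths["ann"], sep="\t", index=False, na_rep=".")
    pd.DataFrame(
        [{"gene": r[4], "rvis_percentile": 10.0, "brain_nx": 2.0} for r in _TABLE2]
    ).to_csv(paths["gene"], sep="\t", index=False)
    pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "detection_count"]).to_csv(
        paths["inhouse"], sep="\t", index=False)
    with open(paths["gmt"], "w") as fh:
        fh.write(table3_gmt_strict())

    truth = pd.DataFrame([
        {"chrom": r[0], "pos": r[1], "ref": r[2], "alt": r[3],
         "family_id": "F04" if r[7] == "de_novo" and r[4] in {"CACNA1C", "PODNL1", "DLL3"}
         else ("F13" if r[4] in {"ODC1", "SAPCD2", "MAOB"} else "F10"),
         "gene": r[4], "seg_class": r[7], "fate": "pass",
         "in_all": True, "in_strict": True}
        for r in _TABLE2
    ])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        fh.write('{"fixture": "table2"}\n')

    return Bundle(
        out_dir=out_dir, vcf_path=paths["vcf"], ped_path=paths["ped"],
        sidecar_path=paths["sidecar"], annotation_path=paths["ann"],
        gene_path=paths["gene"], inhouse_path=paths["inhouse"],
        gmt_path=paths["gmt"], truth_path=paths["truth"],
        manifest_path=paths["manifest"], truth=truth,
    )


# ---------------------------------------------------------------------------
# published gene-set membership lists (for coverage bookkeeping)
# ---------------------------------------------------------------------------

_T3_STRICT = [
    ("GO:0005262", "Calcium channel activity",
     "CACNA1C RYR2 CACNB1 CACNA1E LOXHD1 RYR1 CACNA1G"),
    ("GO:0015085", "Calcium ion transmembrane transporter activity",
     "CACNA1C RYR2 CACNB1 CACNA1E LOXHD1 RYR1 CACNA1G"),
    ("GO:0005245", "Voltage-gated calcium channel activity",
     "CACNA1C CACNB1 CACNA1E RYR1 CACNA1G"),
]

_T3_ALL = [
    ("GO:0042391", "Regulation of membrane potential",
     "WWP2 LRRK2 SHANK1 KCNH7 IFI6 MAPK8IP2 KCNQ1 DSC2 ANK3 ACSBG1 CHRNA4 "
     "CACNA1E SKI RYR2 NRXN1 CACNA1G ANK2 AKAP6"),
    ("GO:0043269", "Regulation of ion transport",
     "DIAPH1 WWP2 CAPN3 STIM2 CNKSR3 CACNA1C SHANK1 WNK2 AKT1 HOMER1 "
     "MAPK8IP2 KCNQ1 CAMK2G ANK3 CHRNA4 RYR2 NRXN1 ANK2 AKAP6"),
    ("GO:0005262", "Calcium channel activity",
     "RYR1 ITPR1 STIM2 CACNB1 CACNA1C LOXHD1 RYR3 CACNA1E RYR2 CACNA1G"),
    ("GO:0015085", "Calcium ion transmembrane transporter activity",
     "RYR1 ITPR2 STIM2 CACNB1 CACNA1C LOXHD1 RYR3 CACNA1E RYR2 CACNA1G"),
    ("GO:0034765", "Regulation of ion transmembrane transport",
     "WWP2 STIM2 SHANK1 WNK2 AKT1 HOMER1 MAPK8IP2 KCNQ1 ANK3 RYR2 NRXN1 ANK2 AKAP6"),
    ("GO:0072509", "Divalent inorganic cation transmembrane transporter activity",
     "RYR1 ITPR1 STIM2 CACNB1 CACNA1C LOXHD1 RYR3 ITPR2 CACNA1E RYR2 CACNA1G"),
    ("GO:0010959", "Regulation of metal ion transport",
     "DIAPH1 WWP2 CAPN3 STIM2 CNKSR3 CACNA1C WNK2 HOMER1 KCNQ1 CAMK2G ANK3 "
     "RYR2 ANK2 AKAP6"),
    ("GO:0032409", "Regulation of transporter activity",
     "WWP2 STIM2 SHANK1 WNK2 HOMER1 KMT2A MAPK8IP2 ANK3 RYR2 NRXN1 ANK2 AKAP6"),
    ("GO:0034762", "Regulation of transmembrane transport",
     "WWP2 STIM2 SHANK1 WNK2 AKT1 HOMER1 MAPK8IP2 KCNQ1 ANK3 RYR2 NRXN1 ANK2 AKAP6"),
    ("GO:0032411", "Positive regulation of transporter activity",
     "STIM2 WNK2 KMT2A ANK3 RYR2 ANK2 AKAP6"),
    ("GO:0032412", "Regulation of ion transmembrane transporter activity",
     "WWP2 STIM2 SHANK1 WNK2 HOMER1 MAPK8IP2 ANK3 RYR2 NRXN1 ANK2 AKAP6"),
    ("GO:0022898", "Regulation of transmembrane transporter activity",
     "WWP2 STIM2 SHANK1 WNK2 HOMER1 MAPK8IP2 ANK3 RYR2 NRXN1 ANK2 AKAP6"),
    ("GO:0051235", "Maintenance of location",
     "ABCA1 CER1 RYR1 NFKBIE ITPR1 OSBPL11 DAG1 ENPP1 LATS1 SHANK1 NFKB1 "
     "TLN1 ANK3 SYNE1 RYR2"),
    ("GO:2000021", "Regulation of ion homeostasis",
     "RYR1 DIAPH1 CAPN3 ITPR1 CACNA1C WNK2 IFI6 ANK3 RYR2 ANK2 AKAP6"),
]


def _gmt(rows) -> str:
    return "\n".join(
        "\t".join([sid, name] + genes.split()) for sid, name, genes in rows
    ) + "\n"


def table3_gmt_strict() -> str:
    """GMT text for the significant sets reported on the strict gene list."""
    return _gmt(_T3_STRICT)


def table3_gmt_all() -> str:
    """GMT text for the significant sets reported on the full gene list."""
    return _gmt(_T3_ALL)
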