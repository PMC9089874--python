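"""Rare deleterious-variant filters.

Three conjunctive predicates over the annotated, QC-passed table:

1. consequence — protein-altering classes (missense, nonsense, stop-loss,
   frameshift and in-frame indels, canonical splicing), plus synonymous
   variants flagged as splice-site (exonic splice-enhancer disruption);
2. rarity — allele frequency <= 1% in every configured population
   database; a null frequency means the variant was not observed there
   and passes;
3. gene constraints — the variant overlaps at least one gene that is both
   intolerant (RVIS percentile <= 25) and brain-expressed (normalised
   expression >= 1).

All boundaries are inclusive.  Conjunction makes application order
irrelevant; tightening any threshold can only shrink the surviving set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import AnnotatedCohort

__all__ = ["FilterConfig", "is_candidate_consequence", "passes_frequency",
           "passes_gene_constraints", "apply_rare_filters", "FilterReport"]

PROTEIN_ALTERING = frozenset(
    {"nonsynonymous", "stopgain", "stoploss", "frameshift_indel",
     "inframe_indel", "splicing"}
)

DEFAULT_DATABASES = ("1000G_ALL", "ExAC_ALL", "ExAC_EAS", "HGVD", "jMorp")


@dataclass
class FilterConfig:
    max_af: float = 0.01
    databases: tuple[str, ...] = DEFAULT_DATABASES
    max_rvis_percentile: float = 25.0
    min_brain_nx: float = 1.0
    protein_altering_classes: frozenset = PROTEIN_ALTERING
    include_splice_synonymous: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_af <= 1.0):
            raise ValueError("max_af must be in [0, 1]")
        if not (0.0 <= self.max_rvis_percentile <= 100.0):
            raise ValueError("max_rvis_percentile must be in [0, 100]")


@dataclass
class FilterReport:
    n_in: int = 0
    n_out: int = 0
    n_fail_consequence: int = 0
    n_fail_frequency: int = 0
    n_fail_gene_constraints: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def is_candidate_consequence(consequence: str, splice_site: bool,
                             cfg: FilterConfig | None = None) -> bool:
    cfg = cfg or FilterConfig()
    if consequence in cfg.protein_altering_classes:
        return True
    return bool(
        cfg.include_splice_synonymous and consequence == "synonymous" and splice_site
    )


def passes_frequency(af: dict[str, float | None], cfg: FilterConfig | None = None) -> bool:
    """Rare in every configured database; null (never observed) passes.
    A configured database missing from the map entirely is a configuration
    error, not a pass."""
    cfg = cfg or FilterConfig()
    for db in cfg.databases:
        if db not in af:
            raise KeyError(f"database {db!r} absent from allele-frequency map")
        v = af[db]
        if v is not None and not (isinstance(v, float) and np.isnan(v)) and v > cfg.max_af:
            return False
    return True


def passes_gene_constraints(genes: list[str], gene_annotations: pd.DataFrame,
                            cfg: FilterConfig | None = None) -> bool:
    """True when ANY overlapped gene is both intolerant and brain-expressed;
    genes missing from the annotation table fail individually."""
    cfg = cfg or FilterConfig()
    for g in genes:
        if g not in gene_annotations.index:
            continue
        row = gene_annotations.loc[g]
        if (row["rvis_percentile"] <= cfg.max_rvis_percentile
                and row["brain_nx"] >= cfg.min_brain_nx):
            return True
    return False


def consequence_mask(cohort: AnnotatedCohort, cfg: FilterConfig) -> np.ndarray:
    ann = cohort.annotations
    return np.array(
        [
            is_candidate_consequence(c, s, cfg)
            for c, s in zip(ann["consequence"], ann["splice_site"])
        ],
        dtype=bool,
    )


def frequency_mask(cohort: AnnotatedCohort, cfg: FilterConfig) -> np.ndarray:
    ann = cohort.annotations
    cols = {}
    for db in cfg.databases:
        col = f"af_{db}"
        if col not in ann.columns:
            raise KeyError(f"database {db!r} absent from annotation table")
        cols[db] = ann[col].to_numpy(dtype=float)
    ok = np.ones(len(ann), dtype=bool)
    for v in cols.values():
        ok &= np.isnan(v) | (v <= cfg.max_af)
    return ok


def gene_constraint_mask(cohort: AnnotatedCohort, cfg: FilterConfig) -> np.ndarray:
    ga = cohort.gene_annotations
    passing = set(
        ga.index[(ga["rvis_percentile"] <= cfg.max_rvis_percentile)
                 & (ga["brain_nx"] >= cfg.min_brain_nx)]
    )
    return np.array(
        [
            any(g in passing for g in str(genes).split(","))
            for genes in cohort.annotations["genes"]
        ],
        dtype=bool,
    )


def apply_rare_filters(
    cohort: AnnotatedCohort, cfg: FilterConfig | None = None
) -> tuple[AnnotatedCohort, FilterReport]:
    """Conjunction of the three predicates with per-rule drop counts
    (each count is the number of variants failing that rule, regardless
    of the other rules)."""
    cfg = cfg or FilterConfig()
    m_cons = consequence_mask(cohort, cfg)
    m_freq = frequency_mask(cohort, cfg)
    m_gene = gene_constraint_mask(cohort, cfg)
    keep = m_cons & m_freq & m_gene
    report = FilterReport(
        n_in=cohort.table.n_sites,
        n_out=int(keep.sum()),
        n_fail_consequence=int((~m_cons).sum()),
        n_fail_frequency=int((~m_freq).sum()),
        n_fail_gene_constraints=int((~m_gene).sum()),
    )
    out = cohort.subset_sites(keep)
    # attribute multi-gene variants to their constraint-passing genes only
    ga = cohort.gene_annotations
    passing = set(
        ga.index[(ga["rvis_percentile"] <= cfg.max_rvis_percentile)
                 & (ga["brain_nx"] >= cfg.min_brain_nx)]
    )
    out.annotations = out.annotations.copy()
    out.annotations["candidate_genes"] = [
        ",".join([g for g in str(gs).split(",") if g in passing]) or str(gs)
        for gs in out.annotations["genes"]
    ]
    return out, report
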