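"""Genotype- and site-level quality control.

Three layers, applied in one pass over an annotated cohort:

* per-call thresholds — read depth, genotype quality, and alternative
  allele ratio (alt-supporting reads / total AD reads) for non-reference
  calls; failing calls are demoted to missing rather than dropping the
  site, so a low-quality parental call can still veto a de novo call
  downstream;
* per-site status — the VQSR FILTER column must read PASS and the site
  must not fall in a segmental duplication;
* cohort exclusion — variants detected in >= 20 carriers of a large
  in-house exome cohort are removed as platform-specific artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import AnnotatedCohort, GT_HOMREF, GT_MISSING, VariantTable

__all__ = ["QcConfig", "alt_allele_ratio", "passes_genotype_qc", "passes_site_qc",
           "inhouse_excluded", "apply_qc", "QcReport"]


@dataclass
class QcConfig:
    min_dp: int = 10
    min_gq: int = 20
    min_aar: float = 0.25
    require_vqsr_pass: bool = True
    exclude_segdup: bool = True
    inhouse_max_detections: int = 19  # exclude at >= 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_aar <= 1.0):
            raise ValueError("min_aar must be in [0, 1]")
        if min(self.min_dp, self.min_gq, self.inhouse_max_detections) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class QcReport:
    n_sites_in: int = 0
    n_sites_out: int = 0
    n_site_fail_filter: int = 0
    n_site_fail_segdup: int = 0
    n_site_fail_inhouse: int = 0
    n_sites_all_calls_missing: int = 0
    n_calls_demoted: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def alt_allele_ratio(ad_ref: int, ad_alt: int) -> float | None:
    """Alt-supporting reads over total AD reads; None when undefined
    (missing AD or zero denominator).  Undefined fails any threshold."""
    if ad_ref < 0 or ad_alt < 0:
        return None
    total = ad_ref + ad_alt
    if total == 0:
        return None
    return ad_alt / total


def passes_genotype_qc(gt: int, ad_ref: int, ad_alt: int, dp: int, gq: int,
                       cfg: QcConfig | None = None) -> bool:
    """Scalar form of the per-call filter (vectorised inside apply_qc).

    Hom-ref calls pass the allele-ratio check vacuously: the ratio
    criterion is defined for calls asserting an alternative allele.
    """
    cfg = cfg or QcConfig()
    if gt == GT_MISSING:
        return False
    if dp < cfg.min_dp or gq < cfg.min_gq:
        return False
    if gt == GT_HOMREF:
        return True
    aar = alt_allele_ratio(ad_ref, ad_alt)
    return aar is not None and aar >= cfg.min_aar


def passes_site_qc(filter_status: str, segdup: bool, cfg: QcConfig | None = None) -> bool:
    cfg = cfg or QcConfig()
    if cfg.require_vqsr_pass and filter_status != "pass":
        return False
    if cfg.exclude_segdup and segdup:
        return False
    return True


def inhouse_excluded(key: str, cohort_counts: dict[str, int],
                     cfg: QcConfig | None = None) -> bool:
    """True when the in-house detection count exceeds the allowed maximum;
    a variant absent from the table counts 0 and is kept."""
    cfg = cfg or QcConfig()
    return cohort_counts.get(key, 0) > cfg.inhouse_max_detections


def apply_qc(
    cohort: AnnotatedCohort,
    cohort_counts: dict[str, int],
    cfg: QcConfig | None = None,
) -> tuple[AnnotatedCohort, QcReport]:
    """Apply all QC layers; returns the surviving cohort and a rule-level
    report.  Idempotent: re-applying to its own output changes nothing."""
    cfg = cfg or QcConfig()
    t = cohort.table
    ann = cohort.annotations
    report = QcReport(n_sites_in=t.n_sites)

    # --- per-call demotion ---
    gt = t.gt.copy()
    adr, ada, dp, gq = t.ad_ref, t.ad_alt, t.dp, t.gq
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where((adr >= 0) & (ada >= 0), adr + ada, 0)
        aar = np.where(denom > 0, ada / np.maximum(denom, 1), np.nan)
    ok_depth = (dp >= cfg.min_dp) & (gq >= cfg.min_gq)
    nonref = (gt != GT_HOMREF) & (gt != GT_MISSING)
    ok_aar = ~nonref | (~np.isnan(aar) & (aar >= cfg.min_aar))
    keep_call = ok_depth & ok_aar & (gt != GT_MISSING)
    demote = (gt != GT_MISSING) & ~keep_call
    report.n_calls_demoted = int(demote.sum())
    gt[demote] = GT_MISSING

    # --- per-site masks ---
    filt_ok = (t.sites["filter_status"] == "pass").to_numpy() | (not cfg.require_vqsr_pass)
    segdup_ok = (~ann["segdup"].to_numpy()) | (not cfg.exclude_segdup)
    keys = t.keys().to_numpy()
    inhouse_ok = np.array(
        [not inhouse_excluded(k, cohort_counts, cfg) for k in keys], dtype=bool
    )
    any_call = np.any(gt != GT_MISSING, axis=1)

    report.n_site_fail_filter = int((~filt_ok).sum())
    report.n_site_fail_segdup = int((filt_ok & ~segdup_ok).sum())
    report.n_site_fail_inhouse = int((filt_ok & segdup_ok & ~inhouse_ok).sum())
    report.n_sites_all_calls_missing = int(
        (filt_ok & segdup_ok & inhouse_ok & ~any_call).sum()
    )

    keep_site = filt_ok & segdup_ok & inhouse_ok & any_call
    out_table = VariantTable(
        samples=list(t.samples),
        sites=t.sites.copy(),
        gt=gt,
        ad_ref=adr.copy(),
        ad_alt=ada.copy(),
        dp=dp.copy(),
        gq=gq.copy(),
        other_alt=t.other_alt.copy(),
    ).subset_sites(keep_site)
    out = AnnotatedCohort(
        table=out_table,
        annotations=ann.loc[keep_site].reset_index(drop=True),
        gene_annotations=cohort.gene_annotations,
        n_unannotated=cohort.n_unannotated,
    )
    report.n_sites_out = out_table.n_sites
    return out, report
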