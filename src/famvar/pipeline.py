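"""End-to-end orchestration: QC -> relatedness report -> rare-variant
filters -> segregation -> candidate sets -> enrichment.

Each stage is a plain function that writes diffable TSV/JSON outputs, so
stage-by-stage runs composed manually produce byte-identical files to a
single :func:`run_all` call.  Every report carries the configuration hash
and seed as provenance.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import enrichment as en
from . import filters as fl
from . import qc as qcmod
from . import relatedness as rel
from . import segregation as seg
from . import variants as vs
from .pedigree import Pedigree, load_pedigrees

__all__ = ["PipelineConfig", "PipelineError", "RunReport", "run_all",
           "stage_qc", "stage_kinship", "stage_filter", "stage_segregate",
           "stage_enrich"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")


@dataclass
class PipelineConfig:
    vcf: str = ""
    ped: str = ""
    sidecar: str = ""
    annotations: str = ""
    genes: str = ""
    inhouse: str = ""
    gmt: str = ""
    out_dir: str = "famvar_out"
    seed: int = 0
    qc: qcmod.QcConfig = field(default_factory=qcmod.QcConfig)
    filter: fl.FilterConfig = field(default_factory=fl.FilterConfig)
    segregation: seg.SegregationConfig = field(default_factory=seg.SegregationConfig)
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        qc_cfg = qcmod.QcConfig(**raw.pop("qc", {}))
        f_raw = raw.pop("filter", {})
        if "databases" in f_raw:
            f_raw["databases"] = tuple(f_raw["databases"])
        filter_cfg = fl.FilterConfig(**f_raw)
        seg_cfg = seg.SegregationConfig(**raw.pop("segregation", {}))
        return cls(qc=qc_cfg, filter=filter_cfg, segregation=seg_cfg, **raw)

    def echo(self) -> dict:
        d = asdict(self)
        d["filter"]["databases"] = list(d["filter"]["databases"])
        d["filter"]["protein_altering_classes"] = sorted(
            d["filter"]["protein_altering_classes"])
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (thresholds, modes, seed) —
        deliberately excludes file locations so the same analysis produces
        the same hash wherever its inputs and outputs live."""
        echo = self.echo()
        for key in ("vcf", "ped", "sidecar", "annotations", "genes",
                    "inhouse", "gmt", "out_dir"):
            echo.pop(key, None)
        return hashlib.sha256(
            json.dumps(echo, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    out_dir: str
    qc_report: dict
    filter_report: dict
    summary_all: dict
    summary_strict: dict
    n_kinship_mismatches: int
    n_unannotated: int


def _provenance(cfg: PipelineConfig) -> str:
    return f"# famvar config_hash={cfg.config_hash()} seed={cfg.seed}"


def _write_tsv(df: pd.DataFrame, path: str, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_cohort(cfg: PipelineConfig) -> vs.AnnotatedCohort:
    for name, path in (("vcf", cfg.vcf), ("annotations", cfg.annotations)):
        if not os.path.exists(path):
            raise PipelineError("site_qc", f"missing {name} file: {path!r}")
    table = vs.read_vcf(cfg.vcf)
    ann = vs.read_annotations(cfg.annotations)
    empty_genes = pd.DataFrame(columns=["rvis_percentile", "brain_nx"])
    empty_genes.index.name = "gene"
    return vs.join_annotations(table, ann, empty_genes)


def stage_qc(cohort: vs.AnnotatedCohort, cfg: PipelineConfig,
             out_dir: str) -> tuple[vs.AnnotatedCohort, qcmod.QcReport]:
    if not os.path.exists(cfg.inhouse):
        raise PipelineError("site_qc", f"missing inhouse counts file: {cfg.inhouse!r}")
    counts = vs.read_inhouse_counts(cfg.inhouse)
    passed, report = qcmod.apply_qc(cohort, counts, cfg.qc)
    d = report.as_dict()
    d["n_unannotated"] = cohort.n_unannotated
    _write_tsv(pd.DataFrame([d]), os.path.join(out_dir, "qc_report.tsv"), cfg)
    vs.write_vcf(passed.table, os.path.join(out_dir, "qc_passed.vcf"))
    return passed, report


def stage_kinship(cohort: vs.AnnotatedCohort, pedigrees: list[Pedigree],
                  cfg: PipelineConfig, out_dir: str) -> pd.DataFrame:
    results = rel.kinship_matrix(cohort.table)
    _write_tsv(rel.kinship_table(results), os.path.join(out_dir, "kinship.tsv"), cfg)
    mismatches = rel.verify_pedigrees(results, pedigrees)
    _write_tsv(mismatches[mismatches["mismatch"]] if len(mismatches) else mismatches,
               os.path.join(out_dir, "kinship_mismatches.tsv"), cfg)
    return mismatches


def stage_filter(cohort: vs.AnnotatedCohort, cfg: PipelineConfig,
                 out_dir: str) -> tuple[vs.AnnotatedCohort, fl.FilterReport]:
    if not os.path.exists(cfg.genes):
        raise PipelineError("rare_filter", f"missing gene annotation file: {cfg.genes!r}")
    cohort.gene_annotations = vs.read_gene_annotations(cfg.genes)
    filtered, report = fl.apply_rare_filters(cohort, cfg.filter)
    _write_tsv(pd.DataFrame([report.as_dict()]),
               os.path.join(out_dir, "filter_report.tsv"), cfg)
    vs.write_vcf(filtered.table, os.path.join(out_dir, "filtered.vcf"))
    filtered.annotations.to_csv(os.path.join(out_dir, "filtered_annotations.tsv"),
                                sep="\t", index=False, na_rep=".")
    return filtered, report


def stage_segregate(cohort: vs.AnnotatedCohort, pedigrees: list[Pedigree],
                    cfg: PipelineConfig, out_dir: str):
    all_set, strict_set = seg.build_candidate_sets(cohort, pedigrees, cfg.segregation)
    _write_tsv(seg.candidates_to_frame(all_set),
               os.path.join(out_dir, "candidates_all.tsv"), cfg)
    _write_tsv(seg.candidates_to_frame(strict_set),
               os.path.join(out_dir, "candidates_strict.tsv"), cfg)
    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "all": seg.summarize(all_set),
        "strict": seg.summarize(strict_set),
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return all_set, strict_set, summary


def stage_enrich(all_set, strict_set, cohort: vs.AnnotatedCohort,
                 cfg: PipelineConfig, out_dir: str) -> None:
    if not os.path.exists(cfg.gmt):
        raise PipelineError("enrichment", f"missing GMT file: {cfg.gmt!r}")
    gene_sets = en.read_gmt(cfg.gmt)
    universe = list(cohort.gene_annotations.index)
    for label, cands in (("all", all_set), ("strict", strict_set)):
        genes = set().union(*[c.genes for c in cands]) if cands else set()
        results = en.enrich(genes, gene_sets, universe, alpha=cfg.alpha)
        _write_tsv(en.results_to_frame(results),
                   os.path.join(out_dir, f"enrichment_{label}.tsv"), cfg)


def run_all(cfg: PipelineConfig) -> RunReport:
    """Run every stage and write all reports under ``cfg.out_dir``."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    for name, path in (("ped", cfg.ped),):
        if not os.path.exists(path):
            raise PipelineError("pedigree", f"missing {name} file: {path!r}")
    pedigrees = load_pedigrees(cfg.ped, cfg.sidecar if cfg.sidecar else None)

    cohort = _load_cohort(cfg)
    passed, qc_report = stage_qc(cohort, cfg, cfg.out_dir)
    mismatches = stage_kinship(passed, pedigrees, cfg, cfg.out_dir)
    filtered, f_report = stage_filter(passed, cfg, cfg.out_dir)
    all_set, strict_set, summary = stage_segregate(filtered, pedigrees, cfg, cfg.out_dir)
    stage_enrich(all_set, strict_set, filtered, cfg, cfg.out_dir)

    manifest = {
        "config": cfg.echo(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }
    with open(os.path.join(cfg.out_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    n_mm = int(mismatches["mismatch"].sum()) if len(mismatches) else 0
    return RunReport(
        out_dir=cfg.out_dir,
        qc_report=qc_report.as_dict(),
        filter_report=f_report.as_dict(),
        summary_all=summary["all"],
        summary_strict=summary["strict"],
        n_kinship_mismatches=n_mm,
        n_unannotated=cohort.n_unannotated,
    )


def config_for_bundle(bundle, out_dir: str, **kwargs) -> PipelineConfig:
    """Convenience: a PipelineConfig pointing at a simulated bundle."""
    return PipelineConfig(
        vcf=bundle.vcf_path, ped=bundle.ped_path, sidecar=bundle.sidecar_path,
        annotations=bundle.annotation_path, genes=bundle.gene_path,
        inhouse=bundle.inhouse_path, gmt=bundle.gmt_path,
        out_dir=out_dir, **kwargs,
    )
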