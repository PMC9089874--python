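"""Synthetic-cohort generator: determinism, Mendelian consistency,
Hardy-Weinberg, fixtures, genotype noise."""

import filecmp
import os

import numpy as np
import pandas as pd
import pytest

from famvar import variants as vs
from famvar.simulate import (SimConfig, SimulationConfigError,
                             add_genotype_noise, default_pedigrees,
                             mendelian_violations, simulate_cohort)


def _files(bundle):
    return [bundle.vcf_path, bundle.ped_path, bundle.sidecar_path,
            bundle.annotation_path, bundle.gene_path, bundle.inhouse_path,
            bundle.gmt_path, bundle.truth_path, bundle.manifest_path]


def test_same_seed_byte_identical(tmp_path):
    cfg = SimConfig(seed=42, n_background_sites=500)
    b1 = simulate_cohort(cfg, str(tmp_path / "a"))
    b2 = simulate_cohort(cfg, str(tmp_path / "b"))
    for f1, f2 in zip(_files(b1), _files(b2)):
        assert filecmp.cmp(f1, f2, shallow=False), (f1, f2)


def test_different_seed_differs(tmp_path):
    b1 = simulate_cohort(SimConfig(seed=1, n_background_sites=300), str(tmp_path / "a"))
    b2 = simulate_cohort(SimConfig(seed=2, n_background_sites=300), str(tmp_path / "b"))
    assert not filecmp.cmp(b1.vcf_path, b2.vcf_path, shallow=False)


def test_background_only_bundle_yields_no_candidates(tmp_path):
    from famvar import pipeline as pl
    cfg = SimConfig(seed=3, n_background_sites=400, n_shared_het=0,
                    n_de_novo=0, n_homozygous=0, n_hemizygous=0,
                    decoys_per_rule=0)
    b = simulate_cohort(cfg, str(tmp_path / "bg"))
    assert len(b.truth) == 0
    report = pl.run_all(pl.config_for_bundle(b, str(tmp_path / "out")))
    assert report.summary_all["n_variants"] == 0
    assert report.summary_strict["n_variants"] == 0


def test_impossible_planting_is_config_error(tmp_path):
    # a single sibship family offers no trio for de novo planting
    with pytest.raises(SimulationConfigError):
        simulate_cohort(SimConfig(seed=1, n_families=1, n_background_sites=10,
                                  n_shared_het=0, n_de_novo=1, n_homozygous=0,
                                  n_hemizygous=0, decoys_per_rule=0),
                        str(tmp_path / "x"))


def test_mendelian_consistency_outside_de_novo(small_bundle):
    """Clean mode: the independent trio scan flags transmission violations
    only at planted de novo sites."""
    table = vs.read_vcf(small_bundle.vcf_path)
    violations = mendelian_violations(table, default_pedigrees())
    truth = small_bundle.truth
    dn = truth[truth["seg_class"] == "de_novo"]
    dn_keys = {f"{c}:{p}" for c, p in zip(dn["chrom"], dn["pos"])}
    keys = table.sites
    for row, child in violations:
        site = f"{keys['chrom'].iloc[row]}:{keys['pos'].iloc[row]}"
        assert site in dn_keys, f"unexpected violation at {site} ({child})"
    # and every planted de novo site does violate transmission in its trio
    observed = {f"{keys['chrom'].iloc[r]}:{keys['pos'].iloc[r]}"
                for r, _ in violations}
    assert observed == dn_keys


def test_founder_hardy_weinberg(small_bundle):
    """Founder genotypes at background sites sit within 3 SE of
    Hardy-Weinberg expectation for the pooled heterozygote count."""
    table = vs.read_vcf(small_bundle.vcf_path)
    ann = pd.read_csv(small_bundle.annotation_path, sep="\t", na_values=["."],
                      dtype={"chrom": str})
    bg = ann["genes"].str.startswith("BG").to_numpy()
    maf = ann.loc[bg, "af_1000G_ALL"].to_numpy(dtype=float)
    founders = [m.individual_id for p in default_pedigrees() for m in p.members
                if m.father_id is None and m.sequenced]
    idx = [table.samples.index(s) for s in founders]
    gt = table.gt[np.ix_(bg.nonzero()[0], idx)]
    called = gt >= 0
    p_het = 2 * maf * (1 - maf)
    expected = float((p_het[:, None] * called).sum())
    var = float((p_het[:, None] * (1 - p_het[:, None]) * called).sum())
    observed = int((gt == 1).sum())
    assert abs(observed - expected) <= 3 * np.sqrt(var)


def test_truth_table_one_fate_per_variant(small_bundle):
    truth = small_bundle.truth
    keys = truth["chrom"].astype(str) + ":" + truth["pos"].astype(str)
    assert not keys.duplicated().any()
    assert set(truth.loc[truth["in_all"], "fate"]) == {"pass"}
    assert (~truth.loc[truth["fate"] != "pass", "in_all"]).all()


def test_bundle_roundtrips_through_readers(small_bundle):
    from famvar.pedigree import load_pedigrees
    table = vs.read_vcf(small_bundle.vcf_path)
    assert len(table.samples) == 39
    ann = vs.read_annotations(small_bundle.annotation_path)
    assert len(ann) == table.n_sites
    genes = vs.read_gene_annotations(small_bundle.gene_path)
    assert genes.index.is_unique
    peds = load_pedigrees(small_bundle.ped_path, small_bundle.sidecar_path)
    assert len(peds) == 14
    cohort = vs.join_annotations(table, ann, genes)
    assert cohort.n_unannotated == 0


# --- noise ----------------------------------------------------------------

def test_noise_rate_zero_is_identity(small_bundle, tmp_path):
    before = open(small_bundle.vcf_path).read()
    b = add_genotype_noise(small_bundle, 0.0, seed=9, out_dir=str(tmp_path))
    assert open(b.vcf_path).read() == before
    assert len(b.noise_ledger) == 0


def test_noise_rate_one_dp_kills_all_calls(tmp_path):
    from famvar import pipeline as pl
    cfg = SimConfig(seed=5, n_background_sites=200)
    b = simulate_cohort(cfg, str(tmp_path / "clean"))
    noisy = add_genotype_noise(b, 1.0, seed=6, kinds=("dp",),
                               out_dir=str(tmp_path / "noisy"))
    report = pl.run_all(pl.config_for_bundle(noisy, str(tmp_path / "out")))
    assert report.qc_report["n_sites_out"] == 0
    assert report.summary_all["n_variants"] == 0


def test_noise_ledger_records_every_perturbation(tmp_path):
    cfg = SimConfig(seed=8, n_background_sites=300)
    b = simulate_cohort(cfg, str(tmp_path / "clean"))
    noisy = add_genotype_noise(b, 0.01, seed=9, out_dir=str(tmp_path / "noisy"))
    clean = vs.read_vcf(b.vcf_path)
    pert = vs.read_vcf(noisy.vcf_path)
    diff = ((clean.gt != pert.gt) | (clean.dp != pert.dp)
            | (clean.gq != pert.gq) | (clean.ad_alt != pert.ad_alt))
    ledger = noisy.noise_ledger
    ledger_cells = {
        (r.chrom, int(r.pos), r.sample) for r in ledger.itertuples()
    }
    for i, j in zip(*np.nonzero(diff)):
        site = clean.sites.iloc[int(i)]
        assert (site.chrom, int(site.pos), clean.samples[int(j)]) in ledger_cells
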