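"""Rare-variant filter predicates and conjunctive-filter algebra."""

import numpy as np
import pandas as pd
import pytest

from famvar.filters import (FilterConfig, apply_rare_filters, consequence_mask,
                            frequency_mask, gene_constraint_mask,
                            is_candidate_consequence, passes_frequency,
                            passes_gene_constraints)
from famvar.variants import AnnotatedCohort, VariantTable

DB = ("1000G_ALL", "ExAC_ALL", "ExAC_EAS", "HGVD", "jMorp")


@pytest.mark.parametrize("consequence, splice, expected", [
    ("stopgain", False, True),
    ("nonsynonymous", False, True),
    ("frameshift_indel", False, True),
    ("inframe_indel", False, True),
    ("stoploss", False, True),
    ("splicing", False, True),
    ("synonymous", False, False),
    ("synonymous", True, True),   # splice-site synonymous kept
    ("other", False, False),
    ("other", True, False),
])
def test_candidate_consequences(consequence, splice, expected):
    assert is_candidate_consequence(consequence, splice) is expected


def test_frequency_all_databases_must_be_rare():
    ok = {db: 0.0005 for db in DB}
    assert passes_frequency(ok)
    bad = dict(ok, ExAC_ALL=0.02)
    assert not passes_frequency(bad)
    # published X-linked variant frequencies (max 0.00052) pass at 1%
    maob = dict(zip(DB, (0.00052, 0.0004, 0.0, 0.00042, 0.0)))
    assert passes_frequency(maob)


def test_frequency_null_means_unobserved_and_passes():
    assert passes_frequency({db: None for db in DB})
    assert passes_frequency({db: float("nan") for db in DB})


def test_frequency_missing_database_is_config_error():
    with pytest.raises(KeyError):
        passes_frequency({"1000G_ALL": 0.0})


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene", "rvis_percentile", "brain_nx"]
                        ).set_index("gene")


def test_gene_constraints_boundaries_inclusive():
    ga = _genes([("A", 25.0, 1.0), ("B", 25.01, 5.0), ("C", 10.0, 0.99)])
    assert passes_gene_constraints(["A"], ga)
    assert not passes_gene_constraints(["B"], ga)
    assert not passes_gene_constraints(["C"], ga)
    # ANY passing overlapped gene suffices
    assert passes_gene_constraints(["B", "A"], ga)
    # unknown genes fail individually
    assert not passes_gene_constraints(["ZZZ"], ga)


def _cohort(ann_rows, gene_rows):
    ann = pd.DataFrame(
        ann_rows,
        columns=["chrom", "pos", "ref", "alt", "genes", "consequence",
                 "splice_site", "segdup"] + [f"af_{d}" for d in DB],
    )
    n = len(ann)
    sites = ann[["chrom", "pos", "ref", "alt"]].copy()
    sites["filter_status"] = "pass"
    z = np.zeros((n, 1), dtype=np.int32)
    table = VariantTable(samples=["S"], sites=sites, gt=z.astype(np.int8),
                         ad_ref=z, ad_alt=z, dp=z, gq=z)
    return AnnotatedCohort(table=table, annotations=ann.reset_index(drop=True),
                           gene_annotations=_genes(gene_rows))


def _decoy_rows():
    """One planted passing variant among 50 decoys, each violating exactly
    one rule."""
    rows = [("1", 1, "A", "G", "GOOD", "nonsynonymous", False, False,
             0.0, 0.0, None, 0.001, 0.0)]
    genes = [("GOOD", 10.0, 2.0)]
    for i in range(50):
        pos = 100 + i
        kind = i % 3
        if kind == 0:    # common
            rows.append(("1", pos, "A", "G", f"CG{i}", "nonsynonymous",
                         False, False, 0.05, 0.0, 0.0, 0.0, 0.0))
            genes.append((f"CG{i}", 10.0, 2.0))
        elif kind == 1:  # non-candidate consequence
            rows.append(("1", pos, "A", "G", f"CG{i}", "synonymous",
                         False, False, 0.0, 0.0, 0.0, 0.0, 0.0))
            genes.append((f"CG{i}", 10.0, 2.0))
        else:            # tolerant or non-brain gene
            rows.append(("1", pos, "A", "G", f"CG{i}", "nonsynonymous",
                         False, False, 0.0, 0.0, 0.0, 0.0, 0.0))
            genes.append((f"CG{i}", 80.0 if i % 2 else 10.0,
                          2.0 if i % 2 else 0.1))
    return rows, genes


def test_single_survivor_among_decoys():
    rows, genes = _decoy_rows()
    cohort = _cohort(rows, genes)
    out, report = apply_rare_filters(cohort)
    assert out.table.n_sites == 1
    assert out.annotations["genes"].iloc[0] == "GOOD"
    assert report.n_in == 51 and report.n_out == 1


def test_filter_order_independence():
    """Conjunctive masks applied in any order give identical survivors."""
    import itertools
    rows, genes = _decoy_rows()
    cohort = _cohort(rows, genes)
    cfg = FilterConfig()
    masks = {
        "cons": consequence_mask(cohort, cfg),
        "freq": frequency_mask(cohort, cfg),
        "gene": gene_constraint_mask(cohort, cfg),
    }
    reference = None
    for perm in itertools.permutations(masks):
        sub = cohort
        alive = np.ones(cohort.table.n_sites, dtype=bool)
        for name in perm:
            alive &= masks[name]
        keys = set(cohort.table.keys()[alive])
        if reference is None:
            reference = keys
        assert keys == reference


def test_threshold_monotonicity_on_random_fixtures():
    rng = np.random.default_rng(23)
    for _ in range(100):
        n = 40
        rows = []
        genes = []
        for i in range(n):
            af = float(rng.choice([0.0, 0.001, 0.005, 0.02, 0.08]))
            cons = str(rng.choice(["nonsynonymous", "synonymous", "stopgain", "other"]))
            rvis = float(rng.uniform(0, 100))
            nx = float(rng.uniform(0, 3))
            rows.append(("1", i + 1, "A", "G", f"G{i}", cons, False, False,
                         af, af, af, af, af))
            genes.append((f"G{i}", rvis, nx))
        cohort = _cohort(rows, genes)
        base, _ = apply_rare_filters(cohort, FilterConfig())
        tight, _ = apply_rare_filters(
            cohort, FilterConfig(max_af=0.001, max_rvis_percentile=10,
                                 min_brain_nx=2.0))
        assert set(tight.table.keys()) <= set(base.table.keys())


def test_empty_table_stays_empty():
    cohort = _cohort([], [("G", 1.0, 2.0)])
    out, report = apply_rare_filters(cohort)
    assert out.table.n_sites == 0 and report.n_in == 0


def test_multi_gene_attribution_to_passing_genes():
    rows = [("1", 1, "A", "G", "PASSG,FAILG", "nonsynonymous", False, False,
             0.0, 0.0, 0.0, 0.0, 0.0)]
    genes = [("PASSG", 10.0, 2.0), ("FAILG", 90.0, 0.0)]
    out, _ = apply_rare_filters(_cohort(rows, genes))
    assert out.annotations["candidate_genes"].iloc[0] == "PASSG"
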