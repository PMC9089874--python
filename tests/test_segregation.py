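"""Genotype-state recoding, segregation predicates, candidate sets."""

import pytest

from famvar.pedigree import Sex, parse_ped
from famvar.segregation import (CandidateVariant, GenotypeState,
                                SegregationClass, SegregationConfig,
                                classify_variant, genotype_state, is_de_novo,
                                is_hemizygous_candidate,
                                is_recessive_homozygous, shared_among_affected,
                                summarize)
from famvar.variants import GT_HET, GT_HOMALT, GT_HOMREF, GT_MISSING

S = GenotypeState


# --- genotype_state -------------------------------------------------------

@pytest.mark.parametrize("gt, sex, chrom, pos, expected", [
    (GT_HOMALT, Sex.MALE, "X", 43_662_605, S.HEMI_ALT),
    (GT_HET, Sex.MALE, "X", 43_662_605, S.HEMI_ALT),   # diploid-coded call
    (GT_HOMREF, Sex.MALE, "X", 43_662_605, S.HOMREF),
    (GT_HET, Sex.FEMALE, "X", 43_662_605, S.HET),
    (GT_HET, Sex.MALE, "X", 1_000_000, S.HET),         # PAR1 is autosomal-like
    (GT_HET, Sex.MALE, "X", 155_000_000, S.HET),       # PAR2
    (GT_HET, Sex.UNKNOWN, "X", 43_662_605, S.MISSING),
    (GT_HET, Sex.UNKNOWN, "7", 100, S.HET),
    (GT_MISSING, Sex.MALE, "7", 100, S.MISSING),
    (GT_HOMALT, Sex.FEMALE, "12", 100, S.HOMALT),
])
def test_genotype_state(gt, sex, chrom, pos, expected):
    assert genotype_state(gt, sex, chrom, pos) is expected


# --- family scaffolds -----------------------------------------------------

QUARTET = parse_ped("""\
F4 FA 0 0 1 1
F4 MO 0 0 2 1
F4 C1 FA MO 1 2
F4 C2 FA MO 2 2
""")[0]

SIBS_WITH_CONTROL = parse_ped("""\
F1 FA 0 0 1 0
F1 MO 0 0 2 1
F1 C1 FA MO 1 2
F1 C2 FA MO 2 2
""")[0]

X_FAMILY = parse_ped("""\
F13 FA 0 0 1 1
F13 MO 0 0 2 2
F13 S1 FA MO 1 2
F13 S2 FA MO 1 2
""")[0]


# --- shared ---------------------------------------------------------------

def test_shared_requires_two_carriers_and_all_affected():
    states = {"C1": S.HET, "C2": S.HET, "MO": S.HOMREF}
    assert shared_among_affected(states, SIBS_WITH_CONTROL)
    assert not shared_among_affected({"C1": S.HET, "C2": S.HOMREF,
                                      "MO": S.HOMREF}, SIBS_WITH_CONTROL)


def test_shared_strict_rejects_control_carrier():
    states = {"C1": S.HET, "C2": S.HET, "MO": S.HET}
    assert shared_among_affected(states, SIBS_WITH_CONTROL, strict=False)
    assert not shared_among_affected(states, SIBS_WITH_CONTROL, strict=True)


def test_shared_missing_affected_call_tolerated():
    """An affected member with a QC-demoted call neither confirms nor
    blocks sharing; the remaining carriers must still number >= 2."""
    states = {"C1": S.HET, "C2": S.MISSING, "MO": S.HOMREF}
    assert not shared_among_affected(states, SIBS_WITH_CONTROL)
    trio_plus = parse_ped("""\
FZ FA 0 0 1 0
FZ MO 0 0 2 1
FZ C1 FA MO 1 2
FZ C2 FA MO 2 2
FZ C3 FA MO 1 2
""")[0]
    states = {"C1": S.HET, "C2": S.HET, "C3": S.MISSING, "MO": S.HOMREF}
    assert shared_among_affected(states, trio_plus)


def test_shared_min2_mode_relaxes_all_affected_rule():
    cfg = SegregationConfig(require_all_affected=False, min_carriers=2)
    trio_plus = parse_ped("""\
FZ C1 0 0 1 2
FZ C2 0 0 2 2
FZ C3 0 0 1 2
""")[0]
    states = {"C1": S.HET, "C2": S.HET, "C3": S.HOMREF}
    assert not shared_among_affected(states, trio_plus)
    assert shared_among_affected(states, trio_plus, cfg=cfg)


# --- de novo --------------------------------------------------------------

def test_de_novo_trio():
    states = {"C1": S.HET, "C2": S.HOMREF, "FA": S.HOMREF, "MO": S.HOMREF}
    assert is_de_novo(states, QUARTET)


def test_de_novo_vetoed_by_missing_parent_call():
    states = {"C1": S.HET, "C2": S.HOMREF, "FA": S.MISSING, "MO": S.HOMREF}
    assert not is_de_novo(states, QUARTET)


def test_de_novo_requires_unaffected_parents():
    affected_parent = parse_ped("""\
FY FA 0 0 1 2
FY MO 0 0 2 1
FY C1 FA MO 1 2
""")[0]
    states = {"C1": S.HET, "FA": S.HOMREF, "MO": S.HOMREF}
    assert not is_de_novo(states, affected_parent)


def test_de_novo_requires_sequenced_parents():
    assert not is_de_novo({"C1": S.HET, "C2": S.HOMREF, "MO": S.HOMREF,
                           "FA": S.HOMREF}, SIBS_WITH_CONTROL)


# --- homozygous -----------------------------------------------------------

def test_homozygous_sibs_with_het_parents():
    states = {"C1": S.HOMALT, "C2": S.HOMALT, "FA": S.HET, "MO": S.HET}
    assert is_recessive_homozygous(states, QUARTET)


def test_homozygous_rejects_het_sib_or_homalt_control():
    assert not is_recessive_homozygous(
        {"C1": S.HOMALT, "C2": S.HET, "FA": S.HET, "MO": S.HET}, QUARTET)
    assert not is_recessive_homozygous(
        {"C1": S.HOMALT, "C2": S.HOMALT, "FA": S.HET, "MO": S.HOMALT}, QUARTET)


# --- hemizygous -----------------------------------------------------------

X = ("X", 43_662_605)


def test_hemizygous_brothers_with_carrier_mother():
    states = {"S1": S.HEMI_ALT, "S2": S.HEMI_ALT, "MO": S.HET, "FA": S.HOMREF}
    assert is_hemizygous_candidate(states, X_FAMILY, *X)


def test_hemizygous_rejects_noncarrier_brother_or_carrier_father():
    assert not is_hemizygous_candidate(
        {"S1": S.HEMI_ALT, "S2": S.HOMREF, "MO": S.HET, "FA": S.HOMREF},
        X_FAMILY, *X)
    assert not is_hemizygous_candidate(
        {"S1": S.HEMI_ALT, "S2": S.HEMI_ALT, "MO": S.HET, "FA": S.HEMI_ALT},
        X_FAMILY, *X)


def test_hemizygous_requires_nonpar_x():
    states = {"S1": S.HEMI_ALT, "S2": S.HEMI_ALT, "MO": S.HET, "FA": S.HOMREF}
    assert not is_hemizygous_candidate(states, X_FAMILY, "7", 100)
    assert not is_hemizygous_candidate(states, X_FAMILY, "X", 1_000_000)


# --- classify precedence --------------------------------------------------

def test_classify_shared_autosomal():
    states = {"C1": S.HET, "C2": S.HET, "FA": S.HET, "MO": S.HOMREF}
    assert classify_variant(states, QUARTET, "5", 100) is SegregationClass.SHARED_HET


def test_classify_x_prefers_hemizygous_over_shared():
    states = {"S1": S.HEMI_ALT, "S2": S.HEMI_ALT, "MO": S.HET, "FA": S.HOMREF}
    assert classify_variant(states, X_FAMILY, *X) is SegregationClass.HEMIZYGOUS_X


def test_classify_de_novo_beats_everything():
    states = {"C1": S.HOMALT, "C2": S.HOMALT, "FA": S.HOMREF, "MO": S.HOMREF}
    assert classify_variant(states, QUARTET, "5", 100) is SegregationClass.DE_NOVO


def test_classify_control_only_carrier_is_null():
    states = {"C1": S.HOMREF, "C2": S.HOMREF, "FA": S.HET, "MO": S.HOMREF}
    assert classify_variant(states, QUARTET, "5", 100) is None


def test_classify_single_class_per_variant_family():
    """Exactly zero or one class fires for arbitrary state patterns."""
    import itertools
    vals = [S.HOMREF, S.HET, S.HOMALT, S.MISSING]
    for pattern in itertools.product(vals, repeat=4):
        states = dict(zip(["FA", "MO", "C1", "C2"], pattern))
        out = classify_variant(states, QUARTET, "5", 100)
        assert out is None or isinstance(out, SegregationClass)


# --- summarize ------------------------------------------------------------

def _cand(chrom, pos, fam, gene, cls=SegregationClass.SHARED_HET):
    return CandidateVariant(chrom=chrom, pos=pos, ref="A", alt="G",
                            family_id=fam, seg_class=cls,
                            carriers=frozenset(), genes=frozenset({gene}))


def test_summarize_union_semantics():
    assert summarize([]) == {"n_variants": 0, "n_genes": 0, "per_class": {},
                             "per_family": {}, "n_candidate_entries": 0}
    cands = [_cand("1", 100, "F01", "A"), _cand("1", 100, "F02", "A"),
             _cand("2", 200, "F01", "B"), _cand("3", 300, "F03", "B")]
    s = summarize(cands)
    assert s["n_variants"] == 3      # same variant in 2 families counts once
    assert s["n_genes"] == 2
    assert s["per_family"] == {"F01": 2, "F02": 1, "F03": 1}


def test_loss_of_function_table_counts():
    """The published loss-of-function candidate list: 15 variants in 15
    distinct genes."""
    from famvar.fixtures import table1_candidates
    s = summarize(table1_candidates())
    assert s["n_variants"] == 15
    assert s["n_genes"] == 15
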