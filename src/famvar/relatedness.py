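"""Pairwise relatedness with the KING-robust kinship estimator.

For a sample pair (i, j) over co-called autosomal biallelic sites::

    phi = (N_het_het - 2 * N_opposite_hom) / (N_het_i + N_het_j)

where ``N_het_het`` counts sites where both are heterozygous,
``N_opposite_hom`` counts opposite homozygotes (AA vs aa), and the
denominator sums each sample's heterozygote counts over the shared sites.
The estimator is robust to population structure because it conditions on
within-pair heterozygosity rather than on cohort allele frequencies.

Expected values: ~0.5 duplicates/MZ twins, ~0.25 first-degree pairs
(parent-offspring, full siblings), ~0.125 second degree, ~0 unrelated.
Degrees are assigned by the standard KING cutpoints (powers of 2^-3/2):
0.354, 0.177, 0.0884, 0.0442.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import pedigree as ped
from .variants import GT_HET, GT_HOMALT, GT_HOMREF, VariantTable

__all__ = ["KinshipResult", "king_kinship", "kinship_matrix", "verify_pedigrees",
           "phi_to_degree", "AUTOSOMES"]

AUTOSOMES = {str(c) for c in range(1, 23)} | {f"chr{c}" for c in range(1, 23)}

# degree cutpoints, KING convention
_CUTS = [(0.354, "duplicate_or_MZ"), (0.177, "first"), (0.0884, "second"),
         (0.0442, "third")]


def phi_to_degree(phi: float | None) -> str:
    if phi is None or np.isnan(phi):
        return "unrelated"
    for cut, name in _CUTS:
        if phi > cut:
            return name
    return "unrelated"


@dataclass(frozen=True)
class KinshipResult:
    sample_i: str
    sample_j: str
    phi: float | None          # None when the denominator is zero
    n_sites: int
    degree: str


def king_kinship(geno_i: np.ndarray, geno_j: np.ndarray,
                 sample_i: str = "i", sample_j: str = "j") -> KinshipResult:
    """KING-robust phi from two aligned genotype vectors (codes 0/1/2,
    -1 missing).  Sites missing in either sample are skipped; a zero
    denominator (no heterozygotes in either sample) yields phi=None with
    degree 'unrelated'."""
    geno_i = np.asarray(geno_i)
    geno_j = np.asarray(geno_j)
    if geno_i.shape != geno_j.shape:
        raise ValueError("genotype vectors must be aligned on the same sites")
    shared = (geno_i >= 0) & (geno_j >= 0)
    gi, gj = geno_i[shared], geno_j[shared]
    n_sites = int(shared.sum())
    het_het = int(np.sum((gi == GT_HET) & (gj == GT_HET)))
    opp_hom = int(np.sum(((gi == GT_HOMREF) & (gj == GT_HOMALT))
                         | ((gi == GT_HOMALT) & (gj == GT_HOMREF))))
    het_i = int(np.sum(gi == GT_HET))
    het_j = int(np.sum(gj == GT_HET))
    denom = het_i + het_j
    if denom == 0:
        return KinshipResult(sample_i, sample_j, None, n_sites, "unrelated")
    phi = (het_het - 2.0 * opp_hom) / denom
    return KinshipResult(sample_i, sample_j, phi, n_sites, phi_to_degree(phi))


def kinship_matrix(table: VariantTable, samples: list[str] | None = None) -> list[KinshipResult]:
    """All-pairs (upper triangle) kinship over autosomal sites of a
    QC-passed table.  X-chromosome sites are excluded."""
    samples = samples if samples is not None else list(table.samples)
    auto = table.sites["chrom"].isin(AUTOSOMES).to_numpy()
    gt = table.gt[auto]
    idx = {s: table.samples.index(s) for s in samples}
    results = []
    for a, b in combinations(samples, 2):
        results.append(king_kinship(gt[:, idx[a]], gt[:, idx[b]], a, b))
    return results


def kinship_table(results: list[KinshipResult]) -> pd.DataFrame:
    """Tabular view mirroring vcftools --relatedness2 column naming."""
    return pd.DataFrame(
        [
            {
                "INDV1": r.sample_i,
                "INDV2": r.sample_j,
                "N_SITES": r.n_sites,
                "RELATEDNESS_PHI": np.nan if r.phi is None else r.phi,
                "DEGREE": r.degree,
            }
            for r in results
        ]
    )


def verify_pedigrees(results: list[KinshipResult],
                     pedigrees: list[ped.Pedigree]) -> pd.DataFrame:
    """Compare genotype-estimated degrees against pedigree-expected ones.

    Within-family pairs get their expected degree from the pedigree
    kinship coefficient; cross-family pairs are expected unrelated.
    Returns a DataFrame of all compared pairs with a ``mismatch`` flag;
    an undefined phi counts as a mismatch whenever relatedness was
    expected.  The report is informational and does not gate the pipeline.
    """
    fam_of: dict[str, ped.Pedigree] = {}
    for p in pedigrees:
        for m in p.members:
            fam_of[m.individual_id] = p
    rows = []
    for r in results:
        pi, pj = fam_of.get(r.sample_i), fam_of.get(r.sample_j)
        if pi is None or pj is None:
            continue
        if pi.family_id == pj.family_id:
            expected = ped.expected_degree(pi, r.sample_i, r.sample_j)
        else:
            expected = "unrelated"
        if r.phi is None:
            mismatch = expected != "unrelated"
        else:
            mismatch = r.degree != expected
        rows.append(
            {
                "sample_i": r.sample_i,
                "sample_j": r.sample_j,
                "family_i": pi.family_id,
                "family_j": pj.family_id,
                "phi": np.nan if r.phi is None else r.phi,
                "observed_degree": r.degree,
                "expected_degree": expected,
                "mismatch": mismatch,
            }
        )
    return pd.DataFrame(rows)
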