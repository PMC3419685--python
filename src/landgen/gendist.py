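"""Individual-pairwise genetic distance (Rousset's a-hat) and similarity
(Moran's I).

Rousset's a-hat contrasts allelic identity within individuals against
identity between the members of a pair, combined over loci as a ratio of
sums (the SPAGeDi convention, consistent with how multilocus theta is
combined): a = sum_l (Qw - Qb) / sum_l (1 - Qw), where Qw is the mean of the
two within-individual identities (1 for a homozygote, 0 for a heterozygote)
and Qb the mean identity over the four between-individual allele pairings.
Monomorphic-in-pair loci contribute 0/0 and drop out; a pair homozygous for
the same allele everywhere has denominator 0 and is masked.

Moran's I treats each individual's per-allele frequencies (0, 0.5, 1) as
variables, centres them on whole-sample allele frequencies, and scales the
cross-product of a pair by the mean centred sum of squares over individuals
— the autocorrelation scaling of genetic spatial autocorrelation practice.
Under isolation by distance a-hat increases, and I decreases, with
geographic distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from landgen.genotypes import MISSING, GenotypeTable
from landgen.matrices import PairwiseMatrix


@dataclass
class IndividualDistanceMatrix:
    """A pairwise genetic matrix plus the per-pair count of usable loci."""

    matrix: PairwiseMatrix
    loci_used: np.ndarray  # (n, n) int


def rousset_a_matrix(table: GenotypeTable) -> IndividualDistanceMatrix:
    """All-pairs Rousset's a-hat over mutually non-missing loci."""
    if table.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    n = table.n_individuals
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    for j in range(table.n_loci):
        a = table.alleles[:, j, :]
        nonmiss = ~(a == MISSING).all(axis=1)
        hom = (a[:, 0] == a[:, 1]).astype(float)
        qw = 0.5 * (hom[:, None] + hom[None, :])
        qb = np.zeros((n, n))
        for c in range(2):
            for d in range(2):
                qb += (a[:, c][:, None] == a[:, d][None, :]).astype(float)
        qb /= 4.0
        usable = nonmiss[:, None] & nonmiss[None, :]
        num += np.where(usable, qw - qb, 0.0)
        den += np.where(usable, 1.0 - qw, 0.0)
        used += usable.astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = num / den
    bad = (den == 0.0) | (used == 0)
    np.fill_diagonal(bad, False)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum() // 2)} pair(s) with zero denominator masked "
            "(both individuals homozygous at every shared locus)"
        )
    values[bad] = np.nan
    np.fill_diagonal(values, 0.0)
    mask = ~bad & ~np.eye(n, dtype=bool)
    mat = PairwiseMatrix(
        ids=list(table.ids), values=values, kind="rousset_a", mask=mask
    )
    return IndividualDistanceMatrix(matrix=mat, loci_used=used)


def morans_i_matrix(
    table: GenotypeTable, reference: str = "whole_sample"
) -> IndividualDistanceMatrix:
    """All-pairs Moran's I genetic similarity relative to the whole sample."""
    if reference != "whole_sample":
        raise ValueError("only the whole_sample reference is implemented")
    n = table.n_individuals
    if n < 3:
        raise ValueError("need at least 3 individuals")
    dev_cols = []
    present = np.zeros((n, table.n_loci), dtype=bool)
    for j in range(table.n_loci):
        a = table.alleles[:, j, :]
        nonmiss = ~(a == MISSING).all(axis=1)
        present[:, j] = nonmiss
        sizes = np.unique(a[nonmiss])
        sizes = sizes[sizes != MISSING]
        if len(sizes) < 2:
            continue
        # individual frequency of each allele: 0, 0.5 or 1
        freqs = (a[:, :, None] == sizes[None, None, :]).sum(axis=1) / 2.0
        pbar = freqs[nonmiss].mean(axis=0)
        dev = np.where(nonmiss[:, None], freqs - pbar[None, :], 0.0)
        dev_cols.append(dev)
    if not dev_cols:
        raise ValueError("no polymorphic locus: Moran's I undefined")
    D = np.hstack(dev_cols)
    denom = float((D**2).sum(axis=1).mean())
    values = (D @ D.T) / denom
    all_missing = ~present.any(axis=1)
    mask = ~np.eye(n, dtype=bool)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} individual(s) missing at all loci masked"
        )
        mask &= ~all_missing[:, None] & ~all_missing[None, :]
    used = (present[:, None, :] & present[None, :, :]).sum(axis=2)
    mat = PairwiseMatrix(
        ids=list(table.ids), values=values, kind="morans_i", mask=mask
    )
    return IndividualDistanceMatrix(matrix=mat, loci_used=used)
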