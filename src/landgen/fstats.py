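"""Weir-Cockerham F-statistics with genotype-permutation significance.

Theta is the Weir & Cockerham (1984) moment estimator of F_ST, combined over
alleles and loci as a ratio of summed variance components (sum a over
sum a+b+c), the convention FSTAT popularised.  Significance of pairwise theta
comes from permuting whole diploid genotypes between the two units — a
randomisation scheme that does not assume Hardy-Weinberg proportions within
units.  Negative estimates are reported as computed, never truncated, since
truncation would bias the partition summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from landgen.genotypes import MISSING, GenotypeTable
from landgen.matrices import PairwiseMatrix


@dataclass
class FstResult:
    pair: tuple[str, str]
    theta: float
    p: float
    n_perm: int
    significant_after_bonferroni: bool


@dataclass
class PartitionSummary:
    """Mean/min/max of pairwise values over all, same- and different-population
    pairs."""

    overall: tuple[float, float, float]
    same: tuple[float, float, float]
    different: tuple[float, float, float] | None


# ---------------------------------------------------------------------------
# variance components


def _locus_components(alleles: np.ndarray, labels: np.ndarray):
    """Weir-Cockerham per-allele variance components (a, b, c) at one locus.

    ``alleles``: (n, 2) calls; ``labels``: group label per individual.
    Individuals missing at the locus are dropped (per-locus complete cases);
    groups left empty are dropped.  Returns (sum_a, sum_abc) over alleles,
    or (0, 0) when the locus is uninformative.
    """
    nonmiss = ~(alleles == MISSING).all(axis=1)
    a = alleles[nonmiss]
    lab = labels[nonmiss]
    groups = [g for g in dict.fromkeys(lab) if (lab == g).sum() >= 1]
    if len(groups) < 2:
        return 0.0, 0.0
    sizes = np.unique(a)
    if len(sizes) < 2:
        return 0.0, 0.0
    r = len(groups)
    n_i = np.array([(lab == g).sum() for g in groups], dtype=float)
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0
    sum_a = sum_abc = 0.0
    for allele in sizes:
        p_i = np.array(
            [(a[lab == g] == allele).sum() / (2.0 * (lab == g).sum()) for g in groups]
        )
        h_i = np.array(
            [
                ((a[lab == g] == allele).sum(axis=1) == 1).mean()
                for g in groups
            ]
        )
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        comp_a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
        comp_b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        comp_c = hbar / 2.0
        sum_a += comp_a
        sum_abc += comp_a + comp_b + comp_c
    return sum_a, sum_abc


def wc_theta(
    table: GenotypeTable,
    grouping: np.ndarray | None = None,
    loci: list[str] | None = None,
) -> float:
    """Multilocus Weir-Cockerham theta over the table's groups.

    ``grouping`` overrides the table's group labels; ``loci`` restricts to a
    locus subset.  Raises when every locus is monomorphic (theta undefined).
    """
    labels = table.groups if grouping is None else np.asarray(grouping, dtype=object)
    idx = (
        range(table.n_loci)
        if loci is None
        else [table.loci.index(l) for l in loci]
    )
    num = den = 0.0
    for j in idx:
        sa, sabc = _locus_components(table.alleles[:, j, :], labels)
        num += sa
        den += sabc
    if den == 0.0:
        raise ValueError("theta undefined: no polymorphic locus with >=2 groups")
    return float(num / den)


# ---------------------------------------------------------------------------
# vectorised two-unit theta across genotype permutations


def _pair_theta_permutations(
    table: GenotypeTable, in_first: np.ndarray
) -> np.ndarray:
    """Theta for each row of ``in_first`` (n_splits, n) boolean membership of
    unit 1; unit 2 is the complement.  Fully vectorised over splits."""
    n_splits = in_first.shape[0]
    num = np.zeros(n_splits)
    den = np.zeros(n_splits)
    B1 = in_first.astype(float)
    B2 = 1.0 - B1
    r = 2.0
    for j in range(table.n_loci):
        a = table.alleles[:, j, :]
        nonmiss = ~(a == MISSING).all(axis=1)
        sizes = np.unique(a[nonmiss])
        sizes = sizes[sizes != MISSING]
        if len(sizes) < 2:
            continue
        # per-individual allele-copy counts and het indicators per allele
        C = (a[:, :, None] == sizes[None, None, :]).sum(axis=1).astype(float)
        C[~nonmiss] = 0.0
        H = (C == 1).astype(float)
        H[~nonmiss] = 0.0
        m = nonmiss.astype(float)
        n1 = B1 @ m  # (n_splits,)
        n2 = B2 @ m
        ok = (n1 >= 1) & (n2 >= 1) & (n1 + n2 > 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            nbar = (n1 + n2) / r
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            p1 = (B1 @ C) / (2 * n1)[:, None]  # (n_splits, k)
            p2 = (B2 @ C) / (2 * n2)[:, None]
            h1 = (B1 @ H) / n1[:, None]
            h2 = (B2 @ H) / n2[:, None]
            pbar = (n1[:, None] * p1 + n2[:, None] * p2) / (r * nbar)[:, None]
            s2 = (
                n1[:, None] * (p1 - pbar) ** 2 + n2[:, None] * (p2 - pbar) ** 2
            ) / ((r - 1) * nbar)[:, None]
            hbar = (n1[:, None] * h1 + n2[:, None] * h2) / (r * nbar)[:, None]
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            comp_a = (nbar / nc)[:, None] * (
                s2 - (inner - hbar / 4.0) / (nbar - 1)[:, None]
            )
            comp_b = (nbar / (nbar - 1))[:, None] * (
                inner - ((2 * nbar - 1) / (4 * nbar))[:, None] * hbar
            )
            comp_c = hbar / 2.0
        valid = ok & (nbar > 1) & (nc > 0)
        contrib_a = np.where(valid[:, None], comp_a, 0.0)
        contrib_abc = np.where(valid[:, None], comp_a + comp_b + comp_c, 0.0)
        num += np.nan_to_num(contrib_a).sum(axis=1)
        den += np.nan_to_num(contrib_abc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = num / den
    return theta


def pairwise_fst(
    table: GenotypeTable,
    level: str = "group",
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[FstResult]:
    """Pairwise theta among groups or populations with permutation p-values.

    The permutation unit is the whole diploid genotype (individuals are
    reassigned between the two units), so no Hardy-Weinberg assumption is
    made.  ``significant_after_bonferroni`` compares p with alpha divided by
    the number of pairs.
    """
    if level == "group":
        labels = table.groups
    elif level == "population":
        if table.populations is None:
            raise ValueError("table has no population labels")
        labels = table.populations
    else:
        raise ValueError("level must be 'group' or 'population'")
    units = list(dict.fromkeys(labels))
    usable = []
    for u in units:
        if (labels == u).sum() < 2:
            warnings.warn(f"unit {u!r} has <2 individuals: its pairs are skipped")
        else:
            usable.append(u)
    pairs = list(combinations(usable, 2))
    threshold = alpha / len(pairs) if pairs else alpha
    rng = np.random.default_rng(seed)
    results = []
    for u1, u2 in pairs:
        sel = (labels == u1) | (labels == u2)
        sub = table.subset(sel)
        sub_labels = labels[sel]
        n = len(sub_labels)
        n1 = int((sub_labels == u1).sum())
        obs_mask = (sub_labels == u1)[None, :]
        perm_masks = np.zeros((n_perm, n), dtype=bool)
        for t in range(n_perm):
            perm_masks[t, rng.permutation(n)[:n1]] = True
        theta = _pair_theta_permutations(sub, np.vstack([obs_mask, perm_masks]))
        obs = theta[0]
        null = theta[1:]
        null = null[np.isfinite(null)]
        p = float((1 + np.sum(null >= obs - 1e-12)) / (len(null) + 1))
        results.append(
            FstResult(
                pair=(u1, u2),
                theta=float(obs),
                p=p,
                n_perm=n_perm,
                significant_after_bonferroni=p < threshold,
            )
        )
    return results


def bonferroni_threshold(n_units: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / C(n_units, 2)."""
    n_pairs = n_units * (n_units - 1) // 2
    return alpha / n_pairs


# ---------------------------------------------------------------------------
# partition summaries


def _mmm(values: np.ndarray, digits: int | None):
    if len(values) == 0:
        return None
    out = (float(np.mean(values)), float(np.min(values)), float(np.max(values)))
    if digits is not None:
        out = tuple(round(v, digits) for v in out)
    return out


def fst_partition_summary(
    matrix: PairwiseMatrix,
    partition: dict[str, str],
    digits: int | None = None,
) -> PartitionSummary:
    """Mean/min/max of pairwise values over all pairs, same-population pairs
    and different-population pairs of a unit-level matrix."""
    missing = [u for u in matrix.ids if u not in partition]
    if missing:
        raise ValueError(f"partition lacks labels for units {missing}")
    iu = np.triu_indices(matrix.n, k=1)
    vals = matrix.values[iu]
    pops = np.array([partition[u] for u in matrix.ids], dtype=object)
    same = pops[iu[0]] == pops[iu[1]]
    return PartitionSummary(
        overall=_mmm(vals, digits),
        same=_mmm(vals[same], digits),
        different=_mmm(vals[~same], digits),
    )
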