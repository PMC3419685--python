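"""Genotype quality control for noninvasive (fecal) microsatellite data.

Fecal DNA is dilute and prone to allelic dropout, so genotypes are built from
repeated independent PCR amplifications: a heterozygote is accepted only when
the same two-allele call is seen in at least four replicates, a homozygote
only when the same single-allele call is seen in at least seven, and any
simultaneous support for conflicting calls yields a missing genotype rather
than a guess.  Samples are admitted on template quantity (mean DNA
concentration over two quantification runs > 0.5 ng/ul).  Per-locus screens
cover Hardy-Weinberg equilibrium (allele-shuffling permutation test) and null
alleles (Brookfield-1 heterozygote-deficit estimator with a bootstrap flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from landgen.genotypes import MISSING, GenotypeTable

HET_MIN_REPLICATES = 4
HOM_MIN_REPLICATES = 7
CONCENTRATION_THRESHOLD = 0.5  # ng/ul, strict: mean must exceed this


# ---------------------------------------------------------------------------
# per-locus summary statistics


@dataclass
class LocusStats:
    """Observed/expected heterozygosity, allele count and gene count."""

    locus: str
    group: str | None
    ho: float
    he: float
    k: int
    n_genes: int


def allele_frequencies(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(allele sizes, frequencies) over non-missing calls.

    ``alleles`` is an (m, 2) slice of a genotype table at one locus.
    """
    flat = alleles.reshape(-1)
    flat = flat[flat != MISSING]
    sizes, counts = np.unique(flat, return_counts=True)
    return sizes, counts / counts.sum()


def observed_heterozygosity(alleles: np.ndarray) -> float:
    nonmiss = ~(alleles == MISSING).all(axis=1)
    a = alleles[nonmiss]
    if len(a) == 0:
        return float("nan")
    return float((a[:, 0] != a[:, 1]).mean())


def expected_heterozygosity(alleles: np.ndarray) -> float:
    """Unbiased gene diversity: (g / (g - 1)) * (1 - sum p_i^2), g = genes."""
    _, freqs = allele_frequencies(alleles)
    g = 2 * int((~(alleles == MISSING).all(axis=1)).sum())
    if g <= 1:
        return float("nan")
    return float(g / (g - 1) * (1.0 - np.sum(freqs**2)))


def locus_stats(table: GenotypeTable, group: str | None = None) -> list[LocusStats]:
    """Per-locus Ho, unbiased He, allele count and gene count for one group
    (or the whole table when ``group`` is None)."""
    sub = table if group is None else table.group_subset(group)
    out = []
    for j, locus in enumerate(sub.loci):
        a = sub.alleles[:, j, :]
        nonmiss = ~(a == MISSING).all(axis=1)
        sizes, _ = allele_frequencies(a)
        out.append(
            LocusStats(
                locus=locus,
                group=group,
                ho=observed_heterozygosity(a),
                he=expected_heterozygosity(a) if len(sizes) else float("nan"),
                k=len(sizes),
                n_genes=2 * int(nonmiss.sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# replicate consensus


def consensus_genotype(replicate_calls) -> tuple[int, int] | None:
    """Collapse replicate diploid calls into a consensus call or missing.

    A heterozygous call is *supported* when >= 4 replicates contain both of
    its alleles; a homozygous call when >= 7 replicates show exactly that
    call.  Consensus is the single supported call; any conflict (supported
    het together with supported hom, or two distinct supported hets) and any
    lack of support yield missing (None).
    """
    if not replicate_calls:
        raise ValueError("at least one replicate is required")
    calls = []
    for call in replicate_calls:
        if call is None:
            continue
        a, b = call
        if a == MISSING and b == MISSING:
            continue
        calls.append((min(a, b), max(a, b)))
    if not calls:
        return None
    het_support = {}
    hom_support = {}
    for cand in set(calls):
        a, b = cand
        if a != b:
            # replicates in which both alleles of the candidate appear
            n = sum(1 for c in calls if a in c and b in c)
            if n >= HET_MIN_REPLICATES:
                het_support[cand] = n
        else:
            n = sum(1 for c in calls if c == cand)
            if n >= HOM_MIN_REPLICATES:
                hom_support[cand] = n
    if het_support and hom_support:
        return None  # conflicting evidence: never guess
    if len(het_support) == 1:
        return next(iter(het_support))
    if het_support:
        return None  # two incompatible supported heterozygotes
    if len(hom_support) == 1:
        return next(iter(hom_support))
    return None


def consensus_table(
    replicate_tables: list[GenotypeTable],
) -> GenotypeTable:
    """Apply :func:`consensus_genotype` cell-wise across replicate tables."""
    first = replicate_tables[0]
    n, L = first.n_individuals, first.n_loci
    alleles = np.zeros((n, L, 2), dtype=np.int64)
    for i in range(n):
        for j in range(L):
            calls = [tuple(t.alleles[i, j, :]) for t in replicate_tables]
            cons = consensus_genotype(calls)
            if cons is not None:
                alleles[i, j, :] = cons
    return GenotypeTable(
        ids=first.ids,
        groups=first.groups,
        coords=first.coords,
        loci=list(first.loci),
        alleles=alleles,
        populations=first.populations,
    )


# ---------------------------------------------------------------------------
# sample admission


def qc_filter_samples(concentrations: dict[str, tuple[float, float]]) -> set[str]:
    """Keep samples whose mean DNA concentration over two runs exceeds
    0.5 ng/ul (strictly)."""
    kept = set()
    for sample, pair in concentrations.items():
        c1, c2 = pair
        if c1 < 0 or c2 < 0:
            raise ValueError(f"negative concentration for sample {sample!r}")
        if (c1 + c2) / 2.0 > CONCENTRATION_THRESHOLD:
            kept.add(sample)
    return kept


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium


def hwe_test(
    table: GenotypeTable,
    group: str,
    locus: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation test of HWE within one group at one locus.

    Statistic is |Ho - He|; the null is generated by shuffling the 2n
    observed alleles into random diploid pairs.  He depends only on allele
    frequencies and is invariant under the shuffle, so the null distribution
    is driven by Ho.  p carries the +1 correction and is never exactly 0.
    """
    sub = table.group_subset(group)
    j = sub.loci.index(locus)
    a = sub.alleles[:, j, :]
    a = a[~(a == MISSING).all(axis=1)]
    if len(a) < 5:
        raise ValueError(f"fewer than 5 non-missing individuals at {locus} in {group}")
    sizes, _ = allele_frequencies(a)
    if len(sizes) < 2:
        warnings.warn(f"monomorphic locus {locus} in group {group}: HWE p = 1")
        return 1.0
    he = expected_heterozygosity(a)
    obs = abs(observed_heterozygosity(a) - he)
    pool = a.reshape(-1)
    rng = np.random.default_rng(seed)
    # vectorised: permute the gene pool n_perm times, pair consecutive genes
    perms = np.array([rng.permutation(pool) for _ in range(n_perm)])
    pairs = perms.reshape(n_perm, -1, 2)
    ho_null = (pairs[:, :, 0] != pairs[:, :, 1]).mean(axis=1)
    null = np.abs(ho_null - he)
    return float((1 + np.sum(null >= obs - 1e-12)) / (n_perm + 1))


# ---------------------------------------------------------------------------
# null-allele screen


@dataclass
class NullAlleleResult:
    locus: str
    group: str | None
    r: float
    ci: tuple[float, float] | None
    flagged: bool


def null_allele_screen(
    table: GenotypeTable,
    locus: str,
    group: str | None = None,
    n_boot: int = 500,
    seed: int | None = None,
) -> NullAlleleResult:
    """Brookfield-1 null-allele frequency estimate r = (He - Ho) / (1 + He).

    The locus is flagged when a bootstrap (resampling individuals) 95%
    percentile interval for r excludes 0.  With fewer than 10 non-missing
    individuals the estimate is returned but flagging is suppressed.
    """
    sub = table if group is None else table.group_subset(group)
    j = sub.loci.index(locus)
    a = sub.alleles[:, j, :]
    a = a[~(a == MISSING).all(axis=1)]
    m = len(a)
    if m == 0:
        raise ValueError(f"no non-missing calls at {locus}")

    def brookfield(x: np.ndarray) -> float:
        he = expected_heterozygosity(x)
        ho = observed_heterozygosity(x)
        if not np.isfinite(he):
            return float("nan")
        return (he - ho) / (1.0 + he)

    r = brookfield(a)
    if m < 10:
        return NullAlleleResult(locus, group, r, None, False)
    rng = np.random.default_rng(seed)
    boots = np.array(
        [brookfield(a[rng.integers(0, m, m)]) for _ in range(n_boot)]
    )
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    flagged = bool(lo > 0.0 or hi < 0.0)
    return NullAlleleResult(locus, group, r, (float(lo), float(hi)), flagged)
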