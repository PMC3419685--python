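"""Heterozygosity-excess bottleneck tests and the allele-frequency mode shift.

A recent population crash removes rare alleles faster than it erodes gene
diversity, so for a while the observed (unbiased) heterozygosity He_obs at a
locus exceeds the equilibrium expectation He_eq for the *observed* number of
alleles.  He_eq is obtained by coalescent simulation of n genes conditioned
on the observed allele count k: the scaled mutation rate theta is calibrated
by bisection so the expected allele count matches k, mutations are dropped
on the tree under the chosen model (IAM: every mutation novel; SMM: +/-1
repeat unit; TPM: occasional multi-step geometric jumps), and replicates are
retained only when the realised allele count equals k.  Per locus the
standardised deviation DH = (He_obs - mean He_eq) / sd(He_eq) feeds a
one-tailed Wilcoxon signed-rank test, and a sign test compares the count of
excess loci with its simulation-estimated expectation (Poisson-binomial
tail).  The mode-shift test pools alleles across loci into 0.1-wide
frequency classes: at mutation-drift equilibrium the rarest class dominates
(an L shape); a distorted spectrum signals a bottleneck.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from landgen.genotypes import MISSING, GenotypeTable
from landgen.qc import expected_heterozygosity

MODELS = ("IAM", "SMM", "TPM")


@dataclass
class BottleneckResult:
    population: str
    model: str
    loci: list[str]
    dh: dict[str, float]
    he_obs: dict[str, float]
    he_eq_mean: dict[str, float]
    sign_p: float
    wilcoxon_p: float
    n_excess: int
    n_deficit: int
    replications: int


@dataclass
class ModeShiftResult:
    population: str
    shifted: bool
    histogram: np.ndarray  # allele counts in classes (0,0.1], ..., (0.9,1.0]


# ---------------------------------------------------------------------------
# coalescent machinery


def _coalescent_alleles(
    n: int, theta: float, model: str, rng, p_multi=0.3, mean_step=2.8
) -> np.ndarray:
    """Leaf allele states of one coalescent replicate of n genes.

    Branch lengths are in coalescent units; mutations arrive at rate
    theta / 2 per lineage per unit time.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    blen = np.zeros(2 * n - 1)
    # pre-drawn randomness: one exponential and two pair picks per merge
    j = np.arange(n, 1, -1)
    waits = rng.exponential(2.0 / (j * (j - 1)))
    u_pairs = rng.random((n - 1, 2))
    active = list(range(n))
    depth = np.zeros(2 * n - 1)  # time at which a lineage was created
    t_now = 0.0
    for step in range(n - 1):
        t_now += waits[step]
        a = active.pop(int(u_pairs[step, 0] * len(active)))
        b = active.pop(int(u_pairs[step, 1] * len(active)))
        node = n + step
        parent[a] = parent[b] = node
        blen[a] = t_now - depth[a]
        blen[b] = t_now - depth[b]
        depth[node] = t_now
        active.append(node)
    root = 2 * n - 2
    n_mut = rng.poisson(theta / 2.0 * blen[: 2 * n - 2])
    total_mut = int(n_mut.sum())
    state = np.zeros(2 * n - 1, dtype=np.int64)
    if total_mut:
        if model == "SMM":
            steps = rng.choice([-1, 1], size=total_mut)
        elif model == "TPM":
            mag = np.where(
                rng.random(total_mut) < p_multi,
                rng.geometric(1.0 / mean_step, size=total_mut),
                1,
            )
            steps = rng.choice([-1, 1], size=total_mut) * mag
        else:  # IAM: each mutation is a novel allele id
            steps = np.arange(1, total_mut + 1)
        offsets = np.concatenate([[0], np.cumsum(n_mut)])
        for node in range(2 * n - 3, -1, -1):  # root's children downward
            m = int(n_mut[node])
            base = state[parent[node]]
            if m == 0:
                state[node] = base
            elif model == "IAM":
                state[node] = steps[offsets[node] + m - 1]  # most recent wins
            else:
                state[node] = base + int(steps[offsets[node] : offsets[node] + m].sum())
    return state[:n]


def _expected_k_iam(n: int, theta: float) -> float:
    i = np.arange(n, dtype=float)
    return float(np.sum(theta / (theta + i)))


def _expected_k_mc(n: int, theta: float, model: str, seed: int, reps: int = 300) -> float:
    rng = np.random.default_rng(seed)
    ks = [
        len(np.unique(_coalescent_alleles(n, theta, model, rng)))
        for _ in range(reps)
    ]
    return float(np.mean(ks))


from functools import lru_cache


@lru_cache(maxsize=4096)
def calibrate_theta(n: int, k: int, model: str, seed: int = 0) -> float:
    """Bisection for the theta whose expected allele count is k.

    Ewens' closed form serves the IAM; stepwise models use a Monte-Carlo
    estimate of E[k] with common random numbers inside the bisection.
    """
    if k <= 1:
        return 0.0

    def expected(th: float) -> float:
        if model == "IAM":
            return _expected_k_iam(n, th)
        return _expected_k_mc(n, th, model, seed)

    lo, hi = 1e-4, 1.0
    while expected(hi) < k and hi < 1e4:
        hi *= 2.0
    for _ in range(25 if model == "IAM" else 14):
        mid = np.sqrt(lo * hi)
        if expected(mid) < k:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_he_eq(
    n_genes: int,
    k_alleles: int,
    model: str,
    reps: int = 1000,
    seed: int | None = None,
    p_multi: float = 0.3,
    mean_step: float = 2.8,
) -> np.ndarray:
    """Conditional equilibrium He sample: coalescent replicates retained only
    when the realised allele count equals ``k_alleles``."""
    if not 1 <= k_alleles <= n_genes:
        raise ValueError("need 1 <= k <= n")
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if k_alleles == 1:
        return np.zeros(reps)
    rng = np.random.default_rng(seed)
    # calibration uses common random numbers so it is shared across loci
    theta = calibrate_theta(n_genes, k_alleles, model)
    out = []
    attempts = 0
    max_attempts = 60 * reps
    while len(out) < reps and attempts < max_attempts:
        attempts += 1
        alleles = _coalescent_alleles(n_genes, theta, model, rng, p_multi, mean_step)
        uniq, counts = np.unique(alleles, return_counts=True)
        if len(uniq) != k_alleles:
            continue
        p = counts / n_genes
        out.append(n_genes / (n_genes - 1) * (1.0 - float(np.sum(p**2))))
    if len(out) < min(reps, 20):
        raise RuntimeError(
            f"only {len(out)} replicates retained at k={k_alleles}, n={n_genes}; "
            "increase reps"
        )
    return np.asarray(out)


# ---------------------------------------------------------------------------
# tests


def _poisson_binomial_tail(p: np.ndarray, x: int) -> float:
    """P(X >= x) for a Poisson-binomial with success probabilities p."""
    dist = np.array([1.0])
    for pi in p:
        dist = np.convolve(dist, [1 - pi, pi])
    return float(dist[x:].sum())


def _population_mask(table: GenotypeTable, population: str) -> np.ndarray:
    if table.populations is not None and population in set(table.populations):
        return table.populations == population
    if population in set(table.groups):
        return table.groups == population
    raise ValueError(f"unknown population or group {population!r}")


def het_excess_test(
    table: GenotypeTable,
    population: str,
    model: str,
    reps: int = 10000,
    seed: int | None = None,
) -> BottleneckResult:
    """Per-population heterozygosity-excess battery under one mutation model.

    One-tailed for excess: small sign/Wilcoxon p means more loci show
    He_obs above its conditional equilibrium expectation than equilibrium
    itself would produce.
    """
    sel = _population_mask(table, population)
    sub = table.subset(sel)
    rng = np.random.default_rng(seed)
    loci, dh, he_obs_d, he_mean_d, p_excess = [], {}, {}, {}, []
    excess_flags = []
    for j, locus in enumerate(sub.loci):
        a = sub.alleles[:, j, :]
        nonmiss = ~(a == MISSING).all(axis=1)
        flat = a[nonmiss].reshape(-1)
        k = len(np.unique(flat))
        n_genes = int(2 * nonmiss.sum())
        if k < 2:
            continue
        he_obs = expected_heterozygosity(a)
        he_eq = simulate_he_eq(
            n_genes, k, model, reps=reps, seed=int(rng.integers(2**31))
        )
        mu, sd = float(he_eq.mean()), float(he_eq.std(ddof=1))
        loci.append(locus)
        he_obs_d[locus] = he_obs
        he_mean_d[locus] = mu
        dh[locus] = (he_obs - mu) / sd if sd > 0 else 0.0
        excess_flags.append(he_obs > mu)
        # equilibrium probability that a locus shows excess (distribution is
        # skewed, so this is not 1/2)
        p_excess.append(float(np.mean(he_eq > mu)))
    if len(loci) < 4:
        raise ValueError("need >= 4 polymorphic loci for the excess battery")
    n_excess = int(np.sum(excess_flags))
    n_deficit = len(loci) - n_excess
    sign_p = _poisson_binomial_tail(np.asarray(p_excess), n_excess)
    dh_values = np.array([dh[l] for l in loci])
    wilcoxon_p = float(
        stats.wilcoxon(dh_values, alternative="greater").pvalue
    )
    return BottleneckResult(
        population=population,
        model=model,
        loci=loci,
        dh=dh,
        he_obs=he_obs_d,
        he_eq_mean=he_mean_d,
        sign_p=sign_p,
        wilcoxon_p=wilcoxon_p,
        n_excess=n_excess,
        n_deficit=n_deficit,
        replications=reps,
    )


def mode_shift(table: GenotypeTable, population: str) -> ModeShiftResult:
    """Allele-frequency spectrum mode-shift test.

    Pools alleles of polymorphic loci into ten 0.1-wide frequency classes;
    the spectrum is L-shaped (no shift) iff the lowest class (0, 0.1] holds
    strictly the most alleles.
    """
    sel = _population_mask(table, population)
    sub = table.subset(sel)
    hist = np.zeros(10, dtype=int)
    n_poly = 0
    for j in range(sub.n_loci):
        a = sub.alleles[:, j, :]
        flat = a[a != MISSING]
        if flat.size == 0:
            continue
        sizes, counts = np.unique(flat, return_counts=True)
        if len(sizes) < 2:
            continue
        n_poly += 1
        freqs = counts / counts.sum()
        cls = np.minimum((np.ceil(freqs * 10) - 1).astype(int), 9)
        for c in cls:
            hist[c] += 1
    if n_poly < 5:
        warnings.warn(
            f"only {n_poly} polymorphic loci: mode-shift call is low-information"
        )
    shifted = not (hist[0] > hist[1:].max()) if hist.sum() else True
    return ModeShiftResult(population=population, shifted=bool(shifted), histogram=hist)
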