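"""Bayesian admixture clustering, Delta-K model choice, and migrant detection.

The clusterer is the admixture model with independent Dirichlet(1) allele
frequencies per cluster: each allele copy carries a latent cluster of origin,
individuals carry admixture proportions Q with a symmetric Dirichlet(alpha)
prior, and a Gibbs sampler alternates the allele-origin indicators, the
cluster allele frequencies, and Q.  The marginal data probability for a given
K is estimated from the post-burn-in log-likelihood trace as
mean(lnL) - var(lnL)/2, and Evanno's Delta-K second-difference statistic
picks K across a scan.

Migrant detection follows the assignment/exclusion framework: an
individual's multilocus genotype likelihood under each candidate population's
allele frequencies (Hardy-Weinberg within loci, loci independent, rare-allele
frequency floor), compared against the likelihoods of simulated individuals
drawn from those frequencies.  The home population's frequencies are always
computed leave-one-out so an individual's own alleles never inflate its home
likelihood.  Final labels combine the first-generation-migrant test (both
L_h and L_h/L_max significant and the best population differing from the
sampling population) with an admixture rule (mean Q between 0.2 and 0.8 and
exclusion probability above 0.2 in more than one population).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from landgen.genotypes import MISSING, GenotypeTable


@dataclass
class ClusterResult:
    K: int
    Q: np.ndarray                # (n, K) posterior-mean admixture, replicates merged
    lnP: list[float]             # per-replicate estimate of ln P(X | K)
    replicates: int
    seeds: list[int]
    mixing_warnings: list[str] = field(default_factory=list)


@dataclass
class DeltaKTable:
    ks: list[int]
    mean_lnp: dict[int, float]
    sd_lnp: dict[int, float]
    delta_k: dict[int, float]    # interior K only
    best_k: int


@dataclass
class AssignmentScores:
    individual: str
    home: str
    log_l: dict[str, float]          # per population
    l_h: float
    l_max: float
    best_population: str
    exclusion_p: dict[str, float]    # per population
    migrant_p_lh: float
    migrant_p_ratio: float


@dataclass
class MigrantRecord:
    individual: str
    sampled_population: str
    q_home: float
    scores: AssignmentScores
    label: str                       # resident | migrant | admixed | unclassified
    reason: str = ""


# ---------------------------------------------------------------------------
# data encoding


def _encode(table: GenotypeTable):
    """Per locus: integer-coded alleles (n, 2) with -1 for missing."""
    coded = []
    n_alleles = []
    for j in range(table.n_loci):
        a = table.alleles[:, j, :]
        sizes = np.unique(a[a != MISSING])
        lookup = {s: i for i, s in enumerate(sizes)}
        c = np.full(a.shape, -1, dtype=np.int64)
        for s, i in lookup.items():
            c[a == s] = i
        coded.append(c)
        n_alleles.append(len(sizes))
    return coded, n_alleles


# ---------------------------------------------------------------------------
# Gibbs sampler


def _gibbs_once(
    coded, n_alleles, K: int, iters: int, burnin: int, alpha: float, rng
):
    n = coded[0].shape[0]
    L = len(coded)
    q = rng.dirichlet(np.full(K, alpha), size=n)
    freqs = [rng.dirichlet(np.ones(max(m, 1)), size=K) for m in n_alleles]
    q_sum = np.zeros((n, K))
    lnl_trace = []
    kept = 0
    for sweep in range(iters):
        origin_counts = np.zeros((n, K))
        allele_counts = [np.zeros((K, max(m, 1))) for m in n_alleles]
        lnl = 0.0
        for l in range(L):
            c = coded[l]
            present = c >= 0
            if not present.any() or n_alleles[l] == 0:
                continue
            # w[i, copy, k] = q_ik * P_k,l,allele(i,copy)
            pa = freqs[l].T[np.clip(c, 0, None)]      # (n, 2, K)
            w = q[:, None, :] * pa
            w[~present] = 1.0 / K                     # unused; placeholder
            tot = w.sum(axis=2)
            lnl += float(np.log(tot[present]).sum())
            # sample z by inverse CDF
            u = rng.random((n, 2, 1)) * tot[:, :, None]
            z = (w.cumsum(axis=2) < u).sum(axis=2)
            z = np.clip(z, 0, K - 1)
            zp = z[present]
            cp = c[present]
            np.add.at(allele_counts[l], (zp, cp), 1.0)
            iidx = np.nonzero(present)[0]
            np.add.at(origin_counts, (iidx, zp), 1.0)
        for l in range(L):
            if n_alleles[l] == 0:
                continue
            freqs[l] = _dirichlet_rows(allele_counts[l] + 1.0, rng)
        q = _dirichlet_rows(origin_counts + alpha, rng)
        if sweep >= burnin:
            q_sum += q
            lnl_trace.append(lnl)
            kept += 1
    trace = np.asarray(lnl_trace)
    ln_p = float(trace.mean() - trace.var() / 2.0)
    q_mean = q_sum / max(kept, 1)
    warning = None
    if len(trace) >= 8:
        half = len(trace) // 2
        drift = abs(trace[half:].mean() - trace[:half].mean())
        if trace.std() > 0 and drift > 2.0 * trace.std():
            warning = f"lnL trend ({drift:.1f} > 2 sd): chain may not have mixed"
    return q_mean, ln_p, warning


def _dirichlet_rows(alpha_matrix: np.ndarray, rng) -> np.ndarray:
    g = rng.gamma(alpha_matrix)
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=1, keepdims=True)


def _match_columns(reference: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Greedy label-switching fix: permute q's columns to best match
    the reference mean-Q matrix."""
    K = q.shape[1]
    remaining = list(range(K))
    order = []
    for k in range(K):
        overlaps = [float(reference[:, k] @ q[:, c]) for c in remaining]
        pick = remaining[int(np.argmax(overlaps))]
        order.append(pick)
        remaining.remove(pick)
    return q[:, order]


def gibbs_admixture(
    table: GenotypeTable,
    K: int,
    iters: int = 600,
    burnin: int = 200,
    replicates: int = 1,
    alpha: float = 1.0,
    seed: int | None = None,
) -> ClusterResult:
    """Admixture-model Gibbs sampler at a fixed number of clusters K.

    Returns per-replicate ln P(X|K) estimates and the replicate-averaged Q
    (cluster labels aligned across replicates by greedy matching).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    coded, n_alleles = _encode(table)
    root = np.random.default_rng(seed)
    seeds = [int(root.integers(2**31)) for _ in range(replicates)]
    q_ref = None
    q_acc = np.zeros((table.n_individuals, K))
    ln_ps = []
    warns = []
    for s in seeds:
        rng = np.random.default_rng(s)
        q_mean, ln_p, warning = _gibbs_once(
            coded, n_alleles, K, iters, burnin, alpha, rng
        )
        if warning:
            warns.append(warning)
            warnings.warn(warning)
        if q_ref is None:
            q_ref = q_mean
        else:
            q_mean = _match_columns(q_ref, q_mean)
        q_acc += q_mean
        ln_ps.append(ln_p)
    return ClusterResult(
        K=K,
        Q=q_acc / replicates,
        lnP=ln_ps,
        replicates=replicates,
        seeds=seeds,
        mixing_warnings=warns,
    )


def single_population_lnp(table: GenotypeTable) -> float:
    """Closed-form ln P(X | K=1): product of multinomial-Dirichlet marginal
    terms over loci (Dirichlet(1) prior on allele frequencies), with genotype
    multiplicity factors.  Serves as an analytic check on the K=1 sampler."""
    from scipy.special import gammaln

    coded, n_alleles = _encode(table)
    total = 0.0
    for l, c in enumerate(coded):
        m = n_alleles[l]
        if m == 0:
            continue
        present = c >= 0
        counts = np.bincount(c[present], minlength=m).astype(float)
        g = counts.sum()
        # Dirichlet(1)-multinomial marginal of the gene counts
        total += float(
            gammaln(m) - gammaln(m + g) + gammaln(counts + 1.0).sum()
        )
        het = present.all(axis=1) & (c[:, 0] != c[:, 1])
        total += float(het.sum()) * np.log(2.0)
    return total


# ---------------------------------------------------------------------------
# Delta-K


def delta_k(lnp_by_k: dict[int, list[float]]) -> DeltaKTable:
    """Evanno's second-difference statistic over a K scan.

    Requires at least three consecutive K values with >= 2 replicates each;
    Delta-K(K) = |mean lnP(K+1) - 2 mean lnP(K) + mean lnP(K-1)| / sd lnP(K),
    defined for interior K only; the argmax is reported as best K.
    """
    ks = sorted(lnp_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    mean = {k: float(np.mean(lnp_by_k[k])) for k in ks}
    sd = {k: float(np.std(lnp_by_k[k], ddof=1)) for k in ks}
    dk = {}
    for k in ks[1:-1]:
        if len(lnp_by_k[k]) < 2:
            raise ValueError(f"K={k} has <2 replicates")
        if sd[k] == 0.0:
            raise ValueError(f"zero sd of lnP at K={k}: Delta-K undefined")
        dk[k] = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
    best = max(dk, key=dk.get)
    return DeltaKTable(ks=ks, mean_lnp=mean, sd_lnp=sd, delta_k=dk, best_k=best)


# ---------------------------------------------------------------------------
# assignment and exclusion


def population_frequencies(
    table: GenotypeTable,
    membership: np.ndarray,
    population: str,
    exclude: str | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-locus (allele sizes, frequencies) for one population, optionally
    leaving one individual out."""
    sel = membership == population
    if exclude is not None:
        sel = sel & (table.ids != exclude)
    sub = table.subset(sel)
    freqs = []
    for j in range(table.n_loci):
        a = sub.alleles[:, j, :]
        flat = a[a != MISSING]
        if flat.size == 0:
            freqs.append((np.array([], dtype=np.int64), np.array([])))
            continue
        sizes, counts = np.unique(flat, return_counts=True)
        freqs.append((sizes, counts / counts.sum()))
    return freqs


def assignment_likelihood(
    genotype: np.ndarray,
    population_freqs: list[tuple[np.ndarray, np.ndarray]],
    zero_sub: float = 0.01,
) -> float:
    """Multilocus log-likelihood of a diploid genotype under Hardy-Weinberg.

    ``genotype``: (n_loci, 2) allele sizes (0 = missing).  Any allele unseen
    in the reference population enters at frequency ``zero_sub``, with the
    locus frequencies renormalised.
    """
    log_l = 0.0
    for (a, b), (sizes, freqs) in zip(genotype, population_freqs):
        if a == MISSING and b == MISSING:
            continue
        lookup = dict(zip(sizes.tolist(), freqs.tolist()))
        carried = {a, b}
        unseen = [al for al in carried if al not in lookup]
        norm = 1.0 + zero_sub * len(unseen)
        pa = lookup.get(a, zero_sub) / norm
        pb = lookup.get(b, zero_sub) / norm
        log_l += np.log(pa) + np.log(pb) + (np.log(2.0) if a != b else 0.0)
    return float(log_l)


def _simulate_log_likelihoods(
    source_freqs,
    score_freqs_list,
    n_sim: int,
    rng,
    zero_sub: float = 0.01,
) -> np.ndarray:
    """(n_sim, n_pops) log-likelihoods of individuals simulated from
    ``source_freqs`` scored under each population in ``score_freqs_list``."""
    L = len(source_freqs)
    out = np.zeros((n_sim, len(score_freqs_list)))
    for l in range(L):
        sizes, freqs = source_freqs[l]
        if len(sizes) == 0:
            continue
        draws = rng.choice(len(sizes), size=(n_sim, 2), p=freqs)
        a1 = sizes[draws[:, 0]]
        a2 = sizes[draws[:, 1]]
        het = a1 != a2
        for p, score in enumerate(score_freqs_list):
            s_sizes, s_freqs = score[l]
            lookup = np.full(int(max(sizes.max(), s_sizes.max() if len(s_sizes) else 0)) + 1, 0.0)
            if len(s_sizes):
                lookup[s_sizes] = s_freqs
            p1 = lookup[a1]
            p2 = lookup[a2]
            unseen = (p1 == 0).astype(float) + (p2 == 0).astype(float)
            # conservative renormalisation for unseen alleles
            norm = 1.0 + zero_sub * unseen
            p1 = np.where(p1 == 0, zero_sub, p1) / norm
            p2 = np.where(p2 == 0, zero_sub, p2) / norm
            out[:, p] += np.log(p1) + np.log(p2) + het * np.log(2.0)
    return out


def exclusion_test(
    table: GenotypeTable,
    individual: str,
    membership: np.ndarray,
    populations: list[str],
    n_sim: int = 10000,
    zero_sub: float = 0.01,
    seed: int | None = None,
) -> AssignmentScores:
    """Assignment scores and exclusion/migrant p-values for one individual.

    For each candidate population, p_exclusion is the (+1-corrected)
    proportion of ``n_sim`` simulated resident genotypes whose likelihood
    under that population falls at or below the individual's — small p
    excludes the population.  The first-generation-migrant statistics are
    L_h (home likelihood) and L_h/L_max, referenced against residents
    simulated from the home population.
    """
    i = int(np.flatnonzero(table.ids == individual)[0])
    home = str(membership[i])
    if home not in populations:
        raise ValueError(f"{individual}: home population {home!r} not in candidates")
    rng = np.random.default_rng(seed)
    geno = table.alleles[i]
    freqs_by_pop = {}
    for pop in populations:
        exclude = individual if pop == home else None
        freqs_by_pop[pop] = population_frequencies(table, membership, pop, exclude)
    log_l = {
        pop: assignment_likelihood(geno, freqs_by_pop[pop], zero_sub)
        for pop in populations
    }
    l_h = log_l[home]
    best = max(log_l, key=log_l.get)
    l_max = log_l[best]

    if all(len(s) <= 1 for s, _ in freqs_by_pop[home]):
        warnings.warn(f"population {home!r} monomorphic at every locus")

    score_list = [freqs_by_pop[p] for p in populations]
    exclusion_p = {}
    sims = {}
    for pop in populations:
        sims[pop] = _simulate_log_likelihoods(
            freqs_by_pop[pop], score_list, n_sim, rng, zero_sub
        )
        own = sims[pop][:, populations.index(pop)]
        exclusion_p[pop] = float(
            (1 + np.sum(own <= log_l[pop] + 1e-12)) / (n_sim + 1)
        )
    home_sims = sims[home]
    hi = populations.index(home)
    migrant_p_lh = exclusion_p[home]
    ratio_obs = l_h - l_max
    ratio_sim = home_sims[:, hi] - home_sims.max(axis=1)
    migrant_p_ratio = float(
        (1 + np.sum(ratio_sim <= ratio_obs + 1e-12)) / (n_sim + 1)
    )
    return AssignmentScores(
        individual=individual,
        home=home,
        log_l=log_l,
        l_h=l_h,
        l_max=l_max,
        best_population=best,
        exclusion_p=exclusion_p,
        migrant_p_lh=migrant_p_lh,
        migrant_p_ratio=migrant_p_ratio,
    )


def detect_migrants(
    table: GenotypeTable,
    populations: list[str],
    cluster: ClusterResult | None = None,
    membership: np.ndarray | None = None,
    alpha: float = 0.01,
    q_admixture_bounds: tuple[float, float] = (0.2, 0.8),
    assign_threshold: float = 0.2,
    n_sim: int = 10000,
    seed: int | None = None,
) -> list[MigrantRecord]:
    """Classify each individual as resident, migrant or admixed.

    Migrant: both first-generation statistics (L_h and L_h/L_max) significant
    at ``alpha`` and the best-likelihood population differs from the sampling
    population.  Admixed: mean home-cluster Q strictly inside
    ``q_admixture_bounds`` and exclusion probability above
    ``assign_threshold`` in more than one population.  Otherwise resident.
    Individuals lacking Q or scores are left unclassified with a reason.
    """
    if membership is None:
        if table.populations is None:
            raise ValueError("need population labels or an explicit membership")
        membership = table.populations
    membership = np.asarray(membership, dtype=object)
    q_home = _align_q_to_populations(table, populations, cluster, membership)
    rng = np.random.default_rng(seed)
    records = []
    for idx, ind in enumerate(table.ids):
        home = str(membership[idx])
        if home not in populations:
            records.append(
                MigrantRecord(ind, home, float("nan"), None, "unclassified",
                              "home population not among candidates")
            )
            continue
        scores = exclusion_test(
            table, ind, membership, populations,
            n_sim=n_sim, seed=int(rng.integers(2**31)),
        )
        qh = q_home[idx] if q_home is not None else float("nan")
        sig = scores.migrant_p_lh < alpha and scores.migrant_p_ratio < alpha
        if sig and scores.best_population != home:
            label = "migrant"
        elif (
            q_home is not None
            and q_admixture_bounds[0] < qh < q_admixture_bounds[1]
            and sum(p > assign_threshold for p in scores.exclusion_p.values()) > 1
        ):
            label = "admixed"
        elif q_home is None and cluster is not None:
            label = "unclassified"
        else:
            label = "resident"
        records.append(MigrantRecord(ind, home, float(qh), scores, label))
    return records


def _align_q_to_populations(table, populations, cluster, membership):
    """Map cluster columns onto sampling populations via mean Q; returns each
    individual's Q in its home population's column (or None without Q)."""
    if cluster is None:
        return None
    Q = cluster.Q
    col_of = {}
    taken = set()
    for pop in populations:
        sel = membership == pop
        if not sel.any():
            continue
        means = Q[sel].mean(axis=0)
        for c in np.argsort(means)[::-1]:
            if c not in taken:
                col_of[pop] = int(c)
                taken.add(int(c))
                break
    out = np.full(table.n_individuals, np.nan)
    for i in range(table.n_individuals):
        pop = str(membership[i])
        if pop in col_of:
            out[i] = Q[i, col_of[pop]]
    return out
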