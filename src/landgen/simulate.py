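"""Synthetic landscapes and forward-simulated microsatellite genotypes.

The generator emulates the statistical structure the analysis chain assumes:
a categorical land-cover grid in which one expansive matrix class (the true
barrier) runs as a single contiguous band across the landscape while the
other matrix classes occur as smaller scattered patches, and a set of
monkey-group demes confined to forest cells on either side of the band.
Gene flow follows a cost-distance kernel: the migration rate from deme j
into deme i is proportional to exp(-d_LC(i,j) / lambda), with d_LC computed
on the *true* cost surface, scaled so each deme receives a fixed total
immigrant fraction per generation.  Within demes reproduction is
Wright-Fisher with non-overlapping generations; microsatellites mutate under
the strict stepwise model (SMM) or a two-phase model (TPM) at rate mu per
gamete per locus.  Founder allele frequencies are drawn from a triangular
law over 8-12 contiguous allele sizes per locus, matching the allelic
richness observed in wild squirrel-monkey microsatellite panels.

Every dataset ships with a :class:`SimTruth` record (true barrier class,
true costs, realised migration matrix, group placement, seeds) so recovery
tests can score the downstream verdicts against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import ndimage

from landgen.genotypes import GenotypeTable
from landgen.matrices import PairwiseMatrix
from landgen.rasters import DEFAULT_LEGEND, LandscapeRaster
from landgen.resistance import build_multiclass_surface, least_cost_matrix

DEFAULT_FRACTIONS = {
    "forest": 0.55,
    "oil_palm": 0.15,
    "pasture": 0.14,
    "river": 0.06,
    "residential": 0.05,
    "other": 0.05,
}

DEFAULT_TRUE_COSTS = {
    "forest": 1.0,
    "oil_palm": 50.0,
    "pasture": 1.0,
    "river": 1.0,
    "residential": 1.0,
    "other": 1.0,
}


@dataclass
class SimConfig:
    """Study-condition defaults: 14 groups, 16 unlinked microsatellite loci,
    a contiguous plantation band as the true barrier, and migration scaled so
    groups diverge weakly (F_ST roughly 0.05-0.15)."""

    ncols: int = 120
    nrows: int = 80
    cellsize: float = 20.0
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    barrier_class: str = "oil_palm"
    true_costs: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_COSTS))
    n_groups: int = 14
    group_size: int = 60  # diploid deme size
    n_loci: int = 16
    mutation_rate: float = 5e-4  # per gamete per locus
    mutation_model: str = "SMM"  # or "TPM"
    tpm_p_multi: float = 0.3
    tpm_mean_step: float = 2.8
    dispersal_scale: float = 2500.0  # lambda, cost-distance units
    migration_rate: float = 0.08  # total immigrant fraction per deme per gen
    generations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, not 1")
        if not (0.0 <= self.mutation_rate <= 0.01):
            raise ValueError("mutation rate must lie in [0, 0.01]")
        for name, value in (
            ("ncols", self.ncols),
            ("nrows", self.nrows),
            ("n_groups", self.n_groups),
            ("group_size", self.group_size),
            ("n_loci", self.n_loci),
            ("generations", self.generations),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimTruth:
    """Ground truth of one synthetic dataset."""

    config: SimConfig
    migration: np.ndarray          # (k, k), m[i, j] = rate into i from j
    true_least_cost: PairwiseMatrix
    group_coords: np.ndarray       # (k, 2)
    group_ids: list[str]
    seed: int

    def to_yaml(self, path) -> None:
        doc = {
            "config": asdict(self.config),
            "migration": self.migration.tolist(),
            "true_least_cost": self.true_least_cost.values.tolist(),
            "group_coords": self.group_coords.tolist(),
            "group_ids": list(self.group_ids),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)


# ---------------------------------------------------------------------------
# landscape


def generate_landscape(config: SimConfig) -> LandscapeRaster:
    """Categorical raster with the barrier class as one contiguous band.

    The band spans the full grid width (8-connected, constant thickness with
    a seeded meander); other non-forest classes are laid down as scattered
    rectangular patches; forest fills the remainder.  Realised class
    fractions land within +/-2% of the request.  Deterministic given the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    nrows, ncols = config.nrows, config.ncols
    total = nrows * ncols
    code_of = {name: code for code, name in DEFAULT_LEGEND.items()}
    for name in config.class_fractions:
        if name not in code_of:
            raise ValueError(f"unknown class {name!r}")
    barrier_frac = config.class_fractions.get(config.barrier_class, 0.0)
    thickness = int(round(barrier_frac * nrows))
    if barrier_frac > 0 and (thickness < 1 or thickness >= nrows - 2):
        raise ValueError("barrier fraction infeasible on this grid size")

    data = np.full((nrows, ncols), code_of["forest"], dtype=np.int64)

    if barrier_frac > 0:
        target = int(round(barrier_frac * total))
        base = (nrows - thickness) // 2
        # meandering top edge: +/-1 steps keep the band 8-connected
        steps = rng.integers(-1, 2, size=ncols)
        steps[0] = 0
        shift = np.cumsum(steps)
        span = max(2, nrows // 10)
        shift = np.clip(shift, -span, span)
        for c in range(ncols):
            r0 = int(np.clip(base + shift[c], 1, nrows - thickness - 1))
            data[r0 : r0 + thickness, c] = code_of[config.barrier_class]
        extra = target - thickness * ncols
        if extra > 0:
            for c in range(min(extra, ncols)):
                r0 = int(np.clip(base + shift[c], 1, nrows - thickness - 1))
                data[r0 + thickness, c] = code_of[config.barrier_class]

    # scattered patches for the remaining non-forest classes
    for name, frac in config.class_fractions.items():
        if name in ("forest", config.barrier_class) or frac <= 0:
            continue
        code = code_of[name]
        target = int(round(frac * total))
        placed = 0
        attempts = 0
        elongated = name == "river"
        while placed < target and attempts < 20000:
            attempts += 1
            if elongated:
                h, w = int(rng.integers(6, 18)), int(rng.integers(1, 3))
            else:
                h, w = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            r = int(rng.integers(0, nrows - h + 1))
            c = int(rng.integers(0, ncols - w + 1))
            block = data[r : r + h, c : c + w]
            free = block == code_of["forest"]
            if not free.any():
                continue
            room = target - placed
            cells = np.argwhere(free)
            if len(cells) > room:
                cells = cells[:room]
            block[cells[:, 0], cells[:, 1]] = code
            placed += len(cells)
        if placed < int(0.98 * target):
            raise ValueError(f"could not place class {name!r}: fractions infeasible")

    raster = LandscapeRaster(
        data=data,
        xllcorner=0.0,
        yllcorner=0.0,
        cellsize=config.cellsize,
        legend=dict(DEFAULT_LEGEND),
    )
    return raster


# ---------------------------------------------------------------------------
# Wright-Fisher engine


def _mutate(alleles: np.ndarray, mu: float, model: str, rng, p_multi=0.3, mean_step=2.8):
    """In-place stepwise/two-phase mutation on an integer allele array."""
    if mu <= 0:
        return alleles
    hit = rng.random(alleles.shape) < mu
    n_hit = int(hit.sum())
    if n_hit == 0:
        return alleles
    sign = rng.choice([-1, 1], size=n_hit)
    if model == "SMM":
        step = np.ones(n_hit, dtype=np.int64)
    elif model == "TPM":
        multi = rng.random(n_hit) < p_multi
        # geometric number of repeat units with the requested mean
        step = np.where(
            multi, rng.geometric(1.0 / mean_step, size=n_hit), 1
        ).astype(np.int64)
    else:
        raise ValueError(f"unknown mutation model {model!r}")
    alleles[hit] = np.maximum(alleles[hit] + sign * step, 2)
    return alleles


def founder_pool(
    n_loci: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-locus (allele sizes, frequencies): 8-12 contiguous sizes with
    triangular frequencies."""
    pool = []
    for _ in range(n_loci):
        k = int(rng.integers(8, 13))
        start = int(rng.integers(12, 30))
        sizes = np.arange(start, start + k)
        w = np.minimum(np.arange(1, k + 1), np.arange(k, 0, -1)).astype(float)
        pool.append((sizes, w / w.sum()))
    return pool


def draw_founders(
    k_demes: int, deme_size: int, pool, rng: np.random.Generator
) -> np.ndarray:
    """(k, N, L, 2) founder genotypes drawn iid from the shared pool."""
    L = len(pool)
    out = np.zeros((k_demes, deme_size, L, 2), dtype=np.int64)
    for l, (sizes, freqs) in enumerate(pool):
        out[:, :, l, :] = rng.choice(sizes, size=(k_demes, deme_size, 2), p=freqs)
    return out


def wright_fisher(
    founders: np.ndarray,
    migration: np.ndarray,
    mu: float,
    model: str,
    generations: int,
    rng: np.random.Generator,
    p_multi: float = 0.3,
    mean_step: float = 2.8,
) -> np.ndarray:
    """Forward-simulate diploid demes with non-overlapping generations.

    ``founders``: (k, N, L, 2); ``migration[i, j]``: probability an offspring
    born into deme i has parents drawn from deme j (off-diagonal; the
    remainder stays local).  Rows must sum to at most 1.
    """
    k, N, L, _ = founders.shape
    mig = np.asarray(migration, dtype=float)
    if mig.shape != (k, k):
        raise ValueError("migration matrix shape mismatch")
    if (mig.sum(axis=1) - np.diag(mig) > 1.0 + 1e-9).any():
        raise ValueError("migration row sums exceed 1")
    probs = mig.copy()
    np.fill_diagonal(probs, 0.0)
    diag = 1.0 - probs.sum(axis=1)
    probs[np.diag_indices(k)] = diag
    state = founders.copy()
    for _ in range(generations):
        new = np.empty_like(state)
        for i in range(k):
            src = rng.choice(k, size=N, p=probs[i])
            p1 = src * N + rng.integers(0, N, size=N)
            p2 = src * N + rng.integers(0, N, size=N)
            flat = state.reshape(k * N, L, 2)
            g1 = flat[p1[:, None], np.arange(L)[None, :], rng.integers(0, 2, size=(N, L))]
            g2 = flat[p2[:, None], np.arange(L)[None, :], rng.integers(0, 2, size=(N, L))]
            new[i, :, :, 0] = g1
            new[i, :, :, 1] = g2
        _mutate(new, mu, model, rng, p_multi, mean_step)
        state = new
    return state


# ---------------------------------------------------------------------------
# genotype simulation on a landscape


def _place_groups(
    landscape: LandscapeRaster, config: SimConfig, rng: np.random.Generator
):
    """Forest cells for each group, split between the two sides of the
    barrier band, mutually separated."""
    forest_code = landscape.code_of("forest")
    barrier_code = landscape.code_of(config.barrier_class)
    passable = (landscape.data != barrier_code) & landscape.valid
    labels, n_comp = ndimage.label(passable, structure=np.ones((3, 3)))
    sizes = ndimage.sum(passable, labels, index=range(1, n_comp + 1))
    order = np.argsort(sizes)[::-1] + 1
    side_labels = order[: min(2, len(order))]
    cells = []
    per_side = [
        config.n_groups - config.n_groups // 2,
        config.n_groups // 2,
    ]
    for side, want in zip(side_labels, per_side):
        if want == 0:
            continue
        candidates = np.argwhere((labels == side) & (landscape.data == forest_code))
        if len(candidates) < want:
            raise ValueError("no forest cell available for a group")
        min_sep = max(3.0, 0.15 * min(landscape.nrows, landscape.ncols))
        chosen: list[np.ndarray] = []
        for _ in range(5000):
            if len(chosen) == want:
                break
            cand = candidates[rng.integers(0, len(candidates))]
            if all(np.hypot(*(cand - c)) >= min_sep for c in chosen):
                chosen.append(cand)
        while len(chosen) < want:  # relax separation if the side is cramped
            cand = candidates[rng.integers(0, len(candidates))]
            if not any((cand == c).all() for c in chosen):
                chosen.append(cand)
        cells.extend(chosen)
    if len(cells) < config.n_groups:
        raise ValueError("no forest cell available for a group")
    return np.array(cells[: config.n_groups])


def migration_from_costs(
    d_lc: np.ndarray, dispersal_scale: float, total_rate: float
) -> np.ndarray:
    """Kernel m_ij proportional to exp(-d_LC / lambda), rows scaled to the
    total immigrant fraction."""
    k = d_lc.shape[0]
    w = np.exp(-d_lc / dispersal_scale)
    np.fill_diagonal(w, 0.0)
    mig = np.zeros_like(w)
    for i in range(k):
        s = w[i].sum()
        if s > 0:
            mig[i] = total_rate * w[i] / s
    return mig


def simulate_genotypes(
    landscape: LandscapeRaster,
    true_costs: dict[str, float] | None = None,
    config: SimConfig | None = None,
    sample_sizes: list[int] | None = None,
    seed: int | None = None,
) -> tuple[GenotypeTable, SimTruth]:
    """Forward-simulate genotypes for groups placed on a landscape.

    Groups sit in forest cells only; migration between demes follows the
    cost-distance kernel on the true cost surface.  ``sample_sizes`` takes
    one entry per group (defaults to draws from the study's 10-28 range,
    capped by deme size).
    """
    config = SimConfig() if config is None else config
    true_costs = dict(config.true_costs) if true_costs is None else dict(true_costs)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    cells = _place_groups(landscape, config, rng)
    xs, ys = landscape.rowcol_to_xy(cells[:, 0], cells[:, 1])
    coords = np.column_stack([xs, ys])
    group_ids = [f"G{i+1:02d}" for i in range(config.n_groups)]

    surface = build_multiclass_surface(landscape, true_costs)
    d_lc = least_cost_matrix(surface, coords, ids=group_ids)
    mig = migration_from_costs(
        d_lc.values, config.dispersal_scale, config.migration_rate
    )

    pool = founder_pool(config.n_loci, rng)
    founders = draw_founders(config.n_groups, config.group_size, pool, rng)
    state = wright_fisher(
        founders,
        mig,
        config.mutation_rate,
        config.mutation_model,
        config.generations,
        rng,
        config.tpm_p_multi,
        config.tpm_mean_step,
    )

    if sample_sizes is None:
        sample_sizes = [
            int(min(config.group_size, rng.integers(10, 29)))
            for _ in range(config.n_groups)
        ]
    if len(sample_sizes) != config.n_groups:
        raise ValueError("one sample size per group required")

    ids, groups, rows, xy = [], [], [], []
    for g in range(config.n_groups):
        take = rng.choice(config.group_size, size=sample_sizes[g], replace=False)
        for t, idx in enumerate(take):
            ids.append(f"{group_ids[g]}_{t+1:02d}")
            groups.append(group_ids[g])
            rows.append(state[g, idx])
            xy.append(coords[g])
    table = GenotypeTable(
        ids=np.array(ids, dtype=object),
        groups=np.array(groups, dtype=object),
        coords=np.array(xy, dtype=float),
        loci=[f"L{l+1:02d}" for l in range(config.n_loci)],
        alleles=np.array(rows, dtype=np.int64),
    )
    truth = SimTruth(
        config=config,
        migration=mig,
        true_least_cost=d_lc,
        group_coords=coords,
        group_ids=group_ids,
        seed=seed,
    )
    return table, truth


def simulate_island_model(
    k_demes: int,
    deme_size: int,
    m: float,
    mu: float = 5e-4,
    n_loci: int = 16,
    generations: int = 500,
    model: str = "SMM",
    seed: int | None = None,
) -> GenotypeTable:
    """Finite-island control: uniform migration m split evenly among demes."""
    rng = np.random.default_rng(seed)
    if k_demes == 1:
        mig = np.zeros((1, 1))
    else:
        mig = np.full((k_demes, k_demes), m / (k_demes - 1))
        np.fill_diagonal(mig, 0.0)
    pool = founder_pool(n_loci, rng)
    founders = draw_founders(k_demes, deme_size, pool, rng)
    state = wright_fisher(founders, mig, mu, model, generations, rng)
    ids, groups, rows = [], [], []
    for g in range(k_demes):
        for i in range(deme_size):
            ids.append(f"D{g+1}_{i+1:03d}")
            groups.append(f"D{g+1}")
            rows.append(state[g, i])
    coords = np.zeros((len(ids), 2))
    coords[:, 0] = np.repeat(np.arange(k_demes, dtype=float) * 1000.0, deme_size)
    return GenotypeTable(
        ids=np.array(ids, dtype=object),
        groups=np.array(groups, dtype=object),
        coords=coords,
        loci=[f"L{l+1:02d}" for l in range(n_loci)],
        alleles=np.array(rows, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# replicate genotyping error


def make_replicates(
    table: GenotypeTable,
    dropout_rate: float,
    misscore_rate: float,
    n_reps: int,
    seed: int | None = None,
) -> list[GenotypeTable]:
    """Replicate call sets with allelic dropout and +/-1-step miscalls.

    Per replicate, each true heterozygote independently loses one random
    allele (appearing homozygous for the survivor) with probability
    ``dropout_rate``; every surviving allele call is then displaced by one
    repeat unit, in a random direction, with probability ``misscore_rate``.
    """
    if not (0 <= dropout_rate <= 1 and 0 <= misscore_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        alleles = table.alleles.copy()
        het = (alleles[:, :, 0] != alleles[:, :, 1]) & ~table.missing
        drop = het & (rng.random(het.shape) < dropout_rate)
        which = rng.integers(0, 2, size=het.shape)
        keep = np.take_along_axis(
            alleles, which[:, :, None], axis=2
        ).squeeze(axis=2)
        for c in range(2):
            alleles[:, :, c] = np.where(drop, keep, alleles[:, :, c])
        mis = (rng.random(alleles.shape) < misscore_rate) & (alleles > 0)
        shift = rng.choice([-1, 1], size=alleles.shape)
        alleles = np.where(mis, np.maximum(alleles + shift, 1), alleles)
        reps.append(
            GenotypeTable(
                ids=table.ids,
                groups=table.groups,
                coords=table.coords,
                loci=list(table.loci),
                alleles=alleles,
                populations=table.populations,
            )
        )
    return reps
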