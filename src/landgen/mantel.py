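"""Simple and partial Mantel tests, pair masking, and the one-class cost sweep.

The Mantel statistic is the Pearson correlation of the unmasked off-diagonal
upper-triangle entries of two conformable pairwise matrices; its null
distribution comes from jointly permuting rows and columns of the first
matrix.  The partial statistic r_AB.C = (r_AB - r_AC r_BC) /
sqrt((1 - r_AC^2)(1 - r_BC^2)) is recomputed for every permutation of A
(genetics treated as the response, geography as fixed design).  When a pair
mask restricts the analysis (e.g. to within-population pairs), permutations
are confined to the mask's connected blocks so that only admissible pairs
ever enter the statistic.

The cost sweep reproduces the one-class experimental design: for every
habitat class and every cost in {10, 50, 100, 1000, 5000, 10000}, the focal
class is priced at that cost (all else 1), least-cost distances are
recomputed, and simple and partial Mantel tests are run against both genetic
metrics, one-tailed in each metric's expected direction (positive for
Rousset's a-hat, negative for Moran's I).  A class is called a barrier
candidate when, at some cost, its least-cost correlations beat the Euclidean
baseline in magnitude with significant p simultaneously for both metrics and
both test kinds.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csgraph, csr_matrix

from landgen.matrices import PairwiseMatrix
from landgen.rasters import LandscapeRaster
from landgen.resistance import build_cost_surface, euclidean_matrix, least_cost_matrix

DEFAULT_COSTS = (10, 50, 100, 1000, 5000, 10000)
METRICS = ("rousset_a", "morans_i")
KINDS = ("simple", "partial")
#: expected correlation direction per genetic metric
METRIC_TAILS = {"rousset_a": "greater", "morans_i": "less"}

_CHUNK = 500  # permutations per vectorised block


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    kind: str
    controlled: str | None = None


@dataclass
class BarrierVerdict:
    flagged: bool
    qualifying_costs: list[float]


@dataclass
class SweepResult:
    classes: list[str]
    costs: list[float]
    entries: dict[tuple[str, float, str, str], MantelResult]
    baselines: dict[tuple[str, str], MantelResult]
    alpha: float = 0.05

    def result(self, cls: str, cost: float, metric: str, kind: str) -> MantelResult:
        return self.entries[(cls, cost, metric, kind)]


# ---------------------------------------------------------------------------
# internals


def _check_conformable(*mats: PairwiseMatrix) -> None:
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise ValueError("matrices must share the same ordered ids")


def _joint_mask(*mats: PairwiseMatrix) -> np.ndarray:
    mask = mats[0].effective_mask().copy()
    for m in mats[1:]:
        mask &= m.effective_mask()
    # drop non-finite entries from every matrix
    for m in mats:
        mask &= np.isfinite(m.values)
    return mask

def _pair_index(mask: np.ndarray):
    n = mask.shape[0]
    iu = np.triu_indices(n, k=1)
    keep = mask[iu]
    return iu[0][keep], iu[1][keep]


def _strata_from_mask(mask: np.ndarray) -> np.ndarray:
    """Connected components of the pair-inclusion graph: permutation blocks."""
    n = mask.shape[0]
    _, labels = csgraph.connected_components(csr_matrix(mask), directed=False)
    return labels


def _permutations(
    n: int, n_perm: int, rng: np.random.Generator, strata: np.ndarray | None
) -> np.ndarray:
    perms = np.tile(np.arange(n), (n_perm, 1))
    if strata is None:
        for t in range(n_perm):
            perms[t] = rng.permutation(n)
        return perms
    for lab in np.unique(strata):
        idx = np.flatnonzero(strata == lab)
        if len(idx) < 2:
            continue
        for t in range(n_perm):
            perms[t, idx] = idx[rng.permutation(len(idx))]
    return perms


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    sx = math.sqrt(float(xs @ xs))
    sy = math.sqrt(float(ys @ ys))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: Mantel r undefined")
    return float(xs @ ys) / (sx * sy)


def _tail_count(null: np.ndarray, obs: float, tail: str) -> int:
    eps = 1e-12
    if tail == "greater":
        return int(np.sum(null >= obs - eps))
    if tail == "less":
        return int(np.sum(null <= obs + eps))
    if tail == "two_sided":
        return int(np.sum(np.abs(null) >= abs(obs) - eps))
    raise ValueError(f"unknown tail {tail!r}")


def _permuted_rows(
    values: np.ndarray, perms: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Gather A[p[i], p[j]] for each permutation p over the kept pair list."""
    return values[perms[:, rows], perms[:, cols]]


# ---------------------------------------------------------------------------
# tests


def mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    n_perm: int = 10000,
    tail: str = "two_sided",
    seed: int | None = None,
    method: str = "mc",
) -> MantelResult:
    """Simple Mantel test between two conformable pairwise matrices.

    ``method='exact'`` enumerates every permutation (small n only) and
    reports the exact tail proportion; the default Monte-Carlo p carries the
    +1 correction and is never exactly 0.
    """
    _check_conformable(A, B)
    mask = _joint_mask(A, B)
    rows, cols = _pair_index(mask)
    if len(np.unique(np.concatenate([rows, cols]))) < 4:
        raise ValueError("need at least 4 units with included pairs")
    x = A.values[rows, cols]
    y = B.values[rows, cols]
    r_obs = _pearson(x, y)
    n = A.n
    strata = _strata_from_mask(mask) if (A.mask is not None or B.mask is not None) else None
    ys = y - y.mean()
    sy = math.sqrt(float(ys @ ys))

    if method == "exact":
        if n > 9:
            raise ValueError("exact enumeration is limited to n <= 9")
        perms = np.array(list(itertools.permutations(range(n))))
        null = _null_r(A.values, perms, rows, cols, ys, sy)
        count = _tail_count(null, r_obs, tail)
        return MantelResult(
            r=r_obs, p=count / len(perms), n_perm=len(perms), tail=tail, kind="simple"
        )

    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < n_perm:
        block = min(_CHUNK, n_perm - done)
        perms = _permutations(n, block, rng, strata)
        null = _null_r(A.values, perms, rows, cols, ys, sy)
        count += _tail_count(null, r_obs, tail)
        done += block
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, tail=tail, kind="simple")


def _null_r(values, perms, rows, cols, ys, sy) -> np.ndarray:
    xp = _permuted_rows(values, perms, rows, cols)
    xc = xp - xp.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ ys) / (sx * sy)
    return np.nan_to_num(r)


def partial_mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    C: PairwiseMatrix,
    n_perm: int = 10000,
    tail: str = "two_sided",
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel test of A vs B controlling C (A is permuted)."""
    _check_conformable(A, B, C)
    mask = _joint_mask(A, B, C)
    rows, cols = _pair_index(mask)
    if len(np.unique(np.concatenate([rows, cols]))) < 4:
        raise ValueError("need at least 4 units with included pairs")
    x = A.values[rows, cols]
    y = B.values[rows, cols]
    z = C.values[rows, cols]
    r_ab = _pearson(x, y)
    r_ac = _pearson(x, z)
    r_bc = _pearson(y, z)
    if abs(r_bc) >= 1.0 - 1e-12:
        if abs(r_ab - r_ac) < 1e-9:
            # full-control limit (B and C carry the same information):
            # numerator and denominator both vanish; the partial is 0 by
            # continuity and carries no evidence
            return MantelResult(
                r=0.0, p=1.0, n_perm=0, tail=tail, kind="partial",
                controlled=C.kind,
            )
        raise ValueError("controlled correlation is +/-1: partial r undefined")
    if abs(r_ac) >= 1.0 - 1e-12:
        raise ValueError("controlled correlation is +/-1: partial r undefined")
    r_obs = _partial_r(r_ab, r_ac, r_bc)
    n = A.n
    strata = (
        _strata_from_mask(mask)
        if any(m.mask is not None for m in (A, B, C))
        else None
    )
    ys = y - y.mean()
    zs = z - z.mean()
    sy = math.sqrt(float(ys @ ys))
    sz = math.sqrt(float(zs @ zs))
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < n_perm:
        block = min(_CHUNK, n_perm - done)
        perms = _permutations(n, block, rng, strata)
        xp = _permuted_rows(A.values, perms, rows, cols)
        xc = xp - xp.mean(axis=1, keepdims=True)
        sx = np.sqrt((xc**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r_ab_p = (xc @ ys) / (sx * sy)
            r_ac_p = (xc @ zs) / (sx * sz)
            null = _partial_r(np.nan_to_num(r_ab_p), np.nan_to_num(r_ac_p), r_bc)
        count += _tail_count(null, r_obs, tail)
        done += block
    p = (1 + count) / (n_perm + 1)
    return MantelResult(
        r=float(r_obs),
        p=float(p),
        n_perm=n_perm,
        tail=tail,
        kind="partial",
        controlled=C.kind,
    )


def _partial_r(r_ab, r_ac, r_bc):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    return out


# ---------------------------------------------------------------------------
# pair restriction


def restrict_pairs(
    matrix: PairwiseMatrix, membership: dict[str, str]
) -> PairwiseMatrix:
    """Mask a matrix down to same-population pairs.

    The resulting mask intersects any existing mask; downstream Mantel tests
    then permute individuals only within populations.
    """
    missing = [i for i in matrix.ids if i not in membership]
    if missing:
        raise ValueError(f"membership lacks ids {missing}")
    pops = np.array([membership[i] for i in matrix.ids], dtype=object)
    same = pops[:, None] == pops[None, :]
    np.fill_diagonal(same, False)
    for pop in np.unique(pops):
        if (pops == pop).sum() < 4:
            warnings.warn(
                f"population {pop!r} has <4 members; Mantel tests on it alone "
                "will be refused"
            )
    if matrix.mask is not None:
        same &= matrix.mask
    return matrix.with_mask(same)


# ---------------------------------------------------------------------------
# cost sweep and barrier verdict


def cost_sweep(
    genetic: dict[str, PairwiseMatrix],
    raster: LandscapeRaster,
    coords: np.ndarray,
    classes: list[str],
    costs=DEFAULT_COSTS,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> SweepResult:
    """One-class cost sweep: class x cost grid of Mantel results.

    ``genetic`` maps metric name ('rousset_a', 'morans_i') to an
    individual-level matrix whose ids align with ``coords`` (one coordinate
    row per individual).  For every class x cost the focal surface is built,
    least-cost distances recomputed, and four tests run: simple and partial
    (controlling Euclidean) Mantel against each metric, one-tailed in the
    metric's expected direction.  Euclidean baselines are computed once.
    """
    for metric in METRICS:
        if metric not in genetic:
            raise ValueError(f"genetic matrices must include {metric!r}")
    ids = genetic[METRICS[0]].ids
    _check_conformable(*(genetic[m] for m in METRICS))
    coords = np.asarray(coords, dtype=float)
    if len(coords) != len(ids):
        raise ValueError("one coordinate row per individual required")
    rng = np.random.default_rng(seed)
    euclid = euclidean_matrix(coords, ids=ids)

    baselines: dict[tuple[str, str], MantelResult] = {}
    for metric in METRICS:
        base = mantel(
            genetic[metric],
            euclid,
            n_perm=n_perm,
            tail=METRIC_TAILS[metric],
            seed=int(rng.integers(2**31)),
        )
        baselines[(metric, "simple")] = base
        # the partial statistic already nets out the Euclidean component, so
        # its reference is the zero-correlation line: a partial r
        # significantly in the expected direction marks information beyond
        # Euclidean distance
        baselines[(metric, "partial")] = MantelResult(
            r=0.0, p=1.0, n_perm=0, tail=METRIC_TAILS[metric], kind="partial",
            controlled="euclidean",
        )

    entries: dict[tuple[str, float, str, str], MantelResult] = {}
    for cls in classes:
        for cost in costs:
            surface = build_cost_surface(raster, cls, cost)
            lc = least_cost_matrix(surface, coords, ids=ids)
            for metric in METRICS:
                tail = METRIC_TAILS[metric]
                entries[(cls, cost, metric, "simple")] = mantel(
                    genetic[metric],
                    lc,
                    n_perm=n_perm,
                    tail=tail,
                    seed=int(rng.integers(2**31)),
                )
                entries[(cls, cost, metric, "partial")] = partial_mantel(
                    genetic[metric],
                    lc,
                    euclid,
                    n_perm=n_perm,
                    tail=tail,
                    seed=int(rng.integers(2**31)),
                )
    return SweepResult(
        classes=list(classes),
        costs=[float(c) for c in costs],
        entries=entries,
        baselines=baselines,
        alpha=alpha,
    )


def barrier_call(sweep: SweepResult) -> dict[str, BarrierVerdict]:
    """Barrier verdict per habitat class.

    A class is a barrier candidate iff at some cost every one of the four
    cells (2 metrics x 2 test kinds) has |r| strictly above the Euclidean
    baseline magnitude with p below the sweep's alpha.
    """
    verdicts = {}
    for cls in sweep.classes:
        qualifying = []
        for cost in sweep.costs:
            ok = True
            for metric in METRICS:
                for kind in KINDS:
                    res = sweep.entries[(cls, cost, metric, kind)]
                    base = sweep.baselines[(metric, kind)]
                    if not (abs(res.r) > abs(base.r) and res.p < sweep.alpha):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                qualifying.append(cost)
        verdicts[cls] = BarrierVerdict(
            flagged=bool(qualifying), qualifying_costs=qualifying
        )
    return verdicts
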