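"""Mantel machinery, pair restriction, cost sweep and barrier verdict."""

import numpy as np
import pytest

from landgen.mantel import (
    BarrierVerdict,
    MantelResult,
    SweepResult,
    barrier_call,
    cost_sweep,
    mantel,
    partial_mantel,
    restrict_pairs,
)
from landgen.matrices import PairwiseMatrix
from landgen.rasters import LandscapeRaster


def sym(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def pm(values, kind="euclidean", mask=None):
    ids = [str(i) for i in range(values.shape[0])]
    return PairwiseMatrix(ids, values, kind, mask)


class TestMantel:
    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(0)
        A = pm(sym(rng, 8))
        B = pm(A.values.copy(), "least_cost")
        assert mantel(A, B, n_perm=99, seed=1).r == pytest.approx(1.0)

    def test_negative_affine_gives_minus_one(self):
        rng = np.random.default_rng(0)
        A = pm(sym(rng, 8))
        B = pm(5.0 - 2.0 * A.values, "least_cost")
        # keep B symmetric with zero-ish diagonal irrelevance
        np.fill_diagonal(B.values, 0.0)
        assert mantel(A, B, n_perm=99, seed=1).r == pytest.approx(-1.0)

    def test_monte_carlo_approaches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        A = pm(sym(rng, 5))
        B = pm(sym(rng, 5), "least_cost")
        exact = mantel(A, B, method="exact", tail="greater")
        assert exact.n_perm == 120
        mc = mantel(A, B, n_perm=20000, tail="greater", seed=2)
        assert mc.p == pytest.approx(exact.p, abs=0.02)
        assert mc.r == pytest.approx(exact.r)

    def test_zero_variance_is_an_error(self):
        A = pm(np.zeros((5, 5)) + 1.0 - np.eye(5))
        B = pm(sym(np.random.default_rng(0), 5), "least_cost")
        with pytest.raises(ValueError, match="zero variance"):
            mantel(A, B, n_perm=9, seed=0)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(7)
        A, B = sym(rng, 7), sym(rng, 7)
        r1 = mantel(pm(A), pm(B, "least_cost"), n_perm=9, seed=0).r
        perm = rng.permutation(7)
        r2 = mantel(
            pm(A[perm][:, perm]), pm(B[perm][:, perm], "least_cost"),
            n_perm=9, seed=0,
        ).r
        assert r1 == pytest.approx(r2)


class TestPartialMantel:
    def test_uncorrelated_control_collapses_to_simple(self):
        rng = np.random.default_rng(1)
        A = pm(sym(rng, 40))
        B = pm(sym(rng, 40), "least_cost")
        C = pm(sym(rng, 40), "resistance")
        simple = mantel(A, B, n_perm=9, seed=0).r
        partial = partial_mantel(A, B, C, n_perm=9, seed=0).r
        # r_AC, r_BC are near 0 at n=40, so the partial nearly equals r_AB
        assert partial == pytest.approx(simple, abs=0.05)

    def test_full_control_gives_zero(self):
        rng = np.random.default_rng(2)
        A = pm(sym(rng, 8))
        B = pm(sym(rng, 8), "least_cost")
        r = partial_mantel(A, B, pm(B.values.copy(), "resistance"), n_perm=9, seed=0)
        assert r.r == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_formula(self):
        rng = np.random.default_rng(3)
        A, B, C = sym(rng, 6), sym(rng, 6), sym(rng, 6)
        iu = np.triu_indices(6, k=1)
        x, y, z = A[iu], B[iu], C[iu]
        r_ab = np.corrcoef(x, y)[0, 1]
        r_ac = np.corrcoef(x, z)[0, 1]
        r_bc = np.corrcoef(y, z)[0, 1]
        expect = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        got = partial_mantel(
            pm(A), pm(B, "least_cost"), pm(C, "resistance"), n_perm=9, seed=0
        ).r
        assert got == pytest.approx(expect, abs=1e-12)

    def test_degenerate_control_is_an_error(self):
        rng = np.random.default_rng(4)
        A = pm(sym(rng, 6))
        B = pm(sym(rng, 6), "least_cost")
        with pytest.raises(ValueError, match="partial r undefined"):
            partial_mantel(A, B, pm(A.values.copy(), "resistance"), n_perm=9, seed=0)


class TestRestrictPairs:
    def test_within_pair_combinatorics(self):
        rng = np.random.default_rng(0)
        n = 14
        ids = [str(i) for i in range(n)]
        member = {ids[i]: ("x" if i < 5 else "y") for i in range(n)}
        m = restrict_pairs(pm(sym(rng, n)), member)
        assert m.mask.sum() // 2 == 10 + 36  # C(5,2) + C(9,2)

    def test_single_population_keeps_all_pairs(self):
        rng = np.random.default_rng(1)
        m = restrict_pairs(pm(sym(rng, 6)), {str(i): "x" for i in range(6)})
        assert m.mask.sum() == 6 * 5

    def test_between_pair_entries_never_affect_r(self):
        rng = np.random.default_rng(2)
        A = sym(rng, 10)
        B = sym(rng, 10)
        member = {str(i): ("x" if i < 5 else "y") for i in range(10)}
        mA = restrict_pairs(pm(A), member)
        r1 = mantel(mA, pm(B, "least_cost"), n_perm=49, seed=3)
        A2 = A.copy()
        A2[0, 7] = A2[7, 0] = 99.0  # a between-population pair
        mA2 = restrict_pairs(pm(A2), member)
        r2 = mantel(mA2, pm(B, "least_cost"), n_perm=49, seed=3)
        assert r1.r == r2.r and r1.p == r2.p


def small_genetic(rng, n):
    a = pm(sym(rng, n), "rousset_a")
    i = pm(sym(rng, n), "morans_i")
    return {"rousset_a": a, "morans_i": i}


class TestCostSweep:
    def test_grid_is_complete(self):
        rng = np.random.default_rng(0)
        raster = LandscapeRaster(
            data=np.ones((10, 10), dtype=int), xllcorner=0, yllcorner=0,
            cellsize=20,
        )
        raster.data[4:6, :] = 2
        coords = np.column_stack(
            [rng.uniform(10, 190, 8), rng.uniform(10, 190, 8)]
        )
        sweep = cost_sweep(
            small_genetic(rng, 8), raster, coords,
            classes=["oil_palm", "pasture"], costs=(10, 50), n_perm=49, seed=0,
        )
        assert len(sweep.entries) == 2 * 2 * 2 * 2
        assert len(sweep.baselines) == 4

    def test_one_class_raster_collapses_to_baseline(self):
        # all-forest raster: every focal surface is constant, so the sweep r
        # is identical across classes and costs (the chamfer geometry is the
        # same scaled matrix) and, for axis-aligned points, equals the
        # Euclidean baseline exactly
        rng = np.random.default_rng(1)
        raster = LandscapeRaster(
            data=np.ones((6, 20), dtype=int), xllcorner=0, yllcorner=0,
            cellsize=20,
        )
        # points on one row: chamfer == Euclidean
        cols = [1, 4, 7, 10, 13, 16]
        coords = np.array([raster.rowcol_to_xy(3, c) for c in cols])
        genetic = small_genetic(rng, 6)
        sweep = cost_sweep(
            genetic, raster, coords, classes=["forest"],
            costs=(10, 1000), n_perm=49, seed=0,
        )
        for metric in ("rousset_a", "morans_i"):
            base = sweep.baselines[(metric, "simple")].r
            for cost in (10.0, 1000.0):
                got = sweep.entries[("forest", cost, metric, "simple")].r
                assert got == pytest.approx(base, abs=1e-12)


def make_sweep(cells, base_r=0.2):
    baselines = {}
    for metric in ("rousset_a", "morans_i"):
        sign = 1 if metric == "rousset_a" else -1
        baselines[(metric, "simple")] = MantelResult(
            r=sign * base_r, p=0.001, n_perm=999, tail="greater", kind="simple"
        )
        baselines[(metric, "partial")] = MantelResult(
            r=0.0, p=1.0, n_perm=0, tail="greater", kind="partial"
        )
    entries = {}
    for (cls, cost), (r_gain, p) in cells.items():
        for metric in ("rousset_a", "morans_i"):
            sign = 1 if metric == "rousset_a" else -1
            for kind in ("simple", "partial"):
                ref = base_r if kind == "simple" else 0.0
                entries[(cls, cost, metric, kind)] = MantelResult(
                    r=sign * (ref + r_gain), p=p, n_perm=999,
                    tail="greater", kind=kind,
                )
    classes = sorted({c for c, _ in cells})
    costs = sorted({c for _, c in cells})
    return SweepResult(classes=classes, costs=costs, entries=entries,
                       baselines=baselines, alpha=0.05)


class TestBarrierCall:
    def test_consistent_winner_flagged_with_cost(self):
        sweep = make_sweep({("palmlike", 10.0): (0.08, 0.001),
                            ("palmlike", 50.0): (-0.05, 0.4)})
        sweep.classes = ["palmlike"]
        v = barrier_call(sweep)["palmlike"]
        assert v.flagged and v.qualifying_costs == [10.0]

    def test_single_metric_success_not_flagged(self):
        sweep = make_sweep({("palmlike", 10.0): (0.08, 0.001)})
        # degrade the Moran cells: below baseline magnitude
        for kind in ("simple", "partial"):
            sweep.entries[("palmlike", 10.0, "morans_i", kind)] = MantelResult(
                r=-0.01, p=0.2, n_perm=999, tail="less", kind=kind
            )
        assert not barrier_call(sweep)["palmlike"].flagged

    def test_all_equal_sweep_never_flags(self):
        sweep = make_sweep({("a", 10.0): (0.0, 0.5), ("b", 10.0): (0.0, 0.5)})
        assert not any(v.flagged for v in barrier_call(sweep).values())


def test_type_one_error_calibration_small():
    """Independent matrices: rejection at alpha=0.05 stays near nominal.

    A reduced version of the full calibration run (which the acceptance
    suite performs at 2000 replicates)."""
    rng = np.random.default_rng(123)
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        A = pm(sym(rng, 15))
        B = pm(sym(rng, 15), "least_cost")
        res = mantel(A, B, n_perm=99, tail="two_sided",
                     seed=int(rng.integers(2**31)))
        rejections += res.p < 0.05
    assert 0.02 <= rejections / n_rep <= 0.09
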