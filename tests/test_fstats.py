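"""Weir-Cockerham theta: oracle agreement, permutation p, summaries."""

import itertools

import numpy as np
import pytest

from landgen.fixtures import load_fst_fixture
from landgen.fstats import (
    bonferroni_threshold,
    fst_partition_summary,
    pairwise_fst,
    wc_theta,
)
from landgen.genotypes import GenotypeTable
from landgen.matrices import PairwiseMatrix
from tests.conftest import make_table


def oracle_theta(alleles_by_locus, labels):
    """Independent implementation of the 1984 variance components,
    written against the published component formulas, looped naively."""
    labels = np.asarray(labels, dtype=object)
    num = den = 0.0
    for alleles in alleles_by_locus:
        alleles = np.asarray(alleles)
        keep = ~(alleles == 0).all(axis=1)
        a = alleles[keep]
        lab = labels[keep]
        groups = sorted(set(lab))
        r = len(groups)
        if r < 2:
            continue
        n_i = np.array([float((lab == g).sum()) for g in groups])
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        for allele in sorted(set(a.reshape(-1))):
            p_i = []
            h_i = []
            for g in groups:
                ag = a[lab == g]
                p_i.append((ag == allele).sum() / (2.0 * len(ag)))
                h_i.append(((ag == allele).sum(axis=1) == 1).mean())
            p_i, h_i = np.array(p_i), np.array(h_i)
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            if pbar in (0.0, 1.0) and s2 == 0:
                continue
            A = (nbar / nc) * (
                s2
                - 1.0
                / (nbar - 1)
                * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
            )
            B = (
                nbar
                / (nbar - 1)
                * (
                    pbar * (1 - pbar)
                    - (r - 1) / r * s2
                    - (2 * nbar - 1) / (4 * nbar) * hbar
                )
            )
            C = hbar / 2.0
            num += A
            den += A + B + C
    return num / den


class TestTheta:
    def test_fixed_differences_give_one(self):
        t = make_table([[1, 1]] * 5 + [[2, 2]] * 5, ["a"] * 5 + ["b"] * 5)
        assert wc_theta(t) == pytest.approx(1.0)

    def test_duplicated_group_is_noise_around_zero(self):
        rng = np.random.default_rng(7)
        g = rng.integers(1, 5, size=(10, 3, 2))
        t = GenotypeTable(
            ids=[f"i{k}" for k in range(20)],
            groups=["a"] * 10 + ["b"] * 10,
            coords=np.zeros((20, 2)),
            loci=["L0", "L1", "L2"],
            alleles=np.vstack([g, g]),
        )
        assert wc_theta(t) <= 0.05

    def test_matches_independent_component_oracle(self):
        rng = np.random.default_rng(11)
        rows = rng.integers(1, 6, size=(20, 1, 2))
        labels = ["a"] * 10 + ["b"] * 10
        t = make_table(rows, labels)
        expected = oracle_theta([rows[:, 0, :]], labels)
        assert wc_theta(t) == pytest.approx(expected, abs=1e-12)

    def test_oracle_agreement_multilocus_with_missing(self):
        rng = np.random.default_rng(5)
        rows = rng.integers(1, 5, size=(24, 4, 2))
        rows[rng.random((24, 4)) < 0.15] = 0
        labels = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        t = make_table(rows, labels)
        expected = oracle_theta(
            [rows[:, j, :] for j in range(4)], labels
        )
        assert wc_theta(t) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_allele_relabelling_and_group_order(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(1, 5, size=(16, 2, 2))
        labels = ["a"] * 8 + ["b"] * 8
        t = make_table(rows, labels)
        base = wc_theta(t)
        relab = rows.copy()
        relab[rows == 1], relab[rows == 4] = 4, 1  # swap two allele labels
        assert wc_theta(make_table(relab, labels)) == pytest.approx(base, abs=1e-12)
        perm = np.concatenate([np.arange(8, 16), np.arange(8)])
        assert wc_theta(t.subset(perm)) == pytest.approx(base, abs=1e-12)

    def test_monomorphic_everywhere_is_an_error(self):
        t = make_table([[1, 1]] * 6, ["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="no polymorphic locus"):
            wc_theta(t)


class TestPairwise:
    def test_exhaustive_three_vs_three_enumeration(self):
        # 3 vs 3 individuals: the permutation p at large n_perm approaches
        # the exhaustive C(6,3)=20-split enumeration
        rows = [[1, 1], [1, 2], [2, 2], [2, 2], [2, 3], [3, 3]]
        labels = ["a"] * 3 + ["b"] * 3
        t = make_table(rows, labels)
        obs = wc_theta(t)
        arr = np.array(rows)[:, None, :]
        splits = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6, dtype=object)
            lab[list(combo)] = "a"
            splits.append(oracle_theta([arr[:, 0, :]], lab))
        exact = np.mean([s >= obs - 1e-12 for s in splits])
        res = pairwise_fst(t, n_perm=4000, seed=1)[0]
        assert res.theta == pytest.approx(obs)
        assert res.p == pytest.approx(exact, abs=0.03)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for seed in range(40):
            rows = rng.integers(1, 5, size=(16, 2, 2))
            t = make_table(rows, ["a"] * 8 + ["b"] * 8)
            ps.append(pairwise_fst(t, n_perm=199, seed=seed)[0].p)
        ps = np.array(ps)
        # +1-corrected p under the null: no mass at 0, roughly uniform
        assert ps.min() > 0
        assert 0.25 < ps.mean() < 0.75

    def test_bonferroni_threshold_matches_published_rounding(self):
        assert bonferroni_threshold(14) == pytest.approx(0.05 / 91)
        assert round(bonferroni_threshold(14), 4) == 0.0005

    def test_small_unit_skipped_with_warning(self):
        t = make_table([[1, 2]] * 5 + [[2, 2]], ["a"] * 5 + ["b"])
        with pytest.warns(UserWarning, match="<2 individuals"):
            assert pairwise_fst(t, n_perm=10, seed=0) == []


class TestPartitionSummary:
    def test_constant_matrix(self):
        v = np.full((4, 4), 0.3)
        np.fill_diagonal(v, 0)
        m = PairwiseMatrix(list("abcd"), v, "fst")
        s = fst_partition_summary(m, {"a": "x", "b": "x", "c": "y", "d": "y"})
        assert s.overall == (0.3, 0.3, 0.3)
        assert s.same == (0.3, 0.3, 0.3)
        assert s.different == (0.3, 0.3, 0.3)

    def test_single_population_between_empty(self):
        v = np.full((3, 3), 0.1)
        np.fill_diagonal(v, 0)
        m = PairwiseMatrix(list("abc"), v, "fst")
        s = fst_partition_summary(m, {"a": "x", "b": "x", "c": "x"})
        assert s.different is None

    def test_published_fixture_summaries(self):
        fx = load_fst_fixture()
        s = fst_partition_summary(
            fx.as_pairwise_matrix(), fx.population_of, digits=2
        )
        assert s.same[0] == 0.06 and s.different[0] == 0.14
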