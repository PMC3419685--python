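"""Packaged reference data: published pairwise F_ST among squirrel-monkey groups.

The fixture carries the published pairwise Weir-Cockerham F_ST estimates among
the 14 sampled groups of the Central American squirrel monkey
(*Saimiri oerstedii citrinellus*) from the Central Pacific of Costa Rica,
together with per-pair significance flags (Bonferroni-corrected permutation
tests), per-group sample sizes, and the western/eastern population partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from landgen.matrices import PairwiseMatrix

WESTERN_GROUPS = ("E", "G", "K", "O", "PD")
EASTERN_GROUPS = ("B", "C", "H", "I", "M", "P", "R", "T", "V")
GROUP_ORDER = WESTERN_GROUPS + EASTERN_GROUPS


@dataclass
class FstFixture:
    """Published 14-group pairwise F_ST matrix with metadata."""

    group_ids: list[str]
    fst: np.ndarray            # (14, 14) symmetric, nan diagonal
    significant: np.ndarray    # (14, 14) symmetric bool
    n: dict[str, int]          # per-group sample size
    population_of: dict[str, str]  # group -> "western" | "eastern"

    def fst_of(self, a: str, b: str) -> float:
        return float(self.fst[self.group_ids.index(a), self.group_ids.index(b)])

    def as_pairwise_matrix(self) -> PairwiseMatrix:
        return PairwiseMatrix(ids=self.group_ids, values=self.fst, kind="fst")

    @property
    def n_total(self) -> int:
        return sum(self.n.values())


def _data_path(name: str):
    return resources.files("landgen.data").joinpath(name)


def load_fst_fixture() -> FstFixture:
    """Load the packaged published pairwise F_ST fixture.

    Returns the full 91-pair matrix (upper and lower triangles mirrored),
    per-pair significance at the Bonferroni-corrected threshold, per-group
    sample sizes, and the western/eastern partition.
    """
    pairs = pd.read_csv(_data_path("saimiri_fst_pairs.csv"))
    meta = pd.read_csv(_data_path("saimiri_groups.csv"))
    ids = list(GROUP_ORDER)
    k = len(ids)
    fst = np.full((k, k), np.nan)
    sig = np.zeros((k, k), dtype=bool)
    for _, row in pairs.iterrows():
        i, j = ids.index(row["group1"]), ids.index(row["group2"])
        fst[i, j] = fst[j, i] = row["fst"]
        sig[i, j] = sig[j, i] = bool(row["significant"])
    n = dict(zip(meta["group"], meta["n"].astype(int)))
    pop = dict(zip(meta["group"], meta["population"]))
    if len(pairs) != k * (k - 1) // 2:
        raise ValueError("fixture must contain exactly 91 pairs")
    return FstFixture(group_ids=ids, fst=fst, significant=sig, n=n, population_of=pop)
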