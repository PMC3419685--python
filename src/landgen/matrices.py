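"""Symmetric pairwise distance/similarity matrices with optional pair masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KINDS = {"rousset_a", "morans_i", "euclidean", "least_cost", "resistance", "fst"}


@dataclass
class PairwiseMatrix:
    """Symmetric matrix over ordered labels; the diagonal carries no meaning.

    ``mask``, when present, is a symmetric boolean matrix marking which pairs
    participate in downstream statistics; it never selects the diagonal.
    """

    ids: list[str]
    values: np.ndarray
    kind: str
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if self.kind not in KINDS:
            raise ValueError(f"kind {self.kind!r} not one of {sorted(KINDS)}")
        offdiag = ~np.eye(n, dtype=bool)
        v, vt = self.values[offdiag], self.values.T[offdiag]
        finite = np.isfinite(v) & np.isfinite(vt)
        if not np.array_equal(np.isfinite(v), np.isfinite(vt)) or not np.allclose(
            v[finite], vt[finite]
        ):
            raise ValueError("values must be symmetric off the diagonal")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n, n):
                raise ValueError("mask shape mismatch")
            if not np.array_equal(self.mask, self.mask.T):
                raise ValueError("mask must be symmetric")
            if self.mask[np.diag_indices(n)].any():
                raise ValueError("mask must not select the diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def effective_mask(self) -> np.ndarray:
        """Pair-inclusion mask: the explicit mask, or all off-diagonal pairs."""
        off = ~np.eye(self.n, dtype=bool)
        return off if self.mask is None else (self.mask & off)

    def upper_values(self) -> np.ndarray:
        """Included upper-triangle entries, row-major order."""
        iu = np.triu_indices(self.n, k=1)
        keep = self.effective_mask()[iu]
        return self.values[iu][keep]

    def with_mask(self, mask: np.ndarray) -> "PairwiseMatrix":
        return PairwiseMatrix(self.ids, self.values, self.kind, mask)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str) -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(c) for c in df.columns], values=df.to_numpy(), kind=kind)
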