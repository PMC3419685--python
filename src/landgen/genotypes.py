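"""Diploid microsatellite genotype tables and their on-disk dialects.

Two dialects are supported: classic GenePop text (3-digit allele codes,
``Pop`` separators, ``000000`` missing) for interoperability with the
population-genetics program ecosystem, and a lossless native CSV with one row
per individual carrying id, group, optional population, projected x/y
coordinates in metres, and a ``<locus>_a`` / ``<locus>_b`` column pair per
locus.  GenePop carries no coordinates, so only the CSV dialect round-trips a
table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = 0  # sentinel allele size; a call is missing iff both alleles are 0


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates its dialect."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele-size calls with spatial metadata.

    Parameters
    ----------
    ids : array of str, shape (n,)
        Unique individual identifiers.
    groups : array of str, shape (n,)
        Sampling-group label per individual (non-empty).
    coords : array of float, shape (n, 2)
        Projected x/y coordinates in metres (planar CRS assumed).
    loci : list of str
        Locus names, shared by every individual.
    alleles : int array, shape (n, n_loci, 2)
        Allele sizes (positive integers); both entries 0 encode a missing
        call.  Pairs are stored order-free: (a, b) is normalised to a <= b.
    populations : array of str or None
        Optional higher-level population label per individual.
    """

    ids: np.ndarray
    groups: np.ndarray
    coords: np.ndarray
    loci: list[str]
    alleles: np.ndarray
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=object)
        n = len(self.ids)
        if self.alleles.shape != (n, len(self.loci), 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {len(self.loci)}, 2)"
            )
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 2)")
        if not np.all(np.isfinite(self.coords)):
            bad = self.ids[~np.isfinite(self.coords).all(axis=1)]
            raise ValueError(f"non-finite coordinates for individuals {list(bad)}")
        if any(not g for g in self.groups):
            raise ValueError("empty group label")
        # normalise pair order and enforce no half-calls
        self.alleles = np.sort(self.alleles, axis=2)
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-call (one allele missing) for {self.ids[i]} at {self.loci[l]}"
            )
        if (self.alleles < 0).any():
            raise ValueError("negative allele size")

    # ---- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing(self) -> np.ndarray:
        """Boolean (n, n_loci) mask, True where the call is missing."""
        return (self.alleles == MISSING).all(axis=2)

    def group_ids(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.groups))

    def subset(self, index: np.ndarray) -> "GenotypeTable":
        """Row-subset (boolean mask or integer index array)."""
        idx = np.asarray(index)
        return GenotypeTable(
            ids=self.ids[idx],
            groups=self.groups[idx],
            coords=self.coords[idx],
            loci=list(self.loci),
            alleles=self.alleles[idx],
            populations=None if self.populations is None else self.populations[idx],
        )

    def group_subset(self, group: str) -> "GenotypeTable":
        return self.subset(self.groups == group)

    def group_coords(self) -> dict[str, np.ndarray]:
        """Mean coordinate per group, in first-appearance order."""
        return {
            g: self.coords[self.groups == g].mean(axis=0) for g in self.group_ids()
        }

    def allele_counts(self, locus: int, index: np.ndarray | None = None):
        """(alleles, counts) over non-missing calls at one locus."""
        a = self.alleles[:, locus, :] if index is None else self.alleles[index][:, locus, :]
        flat = a.reshape(-1)
        flat = flat[flat != MISSING]
        return np.unique(flat, return_counts=True)

    # ---- CSV dialect (lossless native) -----------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, object] = {
            "id": self.ids,
            "group": self.groups,
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
        }
        if self.populations is not None:
            data["population"] = self.populations
        for j, locus in enumerate(self.loci):
            data[f"{locus}_a"] = self.alleles[:, j, 0]
            data[f"{locus}_b"] = self.alleles[:, j, 1]
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeTable":
        required = {"id", "group", "x", "y"}
        if not required.issubset(df.columns):
            raise GenotypeParseError(f"missing columns {required - set(df.columns)}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        bad = ~np.isfinite(xy).all(axis=1)
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise GenotypeParseError(
                f"non-finite coordinate in row {row} (id={df['id'].iloc[row]!r})"
            )
        locus_cols = [c for c in df.columns if c.endswith("_a")]
        loci = [c[:-2] for c in locus_cols]
        for locus in loci:
            if f"{locus}_b" not in df.columns:
                raise GenotypeParseError(f"locus {locus} lacks a _b column")
        n = len(df)
        alleles = np.zeros((n, len(loci), 2), dtype=np.int64)
        for j, locus in enumerate(loci):
            for k, suf in enumerate("ab"):
                col = pd.to_numeric(df[f"{locus}_{suf}"], errors="coerce")
                alleles[:, j, k] = col.fillna(MISSING).to_numpy(dtype=np.int64)
        populations = (
            df["population"].to_numpy(dtype=object) if "population" in df.columns else None
        )
        return cls(
            ids=df["id"].astype(str).to_numpy(dtype=object),
            groups=df["group"].astype(str).to_numpy(dtype=object),
            coords=xy,
            loci=loci,
            alleles=alleles,
            populations=populations,
        )

    @classmethod
    def read_csv(cls, path) -> "GenotypeTable":
        return cls.from_dataframe(pd.read_csv(path))

    # ---- GenePop dialect --------------------------------------------------

    def write_genepop(self, path, title: str = "landgen export") -> None:
        """Write GenePop text with 3-digit allele codes, one Pop per group."""
        if (self.alleles > 999).any():
            raise ValueError("allele size exceeds the 3-digit GenePop code width")
        lines = [title]
        lines.extend(self.loci)
        for g in self.group_ids():
            lines.append("Pop")
            for i in np.flatnonzero(self.groups == g):
                codes = " ".join(
                    f"{self.alleles[i, j, 0]:03d}{self.alleles[i, j, 1]:03d}"
                    for j in range(self.n_loci)
                )
                lines.append(f"{self.groups[i]}:{self.ids[i]} , {codes}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def read_genepop(cls, path) -> "GenotypeTable":
        """Parse GenePop text (3-digit codes).  Coordinates default to 0."""
        with open(path) as fh:
            raw = [ln.rstrip("\n") for ln in fh]
        lines = [ln for ln in raw if ln.strip()]
        if len(lines) < 3:
            raise GenotypeParseError("truncated GenePop file")
        # locus list: one per line until the first Pop, or comma-separated
        loci: list[str] = []
        i = 1
        while i < len(lines) and lines[i].strip().lower() != "pop":
            part = lines[i].strip()
            loci.extend(s.strip() for s in part.split(",") if s.strip())
            i += 1
        if i == len(lines):
            raise GenotypeParseError("no Pop separator found")
        ids: list[str] = []
        groups: list[str] = []
        rows: list[list[tuple[int, int]]] = []
        pop_index = 0
        for lineno, line in enumerate(lines[i:], start=i + 1):
            if line.strip().lower() == "pop":
                pop_index += 1
                continue
            if "," not in line:
                raise GenotypeParseError(f"line {lineno}: expected 'name , codes'")
            name, codes_str = line.split(",", 1)
            name = name.strip()
            if ":" in name:
                group, ind = name.split(":", 1)
            else:
                group, ind = f"pop{pop_index}", name
            codes = codes_str.split()
            if len(codes) != len(loci):
                raise GenotypeParseError(
                    f"line {lineno}: {len(codes)} genotypes for {len(loci)} loci"
                )
            calls = []
            for code in codes:
                if len(code) != 6 or not code.isdigit():
                    raise GenotypeParseError(
                        f"line {lineno}: allele code {code!r} is not 6 digits"
                    )
                calls.append((int(code[:3]), int(code[3:])))
            ids.append(ind)
            groups.append(group)
            rows.append(calls)
        alleles = np.array(rows, dtype=np.int64)
        n = len(ids)
        return cls(
            ids=np.array(ids, dtype=object),
            groups=np.array(groups, dtype=object),
            coords=np.zeros((n, 2)),
            loci=loci,
            alleles=alleles,
        )


def read_genotypes(path, format: str = "csv") -> GenotypeTable:
    """Read a genotype table in the ``genepop`` or ``csv`` dialect."""
    if format == "csv":
        return GenotypeTable.read_csv(path)
    if format == "genepop":
        return GenotypeTable.read_genepop(path)
    raise ValueError(f"unknown genotype format {format!r}")
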