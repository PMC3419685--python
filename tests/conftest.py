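import numpy as np
import pytest

from landgen.genotypes import GenotypeTable
from landgen.rasters import LandscapeRaster


def make_table(rows, groups, coords=None, loci=None, populations=None):
    """Small genotype-table helper: rows is (n, L, 2) nested lists."""
    alleles = np.asarray(rows)
    if alleles.ndim == 2:
        alleles = alleles[:, None, :]
    n, L, _ = alleles.shape
    return GenotypeTable(
        ids=[f"i{k}" for k in range(n)],
        groups=list(groups),
        coords=np.zeros((n, 2)) if coords is None else np.asarray(coords, float),
        loci=[f"L{j}" for j in range(L)] if loci is None else loci,
        alleles=alleles,
        populations=populations,
    )


@pytest.fixture
def hw_table():
    """One group, one locus at exact Hardy-Weinberg proportions
    (25 AA, 50 AB, 25 BB)."""
    rows = [[1, 1]] * 25 + [[1, 2]] * 50 + [[2, 2]] * 25
    return make_table(rows, ["g"] * 100)


@pytest.fixture
def uniform_raster():
    return LandscapeRaster(
        data=np.ones((12, 12), dtype=int), xllcorner=0.0, yllcorner=0.0, cellsize=20.0
    )
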