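# landgen

Landscape genetics for fragmented populations typed at microsatellite loci.

`landgen` addresses a question conservation geneticists face in
human-modified landscapes: **which classes of unsuitable "matrix" habitat —
oil-palm plantation, cattle pasture, river, residential area — actually
impede gene flow between forest fragments, and at what spatial scale?**  The
package re-implements, as one tested Python pipeline, the analysis chain
used to answer that question for the endangered Central American squirrel
monkey (*Saimiri oerstedii citrinellus*) in the Central Pacific of Costa
Rica: from raw replicate allele calls on fecal DNA through population
structure, individual-based landscape genetics, and the scale-dependent
barrier verdict.

## What is inside

- **Genotype QC** (`landgen.qc`): multi-tube consensus genotyping
  (heterozygotes accepted at ≥4 concordant replicates, homozygotes at ≥7),
  DNA-concentration admission (mean over two runs > 0.5 ng/µl), permutation
  Hardy–Weinberg tests, Brookfield-1 null-allele screen.
- **F-statistics** (`landgen.fstats`): Weir–Cockerham θ combined over loci as
  Σa/Σ(a+b+c), pairwise permutation tests that randomise whole diploid
  genotypes (no HWE assumption), Bonferroni thresholds, partition summaries.
  A packaged fixture carries the published 14-group pairwise F_ST matrix
  (91 pairs, N = 233 individuals) with its western/eastern partition.
- **Individual genetic distance** (`landgen.gendist`): Rousset's â
  (allelic identity within vs between individuals, ratio-of-sums over loci)
  and Moran's I genetic similarity (allele-frequency autocorrelation).
- **Geographic distances** (`landgen.resistance`): least-cost distances on
  8-connected cost grids (move cost = cellsize·(c₁+c₂)/2, ×√2 diagonal),
  circuit-theory effective resistance and all-to-one cumulative current maps
  via sparse Laplacian solves, Euclidean distances, and the residential-area
  rule (clusters of residences <100 m apart totalling >3 ha).
- **Mantel machinery** (`landgen.mantel`): simple and partial Mantel tests
  (r_AB·C = (r_AB − r_AC·r_BC)/√((1−r_AC²)(1−r_BC²))) with 10,000-permutation
  defaults, within-population pair masking, the one-class cost sweep over
  costs {10, 50, 100, 1000, 5000, 10000}, and the barrier verdict: a class is
  a barrier candidate only if, at some cost, least-cost distances beat the
  Euclidean baseline for **both** genetic metrics in **both** simple and
  partial tests.
- **Clustering & migrants** (`landgen.clustering`): admixture-model Gibbs
  sampler, Evanno's ΔK, GENECLASS-style assignment/exclusion tests (L_h and
  L_h/L_max against simulated residents, leave-one-out home frequencies),
  and the migrant/admixed classification rule.
- **Bottleneck tests** (`landgen.bottleneck`): conditional-on-k coalescent
  He distributions under IAM/SMM/TPM, sign and Wilcoxon heterozygosity-excess
  tests, allele-frequency mode-shift.
- **Synthetic data** (`landgen.simulate`): a forward Wright–Fisher simulator
  on generated land-cover rasters with a cost-distance migration kernel
  m_ij ∝ exp(−d_LC/λ) and known barrier truth, plus replicate-error
  generation (allelic dropout, ±1 miscalls) for QC testing.

File formats: GenePop text and a lossless CSV dialect for genotypes, ESRI
ASCII grids for rasters, CSV for matrices, YAML for configuration.

## Worked example

Simulate a landscape whose oil-palm band is a true barrier (relative cost
50), run the cost sweep, and ask for the barrier verdict:

```python
import numpy as np
from landgen.simulate import SimConfig, generate_landscape, simulate_genotypes
from landgen.gendist import rousset_a_matrix, morans_i_matrix
from landgen.mantel import cost_sweep, barrier_call
from landgen.fstats import wc_theta

cfg = SimConfig(ncols=80, nrows=60, n_groups=6, group_size=60,
                generations=200, seed=1)
land = generate_landscape(cfg)
table, truth = simulate_genotypes(land, config=cfg,
                                  sample_sizes=[12] * 6, seed=501)
print("multilocus theta over all groups:", round(wc_theta(table), 3))

genetic = {"rousset_a": rousset_a_matrix(table).matrix,
           "morans_i": morans_i_matrix(table).matrix}
sweep = cost_sweep(genetic, land, table.coords,
                   classes=["oil_palm", "pasture", "river", "residential"],
                   costs=(10, 50, 100, 1000, 5000, 10000),
                   n_perm=999, seed=7)
base = sweep.baselines[("rousset_a", "simple")]
palm = sweep.entries[("oil_palm", 50.0, "rousset_a", "simple")]
print(f"Euclidean baseline r = {base.r:.3f} (p = {base.p:.4f})")
print(f"oil palm @ cost 50   r = {palm.r:.3f} (p = {palm.p:.4f})")
for cls, verdict in barrier_call(sweep).items():
    print(cls, "barrier" if verdict.flagged else "-", verdict.qualifying_costs)
```

Output:

```
multilocus theta over all groups: 0.066
Euclidean baseline r = 0.190 (p = 0.0010)
oil palm @ cost 50   r = 0.236 (p = 0.0010)
oil_palm barrier [10.0, 50.0, 100.0, 1000.0, 5000.0, 10000.0]
pasture - []
river - []
residential - []
```

Reading: the groups are weakly diverged (θ ≈ 0.06, the regime the field
study reports); pricing the oil-palm band above 1 makes least-cost distance
a better predictor of Rousset's â than straight-line distance (r 0.236 vs
0.190, both one-tailed significant), the same holds for Moran's I and for
the partial tests controlling Euclidean distance, so only the true barrier
class is flagged.  Restricting the analysis to within-population pairs
(`landgen.mantel.restrict_pairs`) removes the cross-barrier signal and the
flag disappears — the scale-dependence pattern.

The same steps are available from a shell via the `landgen` command
(`landgen simulate`, `landgen qc`, `landgen fstats`, `landgen gendist`,
`landgen distances`, `landgen current`, `landgen sweep`, `landgen cluster`,
`landgen assign`, `landgen bottleneck`); each subcommand is a thin wrapper
over the functions above.

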