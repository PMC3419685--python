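# Methods

This note documents the models, estimators and numerical choices behind
`landgen`, and what the synthetic-data experiments do and do not establish.

## Scope and data model

The package re-implements a complete landscape-genetics inference chain for
diploid microsatellite data sampled from social groups of a forest-dwelling
primate (*Saimiri oerstedii citrinellus*, the Central American squirrel
monkey) living in a fragmented, human-modified landscape: replicate-based
consensus genotyping and QC, Weir–Cockerham F-statistics, individual-level
genetic distance/similarity, least-cost and circuit-theory geographic
distances over a categorical land-cover raster, simple and partial Mantel
tests with a one-class cost sweep, a barrier verdict, Bayesian admixture
clustering with Evanno's ΔK, assignment-based migrant detection, and
heterozygosity-excess bottleneck tests.

Coordinates are assumed to be in a projected metric CRS; all geometry is
planar.  Rasters follow the ESRI ASCII grid convention with a lower-left
origin and cell-centre coordinates x = xll + (col + 0.5)·cellsize.  Genotype
tables are order-free in each diploid call; a call is missing only when both
alleles are absent (no half-calls).  The native lossless dialect is CSV;
GenePop (3-digit codes) is supported for interoperability but carries no
coordinates.

A packaged fixture carries the published pairwise F_ST matrix among the 14
sampled groups (91 pairs, per-pair Bonferroni significance flags, per-group
sample sizes summing to 233, and the western/eastern partition).  Note the
published *overall* mean (0.103) does not equal the arithmetic mean of the
91 printed entries (≈0.0996); the within-population (0.06) and
between-population (0.14) means do recompute exactly at printed precision,
and those are the quantities the package asserts.

## Estimators

**Weir–Cockerham θ.**  Per locus and allele the a/b/c variance components
are computed from group sample sizes, allele frequencies and heterozygote
frequencies; the multilocus estimate is the ratio of summed components
(Σa / Σ(a+b+c)), the combining rule FSTAT uses.  Missing data are handled by
per-locus complete cases; negative estimates are reported as computed.
Significance of a pairwise θ comes from permuting whole diploid genotypes
between the two units (no Hardy–Weinberg assumption), with the +1-corrected
p-value; the family-wise threshold is α divided by the number of pairs
(0.05/91 ≈ 0.0005 for 14 groups).

**Rousset's â.**  For a pair of individuals, Q̂_w is the mean of the two
within-individual allelic identities (1 for a homozygote, 0 for a
heterozygote) and Q̂_b the mean identity of the four between-individual
allele pairings; â = Σ_l (Q̂_w − Q̂_b) / Σ_l (1 − Q̂_w) over mutually
non-missing loci (ratio of sums, the SPAGeDi convention, chosen for
consistency with the θ combining rule).  Loci monomorphic within a pair
contribute 0/0 and drop out; a pair with zero denominator at every locus is
masked.

**Moran's I.**  Each individual is represented by its per-allele frequencies
(0, 0.5, 1) at every locus; deviations are taken from whole-sample allele
frequencies, and the pair statistic is the cross-product normalised by the
mean centred sum of squares over individuals.  Alternative normalisations
exist in the autocorrelation literature; this one makes I of an individual
with itself average 1 over the sample and preserves the sign conventions the
analysis relies on (â rises, I falls, with distance under isolation by
distance).

**Geographic distances.**  The grid graph is 8-connected; a move costs
cellsize·(c_from + c_to)/2, times √2 on diagonals (the ArcGIS COSTDISTANCE
convention).  Least-cost distance is Dijkstra on that graph
(scipy.sparse.csgraph); with uniform costs it reduces exactly to the chamfer
metric cellsize·(max(|Δc|,|Δr|) + (√2−1)·min(|Δc|,|Δr|)).  Effective
resistance treats each edge as a resistor of the same value: one node is
grounded per connected component, L v_p = e_p is solved with a sparse LU
factorisation, and R_ij = v_i(i) + v_j(j) − 2 v_i(j).  Current maps follow
the all-to-one scheme: each group is grounded in turn, all other groups
inject current proportional to group size, and per-cell current magnitudes
(half the sum of absolute incident edge currents) accumulate over focal
choices.  Solver residuals are checked against the requested tolerance and
surfaced in the result.

**Residential classifier.**  Residence cells are dilated by 50 m; 8-connected
components of the dilation implement single linkage at <100 m.  A cluster
becomes "residential" only when its *original* footprint strictly exceeds
3 ha; smaller clusters fall to "other non-forest".

**Mantel machinery.**  The statistic is the Pearson correlation of unmasked
off-diagonal upper-triangle entries; the null jointly permutes rows and
columns of the first (genetic) matrix; p-values carry the +1 correction.
The partial statistic r_AB·C = (r_AB − r_AC·r_BC)/√((1−r_AC²)(1−r_BC²)) is
recomputed per permutation of A only (genetics as response, geography as
fixed design).  When B and C carry identical information (r_BC = ±1 with
r_AB = r_AC) the partial is taken as 0 by continuity; a degenerate control
(|r_AC| = 1) is an error.  When a pair mask is present (within-population
restriction), permutations are confined to the mask's connected blocks so
that no between-population pair can enter the statistic under the null —
this is what makes the masking contract exact (altering an excluded pair can
never change r or p).  Tests default to one tail in each metric's expected
direction (greater for â, less for I), with two-sided available.

**Cost sweep and barrier verdict.**  For each habitat class and each cost in
{10, 50, 100, 1000, 5000, 10000} the focal class is priced at that cost with
all other classes at 1, least-cost distances are recomputed, and four tests
run: simple and partial (controlling Euclidean) Mantel against both genetic
metrics.  The Euclidean baseline for the simple tests is the simple Mantel
of each metric against straight-line distance, computed once.  For the
partial tests the reference is the zero-correlation line: the partial
statistic already nets out the Euclidean component, so any significant
partial r in the expected direction marks information beyond Euclidean
distance.  A class is called a barrier candidate iff at some cost all four
cells succeed simultaneously — simple |r| above the baseline magnitude and
significant, partial significant.  Comparisons of r across classes remain
descriptive; no test between correlations is attempted.

**Admixture clustering.**  The Gibbs sampler implements the admixture model
with independent Dirichlet(1) allele frequencies per cluster and a fixed
symmetric Dirichlet(α = 1) prior on individual admixture proportions
(the correlated-frequencies prior is deliberately out of scope).  Allele
origins, cluster frequencies and Q are updated in turn; ln P(X|K) is
estimated from the post-burn-in log-likelihood trace as mean − var/2, the
standard deviance-style approximation, which is validated at K = 1 against
the closed-form Dirichlet-multinomial marginal (agreement to ~10%; the
approximation is known to sit below the exact marginal).  Label switching
across replicates is resolved by greedy column matching on mean Q before
averaging.  ΔK is the Evanno second difference |lnP(K+1) − 2lnP(K) +
lnP(K−1)| / sd(lnP(K)), defined for interior K with ≥2 replicates.

**Migrant detection.**  Assignment likelihood is the Hardy–Weinberg product
over loci under a population's allele frequencies, with unseen alleles
floored at 0.01 (the conventional GENECLASS default) and frequencies
renormalised; the home population's frequencies are always leave-one-out.
First-generation-migrant p-values reference the observed L_h and L_h/L_max
against n_sim simulated residents; an individual is a migrant when both
statistics are significant at α = 0.01 and the best-likelihood population
differs from the sampling population; it is potentially admixed when its
mean home-cluster Q lies strictly between 0.2 and 0.8 and more than one
population retains exclusion probability above 0.2.

**Bottleneck battery.**  The conditional equilibrium He distribution is
simulated on the coalescent: θ is calibrated by bisection so the expected
allele count matches the observed k (Ewens' formula under IAM; a common-
random-number Monte-Carlo estimate of E[k] under SMM/TPM), mutations are
dropped on the tree (IAM novel-allele; SMM ±1; TPM ±geometric with
p_multi = 0.3 and mean step 2.8 — the historical program's common defaults),
and replicates are kept only when the realised allele count equals k.
DH = (He_obs − mean He_eq)/sd(He_eq) per locus feeds a one-tailed Wilcoxon
signed-rank test; the sign test compares the count of excess loci with a
Poisson-binomial expectation whose per-locus success probabilities are
estimated from the same simulations.  The Wilcoxon is the primary detector
in the recovery experiments (more powerful than the sign test at 16 loci);
both are reported.  The mode-shift test pools alleles of polymorphic loci
into ten 0.1-wide frequency classes and calls "no shift" iff the lowest
class strictly dominates.

## Synthetic data: what it emulates

The generator mirrors the study conditions: 14 groups (samples of 10–28
individuals drawn from demes of 60), 16 unlinked microsatellite loci,
founder allele frequencies triangular over 8–12 contiguous allele sizes per
locus (matching observed allelic richness of 3–15 alleles), SMM mutation at
µ = 5·10⁻⁴ per gamete per locus, and a landscape in which one expansive
matrix class (oil-palm plantation, true relative cost 50) crosses the grid
as a single contiguous band while pasture, river, residential and other
non-forest classes occur as scattered patches.  Migration between demes
follows m_ij ∝ exp(−d_LC(i,j)/λ) on the true cost surface with λ = 2500
cost-metres and a total immigrant fraction of 0.08 per deme per generation,
run for 200 non-overlapping generations.  These defaults put pairwise group
θ in the weakly-diverged regime the study reports (within-side ≈ 0.01–0.07,
between-side ≈ 0.08–0.18).  The total migration fraction and λ are free
choices of the generator (the study estimates neither); they were fixed from
the target F_ST regime before the recovery experiments were frozen.

Deliberate simplifications, and what they imply for the tests: generations
are non-overlapping (the real species has long, overlapping generations, so
real time-to-signal is slower than simulated generations suggest);
individuals are placed at their group centroid (within-group geographic
variance is zero, so Mantel signal is carried entirely by between-group
structure); there is no genotyping error in the recovery experiments unless
`make_replicates` injects it; and allele-size homoplasy under SMM is fully
realistic but founder diversity is not mutation–drift equilibrated unless
runs are long (recovery experiments that need stationarity draw directly
from the coalescent's stationary law instead).  Passing recovery tests
therefore shows the chain detects the modelled signal at desk scale; it does
not certify power for any particular empirical dataset.

## Problem sizes in the shipped experiments

The test-suite experiments are scaled to single-CPU runs: barrier recovery
uses 6 groups of 12 sampled individuals on an 80×60 grid at 20 m resolution
with 499 Mantel permutations, 10 seeds; island-model recovery uses k = 4
demes of N = 50 run 1000 generations (long enough to reach
migration–drift–mutation equilibrium; the finite-island reference is
1/(1+4Nm·k/(k−1)), the k/(k−1) factor arising because immigrants are drawn
from the k−1 other demes); Mantel calibration uses 2000 independent 30-unit
matrix pairs at 999 permutations; migrant detection plants 2 first-
generation migrants per seed over 20 seeds with 1500 simulated residents per
test.  Production defaults (10,000 permutations and simulated individuals)
remain the module defaults.

## Known limitations

- The admixture sampler's lnP estimator shares the known bias of the
  deviance approximation; ΔK is robust to it, absolute lnP values are not
  comparable across implementations.
- The dual-statistic migrant rule (both L_h and L_h/L_max at α = 0.01) loses
  power below ~80% when deme divergence drops to θ ≈ 0.1 with 16 loci; the
  shipped recovery experiment runs at moderate divergence (θ ≈ 0.2–0.4).
- Resistance solves use one sparse LU per focal/component; grids far beyond
  ~10⁵ cells would warrant a preconditioned CG instead.
- The exact replicate-consensus reading ("alleles scored at least four
  times") counts concordant whole-genotype replicates; the alternative
  allele-observation count is not implemented as a switch, only documented
  here as the one open reading.
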