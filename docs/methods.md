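# Methods

## Scope and data model

The package implements the genomic-selection workflow of a line-breeding
program in four stages — phenotypic mixed model, population structure,
RR-BLUP prediction, accuracy assessment — plus a forward simulator that
generates populations with the statistical structure the analysis assumes.
All containers are plain: a dosage matrix (lines × SNP markers, 0/1/2,
NaN for missing), a genetic map in centimorgans (no physical coordinates),
long-format per-location entry means, and a line→group membership table.
Replicates within a location are never modelled; the per-location adjusted
entry mean is the pipeline's atomic observation, and the simulator emits
entry means directly.

## Phenotypic mixed model

`y_ij = μ + l_j + g_i + e_ij` with `l_j ~ N(0, σ²_L)`, `g_i ~ N(0, σ²_G)`
independent, and residual `e_ij ~ N(0, σ²_e)`.  With one observation per
line×location cell the genotype×location interaction is confounded with —
and absorbed by — the residual, so no separate G×L component is fitted.

REML is implemented directly for this fixed two-random-effect structure
rather than delegated to a generic mixed-model engine: the restricted
likelihood is evaluated exactly through the Woodbury identity, and because
the genotype block of `Γ⁻¹ + Z'Z` is diagonal, each evaluation reduces to a
J×J Cholesky (J = number of locations, ≤ 7 here), making a full fit a few
milliseconds even at 900+ lines.  The residual variance is profiled out and
the two variance ratios are maximized by Nelder–Mead in log space
(`xatol 1e-9`, `fatol 1e-12`, start at the balanced-ANOVA moment
estimators, ratios clipped to e^±30).  Ratios below 1e-6 are reported as a
zero component with a `clamped` flag — the REML parameter space is
`σ² ≥ 0`, and boundary solutions are legitimate estimates, not errors.  On
balanced tables with interior solutions the fit reproduces the closed-form
ANOVA moment estimators (`σ̂²_G = (MS_G − MS_E)/J`) to 1e-6; that closed
form is the independent oracle in the test suite.

Significance of `σ²_G` uses the likelihood-ratio statistic of the full
model against the location-only model with the halved χ²₁ P value — the
null value lies on the boundary of the parameter space, so the naive
χ²₁ tail is conservative by a factor of two.

Heritability is on an entry-mean basis, `h² = σ²_G / (σ²_G + σ²_e / L)`.
For unbalanced trials `L` defaults to the **harmonic** mean of per-line
location counts, because `σ²_e/L` is then the average error variance of a
line mean; the arithmetic mean and the total location count are available
as alternatives (`effective_locations`).  The same `L` enters the ridge
penalty, keeping the two uses consistent.

BLUEs treat genotype as fixed (cell-means coding, so the estimate is the
adjusted line mean directly) and location as random; the location variance
ratio is re-estimated by REML in this fixed-genotype model and the GLS
solution exploits the diagonal J×J structure.  A single-location dataset
returns raw entry means unchanged.

## Population structure

Modified Rogers' distance between two lines is computed from within-line
allele frequencies (dosage/2):
`D = sqrt( Σ_k Σ_alleles (p−q)² / (2m) )`.  For biallelic markers the
two-allele inner sum collapses to `2(p−q)²`, so the implementation uses
`(1/√m)·` Euclidean distance on frequency vectors; the tests check it
against the literal double-sum.  Because MRD is a scaled Euclidean norm it
is exactly embeddable: classical PCoA (double-center `−D²/2`,
eigendecompose) yields eigenvalues ≥ −1e-10, and anything inside that
tolerance is treated as zero.  Distances require complete genotypes; the
pipeline imputes first and records the imputation mode in run metadata.

## RR-BLUP

Missing dosages are imputed per marker from the observed genotype-class
frequencies (seeded sampling; a deterministic mean-dosage mode exists for
pipelines that need bitwise stability under re-ordering).  Dosage columns
are used raw — not centered or standardized — in reported predictions;
centering is algebraically absorbed into the intercept.

The penalty is `λ = (σ²_e/L) / (σ²_G/Nm)`: marker-effect variance is the
genotypic variance split equally over the `Nm` fitted markers, and the
entry-mean error variance `σ²_e/L` plays the residual role.  By default the
variance components come from the full-data phenotypic fit and are *not*
re-estimated inside cross-validation folds (per-fold re-estimation is a
configuration option); the same convention applies the entire-population
`h` when standardizing family accuracies.

The mixed-model equations are solved with the intercept unpenalized; after
absorbing it, `â = (Z'cZc + λI)⁻¹ Z'c yc` with `Zc` the column-centered
training dosages.  The solver picks whichever of the marker-space
(`Nm×Nm`) or observation-space (`N×N`) symmetric systems is smaller — the
two are algebraically identical, and `gblup_oracle` exposes the
observation-space (genomic-kinship) route independently as the central
correctness cross-check (agreement to 1e-8 is asserted in the tests).
`λ = 0` is accepted only when the centered dosage matrix has full column
rank; a rank-deficient system raises instead of silently returning a
minimum-norm solution.

## Accuracy assessment

Fivefold cross-validation partitions the lines at random (fold sizes
differing by at most one), fits marker effects on 80 % and predicts the
held-out 20 %.  `r_MP` is the Pearson correlation of observed and
predicted phenotypes **per validation fold** (a pooled-per-repeat mode
exists), and `r_GS = r_MP / h`.  Negative correlations are reported as
such, never truncated — sign reversals are a real phenomenon (below) — and
`r_GS` may exceed 1 in magnitude by sampling noise.  The canonical repeat
count in the literature is 10,000; the default here is 100, which the
convergence test shows is within Monte-Carlo noise of the asymptote for
these population sizes, and every output records the repeats used.  An
ambiguity worth noting: "repeated sampling of training and validation
sets" can mean repeated full k-fold partitions or repeated single 80/20
draws; both are implemented (`CVScheme.mode`), defaulting to full
partitions.

Across-population prediction fits once on a training population and
correlates over an independent test group.  Sweeps subsample the training
pool (optionally as nested prefixes) or random marker subsets; the penalty
is recomputed for each marker count since `λ` scales linearly in `Nm`.

A subtlety in null calibration: repeated CV on a *single* noise phenotype
does not average to zero — all repeats share that dataset's conditional
bias (≈0.08 at 80 lines).  Null checks therefore draw a fresh noise
phenotype per replicate, the design under which the zero expectation
actually holds (by `y → −y` symmetry).

## The simulator

**What it emulates.**  A diversity set of partially inbred lines (equal
thirds S1/S2/S3) derived from a finite founder pool by single crosses plus
single-seed-descent selfing, and biparental families each descending from
one F1 between two diversity lines, all families sharing a common parent.
Defaults reproduce the reference geometry: 676 + 4×62 = 924 lines,
677 markers on a nine-chromosome 698 cM map (mean spacing ≈1 cM, max gap
23 cM, chromosome ends pinned so the total length is exact), testcrosses
at 1–7 locations (uniform per-line counts), six traits with target
entry-mean heritabilities 0.71/0.65/0.60/0.55/0.48/0.38.

**Recombination** follows Haldane: crossover counts per chromosome are
Poisson(length in Morgans), positions uniform, no interference — the
simplest standard model, sufficient for the linkage structure the analysis
exploits.

**Founders** are drawn in linkage equilibrium with per-marker minor-allele
frequencies realized exactly from a target drawn uniformly in [0.1, 0.5].
The pool defaults to **8 founders**.  This is the simulator's single most
consequential calibration: with LE founders, every bit of marker–QTL
signal flows through founder-segment cosegregation, and a wide pool
dilutes it until prediction accuracy saturates near 0.25 regardless of
heritability.  A narrow elite pool is realistic for advanced pollinator
germplasm and puts diversity-set cross-validated `r_GS` for
high-heritability traits near 0.6–0.65, the regime reported for real
breeding populations of this layout.

**Traits** are purely additive: 30 hidden QTL by default, positions
uniform on the map, effects Gaussian.  QTL are simulated as extra loci
interleaved with the markers — haplotypes carry both through meiosis, but
the analysis only ever sees marker columns.  The QTL genetic value is
rescaled, and an infinitesimal polygenic term (default 15 % of genetic
variance) added, so the realized entry-mean h² matches the target given
the error SD and the harmonic-mean location count.  The polygenic share is
marker-orthogonal by construction and therefore caps attainable `r_GS` at
√0.85 ≈ 0.92; it represents the many sub-threshold QTL real traits carry.

**The opposite-linkage-phase scenario** re-codes (allele-swaps) all
markers within a window of each QTL inside one family only, leaving QTL
genotypes — hence phenotypes — untouched.  Marker effects estimated in the
diversity set then point the wrong way inside that family and the
prediction signal reverses sign.  The operation is an involution and
refuses families monomorphic at every flanking marker.  The demonstration
scenario (600 training lines, one 150-progeny family, 40 QTL, h² 0.8, no
polygenic term, 40 cM windows) reverses the sign in ≥95 % of replicates.

**What the simulator does not model** — and what passing tests therefore
do not establish about real data: no selection or multi-cycle breeding, no
dominance or epistasis, no multi-allelic QTL behind biallelic SNPs, no
ancestral LD beyond founder-segment sharing, no plot-level field
variation, and location effects that are exchangeable rather than tied to
geography.  Results on simulated data validate the estimators and the
qualitative structure of accuracy (heritability response, training-size
and marker-density trends, phase-reversal sign), not absolute accuracy
levels of any particular crop dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline at 900-line/600-marker
scale with 100 CV repeats, 50-replicate parameter-recovery ensembles, and
50-replicate phase-flip ensembles — sizes chosen so the full suite
completes in a couple of minutes while leaving Monte-Carlo margins well
clear of the assertions.  Heritability-response comparisons hold the
population fixed and vary only the trait: between-population founder
sampling would otherwise confound the h² effect.  All randomness descends
from one master seed via SHA-256-derived per-stage seeds (`io.derive_seed`),
making every pipeline output byte-reproducible.

## Known limitations

Single-trait analysis only; no spatial adjustment within trials; no
GCA/SCA separation (impossible with one common tester); no Bayesian
variable-selection alternatives to RR-BLUP; the LRT's halved-P boundary
correction is an approximation; and the BLUE stage assumes every line
appears at more than one location in aggregate (it raises otherwise).
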