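# Methods

This note documents the models and conventions the package implements,
the choices made where the literature is ambiguous, and what the
synthetic scenarios do and do not emulate.

## Data model

Trees are rooted, dated (branch lengths in consistent time units,
Myr-like), read and written as newick via dendropy; polytomies are
permitted and preserved.  "Age" always means time before present with
extant tips at age 0.  Community data are binary sites × species
incidence matrices; all metrics are incidence-only by construction.
Species in the community but absent from the tree are a hard error by
default; `restrict_to(..., prune_missing=True)` drops them with a
warning.  Names are matched after trimming whitespace, with spaces and
underscores treated as equivalent (the newick convention).

## Dating undated nodes

`bladj_interpolate` fixes the ages of calibrated nodes (the root must
be one) and assigns every undated interior node the age obtained by
evenly spacing the chain of undated nodes between its nearest dated
ancestor and its nearest dated descendant (fewest intervening nodes;
ties resolved toward the oldest candidate, which keeps parent ≥ child).
Branch lengths are recomputed as age differences.  Because interpolated
ages depend only on the fixed set, the procedure is idempotent.

## Intra-plot structure and the null model

PD includes the path to the global root — the convention of the
standard R implementation (`picante::pd`, `include.root=TRUE`), against
which the test suite cross-checks.  MPD averages unordered pairs of
distinct species; MNTD averages each species' distance to its nearest
co-occurring neighbour.

The null model is the taxa shuffle: tip labels permuted over the
regional pool, defined as the species present in the community matrix
(tree tips never recorded in any plot do not enter the shuffle).  One
label permutation per null iteration is shared across all plots, which
makes null draws comparable between plots and costs one permutation per
iteration; marginally per plot this is equivalent to independent
shuffles.  `sd_null` uses the n−1 denominator.  When all null draws are
identical (star phylogenies, a plot containing the whole pool) the SES
is reported as missing and logged, never as ±∞; identical draws are
detected by a zero range rather than a zero floating-point standard
deviation, which can be polluted by summation round-off.  Default
iteration count: 999.

## Phylobetadiversity conventions

- **Fuzzy weighting.**  `q_ij = s_ij / Σ_k s_ik` sums over the whole
  pool *including* the focal species (`s_ii = 1`), keeping each row of
  q a probability vector.  Matrix **P** renormalizes belonging within
  each plot's species set, so each plot's incidence total is conserved
  exactly (a column of **P** sums to the plot's richness); consequently
  `p_ik > 0` only where `w_ik = 1`.  Pair dissimilarity is Bray–Curtis
  on **P** columns with the square root applied after aggregation.
- **COMDIST** averages over *all* cross pairs, including shared species
  as zero-distance pairs — required for the identity with between-plot
  Rao's D (quadratic entropy with uniform incidence weights), which the
  acceptance suite asserts.
- **COMDISTNT** is symmetrized as the unweighted mean of the two
  directional means, ½[mean_i min_j d_ij + mean_j min_i d_ij].  (The R
  reference implementation instead averages the pooled nearest-taxon
  distances, weighting directions by richness; the two coincide for
  equal-richness plots, which is how the R cross-check is framed.)
- **Rao's H** divides between-plot Rao's D by the mean of the two
  within-plot quadratic entropies, computed over ordered pairs
  including self (divisor n²) — forced by the Rao identity and making
  H(plot, plot) = 1 exactly.  H is undefined for monospecific plots.
- **UniFrac** classifies the edges of the spanning subtree of the two
  plots' union, rooted at the tree's global root: edges whose tip set
  intersects exactly one plot are exclusive; the statistic is exclusive
  length over total subtree length.  Shared basal edges cancel in the
  numerator, so the root-vs-MRCA choice only shifts the denominator;
  the rooted convention is used and asserted (identity with Jaccard on
  star phylogenies).

## PCPS

PCoA Gower-centers −½d², takes the symmetric eigendecomposition, and
keeps axes with eigenvalue > 1e-10 × the largest; scores are
eigenvectors scaled by √eigenvalue.  Percent-of-variation uses the sum
of positive eigenvalues as denominator: sqrt-Bray–Curtis input is
near-metric, and tiny negative eigenvalues are expected and excluded.
Axis signs are deterministic: raw PCoA makes the largest-magnitude site
score positive; the PCPS workflow then orients each retained axis so
the species with the largest-magnitude correlation correlates
positively.  The retention rule keeps axes holding more than 5% of the
variation (threshold configurable).  Note that the percent held by the
leading axis shrinks as plot count grows when dissimilarities are close
to saturated, so at large n the rule can retain nothing; the analysis
drivers then still report permutation ANOVAs for the leading axes,
labelled as such.

## Permutation inference

The observed one-way F is the classical statistic; PERMANOVA's pseudo-F
uses SS_total = Σ_{i<j} d²/N and SS_within = Σ_g Σ_{i<j∈g} d²/n_g with
unrestricted site-label permutations (one-factor design).  P-values are
(b+1)/(B+1) where b counts null statistics ≥ the observed (ties count
as exceedances; B defaults to 999).  Zero within-group variance yields
an infinite statistic and the minimal P.  Pairwise contrasts re-run the
test on each two-group subset and are reported raw; Holm adjustment is
available but off by default.  Mantel correlates lower triangles
(Pearson) and permutes rows+columns of the second matrix, one-sided for
positive association.  All tests evaluate their permutation null in a
single vectorized pass and are bit-reproducible under a fixed seed.

## Synthetic scenarios

The generator emulates a three-vegetation-type floristic survey: a pool
split into a small deep-diverging clade D (root split, age 300) and two
subclades S1/S2 of a large clade (split 150; crowns 120/100/100 unless
a preset overrides them); within-clade topologies are pure-birth with
node ages rescaled to the crown age, so trees are ultrametric.  Plots
sample species without replacement with per-clade weights; richness is
a negative binomial shifted to minimum 2 (dispersion 8) truncated at
the number of sampleable species; groups default to 63/50/96 plots,
mirroring an unbalanced design.

Presets (each preset's defaults are its study conditions):

- **atlantic-like** (pool 25/40/40, richness mean 15): Mixed samples
  the deep clade heavily (p = 0.95) plus both subclades; Dense and
  Seasonal avoid it and lean moderately toward opposite subclades
  (0.7/0.45 and 0.45/0.7).  Designed so Mixed is the most diverse and
  overdispersed group, the deep split is the dominant P-space gradient,
  and Dense/Seasonal resemble each other more than either resembles
  Mixed.  Total subclade confinement was deliberately avoided: it makes
  the subclade-turnover gradient of the two large groups dominate axis
  1 and hide the deep-split gradient.
- **neutral**: one shared occurrence-probability vector; used for
  type-I-error calibration.
- **terminal-contrast** (pool 8/26/26 at test scale, S1/S2 split at 60
  with crowns 50, richness mean 24): the deep clade is sampled
  identically everywhere and groups differ only in S1/S2 weights
  (0.95/0.25 vs 0.6/0.6 vs 0.25/0.95).  The discriminating split must
  be young and occupancy moderate: a deeper split re-exposes COMDIST to
  the group signal, and very low occupancy saturates UniFrac.
- **clade-driven** (pool 10/45/45, richness mean 15): a species-poor
  but maximally divergent deep clade with a strong occurrence contrast
  and only moderate subclade shifts — group identity is carried by
  clade proportions while species identity turns over heavily, the
  regime where phylogeny-weighted composition out-discriminates raw
  composition.

What the generator does **not** emulate: spatial or environmental
autocorrelation between plots, widespread dominant species shared
across all groups, multi-scale clade structure below the three blocks,
or abundances.  Two consequences observed and accepted: (i) sqrt-BC
dissimilarities on matrix **P** run close to saturation at low plot
occupancy, because **P** confines mass to each plot's own species — so
fuzzy weighting's group fit is far weaker here than in real floristic
data, and the full cross-method ordering of PERMANOVA fits seen in real
surveys (fuzzy best, COMDIST worst) is not reproduced by a three-clade
world, where COMDIST unavoidably sees subclade-fraction shifts; the
per-claim directional contrasts are what the tests assert.  (ii) A
clade's P-space gradient carries weight proportional to its species
count, not its branch length, so a realistically species-poor deep
clade cannot dominate axis 1; the atlantic-like preset gives the deep
clade a quarter of the pool for that reason.

## Problem sizes and calibration design

Tests and the acceptance suite run scaled designs chosen to keep the
default suite in minutes: pattern-recovery studies use 16/12/24 plots
per group, 50 replicate simulations, and 199-iteration nulls; the
acceptance script runs the full 63/50/96-plot design with a 105-species
pool and 199 permutations.  Null-model calibration uses 1000 replicates
of 199 permutations per test.  SES calibration pools ten replicate
200-plot/999-null realizations: within one realization the per-plot
z-scores are correlated (one tree, shared null permutations), so the
mean of a single realization has sampling noise of roughly ±0.1 — the
pooled estimate is what the bands are applied to.

## Known limitations

- COMDISTNT's symmetrization differs from the pooled-mean convention of
  the R reference for unequal richness (documented above).
- The taxa-shuffle null is the only null model provided; richness- or
  occupancy-constrained nulls are out of scope.
- Permutation ANOVA/PERMANOVA are one-factor with unrestricted
  permutations; no strata, no multi-factor designs, no dispersion test.
- Abundance-weighted variants of all measures are deliberately absent.
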