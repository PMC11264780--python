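# Methods

## The assembly null models

**βMNTD.** For communities *k*, *m* with per-sample relative abundances
*f* and patristic distances *d* on a rooted tree, the abundance-weighted
beta mean nearest taxon distance is the mean over both directions of
Σᵢ fᵢ · min over the other sample's taxa of d(i, ·), with *i* ranging over
taxa present in one sample and fᵢ renormalized within that sample. Taxa
shared by both samples contribute a minimum distance of zero. The
unweighted form replaces fᵢ by 1/S within each direction and averages the
two per-direction means. Note that picante's `comdistnt` pools both
directions' nearest-neighbour vectors before averaging in its unweighted
mode, so the two conventions differ when the samples' richness differs; the
weighted mode is identical (and is verified against picante in the test
suite on a frozen fixture).

**βNTI.** The null model shuffles taxon identities uniformly at random
across the tips of the pool's pruned tree — implemented as a simultaneous
random permutation of the rows and columns of the patristic distance matrix
restricted to the pool. βNTI is the z-score of the observed βMNTD against
`n_reps` (default 999) such replicates. Pairs with null standard deviation
zero (e.g. both samples containing the whole pool, so every nearest
distance is structurally zero) are flagged undefined and excluded from
classification with a logged count. βNTI assumes phylogenetic niche
conservatism: relatives must be ecologically more similar than distant
taxa, otherwise selection leaves no phylogenetic imprint for the metric to
detect.

The pool is, by default, the set of taxa occurring in the samples of one
niche × health stratum (`pool_scope="group"`); `"all_samples"` uses the
whole table while still classifying only within-group pairs. Per-group runs
derive their seeds from the top-level seed through `SeedSequence`, so a run
is reproducible from the manifest alone.

**RC_bray.** For each pair and each replicate, two null communities are
assembled from the pool: each sample's observed richness Sₓ is drawn
without replacement with probability proportional to taxon occupancy
(Gumbel top-k sampling, equivalent to successive draws proportional to
weight); the sample's observed read total Nₓ is then distributed over the
drawn taxa with one guaranteed read each and the remaining Nₓ − Sₓ reads
multinomial, proportional to pool-wide relative abundance renormalized over
the drawn taxa. The guaranteed read makes the drawn richness realized.
RC = 2·[(#{null < obs} + ½·#{null = obs})/n_reps] − 1, with ties detected at
1e-12. RC is therefore in [−1, 1], monotone in the observed dissimilarity
for a fixed null sample, −1 when the observed dissimilarity lies below every
replicate, +1 above.

**Classification.** |βNTI| ≥ 2 → selection (heterogeneous if positive,
homogeneous if negative); otherwise RC ≥ 0.95 → dispersal limitation with
drift, RC ≤ −0.95 → homogenizing dispersal, else drift. Boundary values
classify as the non-drift category: the source framework's strict
inequalities leave exact boundary values unassigned, and assigning them to
the adjacent non-drift class keeps the map total. "Variable selection" and
"heterogeneous selection" are treated as synonyms. Pairs are formed within
groups only; per-group process fractions are computed over classified pairs
and sum to one.

## Diversity and group tests

ENS (effective number of species) defaults to inverse Simpson (Hill order
2), which equals S for a perfectly even community. A literal
`exp_simpson_literal` mode — the exponential of the Gini–Simpson index — is
retained for comparability but flagged: it is bounded by e ≈ 2.72 and
cannot represent rich communities. ENS is computed per rarefaction draw and
averaged; rarefaction subsamples without replacement (multivariate
hypergeometric) to a common depth, by default the minimum retained total of
the stratum, with 100 draws.

Bray–Curtis uses Σ|x−y| / Σ(x+y) (scipy); weighted UniFrac (raw and
normalized) comes from scikit-bio and is cross-checked in tests against the
half-L1 identity on star trees and two-leaf hand values. PCoA is classical
metric scaling; negative eigenvalues are reported and excluded from the
explained-variance denominator, matching the common two-axis
percent-explained reporting convention.

PERMANOVA (pseudo-F from among/within sums of squared distances, free label
permutation, p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)) and the
betadisper-style dispersion test are implemented natively so that an
exhaustive-enumeration mode is available for small designs; their statistics
are verified against scikit-bio's `permanova` and `permdisp(test="centroid")`
to machine precision. The dispersion test measures each sample's distance
to its group centroid in full-rank positive-eigenvalue PCoA space and takes
the one-way ANOVA F of those distances. Its permutations reassign samples
to groups and **recompute** the centroid distances: permuting the fixed
distances (the R `permutest.betadisper` scheme) is mildly liberal, because
distances within a group share an estimated centroid — measured type-I
error 0.068 at nominal 0.05 over 1000 null replicates, versus 0.057 for the
refit scheme adopted here. When the centroid distances are constant up to
float noise (e.g. duplicated coordinate sets) the test returns p = 1
directly. The rank-sum test uses exact enumeration for tie-free pooled
n ≤ 20 and the midrank normal approximation with tie correction otherwise.

## Associations

Core taxa: occurrence in ≥ 95% of the group's samples AND mean relative
abundance across those samples ≥ 0.1%, both inclusive with a 1e-12
tolerance so exact boundary cases land inside. The alternative reading of
the abundance rule (threshold per qualifying sample rather than the group
mean) is available via the `abundance_min` semantics of `core_taxa`
combined with prevalence over thresholded counts; the group-mean reading is
the default. Spearman correlations (midranks, two-sided) between
phylum-level relative abundance and each soil-chemistry variable are
Benjamini–Hochberg adjusted within each niche × health group's full
phylum × variable family; missing chemistry is dropped pairwise. Diversity
regressions are ordinary least squares of ENS on one chemistry variable per
group, reporting slope, intercept, adjusted R² and the two-sided slope p.

Geographic distances are haversine great circles (Earth radius 6371.0 km)
between farms, expanded to sample pairs by farm membership (within-farm
distance 0). Chemistry distances are Euclidean on per-variable z-scores.
Mantel tests (scikit-bio) correlate upper triangles under simultaneous
row/column permutation of the second matrix, one-sided "greater" by default
— the direction of distance-decay hypotheses — with Pearson correlation by
default and Spearman available.

## The synthetic study generator

The generator emulates the design of a 13-farm, 4-niche (bulk soil,
rhizosphere soil, root, shoot), healthy/unhealthy survey in a ~1° region
around 50°N 23°E, at desk scale. What it reproduces: a shared lognormal
metacommunity, phylogenetically structured taxa with clade-conserved
traits, farm-level chemistry linearly coupled (plus noise, sd 0.3 on pH) to
a latent environmental axis that differs between health groups, jittered
farm coordinates, lognormal sequencing-depth variation around 5000 reads,
and communities assembled under known regimes. What it does not reproduce:
real 16S richness (tens of thousands of ASVs), taxonomic realism beyond
clade-labelled phyla, chimeras/contamination, compositional sequencing
artefacts, or spatially autocorrelated dispersal (farm pools are
independent of coordinates). Passing recovery tests therefore show the
inference machinery is sound under the stated generative assumptions, not
that real strawberry data would classify identically.

**Tree and traits.** Pure-birth (Yule) topology with exponential waiting
times, rescaled to unit depth; an optional depth-power transform
(`depth_skew` < 1) concentrates branch length on deep edges (off by
default). Traits evolve by Brownian motion with a Pagel-δ depth transform
(default δ = 0.3): per-branch variance ∝ depth_child^δ − depth_parent^δ,
concentrating trait change on deep branches. Plain Brownian motion on a
Yule tree leaves almost no trait–patristic correlation among tips
(measured ≈ 0.05–0.07), i.e. no niche conservatism — and without
conservatism βNTI is structurally blind to selection. δ = 0.3 raises the
correlation to ≈ 0.29, a conservatism level at which nearest-taxon metrics
are informative.

**Regimes.** Each sample realizes an exact target richness (default 110 of
600 taxa): taxa drawn without replacement proportional to regime weights
(Gumbel top-k), one read per drawn taxon, remainder multinomial.

- *Selection*: arrival weights mix a Gaussian fitness kernel on the trait,
  exp(−(trait−env)²/2σ²) with σ defaulting to 0.2 × the realized trait sd,
  with a neutral immigration fraction ν (default 0.3); abundance fill uses
  the sharper mixture ν², so maladapted immigrants arrive but stay rare.
  The kernel is fitness-proportional rather than multiplied by
  metacommunity abundance: abundance-weighted selection makes every sample
  fixate on the same dominant taxa, and taxa shared by a pair contribute
  zero to βMNTD under the observation and under every null replicate alike,
  erasing the very signal the regime is meant to produce. With ν = 1 the
  regime reduces exactly to drift (tested).
- *Drift*: multinomial sampling proportional to metacommunity abundance.
- *Dispersal limitation*: each farm receives a uniform-random local pool of
  a fraction m (default 0.2) of the taxa, shared by the farm's samples,
  with within-pool abundances re-drawn around the metacommunity values by a
  lognormal founder-effect factor (sd 2.0); samples then assemble neutrally
  within the farm pool. Uniform (not abundance-weighted) pool membership is
  deliberate: which taxa reach a farm being independent of regional
  abundance is the defining property of dispersal assembly, and it is what
  generates between-farm turnover. m = 1 with no explicit pool reduces
  exactly to drift (tested).
- *Mixed* (the default study): healthy groups assemble under selection,
  unhealthy under drift, and both rhizosphere groups under dispersal
  limitation, so a single dataset exercises every classifier output.

**Sizes.** Defaults are 600 taxa and richness 110 per sample because the
magnitude of βNTI grows with the number of independent nearest-taxon
contributions per pair: at richness 25–70 the z-scores of strongly selected
communities plateau around −1 to −1.9 and selection is under-called, while
at 110 the selection scenario yields |βNTI| ≥ 2 for 61–80% of within-group
pairs across seeds. Real surveys, with richness in the hundreds to
thousands per sample, sit well beyond this threshold. Twelve samples per
group keeps 999-replicate null models at interactive runtimes.

## Numerical and procedural choices

- 999 null replicates by default (p-granularity 1/1000 versus runtime);
  99 is the enforced minimum.
- All randomness flows from explicit seeds through `numpy` `SeedSequence`;
  identical configs give bitwise-identical outputs, and the pipeline's TSV
  outputs (fixed float format, fixed ordering) are byte-identical across
  re-runs. The run manifest records every parameter, seed, threshold and
  assumption flag.
- Under neutral generation the RC tails are conservative (essentially no
  pairs beyond ±0.95) because the occupancy-constrained null is a
  deliberately different dialect from the generator; βNTI tails calibrate
  at the nominal ~5%. The βNTI calibration experiments pool pairs over many
  independent tip-shuffle realizations, because all pairs of one shuffled
  dataset share a single realization and are strongly correlated
  (per-dataset mean βNTI has standard deviation ≈ 0.6).
- Harmonization (`intersect`) restricts taxa to tree leaves and samples to
  metadata rows, prunes the tree, drops all-zero rows/columns with a logged
  count, and is idempotent; `strict` raises on any mismatch. Missing branch
  lengths read as 0 with a warning; missing chemistry propagates as NaN and
  is dropped pairwise downstream.
- The study's source data pipeline would supply its own phylogeny; none is
  published with the count table, so the package requires a user-supplied
  or simulated tree and records that requirement in the run manifest.

## Known limitations

- RC_bray's null dialect (occupancy draw + abundance fill + forced minimum
  read) is one of several in circulation; fractions are comparable across
  groups within a run, less so across software.
- The dispersion test's refit permutation scheme is slightly more
  conservative than the R tool family's fixed-distance scheme; p-values
  will not match vegan's `permutest.betadisper` exactly.
- Process fractions inherit the thresholds (2, 0.95); they are reported in
  every output alongside replicate counts to prevent silent assumption
  drift, but the classification is not continuous in βNTI/RC.
- Desk-scale core-taxa counts are small: with 12 samples and stochastic
  richness 110/600, few taxa reach 95% prevalence; real-data core sets are
  larger because real communities have stable dominant members.
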