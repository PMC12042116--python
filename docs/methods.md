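# Methods

This note records the statistical conventions the package implements, the
design of the synthetic-transect generator, the numerical choices that
were genuinely open, and what the validation suite does and does not
demonstrate.

## Diversity and distance conventions

Richness counts OTUs with count > 0; the Shannon index is −Σ pᵢ ln pᵢ in
nats (natural log, the vegan default — the log base is a convention, not
a result). Both are computed on rarefied counts: each sample is
subsampled without replacement (multivariate hypergeometric) to a common
depth, by default the smallest sample total of the table, mirroring the
usual "resample to the minimum read count" practice. All-zero OTU
columns are retained after rarefaction so matrices stay alignable across
stages; richness simply ignores them.

Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) is computed on
rarefied counts, and similarity is 1 − d. Bray–Curtis is not a metric:
the triangle inequality can fail, and nothing downstream assumes it. A
pair of all-zero samples has an undefined quotient and is set to 0 with a
warning.

Latitudinal regions are 5°-wide bins over 60–80 °N, half-open [lo, lo+5)
with the top edge inclusive, so every in-range sample belongs to exactly
one of 60–65, 65–70, 70–75, 75–80. Whether a boundary site (exactly 65,
70 or 75 °N) belongs to the lower or upper band is a convention; here it
goes up.

## Distance–decay and Mantel

The DDR is an ordinary least-squares fit of pairwise similarity on
great-circle (haversine, R = 6371 km) distance over all S(S−1)/2
unordered pairs, on raw kilometres with the slope reported per 100 km
(recorded in output headers, since slope magnitudes are meaningless
without their distance unit). The default p-value is the slope's t-test;
pairs are not independent, so this p is the usual descriptive convention
rather than an exact test, and a permutation alternative (shuffling the
community matrix's sample order) is available via `p_method="permutation"`.

The Mantel test correlates the upper triangles of two distance matrices
(Spearman by default, 999 permutations) and permutes the row/column order
of one matrix jointly; p is two-sided with the +1 correction. Ranking the
whole matrix once is valid because a joint permutation only rearranges
the same multiset of entries.

## Permutation tests of community structure

All three group tests are one-way (region is the only factor tested),
use label shuffling, and report p = (#extreme + 1)/(n_perm + 1) with 999
permutations by default, so p = 0 is impossible.

* PERMANOVA: pseudo-F = (SS_between/(g−1))/(SS_within/(n−g)) with sums of
  squares from squared distances (SS_total = Σd²/n within the whole set,
  SS_within analogously per group). The decomposition
  SS_total = SS_within + SS_between is asserted to 1e-9 in tests.
* ANOSIM: R = (mean between-group rank − mean within-group rank)/(M/2),
  M = n(n−1)/2, midranks for ties.
* MRPP: δ = Σ_g (n_g/n) · mean within-group distance; small δ indicates
  structure, so the p-value counts δ_perm ≤ δ_obs. The chance-corrected
  agreement A = 1 − δ/E[δ_perm] is reported alongside.

A label permutation that happens to reproduce the observed partition
reproduces the observed statistic exactly; minimal p-values are therefore
minimal only up to that (small) probability, which the tests account for.

NMDS wraps nonmetric SMACOF (scikit-learn) — iterative stress
minimization with isotonic regression of configuration distances on
dissimilarity ranks, which is the same majorization family as Kruskal's
classic algorithm — with 20 random restarts, the best configuration kept,
coordinates centred, and Kruskal stress-1 recomputed independently from
the final embedding. Results are deterministic under the seed;
non-convergence is reported via a flag, not an exception.

## Constrained ordination and variation partitioning

CCA follows the weighted chi-square formulation: with P the table divided
by its grand total, r and c the row/column mass vectors, the analysis
eigen-decomposes the projection of Q̄ = (P − rcᵀ)/√(rcᵀ) onto the
row-weighted, weighted-centred environmental matrix. Total inertia then
equals the table's chi-square statistic divided by the grand total (an
oracle identity asserted to 1e-9). Covariates are VIF-pruned first:
iteratively drop the variable with the largest VIF = 1/(1−R²) above 10
(infinite VIFs, i.e. exact collinearity, go first; ties drop the
rightmost column). Significance comes from shuffling environmental rows
against the pseudo-F of constrained inertia (999 permutations).

Variation partitioning uses CCA-based R² adjusted by permutation
(R²_adj = 1 − (1−R²)/(1−mean R²_perm), 999 permutations) for the three
models E, S (longitude, latitude, depth) and E+S, then
shared = adjR²(E) + adjR²(S) − adjR²(E+S), pure fractions by difference,
residual = 1 − adjR²(E+S). The four fractions sum to 1 identically; pure
and shared fractions may be slightly negative, as adjusted-R² fractions
legitimately are. All three models share one pre-drawn permutation set
(common random numbers), which makes degenerate identities (S identical
to E ⇒ pure fractions exactly 0) hold to machine precision instead of
only stochastically.

Taxa–environment relations are Spearman correlations between the most
abundant taxa (top 10 bacterial, top 5 archaeal/fungal by mean relative
abundance, at phylum-with-Proteobacteria-split or genus rank) and every
numeric covariate. Stars follow the raw p-value (*, **, *** at 0.05,
0.01, 0.001); a BH-adjusted column is emitted alongside because raw-star
heatmaps understate multiplicity.

## Specificity–occupancy

For species S and habitat H: specificity = (mean abundance of S over
samples of H) / (sum of those means over all habitats), occupancy =
(sites in H where S is present)/(sites in H). Abundances are per-sample
relative abundances computed after rarefaction — "mean abundance" is
unitless in the defining formula and relative abundance removes residual
depth artifacts — and the habitat mean includes zero samples. Specificity
sums to 1 across habitats for any OTU present anywhere; an OTU absent
everywhere is reported with specificity NA and occupancy 0. A specialist
has specificity ≥ 0.7 AND occupancy ≥ 0.7 (inclusive); above threshold
0.5 an OTU can be specialist of at most one habitat.

## Co-occurrence networks

Networks are built per latitudinal region and domain independently —
including the BH adjustment, which is applied across all tested pairs of
that one network (whether to adjust per network or globally is a
reporting choice; per-network is implemented and stated here). Filters
follow the strict reading of their thresholds: prevalence strictly
greater than 50% of the region's samples, |ρ| strictly greater than 0.7,
adjusted p strictly below 0.05. Spearman p-values use the t
approximation with midranks, which is accurate at these sample sizes and
fast for thousands of pairs; constant OTU vectors have undefined ρ and
their pairs are skipped with a warning.

Topology: nodes and links, avgK = 2L/N, average local clustering
coefficient with degree-1 nodes contributing 0, fraction of positive
edges, and Newman modularity Q of the partition found by greedy
agglomeration (CNM) on the unsigned, unweighted skeleton — deterministic,
and within 0.05 of the exhaustively best partition on small graphs in
tests. Empty networks report zeroed metrics with an `empty` flag rather
than raising.

## Synthetic-transect generator

The generator emulates the study design the analyses assume: 72 stations
uniform over 60–80 °N and 155–180 °W (west longitudes stored as negative
degrees east for unambiguous haversine input), with depth stepping from a
shelf mean of 196 m below 75 °N to a basin mean of 1017 m above, salinity
and pH rising linearly with latitude, temperature and organic carbon
falling, and nutrients declining weakly — all with Gaussian noise scaled
by one global `env_noise_sd` knob (at 0 the linear covariates correlate
exactly ±1 with latitude).

Community counts come from a log-normal latent field sampled through a
negative-binomial observation model (variance μ + dispersion·μ², default
dispersion 0.3; dispersion 0 degrades to Poisson). Sequencing depth
defaults to 20 000 reads/sample, and per-domain OTU richness to 300
bacterial, 120 archaeal and 120 fungal OTUs — free parameters of the
design, set to plausible amplicon-survey scales.

Three features are planted, deliberately orthogonal so each downstream
stage recovers exactly its own signal:

* **Turnover.** Each ordinary OTU gets a spatial field: a Gaussian-kernel
  mixture (bandwidth 2.5° latitude) of four region archetypes, centred
  and rescaled to unit range across sites, multiplied by the domain's
  `turnover_rate` (defaults archaea 1.7 > bacteria 1.3 > fungi 0.9).
  Unit-range normalization makes the fitted DDR slope scale with the
  turnover knob independently of domain richness, and caps the regional
  contrast of ordinary OTUs so none can reach specialist-level
  specificity by chance (worst case ≈ 0.67 over 25 validation seeds,
  against the 0.7 threshold). The defaults realize fitted slopes of
  about −0.009, −0.007 and −0.004 per 100 km with the planted ordering
  recovered, significantly, on every validation seed.
* **Specialists.** `n_specialists_per_region` OTUs per band (default 3)
  have no spatial field; instead their log abundance is a low baseline
  (N(−3.2, 0.3)) plus log(boost) inside the home band and −log(boost)
  outside (default boost 50). The low baseline keeps their home-region
  read share at ~0.5–2% so they do not distort community-level distance
  decay, while home counts stay in the hundreds, making home occupancy
  ≈ 1 and specificity ≈ 1.
* **Co-occurrence blocks.** `n_cooc_blocks` groups of `block_size` OTUs
  (default 3 × 8) share a uniform(−1, 1) latent factor, centred within
  each latitude band so block membership cannot masquerade as regional
  specificity, scaled by `block_loading` (default 2.5 — chosen because
  2.0 leaves within-block rank correlations ≈ 0.77, too close to the
  strict 0.7 edge threshold to survive count noise reliably). Block
  baselines are offset by −0.5 to compensate E[e^{λf}], keeping block
  read share ordinary so blocks do not dilute the turnover signal.

All defaults above were fixed by design-time simulation of the
generator's own diagnostics (slope separation, worst-case specificity,
block-component recovery over 25 seeds) before the validation suite was
frozen, and are study conditions, not tuning knobs.

What the generator does **not** emulate: compositional coupling beyond
the shared normalization, phylogenetic correlation of abundances,
distance decay in the east–west direction (structure follows latitude
only, so longitude scatter adds realistic noise to the DDR), habitat
covariance of specialists with environmental covariates, and any
read-level artifacts (chimeras, clustering error). Passing tests
demonstrate that the statistical machinery recovers structure of the
planted kind at realistic noise levels — not that real Arctic sediment
communities behave like the generator. In particular, on synthetic data
the pure-environmental VPA fraction is near zero (the covariates are
noisy proxies of the same latitude axis that drives turnover, so space
subsumes them); the relative sizes of E and S fractions in real data are
an empirical outcome, not a property this package asserts.

## Numerical choices and degenerate inputs

* Permutation p-values always use the +1 correction; permutation counts
  default to 999 everywhere.
* All randomness flows from one root seed through named substreams
  (CRC32 of the stage name folded into the seed, kept < 2³¹), so any
  stage is reproducible in isolation and full pipeline runs are
  byte-identical under a fixed config.
* Rarefaction deeper than a sample's total raises, naming the offending
  samples; depth 0 yields all-zero rows.
* Constant vectors: Spearman pairs are skipped (networks), Mantel on a
  constant matrix raises, flat similarity yields slope 0 / R² 0, constant
  taxa report NA correlations.
* VIF with exact collinearity reports ∞ and is pruned first.
* Floating-point output uses fixed `%.10g`/`%.12g` formatting so written
  TSVs are byte-stable.

## Known limitations

* The DDR t-test treats pairs as independent, which they are not; use the
  permutation flag when the p-value matters.
* PERMANOVA is sensitive to dispersion differences between groups; no
  PERMDISP companion test is provided.
* Spearman-threshold networks ignore compositionality; no SparCC-style
  correction is attempted.
* CCA assumes unimodal species responses; no detrending or db-RDA
  variants are provided.
* One-way designs only; no nested or multi-factor permutation schemes.
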