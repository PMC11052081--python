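# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations behind the package. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Plate correction and CLPP statistics

**Correction.** EcoPlate color development is quantified per well and
timepoint as `(OD590 − OD750) − c(t)`, where the 750 nm read captures
turbidity (e.g. fungal growth) and `c(t)` is the mean of the three water
blanks after their own 590−750 subtraction. Two conventions are ours:

- *Control aggregation.* The mean of the three blanks is used (rather than a
  single designated blank) to reduce blank-to-blank noise.
- *Clipping.* Negative corrected values are set to 0. Negative color
  development is physically meaningless, and letting negative wells persist
  would deflate AWCD averages; the cost is a small upward bias exactly at
  zero signal.
- *Time grids.* The 590 and 750 nm channels must be measured on identical
  time grids; no interpolation is attempted, because both wavelengths come
  from the same read session in practice.

**AWCD.** `AWCD(t) = Σᵢ ODᵢ(t) / n` with replicate wells averaged per
substrate first and `n` the number of substrates in the chosen subset (all
31, or one carbon category). Averaging replicates before any index
computation is the default; per-replicate computation is available by
constructing profiles from individual replicate series.

**Richness.** A substrate counts as oxidized when its replicate-averaged
corrected OD is ≥ 0.5 (default threshold) at two *consecutive* reads — the
consecutiveness requirement suppresses single-read noise spikes. Richness is
reported as the **count** of oxidized substrates; a variant that sums the
qualifying OD values is exposed (`richness(..., mode="sum")`) but not used
by defaults, since the quantity is conventionally an index of substrate
number.

**Diversity indices.** From `Pᵢ = ODᵢ / Σⱼ ODⱼ` at a reference timepoint:
Shannon `H = −Σ Pᵢ ln Pᵢ` (zero entries contribute 0) and the **log-form
Simpson index** `D = −ln Σ Pᵢ²`. The log form (0 for a single substrate,
ln N at uniform use) is the pipeline's reported quantity; the classical
Gini–Simpson `1 − Σ Pᵢ²` is provided as `gini_simpson` for users who expect
the conventional definition, but no default code path calls it. When a
plate shows zero total color development, the indices are reported as
undefined (None), never as 0 — an inactive plate carries no composition
information.

**Reference timepoint.** Plate-reader campaigns rarely state which read the
indices summarize. The default is the detected stable-phase onset, falling
back to the final read when the curve is still rising; any explicit time on
the grid can be requested instead. The pipeline additionally exports the
full per-timepoint AWCD table so downstream users are not bound to one
choice.

**Phase detection.** Slopes are taken between consecutive timepoints. The
exponential phase starts at the first slope above `slope_eps`; the stable
phase starts at the first timepoint after which no slope ever exceeds
`slope_eps` again, provided at least `window` quiet steps are observed.
Defaults: `window = 3` reads, `slope_eps` = 2 % of the final AWCD per 24 h.
Against noise-free logistic inputs this rule lands within one 24 h sampling
interval of the analytic 99 %-saturation time (tested).

## Community statistics

Shannon diversity and Pielou evenness `E = H / ln S_obs` are computed per
sample on relative abundances; `E` is undefined for single-ASV samples. The
plate indices and the ASV-table indices share one entropy routine.

Bray–Curtis dissimilarity is computed on relative abundances by default
(raw-count basis available), via `scipy.spatial.distance`.

ANOSIM follows the rank-based definition:
`R = (r̄_between − r̄_within) / (M/2)` with all `M = n(n−1)/2` distances
ranked using midranks for ties. The p-value uses the add-one estimator
`p = (1 + #{R_perm ≥ R_obs}) / (1 + n_perm)` under seeded label
permutations; for small designs an exact mode enumerates every distinct
labeling (identity included). The implementation is cross-checked in the
test suite against both a brute-force enumeration oracle and scikit-bio.

## Co-occurrence networks

Construction: keep the `k = 200` ASVs with the highest total relative
abundance (ties broken lexicographically for determinism); compute all-pairs
Spearman ρ with midrank ties and two-sided p from the t approximation with
n−2 degrees of freedom (exact rank-permutation p available for n ≤ 8);
Benjamini–Hochberg-adjust the strict upper triangle; retain edges with
`|ρ| > 0.6` **and** adjusted `p < 0.05`; partition with Louvain at
resolution 1.0 under a mandatory seed and report Newman–Girvan modularity Q.

**Correlation basis.** The screen runs on the abundance table *as given*
(counts) by default, with per-sample relative abundance available as an
option (`basis="relative"`). Row normalization places the shared sample
total in every denominator; when totals vary across samples — which they
necessarily do whenever coherent groups of taxa rise and fall together —
this injects spurious cross-group rank correlations strong enough to pass
the `|ρ| > 0.6` gate (the classic compositionality artifact). On
planted-guild benchmarks the proportion basis merges planted modules, while
the counts basis recovers them cleanly, so counts are the default. Plain
Spearman on either basis is not a compositionality-aware method (unlike
e.g. SparCC or SPIEC-EASI, which are deliberately out of scope); on real
amplicon data, where only compositions are observable, edges should be read
as associations in the observed abundances, not as proof of ecological
interaction.

**Modularity treatment of signs.** Q is computed on the unweighted,
sign-agnostic edge set by default, matching common practice in graph tools
used for microbial networks; a `signed=True` option weights edges by |ρ|.
Edgeless graphs return an undefined (None) Q rather than 0.

Edge-sign summaries report the positive-edge fraction overall, within each
domain, between domains, and per unordered phylum pair; strata without edges
are omitted rather than reported as 0/0.

## Synthetic data generators

**Plates.** Per-substrate color development is logistic,
`K / (1 + exp(−r (t − t₀)))` — the simplest family with an exponential phase
followed by a plateau. The 590 nm channel adds a per-well turbidity level,
Gaussian instrument noise, and a slowly drifting shared baseline; the
750 nm channel carries turbidity and noise only; control wells carry the
baseline only. Defaults emulate a 100-day incubation read every 24 h.
Per-substrate kinetics default to K ~ U(0.8, 1.6) OD, r ~ U(0.008, 0.03) /h,
t₀ ~ U(300, 900) h — order-of-magnitude choices for multi-week cold-water
incubations; no published dispersion data exist for plate noise, so
`od_noise_sd = 0.01`, turbidity 0.05 ± 0.01, and control drift 0.002 OD per
day are similarly order-of-magnitude. A sample is characterized by a
substrate-affinity vector in [0, 1] scaling each asymptote.

**ASV tables.** Per sample s and guild g a latent factor `f_{s,g} ~ N(0,1)`
is shared by the guild's ASVs: `z = √ρ·f + √(1−ρ)·ε`, so within-guild latent
correlation is exactly the configured `within_guild_rho` (default 0.95, 4
guilds of 20 ASVs, 20 samples). Counts are `Poisson(exp(μ_a + z + effects))`
with per-ASV log-normal abundance (μ_a ~ N(ln 100, 0.8²)) — a log-normal
latent with Poisson rounding is simpler to parameterize than a
Dirichlet-multinomial and adequate for rank-based downstream statistics.
Modest environmental structure is added through per-ASV depth and
layer coefficients (sd 0.1 and 0.15 on the log scale). These scales are
deliberately subordinate to the guild factor: environment effects and count
noise attenuate rank correlations, and the generator is required (and
tested) to keep the mean within-guild Spearman ρ of the *counts* within 0.1
of the configured latent value. Taxonomy interleaves archaeal
(Nitrososphaeria, Halobacteria, Thermoplasmata) and bacterial
(Alpha-/Gammaproteobacteria, Actinobacteria, Bacteroidia, Cyanobacteriia,
Anaerolineae) lineages within every guild, so domain-stratified edge
summaries are populated.

**Metadata.** Water-column profiles are deterministic smooth shapes, not
fits: temperature decays from ≈19.9 °C at the surface to ≈1.1 °C at 5000 m;
salinity has a subsurface minimum (lowest at 800 m among the standard
sampling depths 0/200/800/2000/5000 m); nutrients increase monotonically
with depth. BBL stations sit near the deep endpoint with elevated
nutrients.

**What the generators do not emulate.** Real plate data show well-to-well
carryover, non-logistic (diauxic, lagged) kinetics, and replicate
heteroscedasticity; real ASV tables are compositional with library-size
variation, zero inflation, overdispersion beyond Poisson, and negative
(exclusion) correlations — the planted structure is purely positive
co-variation, so negative edges arise only from sampling noise. Passing
tests therefore demonstrate correctness of the computations and
recoverability of planted structure under the stated model, not performance
guarantees on field data.

## Determinism and problem sizes

All stochastic steps (generators, ANOSIM permutations, Louvain) take
explicit seeds; the pipeline manifest records the config snapshot, seed,
and SHA-256 of every input and output, and a replay from the manifest
reproduces identical hashes. No stage reads the wall clock for numerics.

Test and benchmark sizes are chosen so the full suite runs in well under a
minute on one CPU: 80-ASV / 20-sample tables for network benchmarks (3160
correlation pairs), 20 replicate generator seeds for the parameter-recovery
check, exhaustive oracles only at enumerable sizes (6-sample ANOSIM
labelings, ≤ 8-node graph partitions, n ≤ 8 exact Spearman permutations).
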