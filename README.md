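# clpp

Community-level physiological profiling (CLPP) and co-occurrence network
analysis for depth-stratified marine microbial communities.

Marine prokaryotes drive the decomposition and remineralization of sinking
organic matter, and both their carbon-source preferences and their
association patterns shift from the surface ocean down to the benthic
boundary layer (BBL). This package implements the computational side of a
combined culture-based / sequence-based workflow for studying that vertical
structure:

1. **Biolog EcoPlate kinetics.** A 96-well EcoPlate carries 31 carbon
   substrates (6 categories: carbohydrates, polymers, phenolic, carboxylic,
   amino acids, amines) in triplicate plus water blanks. Color development
   is read at 590 nm with a parallel 750 nm turbidity read. The package
   corrects each well as `(OD590 − OD750) − control(t)` (clipped at 0) and
   computes, per plate:
   - average well color development, `AWCD(t) = Σᵢ ODᵢ(t) / n` over the n
     substrates of the plate or of one carbon category;
   - richness *R* — the number of substrates whose corrected OD reaches 0.5
     at two consecutive reads;
   - the relative color development `Pᵢ = ODᵢ / Σⱼ ODⱼ` and from it the
     Simpson index `D = −ln Σ Pᵢ²` (log form) and Shannon index
     `H = −Σ Pᵢ ln Pᵢ`;
   - growth-phase onsets (exponential / stable) from the AWCD slope.
2. **ASV community statistics.** Relative abundance, Shannon diversity and
   Pielou evenness per sample, Bray–Curtis dissimilarity
   `d = Σ|x−y| / Σ(x+y)`, and rank-based ANOSIM with a seeded
   label-permutation null (exact enumeration available for small designs).
3. **Co-occurrence networks.** Top-k abundant ASVs, all-pairs Spearman ρ,
   Benjamini–Hochberg FDR on the correlation p-values, edges where
   `|ρ| > 0.6` **and** adjusted `p < 0.05`, Louvain partitioning with Newman
   modularity Q (Q > 0.4 read as modular structure), and positive/negative
   edge proportions overall and per taxonomic stratum
   (archaea–archaea, bacteria–bacteria, archaea–bacteria, phylum pairs).
4. **Synthetic data.** Generators for dual-wavelength plate time series
   (logistic color development per substrate) and ASV tables with *planted
   guilds* — groups of taxa sharing a latent factor — plus depth-gradient
   sample metadata, so the entire pipeline is testable without any
   sequencing data.

The package is a library first (`import clpp`); `examples/` holds one short
narrative script per capability, and a thin `clpp` command-line tool wraps
the pipeline for shell use.

## Worked example

`python examples/03_cooccurrence_network.py` simulates an 80-ASV table with
4 planted guilds (latent within-guild correlation 0.95, 20 samples) and runs
the full network construction:

```
nodes: 80, edges: 773, isolated: 0
modularity Q = 0.733  (> 0.4 indicates modular structure)
modules recovered: 4 (sizes [20, 20, 20, 20]) vs 4 planted guilds

edge signs by taxonomic stratum:
          stratum  n_edges  positive_fraction  negative_fraction
          overall      773                1.0                0.0
  archaea-archaea       41                1.0                0.0
bacteria-bacteria      425                1.0                0.0
 archaea-bacteria      307                1.0                0.0
```

The Louvain partition recovers the four planted guilds exactly, Q = 0.733
is near the theoretical ceiling for four equal modules (1 − 1/4 = 0.75),
and all retained edges are positive because the planted structure is
co-variation within guilds. The other examples cover plate profiling
(`01`), Bray–Curtis + ANOSIM habitat comparison (`02`), and the end-to-end
pipeline with its replayable manifest (`04`).

The same analyses run from the shell:

```bash
clpp run --out demo/            # simulate → profile → community → network
clpp report --manifest demo/manifest.json
clpp replay --manifest demo/manifest.json --out demo2/   # verifies hashes
```

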