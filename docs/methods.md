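# Methods

## The model

`divergesim` simulates pairs of diploid Wright–Fisher populations diverging
under quantitative-trait selection, and asks how demography shapes the genome
scan statistics F_ST, D_XY and Δπ computed between them.

Each simulated unit is a fixed-length genomic region (25 kb at full scale)
containing one centrally placed multi-exon gene that acts as a QTL. Mutations
arrive at rate μ per bp per gamete per generation, uniformly over the region.
Inside exons, 7/10 of mutations are non-synonymous and receive an additive
phenotypic effect drawn from Normal(0, μ_σ); synonymous, intronic and
intergenic mutations are neutral. An individual's phenotype is the
dosage-additive sum of its non-synonymous effects (plus the contribution of
fixed substitutions). Gametes recombine with crossover counts
Poisson(r·L) and uniform breakpoints.

Fitness is Gaussian around a phenotypic optimum, rescaled so the optimum has
fitness 1:

    w_sel(z) = exp(−(z − opt)² / (2 σ²))

The ancestral population (AP) always has opt = 0, σ = 1. The diverged
population (DP) has opt = 10 with σ = S_σ = 10^(−S) in the divergent regime,
opt = 0 in the null regime; the neutral regime applies no selection at all.
Each region's selection strength S is drawn once from Uniform(−1, 1) and
shared by all treatments, so S_σ spans 0.1 (steepest peak) to 10 (nearly
flat). Individuals additionally pay a competition cost for phenotypic
proximity: every pair closer than C_dist = 1.2 contributes
C_max·exp(−d²/(2·C_σ²)) (C_max = 1, C_σ = 0.4) to both members' penalties.

How selection and competition combine is a modelling choice (the Wright–
Fisher literature offers several): the default is density-dependent,
w = w_sel / (1 + C/N), which keeps fitness positive; a multiplicative form
w = w_sel·exp(−C/N) is available via `SimParams.fitness_combination`.
Competition applies whenever selection does (burn-in and divergence phases).

A run is: a burn-in of one population of N = 1000 for 5·2N = 10,000
generations under stabilizing selection around 0 (neutrally, in the neutral
regime); a split in which AP keeps all 1000 individuals and DP is founded by
BN individuals sampled without replacement (founding bottleneck, BN ∈ {100,
1000}); then 10,000 generations of divergence with DP held at dp_fraction ×
1000 individuals (prolonged bottleneck, ∈ {10, 100, 500, 1000}) and symmetric
migration m ∈ {0, 0.002} (each offspring takes both parents from the other
deme with probability m, fitness-proportionally within the source deme).
The 2 × 4 × 2 factorial gives 16 demographic treatments; a shared cohort of
100 regions is iterated 20 times per treatment per regime at full scale.

Within a generation the order is: fitness → parent choice (with migration) →
recombination → mutation → fixation purge. Parent sampling evaluates fitness
in log space shifted by the deme maximum; this is algebraically identical to
sampling proportional to raw fitness but immune to underflow when a deme
starts 100 σ from a steep optimum (raw Gaussian fitness underflows at
~exp(−745)). The founding bottleneck samples diploid individuals, not
haplotypes.

## Statistics

All statistics are single region-wide values over all sites, monomorphic and
polymorphic, mirroring windowed genome scans:

* π — mean pairwise difference per site, with the n/(n−1) small-sample
  correction (DP samples can be as small as 20 haplotypes).
* F_ST = 1 − ΣH_S / ΣH_T as a ratio of sums across sites (robust at
  low-diversity sites). H_S is the unweighted mean of the two within-deme
  expected heterozygosities; H_T uses the unweighted mean allele frequency
  (Nei's convention), which guarantees H_T = H_S + (p₁−p₂)²/2 and hence
  F_ST ∈ [0, 1] even with a 100-fold size difference between demes. F_ST is
  missing when H_T = 0.
* D_XY — mean per-site difference over all between-deme haplotype pairs,
  normalized per pair and per site (an unnormalized double-sum mode exists
  for audit; it scales with sample size and cannot be compared across DP
  sizes). Substitutions privately fixed in one deme since the split are
  counted through a per-deme ledger.
* Δπ = log₁₀(π_AP/π_DP); missing (not ±∞) when either π is 0.

At each of 12 sampling points (1%, 5%, 10%, 20%, …, 100% of the divergence
period — generations 100, 500, 1000, 2000, … 10,000 at full scale) each
statistic is computed per generation over the preceding 20 generations and
averaged, missing values excluded; a window is truncated at the previous
sampling point in very short test runs. `pheno_gen` records the first
generation DP's median phenotype comes within 1 unit of its optimum
(a threshold is needed because the optimum is approached asymptotically);
runs that never arrive carry the final generation and a censored flag.

The haplotype representation is a 0/1 matrix over currently segregating
sites. Columns fixed in all demes (or lost everywhere) contribute nothing to
any statistic and a constant to phenotypes, so they are folded into per-deme
phenotype offsets and purged lazily (every 25 generations, and whenever
statistics are collected); without migration, columns fixed in one deme and
lost in the other move to the substitution ledger. Purging is exactly
invariant for every statistic (tested bit-for-bit). Two mutations at the
same bp are kept as separate sites (infinite-sites on a discrete grid);
collisions are rare at the simulated θ and only affect the exon lookup and
recombination mapping, not the statistics.

## Downstream analyses

* **Correlations** — Pearson r of each measure against S (and against each
  other) across regions, per treatment × generation × iteration, averaged
  with equal weight over iterations, optionally further averaged within
  levels of one demographic factor. Cells with < 3 complete pairs or zero
  variance are missing and counted. Missing statistics are dropped pairwise.
* **Outliers and spike-in error rates** — outliers are values strictly above
  the empirical 95% quantile (type-7 interpolation; ties at the cut excluded,
  so a set never exceeds 5%). The spike-in permutation pools all neutral
  records of a treatment × generation, replaces a random 5% (one record per
  region) with divergent-regime records of the same regions, calls outliers
  per measure, and averages FPR (neutral fraction of the outlier set) and FNR
  (spiked records missed) over 100 permutations. Combined-measure sets are
  intersections; an empty intersection has FPR 0 and FNR 1.
* **Overlap ("convergence")** — proportional overlap |A∩B| / mean(|A|,|B|)
  (Jaccard available) of outlier *region* sets between treatments, within
  each permutation replicate, averaged over replicates; treatments are
  ordered by average-linkage clustering on 1 − overlap with deterministic,
  input-order-preserving tie-breaks.
* **Mixed models** — per measure and migration stratum at the final sampling
  generation: measure ~ S + gene length + exon N + coding fraction +
  pheno_gen with crossed random intercepts for region and treatment, REML via
  statsmodels MixedLM. Predictors are z-scored (raw-scale refits are a
  keyword away); censored pheno_gen records are excluded and counted;
  zero-variance predictors and singular random terms are dropped with a log
  note. Variance explained is reported as marginal (fixed) and conditional
  (fixed + random) percentages of the fixed + random + residual total; the
  reported df is the residual df, an approximation (no Satterthwaite).

## Scaled profiles

The full factorial (100 regions × 16 treatments × 3 regimes × 20 iterations
× 20,000 generations at N = 1000) is hours-to-days of compute and is what
`full_plan` describes. Tests and the replication script use scaled profiles
chosen so the population-scaled parameters match the full profile:

* **desk** (`desk_plan`): N = 100, 2.5 kb regions, 1000 + 1000 generations,
  μ = 4.89e−5 and r = 1e−5 (the full profile's own 10× alternate scaling, so
  4Nμ and 4Nr are unchanged), m ∈ {0, 0.02} (preserving 4Nm = 8), 16 regions
  × 5 iterations over the grid {DP 0.1, 1.0} × {m off, on} with no founding
  bottleneck — the factors with first-order effects. Fitness functions stay
  on their absolute scale, mirroring how the full profile's mutation-rate
  scalings are treated as populations of larger effective size; a
  `selection_scale` knob implements the alternative 2Ns-preserving rescaling
  but is off by default, because scaled selection drives sweeps hard enough
  to swamp the segregating-site signal that makes D_XY sensitive to DP size.
* the trend-replication fixture widens desk to 40 regions × 2 iterations
  (region count, not iteration count, sets the precision of across-region
  correlations);
* **micro**: 4–5 regions, N = 40–50, a few hundred generations — a
  seconds-scale smoke profile for schema and integrity tests.

What scaled runs do and do not show: the directional effects of prolonged
bottlenecks and migration, the early Δπ peak at the sweep era, and the
migration dependence of the F_ST–S correlation all reproduce at desk scale.
Absolute magnitudes do not transfer (for example, desk spike-in pools are 80
records with a 20% spike rather than 2000 with 5%, so error rates are
coarser), and effects the full profile develops only late (D_XY's slow
response without migration) are weak at one-tenth the region length.

## Synthetic fixtures

Downstream stages are additionally tested on distribution-level fixtures
that bypass the simulator: records with an exactly injected measure–S
correlation (r·S/sd(S) + √(1−r²)·ε construction), neutral/divergent pools
with a configurable location shift (0 = exchangeable, large = perfectly
separable), and block-structured outlier sets with known within/between
overlap. These share the production TSV schema so the permutation and
overlap code paths are identical; they do not emulate linkage within
regions, so they validate the analysis machinery, not the population
genetics.

## Numerical and degenerate-input conventions

Missing values propagate as NaN and are dropped pairwise downstream with
counts logged. F_ST with H_T = 0, Δπ with a zero π, correlation cells
without variance, and overlap between two empty sets are all missing rather
than 0 or ±∞. Statistics require ≥ 2 haplotypes per deme (≥ 1 for D_XY).
If every parent weight in a deme is non-finite the engine falls back to
uniform parent choice and counts a warning; with log-space fitness this is
unreachable for finite phenotypes. Seeds derive hierarchically from a master
seed via `numpy.random.SeedSequence` spawn keys
(kind, region, treatment index, regime index, iteration), so results are
independent of execution order and of which cells are re-run after a resume.

## Known limitations

Two demes only; constant sizes after the split; no population expansion,
spatial structure or temporal demographic fluctuation; no explicitly
deleterious mutation class (background selection is only mimicked insofar as
stabilizing selection removes variation); hermaphrodites with selfing
allowed, as in standard Wright–Fisher implementations. How forward
simulators combine competition with selection, and whether migrant parents
are drawn fitness-proportionally, are not uniquely determined conventions;
both choices here are explicit and configurable where alternatives are
defensible.
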