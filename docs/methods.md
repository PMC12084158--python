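# Methods

## The model

Chromatin accessibility over a reference set of clock-like loci
(typically clock-like differentially methylated CpG loci, "ClockDML")
carries a record of mitotic history: as a cell accumulates divisions,
the initially heterogeneous open/closed pattern over these loci
converges toward a homogeneous, broadly open state. The per-cell count
of reference-overlapping ATAC peaks with non-zero coverage —
**ClockAcc** — therefore rises with mitotic age, and its rank across
cells is a relative age estimate.

A raw per-cell ClockAcc from sparse scATAC-seq is noisy, so the
estimator borrows strength across phenotypically similar cells:

1. **Reference peaks.** ATAC peaks overlapping ≥ 1 clock-like locus
   (half-open interval semantics) form the reference; no overlap is a
   hard error.
2. **ClockAcc.** `value[c] = |{p ∈ ref : counts[p, c] > 0}|`. "Opened"
   is defined as any non-zero count at a reference-overlapping peak —
   the minimal assumption workable at scATAC sparsity. Optional
   censor-normalization winsorizes counts per peak at the 95th
   percentile across cells before the test (off by default).
3. **Similarity.** Cells are correlated (Pearson; Spearman available)
   over the top 5% of peaks by dispersion (Fano factor
   variance/mean on raw counts; CV available). The correlation matrix
   is thresholded at its global mean (diagonal included), negatives
   clipped at zero, and each row normalised to sum 1, giving a
   row-stochastic similarity matrix S. Rows that become all-zero fall
   back to identity rows; constant cells get zero correlation with
   everyone.
4. **NNLS.** Assuming phenotype similarity mediates the smoothed
   signal, `x = argmin ‖S·x − c‖₂, x ≥ 0` is solved by the
   Lawson–Hanson active-set algorithm, deconvolving the measured
   ClockAcc c against S.
5. **Reaction-diffusion.** x is relaxed by `x ← w·x₀ + (1−w)·S·x`
   (w = 0.5, tol 1e−4 on max|Δx|, ≤ 100 steps), where x₀ is the NNLS
   solution re-injected each step as the reaction source. The fixed
   point `x* = w(I − (1−w)S)⁻¹x₀` blends each cell's own evidence with
   a geometrically decaying series of neighbourhood averages. A pure
   averaging mode (`diffusion.mode = "pure"`, `x ← w·x + (1−w)·S·x`)
   is provided; its fixed point on a connected graph is the global
   consensus (constant) vector, so it progressively discards the
   per-cell signal the estimator needs — we use it only as the
   degenerate limit in tests. `S·x_final` is the smoothed ClockAcc.
6. **Rank.** Smoothed values are ranked (average ranks on ties) and
   scaled as (rank−1)/(n−1). Smoothed values are first snapped to 12
   relative digits so floating-point dust cannot reorder effectively
   tied cells; a single sample maps to 0.5. Bulk samples report
   1 − rank (see below); single-cell ranks are never reversed.
7. **Iteration.** All peak counts are correlated with the age
   estimate; correlations are z-scored across peaks and peaks with
   Z > 3 (and r > 0 — the method counts *opening* loci; a signed
   option exists) join the reference. The loop repeats until the
   Spearman correlation between successive age vectors exceeds 0.99 or
   5 outer iterations, whichever comes first. Non-convergence is
   flagged, not fatal.

**Why bulk ranks are reversed.** A pooled sample of young cells is
heterogeneous: each cell opens its own subset of clock loci, so the
pool covers many of them and ClockAcc is large. As the population
ages the per-cell patterns converge, and pooled coverage of distinct
loci falls. Bulk ClockAcc therefore orders samples from old to young,
and the rank is reported as 1 − rank. Bulk mode runs a single
smoothing pass (iterative expansion is designed for sparse single-cell
data; a flag enables it for bulk).

## Companion procedures

**Entropy.** The diversity of clock-locus accessibility is the Shannon
entropy of p(x) = per-peak summed counts / grand total over the
reference peaks, in nats (base-2 flag available), with 0·log 0 := 0.

**Clock-locus discovery.** Given a CpG beta matrix with donor ages,
loci with |Pearson r(beta, age)| ≥ 0.7 are clock-like. They are
clustered by average-linkage hierarchical clustering (Euclidean, on
per-locus beta profiles with samples ordered by age; k = 10 by
default, k configurable) and the group whose mean beta correlates most
negatively with age is flagged — the hypomethylating family whose
accessibility rises with age. Ties break toward the lower group id.

**DNAm age model.** Loci with mean coverage strictly > 30× enter a
PCA of the centred loci × samples beta matrix; donor age is regressed
on the PC1 score (ordinary least squares, age untransformed — the
model targets adult cohorts). The PC1 sign is fixed so the slope is
non-negative, making predictions deterministic. At prediction time,
model loci missing from the new matrix are imputed at their training
means (warning; > 50% missing is an error), and a sample at the
training mean predicts the training mean age by construction.

**Cluster phylogeny.** Per-cluster mean accessibility profiles over
the reference peaks give a Euclidean distance matrix; neighbor joining
builds the topology (negative NJ branch lengths are clamped to zero
with a warning) and the tree is re-rooted on the branch of the
cluster with minimal mean inferred age — the outgroup closest to the
mitotic ground state. The default profile uses the initial
reference-overlapping peaks; a flag switches to the expanded set.

**Peak–age association.** The same peak-wise correlation used for
reference expansion, re-exported with two-sided flagging (|Z| above a
cutoff), since peaks closing with age are biologically informative
even though they never join the reference.

**Cross-species mapping.** Genes whose TSS (strand-aware: interval
start for +, end−1 for −) lies within ±100 bp of a clock locus carry a
"promoter clock locus". For each such gene, all target-species peaks
within ±100 bp of an ortholog's TSS (or the promoter windows
themselves when no peak set is given) become putative clock-like loci.
The window is symmetric, so only TSS placement depends on strand.
Chain-file liftover between assemblies is out of scope (external
tools exist for it); this module covers the orthology route.

## Synthetic data

The generators plant known ground truth so every pipeline is testable
offline.

*Single-cell* (`simulate_sc_atac`): cells draw a latent age
~ Uniform(0, 1). Three peak classes:

- **clock (reference) peaks** (default 200 of 2,000) open with
  probability p₀ + (p₁−p₀)·age (p₀ = 0.1, p₁ = 0.9; logistic curve
  available), independently per cell and locus — the heterogeneous,
  stochastically converging signal the method measures;
- **age-responsive program peaks** (default 100) open once age exceeds
  a per-peak threshold τⱼ ~ Uniform(0, 1), with a 5% state-flip rate
  and a 2× read rate. They model coordinated regulatory programs along
  the age axis: cells of similar age share open sets, which is what
  makes cell–cell correlation informative about age and gives the
  iterative expansion genuinely age-correlated peaks to recruit;
- **cell-type block peaks** (the remainder) open with per-block
  probabilities ~ Uniform(0.5, 0.8) over three latent blocks,
  independent of age — the confounding phenotype structure.

Open entries draw reads ~ Poisson(depth); zeros are dropout, so the
default depth 2.3 detects ≈ 90% (1 − e^−2.3) of truly open clock
entries, and depth scales detection for sparsity experiments. The
emitted clock-loci BED overlaps exactly the planted clock peaks.

What the generator does **not** emulate: fragment-length structure,
TSS enrichment, GC bias, doublets, batch effects, or continuous
lineage topologies — a passing recovery test shows the estimator's
mechanics are sound under the stated statistical model, not that it
is robust to every artefact of real scATAC data.

*Bulk* (`simulate_bulk_series`): per-sample clock-peak opening
fraction rises linearly across the series (or is drawn at random for
null calibration); counts are deep (1 + Poisson(20)), no dropout. The
planted mitotic age decreases with the opening fraction, per the
pooling argument above.

*Beta matrix* (`simulate_beta`): donor ages ~ Uniform(20, 70) years; a
rising family (beta = 0.25 + 0.5·t, t = (age−20)/50) and a falling
family (0.75 − 0.5·t) of clock loci with ±10% per-locus slope jitter
and Gaussian noise (default sd 0.02), clipped to [0, 1]; the remaining
loci are age-independent noise around a random baseline. A quarter of
loci draw coverage ≤ 30× to exercise the coverage filter.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open throughout; 1-based CpG position
  lists convert on load (`one_based=True`). No "chr"-prefix
  normalisation; disjoint chromosome name sets trigger a warning.
- Variable-peak ties break toward the lower peak index (stable sort),
  so runs are reproducible.
- A fragment overlapping k peaks counts toward all k.
- All-zero cells keep ClockAcc 0 and stay in the analysis (they read
  as young-or-undersequenced); a minimum-fragment QC filter exists but
  is off by default.
- Dense math is used below ~10⁶ matrix entries; storage is sparse CSC.
- The NNLS target on the first pass is the raw measured ClockAcc.
- Convergence diagnostics (per-iteration reference size, new-peak
  count, rho vs previous, diffusion step count) are logged and stored
  in the results metadata together with the resolved configuration.

## Problem sizes

Tests and the acceptance script run the full estimator at 500 cells ×
2,000 peaks (200 clock peaks), the bulk pipeline at 8 samples, clock
discovery at 200 loci × 24 samples, and the phylogeny at 4 clusters ×
100 cells; these sizes exercise every code path while keeping the
whole suite in the seconds-to-minutes range on a single CPU.

## Known limitations

- Recovery quality depends on sequencing depth; at 10× sparser
  coverage the rank correlation with planted age drops from ≈ 0.95 to
  ≈ 0.86 under the default generator, and will degrade further on
  data without coherent age-responsive programs.
- The estimate is a *relative* rank within the analysed population,
  not an absolute division count; comparing ranks across datasets
  requires a shared reference and comparable depth.
- The similarity matrix assumes phenotype correlation is informative
  about age similarity. Where strong age-independent substructure
  dominates the variable peaks, smoothing can blur age across groups.
- Reference expansion admits only positively age-correlated peaks by
  default; a trajectory whose clock loci close with age would need
  the signed option.
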