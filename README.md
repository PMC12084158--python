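# epitrace

Mitotic-age inference for single-cell and bulk ATAC-seq from the
accessibility of clock-like genomic loci.

## The problem

Single-cell ATAC-seq orders cells by phenotype, but phenotype
similarity alone cannot say which cells are *older* — how many
divisions they have accumulated. Certain genomic loci (clock-like
differentially methylated loci, ClockDML) drift epigenetically with
age, and their chromatin accessibility converges toward a homogeneous
open state as cells divide. Counting the fraction of such reference
loci that are open in each cell gives a phenotype-independent proxy of
mitotic age, usable for lineage ordering, rooting cluster phylogenies
and relating regulatory programs to cellular age.

This package implements that estimator for analysts working with
peak × cell count matrices or fragment files, plus the companion
procedures around it:

- **ClockAcc** — per-cell count of opened reference peaks, i.e.
  `|{p ∈ ref : counts[p, c] > 0}|`, optionally censor-normalized, and
  the Shannon entropy `−Σ p(x)·log p(x)` of reads over the reference;
- **denoising** — cell–cell Pearson similarity over the top 5% most
  dispersed peaks (mean-thresholded, row-normalised to a stochastic
  matrix S), non-negative least squares `min ‖S·x − c‖₂, x ≥ 0`
  (Lawson–Hanson), and reaction-diffusion relaxation
  `x ← w·x₀ + (1−w)·S·x`; the rank of `S·x*` in [0, 1] is the age
  (bulk samples report `1 − rank`);
- **iterative reference expansion** — peaks whose counts correlate
  with the age estimate at Z > 3 join the reference until the age
  vector stabilises (Spearman ρ > 0.99 between rounds);
- **clock-locus discovery** from CpG beta matrices
  (|Pearson r(β, age)| ≥ 0.7, hierarchical grouping, selection of the
  most negatively age-correlated group) and a **PC1 DNAm age model**
  (coverage > 30× filter, `age = a + b·PC1`);
- **downstream analyses** — peak–age association tables, age-bin ×
  phenotype pseudobulk, and a neighbor-joining phylogeny of cluster
  clock-accessibility profiles rooted at the youngest cluster;
- **cross-species mapping** of promoter clock loci through gene
  orthology (±100 bp TSS windows);
- **synthetic generators** for every input class with planted ground
  truth.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from epitrace import EpiTraceModel, simulate_sc_atac

matrix, clock_loci, truth = simulate_sc_atac(seed=1)   # 500 cells, 2,000 peaks
model = EpiTraceModel(matrix, clock_loci)
res = model.fit()
print(res.summary())
```

```
EpiTrace age estimation
==============================================
mode:                single_cell
cells/samples:       500
peaks:               2000
initial reference:   200 peaks
final reference:     260 peaks
outer iterations:    2
converged:           True
----------------------------------------------
iter  n_ref  n_new  rho_vs_prev  diffusion
   1    200     60           --    13 steps
   2    260      0        0.996    13 steps
```

The first pass measured ClockAcc over the 200 reference-overlapping
peaks, denoised it, and recruited 60 additional peaks whose
accessibility tracks the age estimate; the second pass changed the
age vector by less than the convergence threshold (ρ = 0.996 > 0.99),
so the loop stopped. `res.age` holds one rank-age in [0, 1] per cell:

```python
print(spearmanr(res.age, truth.true_age).statistic)   # 0.929
print(res.to_frame().head())
```

```
      cell_id  epitrace_age  clockacc  iteration_converged
0  cell_00000      0.515030     107.0                 True
1  cell_00001      0.851703     219.0                 True
2  cell_00002      0.424850      43.0                 True
3  cell_00003      0.877756     206.0                 True
4  cell_00004      0.230461      62.0                 True
```

A cell that opened 219 of the reference peaks lands near the old end
(0.85); one with 43 open peaks near the young end (0.42 — ranks mix
raw counts with information borrowed from similar cells, so the order
is not a pure sort of the `clockacc` column). The inferred ages
recover the generator's planted mitotic age at Spearman ρ = 0.93.

The same objects drive the rest of the toolkit
(`run_epitrace_bulk`, `discover_clockdml`, `fit_dnam_age`,
`build_cluster_tree`, `associate`, `map_clock_loci`), and a CLI wraps
the common paths:

```sh
epitrace simulate sc --out sim/ --seed 1
epitrace age --mtx sim/matrix.mtx --peaks sim/peaks.bed \
             --barcodes sim/barcodes.txt --clock sim/clock_loci.bed --out out/
epitrace discover-clock --beta beta.tsv --meta samples.tsv \
             --coverage cov.tsv --out clock/
```

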