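# pipflow

Preprocessing toolkit for **PIP-seq** (particle-templated instant partition
sequencing) single-cell RNA-seq data, for people who need the whole path from
raw paired FASTQ to called cells without a microfluidics-vendor pipeline:
combinatorial bead-barcode whitelisting with Hamming-1 error correction, UMI
counting into sparse matrices, ambient-profile Monte-Carlo cell calling,
species-mixing (barnyard) purity and doublet analysis, CROP-seq guide
assignment, hashtag demultiplexing, a templated-emulsification capacity
calculator, and a ground-truthed synthetic-read simulator that makes every
stage testable at desk scale.

## The models at the core

**Combinatorial barcodes.** Beads carry barcodes assembled by split-pool
ligation of four 6-bp sub-barcodes, one per 96-well plate round, followed by a
12-nt UMI: a whitelist of 96⁴ = 84,934,656 barcodes. Because the whitelist is
a full product space, whole-barcode Hamming distance ≤ 1 decomposes per
segment: a read is *exact* when every segment is in its round's set,
*corrected* when exactly one whitelist member sits at distance 1, *ambiguous*
(discarded) when two or more do. The per-segment matcher is provably
equivalent to scanning all 10⁸ barcodes and never materializes them.

**Cell calling.** Barcodes at or below a depth threshold (found at the
steepest slope of the log-log barcode-rank curve if not given) define the
ambient profile p̂. Each candidate barcode b with counts x_b and total t_b is
scored by its multinomial log-likelihood L(x_b) = log Mult(x_b; t_b, p̂);
a Monte-Carlo p-value p = (#{L(sim) ≤ L(obs)} + 1)/(R + 1) is computed against
R simulated draws (shared per total), and Benjamini–Hochberg-adjusted
p < 0.001 flags cells.

**Barnyard statistics.** Per-cell purity = max-species UMIs / total;
cells above a purity threshold (default 0.85) are species-labeled, the rest
mixed. Only a fraction 2p(1−p) of doublets are cross-species at mixing
proportion p, so the total doublet rate is observed_mixed / (2p(1−p)),
compared against the Poisson-loading expectation
(1 − e^−λ − λe^−λ)/(1 − e^−λ).

**Guide and hash rules.** A cell expresses a single guide when
top / Σ(others) ≥ 10 (none / single / multiple partition all cells). Hashtag
counts are CLR-transformed; per-hash thresholds are the 0.99 quantile of the
background (non-positive-cluster) cells, giving negative/singlet/doublet.

**Capacity calculator.** D = V / v_droplet droplets; a cell collides when it
shares a droplet (1 − (1 − 1/D)^(n−1)) or its bead barcode repeats
(1 − (1 − 1/B)^(n−1)); bisection inverts the total rate to the largest n
within a collision budget.

## Worked example

```python
from pipflow import SimConfig, lambda_for_multiplet_fraction
from pipflow.pipeline import run_simulated_pipeline

lam = lambda_for_multiplet_fraction(0.05)     # loading for ~5% multiplets
cfg = SimConfig(seed=1, n_cells=500, loading_lambda=lam, ambient_fraction=0.02)
res = run_simulated_pipeline(cfg, "workdir", n_iterations=2000)
print(res.calls.n_cells, "cells called")
print(res.recovery)
```

prints (seed 1):

```
486 cells called
{'cell_call_precision': 1.0, 'cell_call_recall': 1.0,
 'median_purity': 0.9904, 'median_purity_error': 0.0,
 'true_doublet_rate': 0.0288, 'inferred_doublet_rate': 0.0165,
 'doublet_rate_error': -0.0123, 'guide_accuracy': 1.0,
 'n_guide_cells_scored': 385, 'hash_accuracy': 0.9936}
```

All 486 occupied droplets are recovered with no false positives; the median
cell is 99% species-pure (2% ambient contamination was simulated); every
infected singlet gets its true guide; and the cross-species-corrected doublet
estimate (1.65%) sits within sampling error of the realized rate (2.88% —
only ~half of doublets are cross-species-visible at 50:50 mixing, so the
estimate from 4 observed mixed barcodes is noisy at this scale).

The capacity calculator from the shell:

```bash
$ pipflow design --volume-ul 35 --target-collision 0.06
{"n_cells": 3497, "n_droplets": 56542, ...}
```

i.e. ~3,500 cells fit in 35 µL of templates at a 6% collision budget under
the default 619-pL droplet.

## Layout

| module | role |
| --- | --- |
| `pipflow.barcodes` | schema, whitelist, Hamming-1 matcher, code generation |
| `pipflow.reads` | paired-FASTQ streaming, tag extraction, correction stats |
| `pipflow.quant` | feature assignment, UMI collapse, MatrixMarket I/O |
| `pipflow.matrix_ops` | downsampling, QC, log-normalization, pseudobulk |
| `pipflow.cell_calling` | rank-curve knee, ambient profile, Monte-Carlo test |
| `pipflow.barnyard` | purity, contamination, doublet inference |
| `pipflow.multimodal` | guide assignment, tag counting, hash demux |
| `pipflow.design` | droplet/collision capacity calculator |
| `pipflow.simulate` | ground-truthed synthetic experiment generator |
| `pipflow.pipeline` | end-to-end orchestration |
| `pipflow.cli` | `pipflow` command-line entry points |
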