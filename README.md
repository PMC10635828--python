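# spotalign

Single-cell resolution for spatial transcriptomics: `spotalign` places
individual cells from a scRNA-seq reference onto the spots of a spatial
transcriptomics (ST) sample, turning spot-level measurements (each a
mixture of roughly 1–30 cells) into a map of *which* cell sits *where*.
It is aimed at computational biologists who have a matched scRNA-seq
atlas, an ST count matrix, and global cell-type fractional abundances
from any deconvolution tool, and who want per-cell spatial positions
rather than per-spot proportions.

## Method

Let $A$ be the $N \times C$ scRNA-seq count matrix and $B$ the
$M \times S$ ST count matrix. Both are normalized to counts per million
and moved to $\log_2$ space; all shared genes $G$ are used (no gene
selection or dimension reduction). The number of cells $n_s$ in each
spot is estimated from a two-point linear fit in log-UMI space (the
lowest-UMI spot is anchored at one cell, the mean-UMI spot at a
user-chosen platform mean, e.g. 5 for Visium, 20 for legacy ST), or
supplied directly from segmentation. Each spot is expanded into $n_s$
identical *sub-spots*, giving $\bar B$ with
$L = \sum_s n_s$ columns, and the reference is resampled to a pool
$\bar A$ of exactly $K = L$ cells whose per-type counts follow the
input fractions (duplicating real cells, or generating gene-wise
resampled placeholder cells for benchmarking). The mapping is then the
balanced linear assignment

$$x^* = \arg\min \sum_{k,l} d_{kl}\,x_{kl}, \qquad
\sum_l x_{kl} = 1, \quad \sum_k x_{kl} = 1,$$

with cost $d_{kl} = -\mathrm{corr}(\bar A_k^G, \bar B_l^G)$ (Pearson by
default; Spearman and Euclidean available). The problem is solved
exactly by a shortest-augmenting-path (Jonker–Volgenant) solver that
also returns dual potentials $u, v$; the reduced costs
$r_{kl} = d_{kl} - u_k - v_l \ge 0$ and strong duality
$\sum u + \sum v = \text{total cost}$ certify global optimality of
every mapping. An integer-rounded variant and a per-cell argmax
baseline are included, along with a simulation framework with ground
truth, input-perturbation models for robustness analysis, and
post-hoc confidence scores (a calibrated linear SVM on per-type marker
genes) that flag implausibly placed cells.

## Worked example

Simulate a small tissue with known ground truth, map the (noised)
query cells back onto it, and score the result:

```python
import spotalign as sa

tissue = sa.simulate_tissue(
    n_types=4, n_genes=300, cells_per_type=50,
    layout="blocks", target_mean_cells_per_spot=5,
    noise_p=0.10, seed=7,
)
print(f"tissue: {tissue.atlas.n_columns} cells, "
      f"{tissue.spot_counts.n_columns} spots, grid {tissue.grid}")

mapping = sa.map_cells(
    tissue.query, tissue.annotation, tissue.spot_counts,
    tissue.true_fractions(),
    cell_counts=tissue.true_cell_counts(),
    mode="generation", seed=1,
)
report = sa.precision(mapping, tissue.truth)
print(f"precision: {report.overall:.3f} ({report.tp}/{report.denominator})")
for t, p in report.per_type.items():
    print(f"  {t}: {p:.3f}")
```

Output:

```
tissue: 200 cells, 41 spots, grid (6, 7)
precision: 0.955 (191/200)
  type0: 0.960
  type1: 0.960
  type2: 0.900
  type3: 1.000
```

200 cells were pooled into 41 pseudo-spots on a 6 × 7 grid (≈5 cells
per spot); after perturbing 10% of each cell's genes with
multiplicative $2^{N(0,1)}$ noise, 191 of the 200 cells were still
assigned to exactly their true spot. The same pipeline is available
from the shell:

```sh
spotalign simulate --n-types 4 --seed 7 --out-dir sim/
spotalign map --sc-matrix sim/query_counts.tsv \
    --sc-annotations sim/cell_annotations.tsv \
    --st-matrix sim/spot_counts.tsv \
    --fractions sim/true_fractions.tsv \
    --mean-cells 5 --seed 1 --out-dir run/
spotalign evaluate --mapping run/mapping.tsv --truth sim/truth.tsv \
    --out-dir run/
```

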