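# Methods

## Model and assumptions

`spotalign` treats cell-to-spot mapping as a balanced linear assignment
problem. The modeling assumptions are:

- an ST spot's expression profile is (approximately) the sum of the
  profiles of the cells it captured, so a cell that truly sits in a
  spot should correlate with that spot's profile in log-CPM space;
- global cell-type fractions for the ST sample are known (from any
  external deconvolution tool) and can be converted to integer
  per-type cell counts;
- the number of cells per spot is either known (segmentation) or
  predictable from the spot's total UMI content;
- one cell occupies exactly one sub-spot and vice versa, so with $K$
  pooled query cells and $L$ sub-spots, $K = L$ and the optimal
  relaxed solution is automatically integral (the constraint matrix of
  the assignment polytope is totally unimodular).

The cost between cell $k$ and sub-spot $l$ is $-\mathrm{corr}$
(Pearson by default) of their $\log_2(\mathrm{CPM}+1)$ profiles over
all shared genes. All genes are used deliberately: marker selection or
dimension reduction would inject circularity into downstream marker-
based QC and was found unnecessary for the correlation cost.

## Solver

The exact solver is a shortest-augmenting-path (Jonker–Volgenant
family) implementation: one Dijkstra-like augmentation per row over
column potentials, $O(L^3)$ total, with the inner scan vectorized.
It maintains dual potentials $u$ (cells) and $v$ (sub-spots); at
termination every reduced cost $d_{kl} - u_k - v_l$ is nonnegative and
assigned edges have zero reduced cost, which is checked after every
solve against $\varepsilon = 10^{-8}\max|d|$ and certifies global
optimality (strong duality). The solver is written in-package because
the assignment duals are part of the library's contract — callers get
an optimality certificate with every mapping, not just a permutation.

The integer variant solves $\mathrm{round}(d \cdot \text{scale})$
exactly (default scale $10^6$, keeping magnitudes far below integer-
precision limits) through an independent implementation
(`scipy.optimize.linear_sum_assignment`), reports the total on the
original real costs, and serves two roles: a cross-check through a
disjoint code path, and a stand-in for integer-programming
approximations whose costs must be integral. On random Gaussian costs
at $K = 50$ the two solvers place ≥ 99% of cells identically; residual
disagreements are near-ties below the rounding resolution.

Tie-breaking inside the solver depends on input order, so the pipeline
fixes ordering deterministically (genes sorted lexicographically, pool
columns ordered by type then source cell id) and only the total cost —
not the particular optimal permutation under exact ties — is asserted
against the brute-force oracle.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `mean_cells` | 5 (Visium), 20 (legacy ST) | anchor for the two-point cells-per-spot fit; platform property, in cells/spot |
| `metric` | `neg_pearson` | assignment cost; Spearman and Euclidean offered for robustness checks |
| `mode` | `duplication` (real data), `generation` (benchmarks) | how per-type shortfalls are filled |
| `scale` | $10^6$ | integer-rounding resolution of the approximate solver |
| `bin_size` | 10 000 | partition size for single-cell ST targets; balances diversity against $O(L^3)$ solve cost |
| confidence `threshold` | 0.10 | probability below which a mapped cell is flagged for removal |
| fold-change pseudocount | 1.0 | stabilizes $\log_2$ ratios of mean normalized expression |

Cells-per-spot estimation uses the predictor
$u_s = \log_2(\text{UMI total of spot } s + 1)$ and the line through
$(\min_s u_s,\, 1)$ and $(\mathrm{mean}_s u_s,\, \texttt{mean\_cells})$,
rounded to the nearest integer and clamped at 1. The +1 guards empty
spots; rounding-to-nearest and the clamp are this package's choices
(only the minimum of one cell per spot is principled — a captured spot
contains at least one cell). Per-type integer targets come from
largest-remainder (Hamilton) apportionment of $L$ by the fractions,
ties broken by descending fraction then type name: this minimizes
per-type deviation from $f \cdot L$ and is deterministic. Zero-fraction
types are never mapped.

Sampling uses one named RNG stream per cell type, derived from the
master seed and a CRC of the type name, so adding or removing a type
from the targets never perturbs the draws of other types. In
generation mode, placeholder cells are synthesized gene-by-gene from
the type's observed values; they have no ground-truth location and are
excluded from precision scoring. Whether the surplus branch
($num_{sc,k} \ge num_{ST,k}$) should also differ between modes is not
specified by the scheme's description; both modes down-sample without
replacement there.

## Simulation framework

`generate_atlas` draws a synthetic scRNA-seq atlas: a shared
log-normal baseline of gene means, one disjoint marker block per type
(10% of genes by default) up-scaled by `effect_size` (default 5),
gamma–Poisson (negative-binomial, dispersion 0.15) counts, log-normal
library sizes (mean 2 000 counts, σ = 0.35). These values were chosen
once as representative of a modestly sequenced droplet experiment.
`lay_out_and_pool` places cells in the unit square (contiguous
per-type blocks, a per-type gradient along x, or uniformly at random),
overlays an $m \times n$ grid sized so the mean occupancy of nonempty
spots hits the target (5, 15 or 30 cells/spot), and sums raw counts
per grid cell — pooling conserves totals exactly and the cell→spot
membership is the ground truth.

Query degradation emulates cross-platform technical variation:
`permute_within_type` replaces a fraction (default 20%) of each cell's
genes with the values of a distinct same-type donor (de-duplicating
repeated profiles), and `add_expression_noise` multiplies a fraction
$p \in \{5\%, 10\%, 25\%\}$ of each cell's genes by independent
$2^{N(0,1)}$ draws. The exponentiated-Gaussian noise is applied
multiplicatively — the standard reading of such noise on count data;
an additive reading would be ill-defined at zero counts.

What the simulation does *not* emulate: platform-specific capture
biases, spatial gradients of sequencing depth, segmentation errors,
doublet artifacts, or cell types absent from the reference. Passing
tests therefore demonstrate correctness of the optimization and the
stated robustness properties under a clean generative model, not
performance on any particular real platform.

Perturbation models for robustness analysis follow the four-fold
multiplicative scheme: fractions are scaled by $2^z$ with
$z = \mathrm{clamp}(y, -2, 2)$, $y \sim N(0, \sigma^2)$,
$\sigma = 1/(2x^{1/3})$, then renormalized; cell counts use
$\sigma = p/n^{1/3}$ and
$\bar n = \max(1, \min(n \cdot \mathrm{Round}(2^y), \lceil 1.1M\rceil))$
with $M$ the original maximum and $p$ a per-resolution tuning constant
(1.4 for a five-cells-per-spot design).

## Quality control

Confidence scoring asks, per cell type, whether the type plausibly
belongs to the spot a cell was mapped to. Marker genes (5–50 per type;
one-vs-rest two-sided rank-sum test on genes detected in ≥ 10% of the
type's cells, BH-adjusted, positive log2 fold change required) define
the feature space. Fifty spots containing at least one assigned cell
of the type and fifty without (sampled with replacement when fewer
exist) are reconstituted as pseudo-bulks by averaging the normalized,
per-gene z-scaled profiles of their assigned cells; a linear SVM with
sigmoid-calibrated probabilities separates the two groups, scores
every spot of the scaled ST matrix, and each mapped cell inherits its
spot's probability. The per-gene z-scaling before averaging follows
standard scRNA-seq scaling practice; negatives necessarily come from
*mapped* spots lacking the type, since unmapped spots have no
pseudo-bulk. Types mapped to no spot or to every spot are skipped and
flagged.

## Numerical choices and degenerate inputs

- Zero-variance profiles under correlation metrics get correlation 0
  (neutral cost 0) rather than NaN, which would poison the solver.
- Spearman is Pearson on per-column fractional ranks (average ranks on
  ties).
- All-zero columns stay zero under CPM normalization, with a warning.
- Fractions summing to $s \ne 1$ are rescaled by $1/s$ with a warning
  up to $|s - 1| \le 0.05$ and rejected beyond.
- If all spots have identical UMI totals the two-point fit is
  degenerate and every spot receives the rounded mean.
- Median ties in the near/far partition go to "close" via a rank-based
  split, so group sizes differ by at most one.
- The retention index uses upper-triangle Pearson between the two
  cell–cell correlation matrices; the per-type equal-size subsample
  utility defaults to n = 150 cells.

## Problem sizes used in the checks

The packaged experiments run at desk scale, chosen to exercise every
code path while keeping the full suite fast: simulated precision
studies use 200 cells (5 types × 40) over ~40 spots at 5 cells/spot
with 300 genes, 10 seeds per condition; solver cross-checks use ≥ 500
exhaustively verifiable instances ($K \le 7$) plus 100 Gaussian
instances at $K = 50$; the planted-error QC probe uses 300 cells
(4 types × 75) with 10% of cells swapped across distant blocks, 5
seeds. Perturbation contracts are quantified over $10^4$ draws.

## Known limitations

- Fractions are a required input; no deconvolution is performed.
- Only CPM normalization is implemented (TPM would require gene
  lengths, which are not an input).
- Per-spot composition constraints are not supported — fractions act
  globally, so locally wrong compositions can arise in principle.
- The confidence score is a post-hoc, per-type signal; it does not
  propagate into the assignment itself and has no probabilistic
  interpretation at the level of individual sub-spot choices.
- The brute-force oracle is limited to $K \le 8$ by factorial growth.
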