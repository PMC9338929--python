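# Methods

## Deconvolution model

Each spatial unit's profile is modeled as a non-negative mixture of
reference cell-type profiles, `Y = X beta + eps`. The fit minimizes the
mean relative-entropy (generalized KL) loss

    L(Y, X beta) = (1/n) * sum_g [ y_g log(y_g / yhat_g) - y_g + yhat_g ]

with the convention 0·log 0 = 0 and a floor of 1e-12 on `yhat`, by the
classical multiplicative update for this loss,

    beta_j <- beta_j * (sum_g X_gj y_g / yhat_g) / (sum_g X_gj + l1 + l2 beta_j).

L1 and L2 penalties enter the denominator; both default to 0, which is
also the package's recommended setting. An "angle" penalty slot exists in
the configuration for interface completeness but is not implemented and
must stay 0. Iteration stops when the relative loss decrease over a
10-iteration window falls below `tol = 1e-6` (or the loss reaches the
numerical floor), with a hard cap of `max_iter = 10000`. Units are fit as
columns of one matrix; converged columns are frozen, so results do not
depend on unit processing order. The recorded `loss_trace` is the summed
per-unit loss and is non-increasing.

**Fitting layer.** The model fits raw counts by default. A pooled spot is
literally the sum of its member cells' counts, so the linear mixing
assumption holds on the raw layer; after log transformation it does not,
and on the package's own simulated-spot benchmark the log layer degrades
mean per-spot Pearson r from ≈0.99 to ≈0.88. `RunConfig.decon_layer =
"lognorm"` restores log-layer fitting for users who want profiles on the
normalized scale.

**Degenerate inputs.** Genes absent from every reference type are dropped
(with a warning when the unit expresses them). All-zero units, and units
expressing fewer than `min_genes = 50` genes, are flagged `unsure` and get
zero weights. In single-cell mode a unit whose maximum proportion falls
below `unsure_prop_min = 0.3` is also `unsure`; argmax ties break to the
lexicographically first type name and are flagged ambiguous.

## Integer cell combinations and cell selection

Per-spot integer counts use round-half-up on `M * beta_i` (integer plus
fractional part). Because rounding can overshoot the per-spot budget `M`
(e.g. four types at `M*beta = 7.5` round to 32 > 30), entries are
decremented in ascending order of fractional part (ties by type name)
until the total fits; a spot with signal whose counts round to all zeros
gets one cell of its dominant type. `M` defaults to 30 (Visium-scale
spots); use `M = 1` for bead/single-cell-scale data.

Reference cells matching the integer counts are selected over
`n_restarts = 100` independent draws (without replacement when the
reference allows), keeping the draw whose summed profile minimizes the
squared error to the spot; the comparison uses the log-normalized layer
(configurable). The restart count trades fit quality against runtime
linearly and 100 is comfortable at reference sizes of a few hundred cells
per type.

## Coordinate assignment

The plane around a spot center is split into four fixed axis-aligned
90-degree sectors, half-open in angle `(90q-90, 90q]` measured
counter-clockwise from +x. Per sector the nearest other spot is found
(ties by spot id); its fitted proportion of the cell's type is the sector
ratio `R_q`. Empty sectors (tissue edge) contribute `R_q = 0` and inherit
the minimum distance over populated sectors, keeping displacements local.
A sector is drawn with probability `(R_q+1)/sum_i(R_i+1)`; the angle is
uniform within the sector. The radius weight `alpha` lies in `(0, 0.5]`
with probability `(R_center+1)/(R_center+R_theta+2)` — the abundant-type
side keeps the cell — and in `(0.5, 1]` otherwise, uniform within the
chosen half. The displacement length is exactly `alpha * d_min / 2` where
`d_min` is the distance to the *chosen* sector's neighbor, so a placement
never crosses more than half-way toward a real neighbor spot; this also
makes the placement-radius identity an exact invariant rather than a
statistical one. In single-cell mode the sampler is bypassed and cells
keep their measured coordinates.

## Communication scoring

The spatial graph links each cell to its `K = 10` nearest cells
(Euclidean; ties at the K-th distance break by cell id; K is clamped with
a warning when fewer cells exist). "Co-expressed" means raw count above
`min_expr = 0` — counts are either detected or not at these depths, and
the threshold is configurable. The observed statistic `C0` counts ordered
edges sender→receiver whose endpoints express ligand and receptor; each
of the `Z_perm = 1000` permutations globally reshuffles the type labels
over all cells (graph and expression fixed) and recounts. `P = |{C_z >=
C0}|/Z` can be exactly 0; the reported `S_inter = 1 - P` is capped at
`1 - 1/(Z+1)` so that P = 0 still ranks strictly above P = 1/Z.
Interactions with `P >= 0.05` are dropped. Cells are processed in
canonical (sorted id) order, so the output is invariant to input row
order under a fixed seed.

The receiver-side knowledge graph joins ligand→receptor pairs with the
directed pathway edges; each edge is weighted by the Pearson correlation
of its endpoint genes on the log-normalized layer across the receiver
type's cells (≥ 3 cells required), and edges with non-positive or
undefined weight, or touching unexpressed genes, are pruned. Random walks
(`Z_walk = 1000`) start at the receptor, move with probability
proportional to edge weight, and stop at the first TF (absorbing), after
`max_walk_steps = 10` steps, or when stranded. `eta_k` is the mean
first-hit step rounded to the nearest integer ≥ 1 (a walk-derived
quantity; an unweighted shortest-path variant was considered and
rejected because it ignores edge support). A TF is retained only if
expressed in the receiver with at least one target gene — a non-TF
out-neighbor in the knowledge graph — expressed in at least
`min_cells_frac = 10%` of receiver cells; `theta_k` counts such targets.
The intracellular score is `logistic(sum_k theta_k p_k / eta_k)`.
Because `logistic(0) = 0.5`, an interaction with no retained TF is
hard-zeroed before the combined score `sqrt(S_inter * S_intra)`;
otherwise inactive pairs would leak a nonzero rank.

## Normalization and input hygiene

Global-scaling normalization rescales each unit to `scale_factor = 10,000`
total counts (the convention the method's name implies; configurable)
then applies log1p. All-zero units stay zero and are flagged. Duplicated
gene symbols are ambiguous and every copy is dropped with a logged count.
Symbol revision against a live registry is replaced by an optional static
alias mapping (no network dependency); the default applies no remapping.
Prior-knowledge symbols are uppercased on load and matched
case-insensitively against expression matrices.

## Benchmark procedures

`simulate_spots` bins cells into half-open square cells `[kb, (k+1)b)`
anchored at the minimum coordinate (configurable origin); spot counts are
exact column sums and per-spot label fractions are the ground truth. The
spatial-proximity check is a one-sided Mann–Whitney test (exact
enumeration when the combined sample is ≤ 50 without ties, normal
approximation with tie correction otherwise) of ligand+ sender →
receptor+ receiver distances against all ordered pair distances,
subsampled with the run's seed above 10^6 background pairs and flagged.
Pathway enrichment is the one-sided hypergeometric upper tail on the 2×2
table (targets ∩ pathway / pathway-only / targets-only / rest); no
multiple-testing correction is applied to the primary P, and a
Benjamini–Hochberg column is emitted alongside purely for convenience.

## Synthetic data: what it does and does not emulate

Defaults: 4 cell types × 200 cells, 200 genes, 10 markers per type at
6-fold the base mean of 1.0, negative-binomial counts with dispersion 0.5
(Poisson and noiseless options), unit-square tissue tiled by vertical
stripes (checkerboard option stresses the sector sampler; "null" layout
randomizes positions and labels). These sizes keep every distribution
estimable (≈110 expressed genes per cell, well above the `unsure`
threshold) while the full pipeline runs in seconds.

Three deliberate features mirror communicating tissue. The sender and
receiver types are mixed within their shared region, because the
permutation statistic rewards sender–receiver mingling in excess of
random label placement; with fully segregated zones the contact is
limited to a one-dimensional boundary and is *rarer* than under
shuffling. The planted ligand/receptor/TF/target genes are strictly
type-specific (off-type mean 0.05), so chance-significant type pairs fail
the 10%-of-cells target filter. Receiver cells carry a shared
Gamma(mean 1, var 0.5) pathway-activity factor scaling the chain genes,
which supplies the positive within-type co-expression the knowledge-graph
weights require — without it the receptor→TF edge weight is a noise
correlation with even odds of being pruned.

The generator does not emulate platform artifacts (optical crowding,
segmentation error, spot-boundary geometry), ambient RNA, batch effects
between reference and ST, or cell types missing from the reference.
Passing tests therefore demonstrate correctness of the algorithms under
the stated statistical model, not robustness to those failure modes.

## Problem sizes and numerical choices

The packaged checks use 500–800 cells, 25 grid spots, 200 permutation
tests at Z = 1000, ten pipeline seeds for planted-signal detection, 10^5
placement draws, and Monte-Carlo walks of 3,000–5,000 iterations against
an exact truncated-absorption oracle — sizes at which every Monte-Carlo
tolerance is a multiple of its binomial standard error. Tolerances:
relative loss window 1e-6 for NNLM convergence, 1e-3 for noiseless
mixture recovery, 1e-9 for the placement-radius identity, 1e-10 against
the exact Fisher enumeration.

## Known limitations

- Only 1:1 ligand–receptor pairs; multi-subunit complexes must be reduced
  to per-gene rows upstream.
- No distance decay within the KNN graph and no long-range (endocrine)
  signaling.
- The dense pairwise-distance KNN construction is quadratic in cell count
  and comfortable to ~10^4 cells; larger atlases need a spatial index.
- The angle regularizer of the deconvolution objective is not
  implemented.
- Inhibitory (negative-weight) knowledge-graph edges are pruned rather
  than modeled.
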