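# spacomm

Cell-type decomposition and spatially resolved cell–cell communication
inference for spatial transcriptomics (ST).

Spot-based ST platforms (10x Visium, Slide-seq) measure gene expression at
capture locations that mix several cells, and neither spot- nor
single-cell-resolution platforms say *which* cells are talking to which.
`spacomm` addresses both problems for analysts who have (1) a gene × spot
(or gene × cell) count matrix with 2-D coordinates, (2) a labeled
scRNA-seq reference, and (3) a prior-knowledge base of ligand–receptor
pairs, pathway edges and transcription factors. It produces a single-cell
spatial atlas and a ranked table of ligand–receptor interactions (LRIs)
between cell types, each supported by both spatial co-occurrence and
downstream pathway activation.

## Model

**Deconvolution.** Each spot/cell profile *Y* is modeled as *Y = Xβ + ε*
with *X* [n genes × k types] the mean reference profile per cell type and
*β ≥ 0*. β is fit by multiplicative updates under mean relative-entropy
(generalized Kullback–Leibler) loss, optionally with L1/L2 penalties,
until the relative loss change falls below tolerance or 10,000 iterations.
Proportions are β normalized to sum 1. For single-cell ST the argmax type
labels each cell; low-coverage or ambiguous units are labeled `unsure`.

**Atlas reconstruction.** For spots, proportions become integer cell
counts ω by rounding *Mβᵢ* half-up (capped so Σω ≤ M, the per-spot cell
budget); reference cells matching ω are chosen as the random draw
minimizing the squared distance between their merged profile and the spot.
Each chosen cell is placed at

    x̂ = x₀ + α·d_min·cos(θπ/180)/2,  ŷ = y₀ + α·d_min·sin(θπ/180)/2

where the angular sector of θ is drawn with probability
(R_q+1)/Σ(R_i+1) from the same-type proportions R of the four nearest
neighbor spots, and α ∈ (0,1] favors the half-interval whose end (spot
center vs neighbor) carries more of the cell's type.

**Communication.** A directed K-nearest-neighbor graph (K = 10) links
cells in space. For sender type A, receiver type B and pair (ligand i,
receptor j), C⁰ counts graph edges whose endpoints co-express the pair.
Shuffling cell-type labels Z times gives the permutation
P = |{Cᶻ ≥ C⁰}|/Z; significant pairs (P < 0.05) get the inter-cellular
score S_inter = 1 − P. On the receiver side, a ligand–receptor–TF
knowledge graph weighted by positive co-expression is walked from the
receptor (≤ 10 steps, TFs absorbing); with hit probability p_k, step η_k
and θ_k co-expressed target genes per TF,

    S_intra = logistic( Σ_k θ_k·p_k/η_k ),   score = √(S_inter·S_intra)

and interactions activating no TF-with-target are dropped.

**Benchmarking.** `simulate_spots` bins a labeled single-cell atlas into
grid spots with exact count conservation; composition accuracy is scored
by per-spot Pearson r and RMSE; inferred LRIs are checked by a one-sided
rank-sum test on sender–receiver distances and by co-expression percent;
inferred targets by one-sided Fisher exact pathway enrichment.

## Worked example

`examples/03_score_communication.py` generates the default synthetic
scenario (4 cell types, 200 genes, 800 cells, one planted LRI with a
receptor→TF→targets chain), labels cells by deconvolution and scores all
communications:

```
significant, pathway-activating interactions: 1
sender receiver ligand receptor  C0   P  S_inter  S_intra_raw  S_intra  n_tf  score
 type0    type1   LIGA     RECA 851 0.0    0.999          3.0   0.9526     1 0.9755
planted interaction recovered at rank 1: True
```

851 sender→receiver neighbor pairs co-express LIGA/RECA — far more than
any label permutation produces (P = 0) — and the walk from RECA always
reaches TFA in one step with 3 co-expressed targets (Σθp/η = 3), so the
planted interaction tops the table. `examples/01_deconvolve_spots.py`
prints the spot-recovery metrics (mean per-spot r 0.994, RMSE 0.026 at
seed 0), and the other examples cover atlas reconstruction and the
benchmark metrics.

The same workflow is scriptable from a shell:

```bash
spacomm --seed 3 simulate --out sim/
spacomm --seed 3 reconstruct --st sim/st.tsv --coords sim/coords.tsv \
    --ref sim/ref.tsv --ref-labels sim/ref_labels.tsv --mode cell --out-dir run/
spacomm --seed 3 communicate --atlas run/atlas.tsv --expr run/atlas_expr.tsv \
    --lri sim/lri.tsv --pathways sim/pathways.tsv --tfs sim/tfs.txt \
    --out run/communication.tsv
```

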