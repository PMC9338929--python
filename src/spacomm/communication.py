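"""Spatial ligand-receptor enrichment on the KNN cell graph.

A directed graph links every cell to its K nearest cells in space. For a
sender type A expressing ligand i and receiver type B expressing receptor
j, the observed statistic C0 counts edges u->v with type(u)=A, type(v)=B,
ligand positive in u and receptor positive in v. A null distribution
C1..CZ is produced by globally shuffling the cell-type labels (graph and
expression fixed) and recounting; P = #{Cz >= C0} / Z. Pairs with P below
the cutoff receive the inter-cellular score S_inter = 1 - P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, PriorKnowledge, RunConfig
from .knowledge_graph import (
    build_lrt_kg,
    intracellular_score,
    random_walk_tf_probabilities,
    combined_score,
)

__all__ = [
    "CellGraph",
    "LRIScore",
    "build_knn_graph",
    "count_lr_pairs",
    "permutation_test",
    "score_all_communications",
]


@dataclass
class CellGraph:
    """Directed KNN adjacency over cells in space."""

    cells: list
    types: np.ndarray             # type label per cell (object array)
    src: np.ndarray               # edge source indices, len E = n*K
    dst: np.ndarray               # edge target indices
    K: int
    coords: np.ndarray            # n x 2, kept for distance queries

    @property
    def n_cells(self):
        return len(self.cells)

    @property
    def n_edges(self):
        return len(self.src)

    def edges_between(self, A, B, types=None):
        t = self.types if types is None else types
        return (t[self.src] == A) & (t[self.dst] == B)


@dataclass
class LRIScore:
    sender: str
    receiver: str
    ligand: str
    receptor: str
    c0: int
    perm_counts: np.ndarray
    p_value: float
    s_inter: float
    significant: bool


def build_knn_graph(coords, types, cells=None, K=10):
    """Directed KNN graph; ties at the K-th distance break by cell-id order.

    ``coords`` is an (n, 2) array or a ReconstructedAtlas; duplicates are
    allowed (zero-distance edges), self-edges are not.
    """
    if hasattr(coords, "placements"):  # ReconstructedAtlas
        atlas = coords
        cells = list(atlas.placements["cell"])
        types = atlas.placements["type"].to_numpy(dtype=object)
        coords = atlas.coordinates()
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if cells is None:
        cells = [str(i) for i in range(n)]
    types = np.asarray(types, dtype=object)
    k = min(K, n - 1)
    if k < K:
        warnings.warn(f"K={K} clamped to {k} (only {n} cells)")
    diff = coords[:, None, :] - coords[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(D, np.inf)
    order = np.lexsort((np.arange(n)[None, :].repeat(n, axis=0), D), axis=1)
    nbrs = order[:, :k]
    src = np.repeat(np.arange(n), k)
    dst = nbrs.ravel()
    return CellGraph(cells=list(map(str, cells)), types=types, src=src,
                     dst=dst, K=k, coords=coords)


def _positivity(expr: ExpressionMatrix, gene, cells, min_expr=0.0):
    """Boolean per graph cell: raw count above min_expr, None if gene absent."""
    lookup = {g.upper(): i for i, g in enumerate(expr.genes)}
    gi = lookup.get(str(gene).upper())
    if gi is None:
        return None
    raw = expr.get_layer("raw")
    col = {u: j for j, u in enumerate(expr.units)}
    idx = [col[c] for c in cells]
    return raw[gi, idx] > min_expr


def count_lr_pairs(graph: CellGraph, expr: ExpressionMatrix, A, B,
                   ligand, receptor, min_expr=0.0):
    """Observed count of sender->receiver edges co-expressing the pair."""
    lpos = _positivity(expr, ligand, graph.cells, min_expr)
    rpos = _positivity(expr, receptor, graph.cells, min_expr)
    if lpos is None or rpos is None:
        warnings.warn(f"gene absent for pair ({ligand}, {receptor}); count 0")
        return 0
    mask = lpos[graph.src] & rpos[graph.dst] & graph.edges_between(A, B)
    return int(mask.sum())


def _permutation_labels(types, Z, rng):
    """Z globally shuffled copies of the label vector, as a (Z, n) code array."""
    uniq, codes = np.unique(np.asarray(types, dtype=object), return_inverse=True)
    perms = np.empty((Z, len(codes)), dtype=np.int16)
    for z in range(Z):
        perms[z] = rng.permutation(codes)
    return uniq, codes, perms


def _perm_counts(graph, perms, uniq, A, B, expr_mask):
    """Counts per permutation for edges satisfying the expression mask."""
    a = np.flatnonzero(uniq == A)
    b = np.flatnonzero(uniq == B)
    if len(a) == 0 or len(b) == 0:
        return np.zeros(perms.shape[0], dtype=int)
    src, dst = graph.src[expr_mask], graph.dst[expr_mask]
    match = (perms[:, src] == a[0]) & (perms[:, dst] == b[0])
    return match.sum(axis=1)


def permutation_test(graph: CellGraph, expr: ExpressionMatrix, A, B,
                     ligand, receptor, Z=1000, rng=None, p_cutoff=0.05,
                     min_expr=0.0):
    """Label-shuffling significance of the observed co-expression count."""
    if Z <= 0:
        raise ValueError("Z must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    c0 = count_lr_pairs(graph, expr, A, B, ligand, receptor, min_expr)
    lpos = _positivity(expr, ligand, graph.cells, min_expr)
    rpos = _positivity(expr, receptor, graph.cells, min_expr)
    if lpos is None or rpos is None:
        mask = np.zeros(graph.n_edges, dtype=bool)
    else:
        mask = lpos[graph.src] & rpos[graph.dst]
    uniq, _codes, perms = _permutation_labels(graph.types, Z, rng)
    counts = _perm_counts(graph, perms, uniq, A, B, mask)
    p = float((counts >= c0).sum()) / Z
    sig = p < p_cutoff
    s_inter = min(1.0 - p, 1.0 - 1.0 / (Z + 1)) if sig else 0.0
    return LRIScore(sender=str(A), receiver=str(B), ligand=str(ligand),
                    receptor=str(receptor), c0=c0, perm_counts=counts,
                    p_value=p, s_inter=s_inter, significant=sig)


def score_all_communications(atlas, prior: PriorKnowledge,
                             cfg: RunConfig | None = None, rng=None,
                             expr: ExpressionMatrix | None = None):
    """Score every (sender, receiver, ligand, receptor) combination.

    Runs the permutation test for every ordered type pair (autocrine
    included) against every database pair whose genes are measured, then
    computes the receiver-side knowledge-graph score for significant pairs
    and the combined score sqrt(S_inter * S_intra). Returns a DataFrame
    sorted by combined score.
    """
    cfg = cfg or RunConfig()
    rng = rng if rng is not None else cfg.rng()
    if expr is None:
        expr = atlas.expression
    # canonical cell order: results must not depend on input row order
    placements = atlas.placements.sort_values("cell").reset_index(drop=True)
    cells = list(placements["cell"].astype(str))
    graph = build_knn_graph(
        placements[["x", "y"]].to_numpy(dtype=float),
        placements["type"].to_numpy(dtype=object), cells=cells, K=cfg.K,
    )
    raw = expr.get_layer("raw")
    gene_lookup = {g.upper(): i for i, g in enumerate(expr.genes)}
    col = {u: j for j, u in enumerate(expr.units)}
    cell_idx = np.array([col[c] for c in graph.cells])

    pairs = sorted(
        (l, r) for l, r in prior.lri_pairs
        if l in gene_lookup and r in gene_lookup
    )
    if not pairs:
        return _empty_table()

    pos = {}
    for g in {g for p in pairs for g in p}:
        pos[g] = raw[gene_lookup[g], :][cell_idx] > cfg.min_expr

    uniq, _codes, perms = _permutation_labels(graph.types, cfg.Z_perm, rng)
    type_names = sorted(set(map(str, graph.types)))
    # per receiver type, lazily built knowledge graph and walk cache
    kg_cache, rows = {}, []
    for A in type_names:
        for B in type_names:
            ab = graph.edges_between(A, B)
            if not ab.any():
                continue
            for (l, r) in pairs:
                mask = pos[l][graph.src] & pos[r][graph.dst]
                c0 = int((mask & ab).sum())
                if c0 == 0:
                    continue  # P = 1 by construction
                counts = _perm_counts(graph, perms, uniq, A, B, mask)
                p = float((counts >= c0).sum()) / cfg.Z_perm
                if p >= cfg.p_cutoff:
                    continue
                s_inter = min(1.0 - p, 1.0 - 1.0 / (cfg.Z_perm + 1))
                if B not in kg_cache:
                    rec_cells = [c for c, t in zip(graph.cells, graph.types)
                                 if t == B]
                    rec_expr = expr.subset_units(rec_cells)
                    kg_cache[B] = (build_lrt_kg(prior, rec_expr), rec_expr, {})
                kg, rec_expr, walk_cache = kg_cache[B]
                if r not in walk_cache:
                    walk_cache[r] = random_walk_tf_probabilities(
                        kg, r, prior.tf_set, Z_walk=cfg.Z_walk,
                        max_steps=cfg.max_walk_steps, rng=rng,
                    )
                intra = intracellular_score(walk_cache[r], rec_expr, prior,
                                            kg, min_cells_frac=cfg.min_cells_frac)
                score = combined_score(s_inter, intra.s_intra) if intra.activated else 0.0
                rows.append((A, B, l, r, c0, p, s_inter, intra.s_intra_raw,
                             intra.s_intra if intra.activated else 0.0,
                             len(intra.tf_activations), score))
    if not rows:
        return _empty_table()
    table = pd.DataFrame(rows, columns=[
        "sender", "receiver", "ligand", "receptor", "C0", "P", "S_inter",
        "S_intra_raw", "S_intra", "n_tf", "score",
    ])
    table = table[table["score"] > 0].reset_index(drop=True)
    return table.sort_values(
        ["score", "sender", "receiver", "ligand", "receptor"],
        ascending=[False, True, True, True, True],
    ).reset_index(drop=True)


def _empty_table():
    return pd.DataFrame(columns=[
        "sender", "receiver", "ligand", "receptor", "C0", "P", "S_inter",
        "S_intra_raw", "S_intra", "n_tf", "score",
    ])
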