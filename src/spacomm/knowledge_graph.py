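"""Ligand-receptor-TF knowledge graph and the intracellular score.

The knowledge graph joins the ligand-receptor pairs with directed pathway
edges; each edge is weighted by the positive co-expression (Pearson, on
log-normalized values across receiver-type cells) of its endpoint genes.
Non-positive or undefined correlations are pruned, as are edges touching
genes unexpressed in the receiver.

Starting at the receptor, bounded random walks step to out-neighbors with
probability proportional to edge weight and stop at the first transcription
factor reached (or after ``max_steps``). For TF k hit with probability p_k
at mean step eta_k and owning theta_k co-expressed target genes in the
receiver, the intracellular score is

    S_intra_raw = sum_k theta_k * p_k / eta_k,

passed through the logistic function; the combined communication score is
the geometric mean sqrt(S_inter * S_intra). An interaction that activates
no TF-with-target is hard-zeroed before the geometric mean, since
logistic(0) = 0.5 would otherwise leak a nonzero score to inactive pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .types import ExpressionMatrix, PriorKnowledge

__all__ = [
    "LRTKnowledgeGraph",
    "TFActivation",
    "IntracellularScore",
    "build_lrt_kg",
    "random_walk_tf_probabilities",
    "intracellular_score",
    "combined_score",
]


@dataclass
class LRTKnowledgeGraph:
    """Directed, co-expression-weighted gene graph with role annotations."""

    graph: nx.DiGraph
    roles: dict                   # gene -> set of {"ligand","receptor","tf",...}

    def has_node(self, gene):
        return self.graph.has_node(str(gene).upper())

    def out_neighbors(self, gene):
        g = str(gene).upper()
        if not self.graph.has_node(g):
            return []
        return list(self.graph.successors(g))

    def edge_weight(self, a, b):
        return self.graph[str(a).upper()][str(b).upper()]["weight"]

    def to_frame(self):
        rows = [(a, b, d["weight"], d.get("source", ""))
                for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["src", "dst", "weight", "source"])


@dataclass
class TFActivation:
    tf: str
    p: float                      # hit probability over Z walks
    eta: int                      # rounded mean first-hit step, >= 1
    n_hits: int
    theta_targets: int = 0        # filled in by intracellular_score


@dataclass
class IntracellularScore:
    s_intra_raw: float
    s_intra: float
    tf_activations: list          # retained TFs only
    activated: bool

    def combined(self, s_inter):
        if not self.activated:
            return 0.0
        return combined_score(s_inter, self.s_intra)


def build_lrt_kg(prior: PriorKnowledge, receiver_expr: ExpressionMatrix):
    """Assemble the weighted knowledge graph for one receiver cell type.

    Edges come from the LRI pairs (ligand -> receptor) and the pathway
    edge list; weights are Pearson correlations on the lognorm layer
    across the receiver's cells. Edges with non-positive or undefined
    weight, or with either endpoint unexpressed in the receiver, are
    dropped.
    """
    if receiver_expr.n_units < 3:
        raise ValueError(
            f"receiver has {receiver_expr.n_units} cells; need >= 3 for "
            "co-expression weights"
        )
    raw = receiver_expr.get_layer("raw")
    logn = receiver_expr.get_layer("lognorm")
    lookup = {g.upper(): i for i, g in enumerate(receiver_expr.genes)}
    expressed = {
        g: raw[i, :].sum() > 0 for g, i in lookup.items()
    }

    candidate_edges = [
        (l, r, "lri") for l, r in prior.lri_pairs
    ] + [
        (a, b, src) for a, b, src in prior.pathway_edges
    ]
    genes = sorted({g for a, b, _ in candidate_edges for g in (a, b)
                    if g in lookup and expressed[g]})
    gidx = {g: i for i, g in enumerate(genes)}
    if genes:
        sub = logn[[lookup[g] for g in genes], :]
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.atleast_2d(corr)
    else:
        corr = np.zeros((0, 0))

    G = nx.DiGraph()
    roles = {}
    for a, b, src in candidate_edges:
        if a not in gidx or b not in gidx or a == b:
            continue
        w = float(corr[gidx[a], gidx[b]])
        if not np.isfinite(w) or w <= 0:
            continue
        G.add_edge(a, b, weight=w, source=src)
    for l, r in prior.lri_pairs:
        roles.setdefault(l, set()).add("ligand")
        roles.setdefault(r, set()).add("receptor")
    for t in prior.tf_set:
        roles.setdefault(t, set()).add("tf")
    for n in G.nodes:
        roles.setdefault(n, set())
        if not roles[n] & {"ligand", "receptor", "tf"}:
            roles[n].add("pathway-intermediate")
    return LRTKnowledgeGraph(graph=G, roles=roles)


def random_walk_tf_probabilities(kg: LRTKnowledgeGraph, receptor, tf_set,
                                 Z_walk=1000, max_steps=10, rng=None):
    """Monte-Carlo first-hit probabilities from the receptor to each TF.

    Each of the ``Z_walk`` walks starts at the receptor, moves to an
    out-neighbor with probability proportional to edge weight, and stops
    at the first TF reached (absorbing) or after ``max_steps`` steps, or
    when stranded at a node without out-edges. Returns one
    :class:`TFActivation` per TF ever hit, p = hits / Z_walk and eta the
    mean first-hit step rounded to the nearest integer >= 1.
    """
    rng = rng if rng is not None else np.random.default_rng()
    receptor = str(receptor).upper()
    tf_set = {str(t).upper() for t in tf_set}
    if not kg.graph.has_node(receptor):
        return []
    # adjacency as cumulative-weight arrays for fast sampling
    adj = {}
    for node in kg.graph.nodes:
        nbrs = list(kg.graph.successors(node))
        if nbrs:
            w = np.array([kg.graph[node][b]["weight"] for b in nbrs])
            adj[node] = (nbrs, np.cumsum(w) / w.sum())
    hits, steps_sum = {}, {}
    for _ in range(Z_walk):
        node = receptor
        for step in range(1, max_steps + 1):
            entry = adj.get(node)
            if entry is None:
                break
            nbrs, cum = entry
            node = nbrs[int(np.searchsorted(cum, rng.uniform()))]
            if node in tf_set:
                hits[node] = hits.get(node, 0) + 1
                steps_sum[node] = steps_sum.get(node, 0) + step
                break
    out = []
    for tf in sorted(hits):
        n = hits[tf]
        eta = max(1, int(round(steps_sum[tf] / n)))
        out.append(TFActivation(tf=tf, p=n / Z_walk, eta=eta, n_hits=n))
    return out


def tf_target_genes(kg: LRTKnowledgeGraph, tf, tf_set):
    """Targets of a TF: its knowledge-graph out-neighbors that are not TFs."""
    tf_set = {str(t).upper() for t in tf_set}
    return [g for g in kg.out_neighbors(tf) if g not in tf_set]


def intracellular_score(tf_activations, receiver_expr: ExpressionMatrix,
                        prior: PriorKnowledge, kg: LRTKnowledgeGraph,
                        min_cells_frac=0.1):
    """Aggregate walk hits into the receiver-side activation score.

    A TF is retained only if it is expressed in the receiver and at least
    one of its target genes is co-expressed (raw count > 0 in at least
    ``min_cells_frac`` of receiver cells). theta_k is the number of such
    targets.
    """
    raw = receiver_expr.get_layer("raw")
    lookup = {g.upper(): i for i, g in enumerate(receiver_expr.genes)}
    n_cells = receiver_expr.n_units
    min_cells = max(1, int(np.ceil(min_cells_frac * n_cells)))

    def frac_ok(gene):
        i = lookup.get(gene)
        return i is not None and (raw[i, :] > 0).sum() >= min_cells

    retained, s_raw = [], 0.0
    for act in tf_activations:
        i = lookup.get(act.tf)
        if i is None or raw[i, :].sum() == 0:
            continue
        targets = [g for g in tf_target_genes(kg, act.tf, prior.tf_set)
                   if frac_ok(g)]
        if not targets:
            continue
        act.theta_targets = len(targets)
        retained.append(act)
        s_raw += act.theta_targets * act.p / act.eta
    s_intra = 1.0 / (1.0 + np.exp(-s_raw))
    return IntracellularScore(
        s_intra_raw=s_raw, s_intra=float(s_intra),
        tf_activations=retained, activated=bool(retained),
    )


def combined_score(s_inter, s_intra):
    """Geometric mean of the inter- and intracellular scores."""
    if not (0.0 <= s_inter <= 1.0 and 0.0 <= s_intra <= 1.0):
        raise ValueError("scores must lie in [0, 1]")
    return float(np.sqrt(s_inter * s_intra))
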