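"""Self-contained synthetic datasets for every pipeline stage.

The generator emulates the statistical structure the pipeline assumes: a
labeled scRNA-seq reference with per-type marker genes, a spatial dataset
whose cell types occupy contiguous zones, one planted ligand-receptor
interaction whose ligand marks the sender type and whose receptor,
transcription factor and target genes mark the receiver type, and a
prior-knowledge base containing the planted interaction and chain among
decoys. Three features mirror communicating tissue: (1) sender and
receiver cells are mixed within their shared region, since the spatial
permutation test detects sender-receiver mingling in excess of random
label placement; (2) the planted genes are strictly type-specific (small
leak mean elsewhere), so chance receiver types fail the target
co-expression filter; (3) receiver cells carry a per-cell pathway-activity
factor scaling the chain genes jointly, which produces the positive
within-type co-expression the knowledge-graph edge weights require.
Counts are negative-binomial (Poisson and noiseless options) so the data
carry the overdispersion typical of spatial counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, PriorKnowledge, SpatialCoordinates
from . import io as sio

__all__ = [
    "SyntheticScenario",
    "generate_reference",
    "generate_spatial",
    "generate_prior",
    "write_scenario_files",
]


@dataclass
class SyntheticScenario:
    """Study conditions for the synthetic data.

    Defaults: 4 cell types x 200 cells in a 200-gene universe, 10 marker
    genes per type at 6-fold the base mean of 1.0, negative-binomial noise
    with dispersion 0.5, vertical-stripe zones tiling the unit square, one
    planted ligand-receptor pair from type0 (sender) to type1 (receiver)
    with a receptor->TF->3-target chain, 20 decoy pairs and 30 decoy edges.
    """

    k: int = 4
    n_genes: int = 200
    cells_per_type: int = 200
    n_markers_per_type: int = 10
    base_mean: float = 1.0
    marker_fold: float = 6.0
    dispersion: float = 0.5
    noise: str = "nb"              # {"nb", "poisson", "none"}
    layout: str = "stripes"        # {"stripes", "checkerboard", "null"}
    mix_sender_receiver: bool = True
    sender: int = 0
    receiver: int = 1
    n_planted_targets: int = 3
    planted_leak_mean: float = 0.05
    chain_activity_var: float = 0.5
    n_decoy_lri: int = 20
    n_decoy_edges: int = 30
    n_decoy_tfs: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.cells_per_type < 3:
            raise ValueError("cells_per_type must be >= 3")
        need = self.k * self.n_markers_per_type
        if self.n_genes < need + self.n_decoy_lri * 2 + self.n_decoy_tfs:
            raise ValueError("n_genes too small for markers plus decoys")
        if not (0 <= self.sender < self.k and 0 <= self.receiver < self.k):
            raise ValueError("sender/receiver must index a cell type")
        if self.sender == self.receiver:
            raise ValueError("sender and receiver types must differ")

    # -- derived naming -------------------------------------------------
    @property
    def types(self):
        return [f"type{t}" for t in range(self.k)]

    def marker_indices(self, t):
        s = t * self.n_markers_per_type
        return list(range(s, s + self.n_markers_per_type))

    @property
    def genes(self):
        names = [f"G{i:04d}" for i in range(self.n_genes)]
        # planted genes get readable names: the ligand marks the sender,
        # the receptor/TF/targets mark the receiver
        names[self.marker_indices(self.sender)[0]] = "LIGA"
        recv = self.marker_indices(self.receiver)
        names[recv[0]] = "RECA"
        names[recv[1]] = "TFA"
        for j in range(self.n_planted_targets):
            names[recv[2 + j]] = f"TGTA{j + 1}"
        return names

    @property
    def planted_lri(self):
        return ("LIGA", "RECA", self.types[self.sender], self.types[self.receiver])

    @property
    def planted_chain(self):
        return ("RECA", "TFA", [f"TGTA{j + 1}" for j in range(self.n_planted_targets)])

    @property
    def chain_gene_indices(self):
        """Receiver-marker rows carrying the receptor->TF->targets chain."""
        recv = self.marker_indices(self.receiver)
        return recv[: 2 + self.n_planted_targets]

    def mean_matrix(self):
        """Per-type mean expression, genes x types.

        Ordinary markers sit at ``marker_fold`` times the base mean in their
        own type. The planted ligand/receptor/TF/target genes are strictly
        type-specific: their off-type mean is ``planted_leak_mean``.
        """
        mu = np.full((self.n_genes, self.k), self.base_mean)
        for t in range(self.k):
            mu[self.marker_indices(t), t] = self.base_mean * self.marker_fold
        lig = self.marker_indices(self.sender)[0]
        planted = [lig] + list(self.chain_gene_indices)
        for g in planted:
            owner = self.sender if g == lig else self.receiver
            for t in range(self.k):
                if t != owner:
                    mu[g, t] = self.planted_leak_mean
        return mu

    def _decoy_gene_pool(self):
        used = set()
        for t in range(self.k):
            used.update(self.marker_indices(t))
        return [i for i in range(self.n_genes) if i not in used]


def _draw_counts(mu, scenario, rng):
    """Sample counts with the scenario's noise model; mu is genes x cells."""
    if scenario.noise == "none":
        return np.round(mu)
    if scenario.noise == "poisson":
        return rng.poisson(mu).astype(float)
    if scenario.noise == "nb":
        phi = scenario.dispersion
        if phi <= 0:
            return rng.poisson(mu).astype(float)
        r = 1.0 / phi
        p = r / (r + mu)
        return rng.negative_binomial(r, p).astype(float)
    raise ValueError(f"unknown noise model {scenario.noise!r}")


def _apply_activity(mu, type_idx, scenario, rng):
    """Scale the chain genes of receiver cells by a shared per-cell factor.

    The factor is Gamma with mean 1 and variance ``chain_activity_var``,
    modeling graded pathway activity; it induces positive co-expression of
    receptor, TF and targets within the receiver type.
    """
    v = scenario.chain_activity_var
    if v <= 0:
        return mu
    recv = np.flatnonzero(np.asarray(type_idx) == scenario.receiver)
    if len(recv) == 0:
        return mu
    f = rng.gamma(shape=1.0 / v, scale=v, size=len(recv))
    rows = scenario.chain_gene_indices
    mu = mu.copy()
    mu[np.ix_(rows, recv)] *= f[None, :]
    return mu


def generate_reference(scenario: SyntheticScenario, rng=None):
    """Labeled reference scRNA-seq: (raw ExpressionMatrix, labels Series)."""
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    mu_types = scenario.mean_matrix()
    type_idx = np.repeat(np.arange(scenario.k), scenario.cells_per_type)
    mu = _apply_activity(mu_types[:, type_idx], type_idx, scenario, rng)
    counts = _draw_counts(mu, scenario, rng)
    labels = [scenario.types[t] for t in type_idx]
    ids = [f"ref_{scenario.types[t]}_{i % scenario.cells_per_type}"
           for i, t in enumerate(type_idx)]
    expr = ExpressionMatrix(scenario.genes, ids, counts, layer="raw")
    return expr, pd.Series(labels, index=ids, name="type")


def _positions(scenario, types_per_cell, rng):
    n = len(types_per_cell)
    xy = rng.uniform(0.0, 1.0, size=(n, 2))
    if scenario.layout == "null":
        return xy
    k = scenario.k
    pair = {scenario.sender, scenario.receiver}
    for i, t in enumerate(types_per_cell):
        if scenario.layout == "stripes":
            if scenario.mix_sender_receiver and t in pair:
                # communicating types mingle across their two stripes
                t = int(rng.choice(sorted(pair)))
            # vertical stripe t occupies x in [t/k, (t+1)/k)
            xy[i, 0] = (t + xy[i, 0]) / k
        elif scenario.layout == "checkerboard":
            # 2x2 board, cell types cycling over the squares
            sq = [(0, 0), (1, 0), (0, 1), (1, 1)][t % 4]
            xy[i] = (np.array(sq) + xy[i]) / 2.0
        else:
            raise ValueError(f"unknown layout {scenario.layout!r}")
    return xy


def generate_spatial(scenario: SyntheticScenario, rng=None):
    """Single-cell spatial dataset with type-zoned regions.

    Returns (raw ExpressionMatrix, SpatialCoordinates, labels Series). In
    the ``null`` layout, types are assigned at random positions so no
    interaction is spatially enriched.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed + 1)
    mu_types = scenario.mean_matrix()
    type_idx = np.repeat(np.arange(scenario.k), scenario.cells_per_type)
    if scenario.layout == "null":
        type_idx = rng.permutation(type_idx)
    xy = _positions(scenario, type_idx, rng)
    mu = _apply_activity(mu_types[:, type_idx], type_idx, scenario, rng)
    counts = _draw_counts(mu, scenario, rng)
    ids = [f"cell{i:05d}" for i in range(len(type_idx))]
    expr = ExpressionMatrix(scenario.genes, ids, counts, layer="raw")
    coords = SpatialCoordinates(pd.DataFrame(
        {"unit": ids, "x": xy[:, 0], "y": xy[:, 1]}
    ))
    labels = pd.Series([scenario.types[t] for t in type_idx], index=ids,
                       name="type")
    return expr, coords, labels


def generate_prior(scenario: SyntheticScenario, rng=None):
    """Prior knowledge with the planted interaction/chain among decoys."""
    rng = rng if rng is not None else np.random.default_rng(scenario.seed + 2)
    genes = scenario.genes
    pool = [genes[i] for i in scenario._decoy_gene_pool()]
    rng.shuffle(pool)

    lig, rec, _sender, _receiver = scenario.planted_lri
    receptor, tf, targets = scenario.planted_chain
    lri = {(lig, rec)}
    it = iter(pool)
    for _ in range(scenario.n_decoy_lri):
        lri.add((next(it), next(it)))
    decoy_tfs = [next(it) for _ in range(scenario.n_decoy_tfs)]

    edges = {(receptor, tf, "planted")}
    edges.update((tf, tg, "planted") for tg in targets)
    remaining = list(it)
    for _ in range(scenario.n_decoy_edges):
        a, b = rng.choice(len(remaining), size=2, replace=False)
        if remaining[a] != remaining[b]:
            edges.add((remaining[a], remaining[b], "decoy"))

    sets = {
        "planted_path": frozenset([receptor, tf, *targets]),
        "decoy_path": frozenset(rng.choice(remaining, size=8, replace=False)),
    }
    return PriorKnowledge(
        lri_pairs=lri, pathway_edges=edges,
        tf_set={tf, *decoy_tfs}, pathway_sets=sets,
    )


def write_scenario_files(scenario: SyntheticScenario, outdir):
    """Write every input file the readers consume; returns the path map.

    Each generator derives its own stream from ``scenario.seed``, so the
    files are identical to what the in-memory generators produce.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, ref_labels = generate_reference(scenario)
    st, coords, st_labels = generate_spatial(scenario)
    prior = generate_prior(scenario)

    paths = {
        "ref": outdir / "ref.tsv",
        "ref_labels": outdir / "ref_labels.tsv",
        "st": outdir / "st.tsv",
        "coords": outdir / "coords.tsv",
        "st_labels": outdir / "st_labels.tsv",
        "lri": outdir / "lri.tsv",
        "pathways": outdir / "pathways.tsv",
        "tfs": outdir / "tfs.txt",
    }
    sio.write_expression(ref, paths["ref"])
    ref_labels.rename_axis("cell").reset_index().to_csv(
        paths["ref_labels"], sep="\t", index=False)
    sio.write_expression(st, paths["st"])
    sio.write_coordinates(coords, paths["coords"])
    st_labels.rename_axis("cell").reset_index().to_csv(
        paths["st_labels"], sep="\t", index=False)
    pd.DataFrame(sorted(prior.lri_pairs), columns=["ligand", "receptor"]).to_csv(
        paths["lri"], sep="\t", index=False)
    pd.DataFrame(sorted(prior.pathway_edges),
                 columns=["src", "dst", "source"]).to_csv(
        paths["pathways"], sep="\t", index=False)
    paths["tfs"].write_text("\n".join(sorted(prior.tf_set)) + "\n")
    return paths
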