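"""Core domain containers shared by every stage of the pipeline.

The pipeline moves gene x unit count matrices (cells or spots), 2-D
coordinates, and a prior-knowledge base (ligand-receptor pairs, pathway
edges, transcription-factor list) through deconvolution, atlas
reconstruction and communication scoring. These containers validate the
invariants once at construction so downstream code can assume them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SpatialCoordinates",
    "PriorKnowledge",
    "RunConfig",
]


class ExpressionMatrix:
    """A gene x unit (cell or spot) expression matrix with named axes.

    Parameters
    ----------
    genes : sequence of str
        Gene symbols, one per row. Must be unique.
    units : sequence of str
        Cell or spot identifiers, one per column. Must be unique.
    counts : ndarray, shape (n_genes, n_units)
        Non-negative values. The ``layer`` flag records whether these are
        raw counts or log-normalized values.
    layer : {"raw", "lognorm"}
    lognorm : ndarray, optional
        When ``layer == "raw"`` a log-normalized layer may be attached
        alongside (see :func:`spacomm.io.log_normalize`).
    """

    def __init__(self, genes, units, counts, layer="raw", lognorm=None):
        genes = [str(g) for g in genes]
        units = [str(u) for u in units]
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x units)")
        if counts.shape != (len(genes), len(units)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(genes)} genes x {len(units)} units"
            )
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene symbols")
        if len(set(units)) != len(units):
            raise ValueError("duplicate unit identifiers")
        if np.any(counts < 0):
            raise ValueError("negative expression values")
        if not np.all(np.isfinite(counts)):
            raise ValueError("non-finite expression values")
        if layer not in ("raw", "lognorm"):
            raise ValueError(f"unknown layer {layer!r}")
        self.genes = genes
        self.units = units
        self.counts = counts
        self.layer = layer
        self.lognorm = None if lognorm is None else np.asarray(lognorm, dtype=float)
        self._gene_index = {g: i for i, g in enumerate(genes)}
        self._unit_index = {u: i for i, u in enumerate(units)}

    # -- lookups -------------------------------------------------------
    @property
    def n_genes(self):
        return len(self.genes)

    @property
    def n_units(self):
        return len(self.units)

    def gene_idx(self, gene):
        return self._gene_index.get(str(gene))

    def unit_idx(self, unit):
        return self._unit_index.get(str(unit))

    def get_layer(self, layer):
        """Return the requested layer as an array, or raise if absent."""
        if layer == "raw":
            if self.layer == "raw":
                return self.counts
            raise ValueError("raw layer not available on a lognorm matrix")
        if layer == "lognorm":
            if self.layer == "lognorm":
                return self.counts
            if self.lognorm is not None:
                return self.lognorm
            raise ValueError("lognorm layer not computed; call log_normalize first")
        raise ValueError(f"unknown layer {layer!r}")

    def subset_genes(self, genes):
        idx = [self._gene_index[g] for g in genes]
        return ExpressionMatrix(
            [self.genes[i] for i in idx],
            self.units,
            self.counts[idx, :],
            layer=self.layer,
            lognorm=None if self.lognorm is None else self.lognorm[idx, :],
        )

    def subset_units(self, units):
        idx = [self._unit_index[u] for u in units]
        return ExpressionMatrix(
            self.genes,
            [self.units[i] for i in idx],
            self.counts[:, idx],
            layer=self.layer,
            lognorm=None if self.lognorm is None else self.lognorm[:, idx],
        )

    def to_frame(self, layer=None):
        values = self.counts if layer is None else self.get_layer(layer)
        return pd.DataFrame(values, index=self.genes, columns=self.units)

    def __repr__(self):
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_units} units, "
            f"layer={self.layer!r})"
        )


class SpatialCoordinates:
    """2-D coordinates, one (x, y) pair per unit."""

    def __init__(self, frame):
        frame = pd.DataFrame(frame)
        required = {"unit", "x", "y"}
        if not required.issubset(frame.columns):
            raise ValueError(f"coordinates need columns {sorted(required)}")
        frame = frame[["unit", "x", "y"]].copy()
        frame["unit"] = frame["unit"].astype(str)
        if frame["unit"].duplicated().any():
            dups = frame.loc[frame["unit"].duplicated(), "unit"].tolist()
            raise ValueError(f"duplicate unit ids in coordinates: {dups}")
        xy = frame[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite coordinates")
        self.frame = frame.set_index("unit")

    @property
    def units(self):
        return list(self.frame.index)

    def xy(self, units=None):
        if units is None:
            return self.frame[["x", "y"]].to_numpy(dtype=float)
        missing = [u for u in units if u not in self.frame.index]
        if missing:
            raise KeyError(f"units without coordinates: {missing}")
        return self.frame.loc[list(units), ["x", "y"]].to_numpy(dtype=float)

    def match(self, expr: ExpressionMatrix):
        """Check that every expression unit has a coordinate; raise listing ids."""
        missing = [u for u in expr.units if u not in self.frame.index]
        if missing:
            raise ValueError(f"units missing coordinates: {missing}")
        return self.xy(expr.units)

    def __len__(self):
        return len(self.frame)


@dataclass
class PriorKnowledge:
    """Ligand-receptor pairs, pathway edges/sets and transcription factors.

    Symbols are uppercase-normalized on load; matching against expression
    matrices is therefore done case-insensitively.
    """

    lri_pairs: set = field(default_factory=set)
    pathway_edges: set = field(default_factory=set)  # (geneA, geneB, source)
    tf_set: set = field(default_factory=set)
    pathway_sets: dict = field(default_factory=dict)  # name -> frozenset of genes

    def __post_init__(self):
        self.lri_pairs = {
            (str(l).upper(), str(r).upper()) for l, r in self.lri_pairs
        }
        selfpairs = [p for p in self.lri_pairs if p[0] == p[1]]
        if selfpairs:
            warnings.warn(f"dropping {len(selfpairs)} self-pair LRIs")
            self.lri_pairs -= set(selfpairs)
        self.pathway_edges = {
            (str(a).upper(), str(b).upper(), str(s)) for a, b, s in self.pathway_edges
        }
        self.tf_set = {str(t).upper() for t in self.tf_set}
        self.pathway_sets = {
            str(k): frozenset(str(g).upper() for g in v)
            for k, v in self.pathway_sets.items()
        }


@dataclass
class RunConfig:
    """Tunable parameters for the whole pipeline.

    K : spatial KNN neighbor count (10 by default).
    M : maximum cells per spot; 30 suits Visium-scale spots, 1 means the
        data are already single-cell resolution.
    Z_perm / Z_walk : permutation and random-walk repetition counts.
    max_iter : cap on the multiplicative NNLM iterations.
    lambda1/lambda_alpha/lambda2 : regularization weights, all 0 by default.
    max_walk_steps : bound on the receptor-to-TF walk length.
    p_cutoff : permutation significance threshold for LRIs.
    """

    K: int = 10
    M: int = 30
    Z_perm: int = 1000
    Z_walk: int = 1000
    max_iter: int = 10000
    lambda1: float = 0.0
    lambda_alpha: float = 0.0
    lambda2: float = 0.0
    max_walk_steps: int = 10
    p_cutoff: float = 0.05
    rng_seed: int = 0
    # numerical / operational knobs
    tol: float = 1e-6
    n_restarts: int = 100
    min_genes: int = 50
    unsure_prop_min: float = 0.3
    min_expr: float = 0.0
    min_cells_frac: float = 0.1
    scale_factor: float = 1e4
    decon_layer: str = "raw"   # layer the NNLM fits on; raw keeps pooled
                               # spot counts linear in the mixing weights

    def __post_init__(self):
        for name in ("K", "M", "Z_perm", "Z_walk", "max_iter", "max_walk_steps",
                     "n_restarts"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("lambda1", "lambda_alpha", "lambda2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self):
        return np.random.default_rng(self.rng_seed)
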