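"""Readers/writers for the delimited, matrix-market, GMT and list formats,
plus global-scaling log normalization and gene-symbol hygiene.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .types import ExpressionMatrix, PriorKnowledge, SpatialCoordinates

logger = logging.getLogger("spacomm")

__all__ = [
    "load_expression",
    "write_expression",
    "log_normalize",
    "load_prior_knowledge",
    "load_coordinates",
    "write_coordinates",
]


def _dedupe_genes(genes, counts):
    """Drop every copy of a duplicated gene symbol and unnamed rows.

    Duplicated symbols are ambiguous after symbol revision, so all copies
    are removed rather than arbitrarily keeping one.
    """
    genes = [str(g).strip() for g in genes]
    seen, dup = {}, set()
    for g in genes:
        if g in seen:
            dup.add(g)
        seen[g] = True
    bad = {g for g in dup} | {g for g in genes if g == "" or g.lower() == "nan"}
    if bad:
        logger.warning("dropping %d duplicated/unnamed gene symbols", len(bad))
        warnings.warn(f"dropped {len(bad)} duplicated/unnamed gene symbols")
    keep = [i for i, g in enumerate(genes) if g not in bad]
    return [genes[i] for i in keep], counts[keep, :]


def load_expression(path, format="delimited", genes_path=None, units_path=None,
                    alias=None):
    """Read a gene x unit count matrix.

    Parameters
    ----------
    path : str or Path
        Delimited table (genes as row index, units as header) or a
        matrix-market triplet file.
    format : {"delimited", "mtx"}
    genes_path, units_path : str, required for ``mtx``
        One name per line, rows then columns.
    alias : dict, optional
        Static symbol remapping applied before duplicate removal (the
        offline stand-in for live symbol revision). Default: no remapping.
    """
    path = Path(path)
    if format == "delimited":
        try:
            df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ValueError(f"cannot parse {path}: {exc}") from exc
        genes = [str(g) for g in df.index]
        units = [str(u) for u in df.columns]
        counts = df.to_numpy(dtype=float)
    elif format == "mtx":
        if genes_path is None or units_path is None:
            raise ValueError("mtx format needs genes_path and units_path")
        mat = mmread(str(path))
        counts = np.asarray(mat.todense() if hasattr(mat, "todense") else mat,
                            dtype=float)
        genes = Path(genes_path).read_text().split()
        units = Path(units_path).read_text().split()
        if counts.shape[0] != len(genes) or counts.shape[1] != len(units):
            raise ValueError(
                f"matrix {counts.shape} does not match {len(genes)} gene names "
                f"and {len(units)} unit names"
            )
    else:
        raise ValueError(f"unknown format {format!r}")

    if alias:
        genes = [alias.get(g, g) for g in genes]
    genes, counts = _dedupe_genes(genes, counts)
    if np.any(counts < 0):
        i, j = np.argwhere(counts < 0)[0]
        raise ValueError(f"negative count at gene {genes[i]!r}, unit {units[j]!r}")
    return ExpressionMatrix(genes, units, counts, layer="raw")


def write_expression(expr: ExpressionMatrix, path, layer=None):
    expr.to_frame(layer).to_csv(path, sep="\t", float_format="%.10g")


def log_normalize(m: ExpressionMatrix, scale=1e4):
    """Global-scaling normalization: scale each unit to ``scale`` total
    counts, then take the natural log of (1 + value).

    All-zero units are left all-zero (flagged with a warning); downstream
    deconvolution marks them unsure. Returns a new matrix with the raw
    layer retained and the lognorm layer attached.
    """
    if m.layer != "raw":
        raise ValueError("log_normalize expects a raw-layer matrix")
    totals = m.counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero units left unnormalized")
    safe = np.where(zero, 1.0, totals)
    lognorm = np.log1p(m.counts / safe * scale)
    lognorm[:, zero] = 0.0
    return ExpressionMatrix(m.genes, m.units, m.counts, layer="raw",
                            lognorm=lognorm)


def _parse_gmt(path):
    sets = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs name, desc, >=1 gene")
        name, _desc, *genes = fields
        sets[name] = frozenset(g.strip().upper() for g in genes if g.strip())
    return sets


def _parse_edge_list(path):
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if len(df.columns) < 3:
        raise ValueError(f"{path}: edge list needs 3 columns (src, dst, source)")
    a, b, s = df.columns[:3]
    edges = {
        (str(x).upper(), str(y).upper(), str(z))
        for x, y, z in zip(df[a], df[b], df[s])
    }
    # membership sets per source label, usable for enrichment
    sets = {}
    for x, y, z in edges:
        sets.setdefault(z, set()).update((x, y))
    return edges, {k: frozenset(v) for k, v in sets.items()}


def load_prior_knowledge(lri_path, pathway_path=None, tf_path=None):
    """Assemble a :class:`PriorKnowledge` from the three standard files.

    - LRI table: delimited with ``ligand`` and ``receptor`` columns.
    - Pathway file: GMT (``.gmt`` extension -> gene sets) or a 3-column
      edge list (src, dst, source label -> directed edges plus per-source
      membership sets).
    - TF file: one symbol per line.
    """
    lri = pd.read_csv(lri_path, sep=None, engine="python")
    lri.columns = [c.lower() for c in lri.columns]
    if "ligand" not in lri.columns or "receptor" not in lri.columns:
        raise ValueError("LRI table must have 'ligand' and 'receptor' columns")
    pairs = {(str(l), str(r)) for l, r in zip(lri["ligand"], lri["receptor"])}

    edges, sets = set(), {}
    if pathway_path is not None:
        if str(pathway_path).endswith(".gmt"):
            sets = _parse_gmt(pathway_path)
        else:
            edges, sets = _parse_edge_list(pathway_path)

    tfs = set()
    if tf_path is not None:
        tfs = {
            line.strip() for line in Path(tf_path).read_text().splitlines()
            if line.strip()
        }
    return PriorKnowledge(lri_pairs=pairs, pathway_edges=edges, tf_set=tfs,
                          pathway_sets=sets)


def load_coordinates(path):
    """Read a 3-column delimited file (unit, x, y)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: coordinates need 3 columns (unit, x, y)")
    df = df.iloc[:, :3]
    df.columns = ["unit", "x", "y"]
    try:
        df["x"] = pd.to_numeric(df["x"])
        df["y"] = pd.to_numeric(df["y"])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric coordinate: {exc}") from exc
    return SpatialCoordinates(df)


def write_coordinates(coords: SpatialCoordinates, path):
    coords.frame.reset_index().to_csv(path, sep="\t", index=False,
                                      float_format="%.10g")
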