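"""End-to-end orchestration: decompose -> reconstruct -> communicate.

These functions glue the stage modules together for the CLI and for
scripted runs; each accepts in-memory objects so library users can swap
any stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as sio
from .communication import score_all_communications
from .deconvolution import (
    assign_single_cell_labels,
    build_reference_profile,
    fit_nnlm,
    spot_cell_combination,
    select_spot_cells,
)
from .mapping import ReconstructedAtlas, reconstruct_atlas
from .types import ExpressionMatrix, RunConfig

__all__ = ["decompose", "reconstruct", "communicate"]


def _ensure_lognorm(expr: ExpressionMatrix, cfg: RunConfig):
    if expr.layer == "raw" and expr.lognorm is None:
        return sio.log_normalize(expr, scale=cfg.scale_factor)
    return expr


def decompose(st: ExpressionMatrix, ref: ExpressionMatrix, ref_labels,
              cfg: RunConfig | None = None, mode="spot"):
    """Fit the composition matrix; in ``cell`` mode also assign labels.

    Returns (CompositionMatrix, ReferenceProfile, labels-or-None).
    """
    cfg = cfg or RunConfig()
    st = _ensure_lognorm(st, cfg)
    ref = _ensure_lognorm(ref, cfg)
    profile = build_reference_profile(ref, ref_labels, st_genes=st.genes,
                                      layer=cfg.decon_layer)
    comp = fit_nnlm(st, profile, cfg)
    labels = None
    if mode == "cell":
        labels = assign_single_cell_labels(comp, cfg.unsure_prop_min)
    return comp, profile, labels


def reconstruct(st: ExpressionMatrix, coords, ref: ExpressionMatrix,
                ref_labels, cfg: RunConfig | None = None, mode="spot",
                rng=None):
    """Produce the single-cell atlas from spot (or cell) data.

    Spot mode selects and places reference cells per spot; cell mode keeps
    the original cells at their coordinates with their assigned labels
    ("unsure" cells are dropped from the atlas).
    """
    cfg = cfg or RunConfig()
    rng = rng if rng is not None else cfg.rng()
    st = _ensure_lognorm(st, cfg)
    ref = _ensure_lognorm(ref, cfg)
    comp, profile, labels = decompose(st, ref, ref_labels, cfg, mode=mode)

    if mode == "cell":
        keep = labels.index[labels["label"] != "unsure"]
        placements = pd.DataFrame({
            "cell": list(keep),
            "type": labels.loc[keep, "label"].to_list(),
            "x": coords.frame.loc[keep, "x"].to_list(),
            "y": coords.frame.loc[keep, "y"].to_list(),
            "source_spot": list(keep),
            "source_ref_cell": [""] * len(keep),
        })
        expr = st.subset_units(list(keep))
        return ReconstructedAtlas(placements=placements, expression=expr), comp

    comp_frame = comp.to_frame()
    labmap = {str(k): str(v) for k, v in dict(ref_labels).items()}
    st_log = st.get_layer("lognorm")
    gene_sel = [st.gene_idx(g) for g in profile.genes]
    combos = {}
    for j, unit in enumerate(st.units):
        if comp.unsure_mask[j]:
            continue
        beta = comp.proportions[:, j]
        omega = spot_cell_combination(beta, cfg.M, comp.cell_types)
        sc = select_spot_cells(
            st_log[gene_sel, j], omega, ref.subset_genes(profile.genes),
            labmap, comp.cell_types, rng, n_restarts=cfg.n_restarts,
        )
        sc.unit_id = unit
        combos[unit] = sc
    atlas = reconstruct_atlas(st, coords, comp_frame, combos, ref, rng)
    return atlas, comp


def communicate(atlas: ReconstructedAtlas, prior, cfg: RunConfig | None = None,
                rng=None):
    """Score all sender/receiver x ligand/receptor combinations."""
    cfg = cfg or RunConfig()
    rng = rng if rng is not None else cfg.rng()
    expr = _ensure_lognorm(atlas.expression, cfg)
    atlas = ReconstructedAtlas(placements=atlas.placements, expression=expr)
    return score_all_communications(atlas, prior, cfg, rng)
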