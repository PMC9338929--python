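"""Evaluation procedures: simulated spots, composition accuracy,
spatial-proximity significance, co-expression percent and Fisher pathway
enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix

__all__ = [
    "SimulatedSpotSet",
    "simulate_spots",
    "evaluate_composition",
    "spatial_proximity_test",
    "coexpression_percent",
    "fisher_pathway_enrichment",
]


@dataclass
class SimulatedSpotSet:
    """Spots built by binning a labeled single-cell atlas on a square grid."""

    expression: ExpressionMatrix      # genes x spots, summed member counts
    coords: pd.DataFrame              # spot -> bin-center x, y
    truth: pd.DataFrame               # spot x type, ground-truth proportions
    members: dict                     # spot -> list of member cell ids
    bin_size: float


def simulate_spots(expr: ExpressionMatrix, coords, labels, bin_size,
                   origin=None):
    """Merge cells into square-grid spots of side ``bin_size``.

    Cells fall into half-open bins [k*b, (k+1)*b) anchored at the minimum
    coordinate (or ``origin``); empty bins are dropped. Spot expression is
    the exact column sum of member cells; per-spot type proportions are
    recorded as ground truth.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    frame = coords.frame if hasattr(coords, "frame") else pd.DataFrame(coords)
    xy = frame.loc[expr.units, ["x", "y"]].to_numpy(dtype=float)
    labels = {str(k): str(v) for k, v in dict(labels).items()}
    x0, y0 = (xy.min(axis=0) if origin is None else np.asarray(origin, float))
    ix = np.floor((xy[:, 0] - x0) / bin_size).astype(int)
    iy = np.floor((xy[:, 1] - y0) / bin_size).astype(int)

    members = {}
    for cell, i, j in zip(expr.units, ix, iy):
        members.setdefault((i, j), []).append(cell)
    keys = sorted(members)
    spot_ids = [f"spot_{i}_{j}" for i, j in keys]
    raw = expr.get_layer("raw")
    uidx = {u: c for c, u in enumerate(expr.units)}
    counts = np.column_stack([
        raw[:, [uidx[c] for c in members[k]]].sum(axis=1) for k in keys
    ])
    spot_expr = ExpressionMatrix(expr.genes, spot_ids, counts, layer="raw")
    centers = pd.DataFrame(
        {
            "x": [x0 + (i + 0.5) * bin_size for i, _ in keys],
            "y": [y0 + (j + 0.5) * bin_size for _, j in keys],
        },
        index=pd.Index(spot_ids, name="unit"),
    )
    types = sorted({labels[c] for c in expr.units})
    rows = []
    for k in keys:
        cnt = pd.Series([labels[c] for c in members[k]]).value_counts()
        rows.append([cnt.get(t, 0) / len(members[k]) for t in types])
    truth = pd.DataFrame(rows, index=spot_ids, columns=types)
    return SimulatedSpotSet(
        expression=spot_expr, coords=centers, truth=truth,
        members={s: members[k] for s, k in zip(spot_ids, keys)},
        bin_size=float(bin_size),
    )


def evaluate_composition(pred: pd.DataFrame, truth: pd.DataFrame):
    """Per-spot Pearson r and RMSE between predicted and true compositions.

    Spots with a constant truth vector have undefined correlation and are
    skipped (with a warning) for the r summary; RMSE is always computed.
    Returns a dict with per-spot series and their means.
    """
    spots = [s for s in truth.index if s in pred.index]
    types = [t for t in truth.columns if t in pred.columns]
    if not spots or len(types) < 2:
        raise ValueError("prediction and truth share too few spots/types")
    P = pred.loc[spots, types].to_numpy(dtype=float)
    T = truth.loc[spots, types].to_numpy(dtype=float)
    rmse = np.sqrt(((P - T) ** 2).mean(axis=1))
    rs = np.full(len(spots), np.nan)
    skipped = 0
    for i in range(len(spots)):
        if np.ptp(T[i]) == 0 or np.ptp(P[i]) == 0:
            skipped += 1
            continue
        rs[i] = stats.pearsonr(P[i], T[i])[0]
    if skipped:
        warnings.warn(f"{skipped} spots with constant composition skipped for r")
    return {
        "pearson": pd.Series(rs, index=spots),
        "rmse": pd.Series(rmse, index=spots),
        "mean_pearson": float(np.nanmean(rs)),
        "mean_rmse": float(rmse.mean()),
    }


def spatial_proximity_test(coords, types, expr: ExpressionMatrix, ligand,
                           receptor, A, B, rng=None, max_background=10 ** 6,
                           min_expr=0.0):
    """One-sided rank-sum test: are ligand+ sender to receptor+ receiver
    distances shorter than distances between all ordered cell pairs?

    Exact enumeration is used for small samples (combined n <= 50, no
    ties); the normal approximation with tie correction otherwise. The
    background is subsampled (seeded) above ``max_background`` pairs.
    Returns (P, flags).
    """
    rng = rng if rng is not None else np.random.default_rng()
    coords = np.asarray(coords, dtype=float)
    types = np.asarray(types, dtype=object)
    n = len(types)
    raw = expr.get_layer("raw")
    lookup = {g.upper(): i for i, g in enumerate(expr.genes)}
    li, ri = lookup.get(str(ligand).upper()), lookup.get(str(receptor).upper())
    flags = {"low_n": False, "subsampled": False, "no_pairs": False}
    if li is None or ri is None:
        flags["no_pairs"] = True
        return 1.0, flags
    lpos = raw[li, :] > min_expr
    rpos = raw[ri, :] > min_expr
    send = np.flatnonzero((types == A) & lpos)
    recv = np.flatnonzero((types == B) & rpos)
    pair_d = [
        float(np.hypot(*(coords[u] - coords[v])))
        for u in send for v in recv if u != v
    ]
    if not pair_d:
        flags["no_pairs"] = True
        return 1.0, flags
    if len(pair_d) < 3:
        flags["low_n"] = True

    n_bg = n * (n - 1)
    if n_bg > max_background:
        flags["subsampled"] = True
        us = rng.integers(0, n, size=max_background)
        vs = rng.integers(0, n, size=max_background)
        keep = us != vs
        bg = np.hypot(coords[us[keep], 0] - coords[vs[keep], 0],
                      coords[us[keep], 1] - coords[vs[keep], 1])
    else:
        diff = coords[:, None, :] - coords[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=-1))
        bg = D[~np.eye(n, dtype=bool)]

    x, y = np.asarray(pair_d), np.asarray(bg)
    method = "exact" if (len(x) + len(y) <= 50
                         and len(np.unique(np.concatenate([x, y])))
                         == len(x) + len(y)) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="less", method=method)
    return float(res.pvalue), flags


def coexpression_percent(graph, expr: ExpressionMatrix, A, B, ligand,
                         receptor, min_expr=0.0):
    """Percent of A->B graph edges on which the pair co-expresses."""
    from .communication import count_lr_pairs  # local import, no cycle at load

    n_ab = int(graph.edges_between(A, B).sum())
    if n_ab == 0:
        return 0.0
    c0 = count_lr_pairs(graph, expr, A, B, ligand, receptor, min_expr)
    return 100.0 * c0 / n_ab


def fisher_pathway_enrichment(target_genes, pathway_sets, universe):
    """One-sided (upper-tail) Fisher exact enrichment per pathway.

    For each pathway the 2x2 table is: a = targets in the pathway, b =
    pathway genes not in the targets, c = targets outside the pathway,
    d = the rest of the universe. P is the hypergeometric upper tail at a.
    A Benjamini-Hochberg column is appended for convenience (not part of
    the core procedure).
    """
    universe = {str(g).upper() for g in universe}
    targets = {str(g).upper() for g in target_genes} & universe
    if not pathway_sets:
        raise ValueError("pathway_sets is empty")
    rows = []
    for name in sorted(pathway_sets):
        pw = {str(g).upper() for g in pathway_sets[name]} & universe
        a = len(targets & pw)
        b = len(pw - targets)
        c = len(targets - pw)
        d = len(universe) - a - b - c
        n = a + b + c + d
        if targets:
            p = float(stats.hypergeom.sf(a - 1, n, a + b, a + c))
        else:
            p = 1.0
        rows.append((name, a, b, c, d, p))
    table = pd.DataFrame(rows, columns=["pathway", "a", "b", "c", "d", "p"])
    from statsmodels.stats.multitest import multipletests

    table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    return table
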