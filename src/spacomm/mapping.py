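"""Placement of selected reference cells inside their spots.

Each placed cell is displaced from its spot center (x0, y0) by

    x = x0 + a * d_min * cos(theta * pi / 180) / 2
    y = y0 + a * d_min * sin(theta * pi / 180) / 2

with theta in (0, 360] and a in (0, 1], so every placement lies within
half the distance d_min to the relevant neighbor spot. The space around
the spot is split into four axis-aligned 90-degree sectors; the nearest
neighbor spot in each sector is found, and the sector is drawn with
probability (R_q + 1) / sum_i (R_i + 1) where R_q is the neighbor's fitted
proportion of the cell's type. Within the chosen sector the radius weight
``a`` falls in (0, 0.5] with probability (R_center + 1)/(R_center + R_theta
+ 2) — cells of a type abundant at the center stay near it — and in
(0.5, 1] otherwise; theta and a are uniform within their interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

__all__ = [
    "NeighborContext",
    "CellPlacement",
    "ReconstructedAtlas",
    "compute_neighbor_context",
    "sample_cell_coordinate",
    "reconstruct_atlas",
]

N_QUADRANTS = 4


@dataclass
class NeighborContext:
    spot_id: str
    cell_type: str
    center: tuple                 # (x0, y0)
    neighbor_ids: list            # per quadrant; None when the sector is empty
    distances: np.ndarray         # per quadrant, > 0
    ratios: np.ndarray            # R_q in [0, 1]
    center_ratio: float           # R at (x0, y0) for the cell's type

    @property
    def quadrant_probs(self):
        w = self.ratios + 1.0
        return w / w.sum()


@dataclass
class CellPlacement:
    cell_id: str
    cell_type: str
    spot_id: str
    x: float
    y: float
    theta: float
    alpha: float
    quadrant: int
    source_ref_cell: str = ""


@dataclass
class ReconstructedAtlas:
    """Single-cell spatial product: placements plus their expression."""

    placements: pd.DataFrame      # cell, type, x, y, source_spot, source_ref_cell
    expression: ExpressionMatrix  # genes x placed cells (reference profiles)

    @property
    def labels(self):
        return dict(zip(self.placements["cell"], self.placements["type"]))

    def coordinates(self):
        return self.placements.set_index("cell")[["x", "y"]].to_numpy(dtype=float)


def _quadrant_of(dx, dy):
    """Sector index 1..4 for the half-open angular bins (90q-90, 90q] deg,
    counter-clockwise from +x."""
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0
    if ang == 0.0:
        ang = 360.0
    return int(np.ceil(ang / 90.0))


def compute_neighbor_context(spot_id, cell_type, composition, coords):
    """Nearest neighbor spot in each of the four sectors around a spot.

    Parameters
    ----------
    composition : DataFrame, spots x types, fitted proportions.
    coords : DataFrame indexed by spot with x, y columns (or a
        SpatialCoordinates).
    """
    frame = coords.frame if hasattr(coords, "frame") else coords
    x0, y0 = float(frame.loc[spot_id, "x"]), float(frame.loc[spot_id, "y"])
    others = frame.drop(index=spot_id)
    if len(others) == 0:
        raise ValueError(f"spot {spot_id!r} has no neighbor spots")

    best_id = [None] * N_QUADRANTS
    best_d = np.full(N_QUADRANTS, np.inf)
    for sid, row in others.iterrows():
        dx, dy = float(row["x"]) - x0, float(row["y"]) - y0
        d = float(np.hypot(dx, dy))
        if d == 0.0:
            continue
        q = _quadrant_of(dx, dy) - 1
        if d < best_d[q] or (d == best_d[q] and str(sid) < str(best_id[q])):
            best_d[q], best_id[q] = d, sid

    if not np.isfinite(best_d).any():
        raise ValueError(f"spot {spot_id!r} has no distinct-coordinate neighbors")

    ratios = np.zeros(N_QUADRANTS)
    for q in range(N_QUADRANTS):
        if best_id[q] is not None:
            ratios[q] = float(composition.loc[best_id[q], cell_type])
    # empty sectors (tissue edge): ratio 0, distance imputed from the
    # nearest populated sector so the placement stays local
    fill = float(best_d[np.isfinite(best_d)].min())
    best_d = np.where(np.isfinite(best_d), best_d, fill)
    center_ratio = float(composition.loc[spot_id, cell_type])
    return NeighborContext(
        spot_id=str(spot_id), cell_type=str(cell_type), center=(x0, y0),
        neighbor_ids=best_id, distances=best_d, ratios=ratios,
        center_ratio=center_ratio,
    )


def sample_cell_coordinate(ctx: NeighborContext, rng, cell_id="",
                           source_ref_cell=""):
    """Draw one placement from the sector/radius distribution of ``ctx``."""
    probs = ctx.quadrant_probs
    q = int(rng.choice(N_QUADRANTS, p=probs))  # 0-based
    theta = float(rng.uniform(90.0 * q, 90.0 * (q + 1)))
    if theta == 90.0 * q:  # open lower bound
        theta = 90.0 * (q + 1)
    d_min = float(ctx.distances[q])
    r_center, r_theta = ctx.center_ratio, float(ctx.ratios[q])
    p_inner = (r_center + 1.0) / (r_center + r_theta + 2.0)
    if rng.uniform() < p_inner:
        alpha = float(rng.uniform(0.0, 0.5)) or 0.5
    else:
        alpha = float(rng.uniform(0.5, 1.0)) or 1.0
    x0, y0 = ctx.center
    rad = np.deg2rad(theta)
    return CellPlacement(
        cell_id=str(cell_id), cell_type=ctx.cell_type, spot_id=ctx.spot_id,
        x=x0 + alpha * d_min * np.cos(rad) / 2.0,
        y=y0 + alpha * d_min * np.sin(rad) / 2.0,
        theta=theta, alpha=alpha, quadrant=q + 1,
        source_ref_cell=str(source_ref_cell),
    )


def reconstruct_atlas(st: ExpressionMatrix, coords, composition, combinations,
                      ref: ExpressionMatrix, rng, single_cell=False,
                      labels=None):
    """Place every selected reference cell, producing the single-cell atlas.

    Parameters
    ----------
    st : spot (or cell) expression matrix; only unit ids/coords are used.
    composition : DataFrame spots x types of fitted proportions.
    combinations : mapping spot id -> SpotCellCombination. In single-cell
        mode this may instead carry one reference cell per unit.
    ref : reference expression (raw layer) providing per-cell profiles.
    single_cell : when True each unit keeps its original coordinate and
        the sampler is bypassed.
    labels : unit -> type mapping required in single-cell mode.
    """
    frame = coords.frame if hasattr(coords, "frame") else coords
    records, ref_cols = [], []
    for spot in st.units:
        comb = combinations.get(spot)
        if comb is None or not comb.selected_cells:
            continue
        if single_cell:
            x0 = float(frame.loc[spot, "x"])
            y0 = float(frame.loc[spot, "y"])
            c = comb.selected_cells[0]
            lab = labels[spot] if labels else comb.cell_types[int(np.argmax(comb.omega))]
            records.append((spot, lab, x0, y0, spot, c))
            ref_cols.append(c)
            continue
        # expand selected cells by type, sampling a coordinate for each
        per_type = {}
        cells_left = list(comb.selected_cells)
        # selected_cells were drawn type-block-wise in omega order
        for t, w in zip(comb.cell_types, comb.omega):
            if w > 0:
                per_type[t], cells_left = cells_left[:w], cells_left[w:]
        for t, cells in per_type.items():
            ctx = compute_neighbor_context(spot, t, composition, frame)
            for j, c in enumerate(cells):
                cid = f"{spot}.{t}.{j}"
                pl = sample_cell_coordinate(ctx, rng, cell_id=cid,
                                            source_ref_cell=c)
                records.append((cid, t, pl.x, pl.y, spot, c))
                ref_cols.append(c)
    placements = pd.DataFrame(
        records, columns=["cell", "type", "x", "y", "source_spot",
                          "source_ref_cell"],
    )
    idx = [ref.unit_idx(c) for c in ref_cols]
    expr = ExpressionMatrix(
        ref.genes, list(placements["cell"]), ref.counts[:, idx],
        layer=ref.layer,
        lognorm=None if ref.lognorm is None else ref.lognorm[:, idx],
    )
    return ReconstructedAtlas(placements=placements, expression=expr)
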