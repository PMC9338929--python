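"""Cell-type decomposition by a non-negative linear model.

Each spot/cell expression vector Y is modeled as Y = X beta + eps where X
holds per-type mean reference profiles. beta >= 0 is fit by multiplicative
updates under mean relative-entropy (generalized KL) loss

    L(Y, Xb) = mean_g [ y log(y / yhat) - y + yhat ],

the classical multiplicative algorithm for this loss: with fixed X,

    b_j <- b_j * (sum_g X_gj y_g / yhat_g) / (sum_g X_gj + l1 + l2 b_j).

Iteration stops when the relative loss decrease over a 10-iteration window
falls below ``tol`` or after ``max_iter`` iterations. Fitted weights are
reported as proportions (sum 1); raw weights are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, RunConfig

__all__ = [
    "ReferenceProfile",
    "CompositionMatrix",
    "SpotCellCombination",
    "build_reference_profile",
    "fit_nnlm",
    "assign_single_cell_labels",
    "spot_cell_combination",
    "select_spot_cells",
]

_EPS = 1e-12


@dataclass
class ReferenceProfile:
    """Per-type mean expression X [n genes x k types] from a labeled reference."""

    cell_types: list
    genes: list
    profile: np.ndarray  # n x k, lognorm layer
    cells_by_type: dict  # type -> list of reference cell ids

    @property
    def k(self):
        return len(self.cell_types)


@dataclass
class CompositionMatrix:
    """Fitted non-negative weights C [k types x s units] with diagnostics."""

    cell_types: list
    units: list
    weights: np.ndarray          # k x s, raw beta
    converged: np.ndarray        # bool per unit
    loss_trace: np.ndarray       # summed loss over units, per iteration
    unsure_mask: np.ndarray      # bool per unit

    @property
    def proportions(self):
        total = self.weights.sum(axis=0)
        safe = np.where(total > 0, total, 1.0)
        return self.weights / safe

    def to_frame(self):
        return pd.DataFrame(self.proportions.T, index=self.units,
                            columns=self.cell_types)


@dataclass
class SpotCellCombination:
    unit_id: str
    omega: np.ndarray            # integer count per cell type
    cell_types: list
    selected_cells: list         # chosen reference-cell ids
    fit_error: float

    @property
    def m(self):
        return int(self.omega.sum())


def build_reference_profile(S: ExpressionMatrix, labels, st_genes=None,
                            layer="raw"):
    """Average the reference per cell type, on genes shared with ST.

    Parameters
    ----------
    S : reference scRNA-seq.
    labels : mapping cell id -> type label covering every reference cell.
    st_genes : genes of the spatial matrix; the profile is restricted to
        the intersection (all reference genes when None).
    layer : {"raw", "lognorm"}
        Layer averaged into the profile. Raw is the default because the
        linear mixing model Y = X beta holds for pooled counts; the
        log-transformed layer breaks additivity for multi-cell spots.
    """
    labels = {str(k): str(v) for k, v in dict(labels).items()}
    missing = [u for u in S.units if u not in labels]
    if missing:
        raise ValueError(f"unlabeled reference cells: {missing[:5]}")
    types = sorted(set(labels[u] for u in S.units))
    if len(types) < 2:
        raise ValueError("reference must contain at least 2 cell types")
    genes = S.genes if st_genes is None else [g for g in S.genes if g in set(st_genes)]
    if len(genes) < 2:
        raise ValueError(f"only {len(genes)} shared genes between reference and ST")
    sub = S.subset_genes(genes)
    X = sub.get_layer(layer)
    cells_by_type = {t: [u for u in S.units if labels[u] == t] for t in types}
    for t, cells in cells_by_type.items():
        if not cells:
            raise ValueError(f"cell type {t!r} has no reference cells")
    cols = np.column_stack([
        X[:, [sub.unit_idx(u) for u in cells_by_type[t]]].mean(axis=1)
        for t in types
    ])
    return ReferenceProfile(cell_types=types, genes=genes, profile=cols,
                            cells_by_type=cells_by_type)


def _kl_loss(Y, Yhat):
    """Mean relative entropy per unit: columns of Y vs Yhat."""
    Yhat = np.maximum(Yhat, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(Y > 0, Y * np.log(Y / Yhat), 0.0)
    return (term - Y + Yhat).sum(axis=0) / Y.shape[0]


def fit_nnlm(Y, X: ReferenceProfile, cfg: RunConfig | None = None,
             units=None, min_genes=None, layer=None):
    """Fit beta >= 0 minimizing KL(Y || X beta) for one or many units.

    Parameters
    ----------
    Y : array (n genes,) or (n genes, s units) aligned to ``X.genes``; or
        an :class:`ExpressionMatrix` (gene intersection taken, the layer
        matching the reference profile used; ``cfg.decon_layer`` default).
    """
    cfg = cfg or RunConfig()
    if cfg.lambda_alpha > 0:
        raise NotImplementedError("angle regularization is not implemented; "
                                  "set lambda_alpha = 0")
    raw = None
    if isinstance(Y, ExpressionMatrix):
        units = list(Y.units)
        sub = Y.subset_genes(X.genes)
        raw = sub.counts if sub.layer == "raw" else None
        Y = sub.get_layer(layer or cfg.decon_layer)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, s = Y.shape
    if n != len(X.genes):
        raise ValueError(f"Y has {n} genes, profile has {len(X.genes)}")
    if units is None:
        units = [f"unit{i}" for i in range(s)]

    A = X.profile.copy()
    # genes unrepresented in every reference type carry no information and
    # would force yhat to the floor: drop them
    dead = A.sum(axis=1) == 0
    if dead.any() and np.any(Y[dead, :] > 0):
        warnings.warn(f"dropping {int(dead.sum())} genes absent from the reference")
    if dead.any():
        A, Y = A[~dead, :], Y[~dead, :]
        if raw is not None:
            raw = raw[~dead, :]
        n = A.shape[0]
    k = A.shape[1]

    zero_units = Y.sum(axis=0) == 0
    expressed = (Y if raw is None else raw)
    n_expressed = (expressed > 0).sum(axis=0)
    mg = cfg.min_genes if min_genes is None else min_genes
    unsure = zero_units | (n_expressed < mg)

    colsum = A.sum(axis=0)  # > 0 for every type after dead-gene removal
    B = np.full((k, s), 1.0 / k) * np.maximum(Y.sum(axis=0), _EPS) / colsum[:, None]
    B[:, zero_units] = 0.0

    active = ~zero_units
    converged = zero_units.copy()  # trivially done
    loss = _kl_loss(Y, A @ B)
    trace = [float(loss.sum())]
    window = {0: loss.copy()}
    for it in range(1, cfg.max_iter + 1):
        if not active.any():
            break
        Ya, Ba = Y[:, active], B[:, active]
        Yhat = np.maximum(A @ Ba, _EPS)
        numer = A.T @ (Ya / Yhat)
        denom = colsum[:, None] + cfg.lambda1 + cfg.lambda2 * Ba
        Ba = Ba * numer / denom
        B[:, active] = Ba
        loss_a = _kl_loss(Ya, A @ Ba)
        loss[active] = loss_a
        trace.append(float(loss.sum()))
        if it % 10 == 0:
            prev = window.get(it - 10)
            if prev is not None:
                prev_a = prev[active]
                rel = (prev_a - loss_a) / np.maximum(prev_a, _EPS)
                done = (rel < cfg.tol) | (loss_a < _EPS)
                idx = np.flatnonzero(active)
                converged[idx[done]] = True
                active[idx[done]] = False
            window = {it: loss.copy()}

    return CompositionMatrix(
        cell_types=list(X.cell_types), units=list(units), weights=B,
        converged=converged, loss_trace=np.asarray(trace),
        unsure_mask=unsure,
    )


def assign_single_cell_labels(C: CompositionMatrix, unsure_prop_min=0.3):
    """Label each unit with its maximum-weight type, or "unsure".

    Ties are broken to the lexicographically first type and flagged.
    Returns a DataFrame (label, max_prop, ambiguous) indexed by unit.
    """
    P = C.proportions
    order = np.argsort(C.cell_types)  # lexicographic preference
    sorted_types = [C.cell_types[i] for i in order]
    Ps = P[order, :]
    best = np.argmax(Ps, axis=0)  # first (lexicographically) argmax
    maxp = Ps[best, np.arange(Ps.shape[1])]
    ambiguous = (Ps == maxp[None, :]).sum(axis=0) > 1
    labels = [sorted_types[i] for i in best]
    unsure = C.unsure_mask | (maxp < unsure_prop_min)
    labels = ["unsure" if u else l for l, u in zip(labels, unsure)]
    return pd.DataFrame(
        {"label": labels, "max_prop": maxp, "ambiguous": ambiguous},
        index=pd.Index(C.units, name="unit"),
    )


def spot_cell_combination(beta, M, cell_types=None):
    """Integer cell counts per type for one spot: round M*beta half-up,
    then cap the total at M by decrementing the smallest fractional parts.

    If rounding yields an all-zero combination for a spot with signal, the
    dominant type receives one cell.
    """
    beta = np.asarray(beta, dtype=float)
    if M < 1:
        raise ValueError("M must be >= 1")
    if np.any(beta < 0):
        raise ValueError("beta must be non-negative")
    mb = M * beta
    frac = mb - np.floor(mb)
    omega = np.floor(mb).astype(int) + (frac >= 0.5).astype(int)

    if omega.sum() > M:
        names = cell_types if cell_types is not None else [str(i) for i in range(len(beta))]
        # decrement smallest fractional parts first, ties by type name
        order = sorted(range(len(beta)), key=lambda i: (frac[i], names[i]))
        pos = 0
        while omega.sum() > M:
            i = order[pos % len(order)]
            if omega[i] > 0:
                omega[i] -= 1
            pos += 1
    if omega.sum() == 0 and beta.sum() > 0:
        omega[int(np.argmax(beta))] = 1
    return omega


def select_spot_cells(spot_Y, omega, S: ExpressionMatrix, labels,
                      cell_types, rng, n_restarts=100, layer="lognorm"):
    """Pick the reference-cell draw whose summed profile best matches the spot.

    Over ``n_restarts`` random draws of omega_i cells per type i (without
    replacement when the reference allows, with replacement otherwise),
    keep the draw minimizing sum_g (Y_g - sum_cells profile_g)^2.
    """
    labels = {str(k): str(v) for k, v in dict(labels).items()}
    omega = np.asarray(omega, dtype=int)
    spot_Y = np.asarray(spot_Y, dtype=float)
    V = S.get_layer(layer)
    by_type = {}
    for t, w in zip(cell_types, omega):
        if w == 0:
            continue
        cells = [u for u in S.units if labels.get(u) == t]
        if not cells:
            raise ValueError(f"cell type {t!r} required but absent from reference")
        by_type[t] = (cells, int(w))

    if not by_type:
        return SpotCellCombination(
            unit_id="", omega=omega, cell_types=list(cell_types),
            selected_cells=[], fit_error=float(np.sum(spot_Y ** 2)),
        )

    best_err, best_cells = np.inf, None
    for _ in range(n_restarts):
        chosen = []
        for t, (cells, w) in by_type.items():
            replace = w > len(cells)
            pick = rng.choice(len(cells), size=w, replace=replace)
            chosen.extend(cells[i] for i in pick)
        merged = V[:, [S.unit_idx(c) for c in chosen]].sum(axis=1)
        err = float(np.sum((spot_Y - merged) ** 2))
        if err < best_err:
            best_err, best_cells = err, chosen
    return SpotCellCombination(
        unit_id="", omega=omega, cell_types=list(cell_types),
        selected_cells=best_cells, fit_error=best_err,
    )
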