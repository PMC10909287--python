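"""Fusion of the static and dynamic population grids.

The static (residential) grid is homogeneous; the dynamic grid is a
nested multi-resolution grid whose cell borders align with the static
grid.  Fusion produces one grid — the dynamic-grid geometry — carrying
both population datasets: where a dynamic cell is *smaller* than a
static cell the static population is divided equally among the covering
quarters (uniform within-cell density, applied recursively for 4^k
splits); where it is *larger* the static populations of all covered
static cells are summed.  Total static population is conserved exactly;
fractional populations are kept as reals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import CLASSES

__all__ = ["GridAlignmentError", "fuse_grids", "attach_urban_class"]


class GridAlignmentError(ValueError):
    """Static and dynamic grids overlap partially (are not nested)."""


def _bounds(df: pd.DataFrame) -> np.ndarray:
    x0 = df["x0"].to_numpy(dtype=float)
    y0 = df["y0"].to_numpy(dtype=float)
    s = df["size_m"].to_numpy(dtype=float)
    return np.column_stack([x0, y0, x0 + s, y0 + s])


def _overlap_matrix(a: np.ndarray, b: np.ndarray, eps: float) -> np.ndarray:
    """Boolean (len(a), len(b)) matrix of positive-area overlap."""
    ox = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    oy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    return (ox > eps) & (oy > eps)


def fuse_grids(static: pd.DataFrame, dynamic: pd.DataFrame) -> pd.DataFrame:
    """Attach static populations to the dynamic-grid geometry.

    Both frames need ``cell_id, x0, y0, size_m``; ``static`` also needs
    ``static_pop``.  Every (static, dynamic) cell pair that overlaps must
    be nested — one square contained in the other — otherwise a
    :class:`GridAlignmentError` names the offending pair.  Returns a
    frame ``cell_id, x0, y0, size_m, static_pop`` on the dynamic cells.
    Identical grids reduce fusion to a pure join.
    """
    sb, db = _bounds(static), _bounds(dynamic)
    eps = 1e-6 * max(float(static["size_m"].min()), 1.0)
    overlap = _overlap_matrix(sb, db, eps)

    s_in_d = (
        (sb[:, None, 0] >= db[None, :, 0] - eps)
        & (sb[:, None, 1] >= db[None, :, 1] - eps)
        & (sb[:, None, 2] <= db[None, :, 2] + eps)
        & (sb[:, None, 3] <= db[None, :, 3] + eps)
    )
    d_in_s = (
        (db[None, :, 0] >= sb[:, None, 0] - eps)
        & (db[None, :, 1] >= sb[:, None, 1] - eps)
        & (db[None, :, 2] <= sb[:, None, 2] + eps)
        & (db[None, :, 3] <= sb[:, None, 3] + eps)
    )
    bad = overlap & ~s_in_d & ~d_in_s
    if bad.any():
        si, di = np.argwhere(bad)[0]
        raise GridAlignmentError(
            f"static cell {static['cell_id'].iloc[si]!r} and dynamic cell "
            f"{dynamic['cell_id'].iloc[di]!r} overlap without nesting"
        )

    pop = static["static_pop"].to_numpy(dtype=float)
    s_area = (sb[:, 2] - sb[:, 0]) * (sb[:, 3] - sb[:, 1])
    d_area = (db[:, 2] - db[:, 0]) * (db[:, 3] - db[:, 1])
    # contribution of static cell s to dynamic cell d: full pop when
    # s nests in d, an equal area share when d nests in s
    share = np.where(
        overlap & s_in_d,
        pop[:, None],
        np.where(overlap & d_in_s, pop[:, None] * (d_area[None, :] / s_area[:, None]), 0.0),
    )
    fused = dynamic[["cell_id", "x0", "y0", "size_m"]].copy()
    fused["static_pop"] = share.sum(axis=0)
    return fused


def attach_urban_class(
    fused: pd.DataFrame, static: pd.DataFrame, classes: pd.DataFrame
) -> pd.DataFrame:
    """Label fused cells with urban / densely_populated / rural classes.

    A fused cell that is a quarter (or 4^-k) of a static cell inherits
    that cell's class; a fused cell aggregating several static cells
    takes the class holding the majority of its static population (ties
    broken urban > densely_populated > rural).  Raises if any static
    cell lacks a class label.
    """
    cls = classes.set_index("cell_id")["urban_class"]
    missing = [c for c in static["cell_id"] if c not in cls.index]
    if missing:
        raise ValueError(f"missing urban class for cells: {missing}")
    bad = sorted(set(cls) - set(CLASSES))
    if bad:
        raise ValueError(f"unknown urban classes: {bad}")

    sb, db = _bounds(static), _bounds(fused)
    eps = 1e-6 * max(float(static["size_m"].min()), 1.0)
    overlap = _overlap_matrix(sb, db, eps)
    pop = static["static_pop"].to_numpy(dtype=float)
    labels = cls.loc[static["cell_id"]].to_numpy()

    out = fused.copy()
    chosen = []
    for d in range(len(fused)):
        idx = np.flatnonzero(overlap[:, d])
        if len(idx) == 0:
            raise ValueError(
                f"fused cell {fused['cell_id'].iloc[d]!r} covers no static cell"
            )
        # population mass per class over constituents; class precedence
        # breaks exact ties deterministically
        mass = {c: 0.0 for c in CLASSES}
        multi = len(idx) > 1
        for s in idx:
            mass[labels[s]] += pop[s] if multi else 1.0
        if multi and sum(mass.values()) == 0.0:
            for s in idx:  # empty constituents: fall back to count majority
                mass[labels[s]] += 1.0
        chosen.append(max(CLASSES, key=lambda c: (mass[c], -CLASSES.index(c))))
    out["urban_class"] = chosen
    return out
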