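"""Travel-time bands, population summaries and ED catchments.

Accessibility is expressed in the five conventional travel-time bands to
the closest ED — [0,10), [10,20), [20,30), [30,60) and [60, inf)
minutes — and summarized as population sums and row-normalized
percentage shares per urban class, the layout of a national
accessibility table.  Catchments are the sets of cells routed to the
same closest ED; they partition the reachable cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CLASSES

__all__ = [
    "BAND_LABELS",
    "BAND_EDGES",
    "classify_band",
    "band_labels",
    "BandSummary",
    "summarize_population_by_band",
    "derive_catchments",
    "catchment_centroids",
]

BAND_EDGES = (10.0, 20.0, 30.0, 60.0)
BAND_LABELS = ("0-10", "10-20", "20-30", "30-60", ">60")
TOTAL = "Total"


def classify_band(
    travel_time_min, edges: tuple[float, ...] = BAND_EDGES
) -> pd.Categorical:
    """Band label(s) for travel times; half-open intervals [a, b).

    Accepts a scalar or array; raises on negative times.
    """
    t = np.atleast_1d(np.asarray(travel_time_min, dtype=float))
    if np.any(t < 0):
        raise ValueError("negative travel time")
    labels = band_labels(edges)
    idx = np.digitize(t, edges, right=False)
    return pd.Categorical.from_codes(idx, categories=list(labels), ordered=True)


def band_labels(edges: tuple[float, ...]) -> tuple[str, ...]:
    if tuple(edges) == BAND_EDGES:
        return BAND_LABELS
    pts = [0.0, *edges]
    fmt = lambda v: f"{v:g}"
    return tuple(
        [f"{fmt(a)}-{fmt(b)}" for a, b in zip(pts[:-1], pts[1:])] + [f">{fmt(edges[-1])}"]
    )


@dataclass
class BandSummary:
    """Population sums and row-share percentages per (urban class, band).

    ``sums`` and ``shares_pct`` are DataFrames indexed by urban class
    plus a Total row, with one column per band plus a Total column; each
    row's shares sum to 100%.
    """

    sums: pd.DataFrame
    shares_pct: pd.DataFrame


def summarize_population_by_band(
    population, band, urban_class=None
) -> BandSummary:
    """Cross-tabulate population by accessibility band and urban class.

    Works identically for static populations or any temporal stratum's
    dynamic populations.  ``urban_class=None`` yields only the Total row.
    """
    pop = np.asarray(population, dtype=float)
    band = pd.Categorical(band)
    cls = (
        pd.Series(["all"] * len(pop))
        if urban_class is None
        else pd.Series(list(urban_class))
    )
    df = pd.DataFrame({"pop": pop, "band": band, "cls": cls.to_numpy()})
    bands = list(band.categories)
    rows = [c for c in CLASSES if c in set(df["cls"])] if urban_class is not None else []

    sums = pd.DataFrame(index=rows + [TOTAL], columns=bands, dtype=float)
    for r in rows:
        sub = df[df["cls"] == r]
        sums.loc[r] = sub.groupby("band", observed=False)["pop"].sum().reindex(bands).fillna(0.0)
    sums.loc[TOTAL] = df.groupby("band", observed=False)["pop"].sum().reindex(bands).fillna(0.0)
    row_tot = sums.sum(axis=1)
    shares = sums.div(row_tot.where(row_tot > 0), axis=0) * 100.0
    sums[TOTAL] = row_tot
    shares[TOTAL] = shares[bands].sum(axis=1)
    return BandSummary(sums=sums, shares_pct=shares)


def derive_catchments(assignments: pd.DataFrame) -> pd.DataFrame:
    """Catchment membership ``cell_id -> ed_id`` for reachable cells.

    The catchment of an ED is the set of reachable cells whose closest
    ED it is; together the catchments partition the reachable cells.
    """
    reach = assignments[assignments["reachable"]]
    return reach[["cell_id", "ed_id"]].reset_index(drop=True)


def catchment_centroids(
    catchments: pd.DataFrame, fused: pd.DataFrame
) -> pd.DataFrame:
    """Static-population-weighted centroid per catchment.

    Returns ``ed_id, x, y``.  Catchments whose total static population
    is zero fall back to the unweighted mean of member centroids; an
    empty catchment raises.
    """
    if len(catchments) == 0:
        raise ValueError("no catchments")
    cells = fused.set_index("cell_id")
    rows = []
    for ed_id, grp in catchments.groupby("ed_id"):
        sub = cells.loc[grp["cell_id"]]
        if len(sub) == 0:
            raise ValueError(f"empty catchment for ED {ed_id}")
        cx = sub["x0"].to_numpy() + sub["size_m"].to_numpy() / 2.0
        cy = sub["y0"].to_numpy() + sub["size_m"].to_numpy() / 2.0
        w = sub["static_pop"].to_numpy(dtype=float)
        if w.sum() <= 0:
            w = np.ones_like(w)
        rows.append((ed_id, float(np.average(cx, weights=w)), float(np.average(cy, weights=w))))
    return pd.DataFrame(rows, columns=["ed_id", "x", "y"]).sort_values("ed_id").reset_index(drop=True)
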