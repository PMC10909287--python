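"""Synthetic study-region generator.

Emulates the input stack of a national ED-accessibility study: a
homogeneous residential ("static") population grid, an hourly ambient
("dynamic") population aggregated to a privacy-preserving quadtree grid,
a road lattice with speed limits, ED point locations with hospital
levels, and urban/densely-populated/rural class labels.

The dynamic population follows a deterministic movement model on top of
the residential surface:

* **commuting** — on weekdays during office hours (08-17) a fixed
  fraction of every non-core cell's residents is present in the
  urban-core cells instead (allocated proportionally to core resident
  counts);
* **vacation** — in July a fixed fraction of core residents is present
  in designated vacation cells (the "coastal" boundary ring) at all
  hours, emulating the summer outflow from cities.

With movement fractions at zero, scale 1 and noise off, the dynamic
counts are exactly the static counts aggregated to the dynamic grid —
the identity scenario every downstream ratio test relies on.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import (
    DAYTYPES,
    OFFICE_HOURS,
    VACATION_MONTH,
    WEEKDAY,
    ScenarioConfig,
)
from .roads import RoadSegment

__all__ = [
    "generate_static_grid",
    "generate_road_network",
    "generate_eds",
    "assign_urban_classes",
    "core_mask",
    "vacation_mask",
    "presence_by_stratum",
    "generate_dynamic_observations",
]

URBAN = "urban"
DENSE = "densely_populated"
RURAL = "rural"
CLASSES = (URBAN, DENSE, RURAL)

WALKING_SPEED_KMH = 5.0


# ---------------------------------------------------------------------------
# static grid, classes, masks


def generate_static_grid(config: ScenarioConfig) -> pd.DataFrame:
    """Square static grid with a core-weighted residential density.

    Returns a frame with ``cell_id, i, j, x0, y0, size_m, static_pop``.
    Population per cell is ``round(base_pop + core_peak * exp(-d^2/2s^2))``
    with *d* the Euclidean distance (in cells) to the grid centre, so the
    urban core is much denser than the periphery; ``core_peak=0`` gives a
    uniform grid.  Deterministic given the config (no sampling involved).
    """
    n = config.grid_extent
    cs = config.cell_size
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    centre = (n - 1) / 2.0
    d = np.hypot(ii - centre, jj - centre)
    pop = np.round(
        config.base_pop
        + config.core_peak * np.exp(-(d**2) / (2.0 * config.core_sigma_cells**2))
    ).astype(float)
    return pd.DataFrame(
        {
            "cell_id": [f"s{i:03d}_{j:03d}" for i, j in zip(ii, jj)],
            "i": ii,
            "j": jj,
            "x0": ii * cs,
            "y0": jj * cs,
            "size_m": cs,
            "static_pop": pop,
        }
    )


def _chebyshev_cells(static: pd.DataFrame, config: ScenarioConfig) -> np.ndarray:
    centre = (config.grid_extent - 1) / 2.0
    return np.maximum(
        np.abs(static["i"].to_numpy() - centre),
        np.abs(static["j"].to_numpy() - centre),
    )


def core_mask(static: pd.DataFrame, config: ScenarioConfig) -> np.ndarray:
    """Urban-core cells: Chebyshev distance <= core_radius_cells."""
    return _chebyshev_cells(static, config) <= config.core_radius_cells


def vacation_mask(static: pd.DataFrame, config: ScenarioConfig) -> np.ndarray:
    """Vacation destination cells: the boundary ring (the "coast")."""
    i = static["i"].to_numpy()
    j = static["j"].to_numpy()
    n = config.grid_extent
    return (i == 0) | (i == n - 1) | (j == 0) | (j == n - 1)


def assign_urban_classes(static: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Label every cell urban / densely_populated / rural by core distance.

    The innermost third (by Chebyshev distance to the grid centre) is
    urban — widened to include the commuting core, which is urban by
    construction — the middle third densely populated, the outer third
    rural.  Class derivation from commuting statistics is deliberately
    not modelled: labels are input data downstream.
    """
    d = _chebyshev_cells(static, config)
    dmax = d.max()
    urban_r = max(dmax / 3.0, config.core_radius_cells)
    labels = np.where(
        d <= urban_r, URBAN, np.where(d <= max(2.0 * dmax / 3.0, urban_r), DENSE, RURAL)
    )
    return pd.DataFrame({"cell_id": static["cell_id"].to_numpy(), "urban_class": labels})


# ---------------------------------------------------------------------------
# roads and EDs


def generate_road_network(config: ScenarioConfig) -> list[RoadSegment]:
    """Lattice of road segments over the static-grid cell centres.

    Each grid row is emitted as a single polyline through all of the
    row's cell centres while columns are emitted as unit segments, so
    interior vertices of the row polylines coincide with endpoints of the
    column segments — exercising intersection splitting downstream.
    Segment speed limits are sampled from ``speed_set``; a
    ``walking_fraction`` of segments is re-labelled as 5 km/h walking
    roads (removed by the walking filter).
    """
    n = config.grid_extent
    if n < 2:
        raise ValueError("grid_extent must be >= 2")
    cs = config.cell_size
    rng = np.random.default_rng([config.seed, 11])

    def centre(i: int, j: int) -> tuple[float, float]:
        return ((i + 0.5) * cs, (j + 0.5) * cs)

    segments: list[RoadSegment] = []
    for j in range(n):
        coords = [centre(i, j) for i in range(n)]
        segments.append(RoadSegment(id=f"r{j:03d}", coords=coords, speed_kmh=0.0))
    for i in range(n):
        for j in range(n - 1):
            segments.append(
                RoadSegment(
                    id=f"v{i:03d}_{j:03d}",
                    coords=[centre(i, j), centre(i, j + 1)],
                    speed_kmh=0.0,
                )
            )

    speeds = rng.choice(config.speed_set, size=len(segments))
    n_walk = int(round(config.walking_fraction * len(segments)))
    walk_idx = rng.choice(len(segments), size=n_walk, replace=False)
    speeds[walk_idx] = WALKING_SPEED_KMH
    return [
        RoadSegment(id=s.id, coords=s.coords, speed_kmh=float(v))
        for s, v in zip(segments, speeds)
    ]


def generate_eds(static: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """ED point locations at cell centres, with hospital levels 1-3.

    ``spread`` placement uses farthest-point sampling seeded at the grid
    centre (EDs cover the whole region, as a national hospital network
    does); ``core`` placement takes the ``n_eds`` cells closest to the
    centre (a city-cluster configuration).  Levels are assigned by
    centrality: the EDs nearest the core become level 1, then level 2,
    the rest level 3.
    """
    n = config.grid_extent
    cs = config.cell_size
    centre = (n - 1) / 2.0
    cells = static[["i", "j"]].to_numpy(dtype=float)
    d_centre = np.hypot(cells[:, 0] - centre, cells[:, 1] - centre)
    order = np.lexsort((cells[:, 1], cells[:, 0], d_centre))

    if config.n_eds > len(cells):
        raise ValueError("more EDs than grid cells")
    if config.ed_placement == "core":
        chosen = list(order[: config.n_eds])
    else:
        chosen = [int(order[0])]
        dist = np.hypot(
            cells[:, 0] - cells[chosen[0], 0], cells[:, 1] - cells[chosen[0], 1]
        )
        while len(chosen) < config.n_eds:
            # farthest-point sampling; deterministic tie-break on (d, i, j)
            key = np.lexsort((cells[:, 1], cells[:, 0], -dist))
            nxt = int(key[0])
            chosen.append(nxt)
            dist = np.minimum(
                dist, np.hypot(cells[:, 0] - cells[nxt, 0], cells[:, 1] - cells[nxt, 1])
            )

    chosen = sorted(chosen, key=lambda k: (d_centre[k], cells[k, 0], cells[k, 1]))
    p1, p2, _ = config.ed_level_proportions
    n1 = max(1, int(round(p1 * config.n_eds)))
    n2 = int(round(p2 * config.n_eds))
    levels = [1] * n1 + [2] * n2 + [3] * (config.n_eds - n1 - n2)
    levels = levels[: config.n_eds]
    return pd.DataFrame(
        {
            "ed_id": [f"e{k:02d}" for k in range(config.n_eds)],
            "x": [(cells[k, 0] + 0.5) * cs for k in chosen],
            "y": [(cells[k, 1] + 0.5) * cs for k in chosen],
            "level": levels,
        }
    )


# ---------------------------------------------------------------------------
# dynamic population


def presence_by_stratum(
    static: pd.DataFrame,
    config: ScenarioConfig,
    core: np.ndarray | None = None,
    vacation: np.ndarray | None = None,
) -> dict[tuple[int, str, int], np.ndarray]:
    """Expected persons present per static cell for every stratum.

    Movement order: the July vacation relocation is applied first, then
    weekday office-hour commuting acts on the post-vacation non-core
    population.  Totals are conserved exactly at every stratum.
    """
    if core is None:
        core = core_mask(static, config)
    if vacation is None:
        vacation = vacation_mask(static, config)
    residents = static["static_pop"].to_numpy(dtype=float)
    core_w = residents[core]
    core_weights = (
        core_w / core_w.sum() if core_w.sum() > 0 else np.full(core.sum(), 1.0 / max(core.sum(), 1))
    )

    out: dict[tuple[int, str, int], np.ndarray] = {}
    for month, daytype, hour in config.date_span:
        x = residents.copy()
        if month == VACATION_MONTH and config.vacation_fraction > 0 and vacation.any():
            moved = config.vacation_fraction * x[core]
            x[core] -= moved
            x[vacation] += moved.sum() / vacation.sum()
        if (
            daytype == WEEKDAY
            and OFFICE_HOURS[0] <= hour <= OFFICE_HOURS[1]
            and config.commuting_fraction > 0
        ):
            moved = config.commuting_fraction * x[~core]
            x[~core] -= moved
            x[core] += moved.sum() * core_weights
        out[(month, daytype, hour)] = x
    return out


def _quadtree_leaves(
    P: np.ndarray, cs: float, extent: int, floor: float
) -> list[tuple[str, float, float, float]]:
    """Leaves ``(quadkey, x0, y0, size_m)`` of the privacy quadtree.

    ``P`` has shape (n_strata, extent, extent) and already carries the
    operator scale.  A node splits into 4 while every child would hold at
    least ``floor`` persons at every stratum; refinement may go one level
    below the static resolution (quarter cells), where children take
    equal quarters of the parent cell (uniform within-cell density).
    """

    def node_counts(i0: int, i1: int, j0: int, j1: int) -> np.ndarray:
        return P[:, i0:i1, j0:j1].sum(axis=(1, 2))

    leaves: list[tuple[str, float, float, float]] = []

    def recurse(key: str, i0: int, j0: int, span: int) -> None:
        if span > 1:
            h = span // 2
            kids = [(i0, j0), (i0 + h, j0), (i0, j0 + h), (i0 + h, j0 + h)]
            counts = [node_counts(i, i + h, j, j + h) for i, j in kids]
            if all(c.min() >= floor for c in counts):
                for q, (i, j) in enumerate(kids):
                    recurse(key + str(q), i, j, h)
                return
        else:
            quarter = P[:, i0, j0] / 4.0
            if quarter.min() >= floor:
                for q in range(4):
                    leaves.append(
                        (
                            key + str(q),
                            (i0 + 0.5 * (q % 2)) * cs,
                            (j0 + 0.5 * (q // 2)) * cs,
                            cs / 2.0,
                        )
                    )
                return
        leaves.append((key, i0 * cs, j0 * cs, span * cs))

    recurse("d", 0, 0, extent)
    return leaves


def generate_dynamic_observations(
    static: pd.DataFrame, config: ScenarioConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dynamic quadtree grid and per-stratum counts.

    Returns ``(dynamic_grid, observations)``: the grid as
    ``cell_id, x0, y0, size_m`` and the observations as a long frame
    ``cell_id, month, daytype, hour, count``.  Cells are recursively
    split into 4 while every child would still hold at least
    ``privacy_floor`` persons at every stratum, which yields small cells
    in the dense core and large cells in the periphery — areas differing
    by powers of 4 — with borders aligned to the static grid.  Counts are
    expected presence times ``operator_scale``, with optional independent
    Poisson noise.
    """
    n = config.grid_extent
    if n & (n - 1) != 0:
        raise ValueError(
            "grid_extent must be a power of two for aligned quadtree refinement"
        )
    strata = list(config.date_span)
    if not strata:
        raise ValueError("date_span is empty")
    presence = presence_by_stratum(static, config)

    # index presence onto an (n_strata, extent, extent) array
    P = np.zeros((len(strata), n, n))
    i_idx = static["i"].to_numpy()
    j_idx = static["j"].to_numpy()
    for s, key in enumerate(strata):
        P[s, i_idx, j_idx] = presence[key] * config.operator_scale

    leaves = _quadtree_leaves(P, config.cell_size, n, float(config.privacy_floor))
    dynamic = pd.DataFrame(leaves, columns=["cell_id", "x0", "y0", "size_m"])

    cs = config.cell_size
    rng = np.random.default_rng([config.seed, 23])
    records: list[tuple] = []
    for cell_id, x0, y0, size in leaves:
        if size >= cs:
            i0, j0, span = int(x0 / cs), int(y0 / cs), int(size / cs)
            counts = P[:, i0 : i0 + span, j0 : j0 + span].sum(axis=(1, 2))
        else:
            frac = (size / cs) ** 2
            counts = P[:, int(x0 // cs), int(y0 // cs)] * frac
        if config.noise:
            counts = rng.poisson(counts).astype(float)
        for (month, daytype, hour), c in zip(strata, counts):
            records.append((cell_id, month, daytype, hour, float(c)))
    observations = pd.DataFrame(
        records, columns=["cell_id", "month", "daytype", "hour", "count"]
    )
    return dynamic, observations
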