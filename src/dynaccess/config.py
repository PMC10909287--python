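"""Scenario and pipeline configuration.

A :class:`ScenarioConfig` fully determines a synthetic study region: a
homogeneous static (residential) population grid, a quadtree dynamic
(ambient) population grid with a privacy floor, a lattice road network,
emergency-department (ED) locations, and urban/densely-populated/rural
class labels.  Two preset scenarios encode the behavioural regimes the
analysis is designed to detect: weekday office-hour commuting toward the
urban core, and a July vacation outflow from the core to "coastal"
vacation cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

__all__ = [
    "ScenarioConfig",
    "PipelineConfig",
    "default_scenario",
    "commuting_scenario",
    "vacation_scenario",
]

#: hours (inclusive) of the weekday commuting window
OFFICE_HOURS = (8, 17)
#: month index of the vacation period
VACATION_MONTH = 7

WEEKDAY = "weekday"
WEEKEND = "weekend"
DAYTYPES = (WEEKDAY, WEEKEND)


def _default_date_span() -> list[tuple[int, str, int]]:
    # January and July, both daytypes, all 24 hours: the strata the
    # ratio figures and the catchment comparison need.
    return [
        (month, daytype, hour)
        for month in (1, 7)
        for daytype in DAYTYPES
        for hour in range(24)
    ]


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic study region.

    Parameters
    ----------
    grid_extent:
        Cells per side of the static grid.  Must be a power of two for
        dynamic-grid generation so quadtree cells stay border-aligned
        with the static grid.
    cell_size:
        Static cell side in metres (1000 m emulates a 1 km^2 census grid).
    n_eds:
        Number of emergency departments.
    ed_level_proportions:
        Fractions of EDs assigned levels 1, 2, 3 (level 1 = large urban
        hospitals, assigned to the EDs closest to the core).
    ed_placement:
        ``"spread"`` places EDs by farthest-point sampling over the grid;
        ``"core"`` clusters them in and around the urban core.
    commuting_fraction:
        Fraction of each non-core cell's residents present in urban-core
        cells during office hours (08-17) on weekdays.
    vacation_fraction:
        Fraction of core-cell residents relocated to vacation cells in July.
    privacy_floor:
        Minimum persons per dynamic cell per stratum; enforced by
        quadtree coarsening, never by suppression.
    operator_scale:
        Multiplier applied to dynamic counts, emulating operator-share
        extrapolation making dynamic totals differ from static totals.
    noise:
        If true, dynamic counts are Poisson draws around their expected
        value; off by default so closed-form identities hold exactly.
    base_pop, core_peak, core_sigma_cells:
        Residential density surface: ``base + peak * exp(-d^2 / (2 s^2))``
        with *d* the distance (in cells) to the grid centre.  ``core_peak=0``
        gives a uniform grid.
    core_radius_cells:
        Chebyshev radius (in cells, from the grid centre) of the
        commuting-destination core.
    speed_set:
        Speed limits (km/h) sampled per road segment.
    walking_fraction:
        Fraction of segments re-labelled as walking roads (5 km/h).
    date_span:
        ``(month, daytype, hour)`` strata to emit.
    """

    grid_extent: int = 16
    cell_size: float = 1000.0
    n_eds: int = 16
    ed_level_proportions: tuple[float, float, float] = (0.25, 0.35, 0.40)
    ed_placement: str = "spread"
    commuting_fraction: float = 0.0
    vacation_fraction: float = 0.0
    privacy_floor: int = 5
    operator_scale: float = 1.0
    noise: bool = False
    base_pop: float = 3.0
    core_peak: float = 600.0
    core_sigma_cells: float = 2.5
    core_radius_cells: float = 2.0
    speed_set: tuple[float, ...] = (30.0, 50.0, 70.0, 90.0, 110.0)
    walking_fraction: float = 0.1
    date_span: list[tuple[int, str, int]] = field(default_factory=_default_date_span)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_extent < 2:
            raise ValueError("grid_extent must be >= 2")
        if not (0.0 <= self.commuting_fraction <= 1.0):
            raise ValueError("commuting_fraction must be in [0, 1]")
        if not (0.0 <= self.vacation_fraction <= 1.0):
            raise ValueError("vacation_fraction must be in [0, 1]")
        if self.privacy_floor < 1:
            raise ValueError("privacy_floor must be >= 1")
        if self.operator_scale <= 0:
            raise ValueError("operator_scale must be > 0")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if not (0.0 <= self.walking_fraction <= 1.0):
            raise ValueError("walking_fraction must be in [0, 1]")
        if self.n_eds < 1:
            raise ValueError("n_eds must be >= 1")
        if self.ed_placement not in ("spread", "core"):
            raise ValueError("ed_placement must be 'spread' or 'core'")
        for month, daytype, hour in self.date_span:
            if not (1 <= month <= 12 and 0 <= hour <= 23 and daytype in DAYTYPES):
                raise ValueError(f"invalid stratum {(month, daytype, hour)}")

    def to_dict(self) -> dict:
        return asdict(self)


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """Region with both commuting and vacation dynamics, noise off."""
    return ScenarioConfig(
        commuting_fraction=0.3, vacation_fraction=0.35, seed=seed
    )


def commuting_scenario(seed: int = 0) -> ScenarioConfig:
    """Weekday commuting toward the core; EDs clustered at the core.

    With the EDs at the urban core, the 0-10 min accessibility band is the
    core neighbourhood and the commuting inflow raises its *dynamic* share
    during office hours, so the static/dynamic ratio drops below 1 there
    and rises above 1 in the middle bands.
    """
    return ScenarioConfig(
        commuting_fraction=0.3,
        vacation_fraction=0.0,
        n_eds=3,
        ed_placement="core",
        speed_set=(30.0, 50.0, 70.0),
        seed=seed,
    )


def vacation_scenario(seed: int = 0) -> ScenarioConfig:
    """July outflow from the urban core to vacation cells, with noise.

    Commuting is off so the January strata carry only Poisson noise (a
    spatially unstructured surface), while July carries a strong clustered
    over/underestimation pattern across ED catchments.
    """
    return ScenarioConfig(
        commuting_fraction=0.0,
        vacation_fraction=0.35,
        operator_scale=1.4,
        noise=True,
        n_eds=16,
        ed_placement="spread",
        seed=seed,
    )


@dataclass
class PipelineConfig:
    """End-to-end pipeline run configuration.

    Either ``simulate`` is set (synthetic inputs are generated) or all
    input paths are given.  Band edges default to the 10/20/30/60 minute
    accessibility thresholds.
    """

    simulate: ScenarioConfig | None = None
    roads_path: str | None = None
    eds_path: str | None = None
    static_grid_path: str | None = None
    dynamic_grid_path: str | None = None
    observations_path: str | None = None
    classes_path: str | None = None
    max_snap_m: float = 5000.0
    band_edges: Sequence[float] = (10.0, 20.0, 30.0, 60.0)
    catchment_strata: Sequence[tuple[int, int]] = ((1, 13), (7, 13))
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        edges = list(self.band_edges)
        if any(e <= 0 for e in edges) or edges != sorted(set(edges)):
            raise ValueError("band edges must be positive and strictly increasing")
        if self.simulate is None:
            needed = [
                self.roads_path,
                self.eds_path,
                self.static_grid_path,
                self.dynamic_grid_path,
                self.observations_path,
                self.classes_path,
            ]
            if any(p is None for p in needed):
                raise ValueError(
                    "either a simulate block or all six input paths are required"
                )
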