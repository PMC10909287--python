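"""Static vs dynamic population shares and over/underestimation ratios.

Because total population differs between the residential register and
the operator-extrapolated mobile counts, the two datasets are compared
through *shares*: each dataset is normalized by its own total over the
reachable cells, and the statistic of interest is

    ratio = static_share / dynamic_share

per accessibility band and temporal stratum.  A ratio above 1 means the
static data overestimate the share of the population in that band at
that time; below 1, underestimate; the normalization makes the ratio
invariant to any overall scaling of the dynamic counts.  The same
arithmetic at catchment level gives the percentage difference
``diff_pct = (ratio - 1) * 100`` per ED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DAYTYPES

logger = logging.getLogger(__name__)

__all__ = [
    "Stratum",
    "hour_daytype_strata",
    "month_strata",
    "stratum_dynamic_population",
    "band_shares",
    "ratio",
    "ratio_table",
    "catchment_summaries",
]


@dataclass(frozen=True)
class Stratum:
    """A temporal slice of the observation stream.

    Any combination of ``hour``, ``daytype`` and ``month`` may be set;
    unset fields are pooled over.  ``hour=13, month=7`` is "13:00 in
    July", pooling weekdays and weekends.
    """

    hour: int | None = None
    daytype: str | None = None
    month: int | None = None

    def __post_init__(self) -> None:
        if self.hour is not None and not 0 <= self.hour <= 23:
            raise ValueError(f"hour out of range: {self.hour}")
        if self.daytype is not None and self.daytype not in DAYTYPES:
            raise ValueError(f"unknown daytype: {self.daytype}")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.hour is None and self.daytype is None and self.month is None:
            raise ValueError("empty stratum")

    def as_dict(self) -> dict:
        return {"hour": self.hour, "daytype": self.daytype, "month": self.month}


def hour_daytype_strata() -> list[Stratum]:
    """The 48 hour-by-daytype strata of the weekday/weekend figures."""
    return [Stratum(hour=h, daytype=d) for d in DAYTYPES for h in range(24)]


def month_strata(months=range(1, 13)) -> list[Stratum]:
    """One stratum per month, pooling hours and daytypes."""
    return [Stratum(month=m) for m in months]


def stratum_dynamic_population(
    observations: pd.DataFrame, stratum: Stratum
) -> pd.Series:
    """Mean dynamic count per cell over all rows matching the stratum.

    Raises if no observations match.  The arithmetic mean makes the
    result robust to unequal numbers of pooled timestamps per cell.
    """
    m = pd.Series(True, index=observations.index)
    if stratum.hour is not None:
        m &= observations["hour"] == stratum.hour
    if stratum.daytype is not None:
        m &= observations["daytype"] == stratum.daytype
    if stratum.month is not None:
        m &= observations["month"] == stratum.month
    sub = observations[m]
    if len(sub) == 0:
        raise ValueError(f"no observations for stratum {stratum}")
    return sub.groupby("cell_id")["count"].mean()


def band_shares(population: pd.Series, band: pd.Series) -> pd.Series:
    """Share of total population per accessibility band.

    ``population`` and ``band`` are aligned by index (cell id); only
    reachable cells should be passed.  Raises on a zero total.
    """
    pop = population.astype(float)
    if (pop < 0).any():
        raise ValueError("negative population")
    total = pop.sum()
    if total <= 0:
        raise ValueError("zero total population")
    df = pd.DataFrame({"pop": pop, "band": band.loc[pop.index]})
    return df.groupby("band", observed=False)["pop"].sum() / total


def ratio(static_share: float, dynamic_share: float) -> float:
    """static_share / dynamic_share; NaN when the dynamic share is zero."""
    if dynamic_share < 0:
        raise ValueError("negative dynamic share")
    if dynamic_share == 0:
        return float("nan")
    return static_share / dynamic_share


def ratio_table(
    fused: pd.DataFrame,
    observations: pd.DataFrame,
    strata: list[Stratum],
) -> pd.DataFrame:
    """Per-(stratum, band) static and dynamic shares and their ratio.

    ``fused`` must carry ``cell_id, static_pop, band, reachable``; only
    reachable cells enter either total.  Static shares are computed once
    (the residential surface is time-invariant); dynamic shares are
    recomputed per stratum from the observation stream.
    """
    cells = fused[fused["reachable"]].set_index("cell_id")
    if len(cells) == 0:
        raise ValueError("no reachable cells")
    band = cells["band"]
    static_share = band_shares(cells["static_pop"], band)

    rows = []
    for st in strata:
        dyn = stratum_dynamic_population(observations, st).reindex(cells.index)
        if dyn.isna().any():
            missing = list(dyn[dyn.isna()].index[:5])
            raise ValueError(f"stratum {st}: no observations for cells {missing}")
        dyn_share = band_shares(dyn, band)
        for b in static_share.index:
            s, d = float(static_share[b]), float(dyn_share[b])
            rows.append(
                {
                    **st.as_dict(),
                    "band": b,
                    "static_share": s,
                    "dynamic_share": d,
                    "ratio": ratio(s, d),
                }
            )
    return pd.DataFrame(rows)


def catchment_summaries(
    fused: pd.DataFrame,
    catchments: pd.DataFrame,
    eds: pd.DataFrame,
    observations: pd.DataFrame,
    stratum: Stratum,
) -> pd.DataFrame:
    """Static vs dynamic share and percentage difference per catchment.

    For each ED, ``static_share`` is the catchment's fraction of the
    total static population over reachable cells and ``dynamic_share``
    the analogue at the given stratum; ``diff_pct = (ratio - 1) * 100``.
    EDs with an empty catchment are skipped with a warning.
    """
    cells = fused[fused["reachable"]].set_index("cell_id")
    dyn = stratum_dynamic_population(observations, stratum).reindex(cells.index)
    static_tot = cells["static_pop"].sum()
    dyn_tot = dyn.sum()
    if static_tot <= 0 or dyn_tot <= 0:
        raise ValueError("zero total population over reachable cells")
    levels = eds.set_index("ed_id")["level"]

    rows = []
    for ed_id in eds["ed_id"]:
        members = catchments.loc[catchments["ed_id"] == ed_id, "cell_id"]
        if len(members) == 0:
            logger.warning("ED %s has an empty catchment: skipped", ed_id)
            continue
        s = float(cells.loc[members, "static_pop"].sum() / static_tot)
        d = float(dyn.loc[members].sum() / dyn_tot)
        r = ratio(s, d)
        rows.append(
            {
                "ed_id": ed_id,
                "level": int(levels[ed_id]),
                **stratum.as_dict(),
                "static_share": s,
                "dynamic_share": d,
                "ratio": r,
                "diff_pct": (r - 1.0) * 100.0 if np.isfinite(r) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
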