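"""Spatial clustering and between-level tests on catchment differences.

Global Moran's I with inverse-distance weights tests whether catchment
over/underestimation values cluster in space:

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with w_ij = 1/d_ij for 0 < d_ij <= threshold and 0 beyond, the threshold
chosen automatically as the largest nearest-neighbour distance so every
unit has at least one neighbour.  Under the null of no spatial structure
E[I] = -1/(n-1).  Two p-values are reported: a permutation pseudo
p-value (values shuffled over locations) and the analytic z-test under
the randomization assumption.

Differences between hospital levels are tested with one-way ANOVA and
Tukey's HSD (Tukey-Kramer for unequal group sizes), reported in the
"difference ± 95% family-wise half-width, adjusted p" form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "AnovaResult",
    "TukeyPair",
    "auto_threshold",
    "inverse_distance_weights",
    "morans_i",
    "one_way_anova",
    "tukey_hsd",
]


def _pairwise(points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    return np.hypot(p[:, None, 0] - p[None, :, 0], p[:, None, 1] - p[None, :, 1])


def auto_threshold(points) -> float:
    """Largest nearest-neighbour distance over the point set.

    This is the minimal cut-off guaranteeing every point at least one
    neighbour in a distance-band weighting.  Raises on duplicate points
    (zero distances break inverse-distance weights) or fewer than two
    points.
    """
    d = _pairwise(points)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    np.fill_diagonal(d, np.inf)
    if (d <= 0).any():
        raise ValueError("duplicate points: zero pairwise distance")
    return float(d.min(axis=1).max())


@dataclass
class SpatialWeights:
    """Symmetric inverse-distance weights within a cut-off."""

    w: np.ndarray
    threshold_m: float
    row_standardized: bool = False

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        return float(self.w.sum())


def inverse_distance_weights(
    points, threshold_m: float | None = None, row_standardize: bool = False
) -> SpatialWeights:
    """w_ij = 1/d_ij for 0 < d_ij <= threshold, else 0.

    ``threshold_m=None`` uses :func:`auto_threshold`.  A threshold below
    the automatic one leaves some point neighbourless and only triggers
    a warning.  Optional row standardization divides each row by its sum.
    """
    auto = auto_threshold(points)
    if threshold_m is None:
        threshold_m = auto
    elif threshold_m < auto:
        logger.warning(
            "threshold %.1f m below the auto threshold %.1f m: some points "
            "have no neighbour",
            threshold_m,
            auto,
        )
    d = _pairwise(points)
    with np.errstate(divide="ignore"):
        w = np.where((d > 0) & (d <= threshold_m), 1.0 / d, 0.0)
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        w = np.divide(w, rs, out=np.zeros_like(w), where=rs > 0)
    return SpatialWeights(w=w, threshold_m=float(threshold_m), row_standardized=row_standardize)


@dataclass
class MoranResult:
    I: float
    expected: float
    z: float
    p_analytic: float
    p_permutation: float
    n_permutations: int
    seed: int
    threshold_m: float = math.nan


def _moran_stat(x: np.ndarray, w: np.ndarray, s0: float) -> float:
    z = x - x.mean()
    denom = float(z @ z)
    return float(len(x) / s0 * (z @ w @ z) / denom)


def morans_i(
    values,
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with permutation and analytic randomization tests.

    The permutation pseudo p-value is two-sided around the null
    expectation: ``(1 + #{|I* - E| >= |I - E|}) / (1 + n_permutations)``.
    The analytic test uses the variance of I under the randomization
    (permutation) assumption and a normal approximation.  Raises on a
    constant surface, where I is undefined.
    """
    x = np.asarray(values, dtype=float)
    w = weights.w
    n = len(x)
    if n != w.shape[0]:
        raise ValueError("values length does not match weights")
    if np.var(x) == 0:
        raise ValueError("constant surface, I undefined")
    s0 = weights.s0
    I = _moran_stat(x, w, s0)
    e_i = -1.0 / (n - 1)

    # analytic variance under the randomization assumption
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
    z = x - x.mean()
    b2 = n * (z**4).sum() / ((z**2).sum() ** 2)
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    if n > 3:
        var_i = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    else:  # randomization variance needs n >= 4
        var_i = math.nan
    zscore = (I - e_i) / math.sqrt(var_i) if var_i > 0 else math.nan
    p_analytic = (
        2.0 * stats.norm.sf(abs(zscore)) if math.isfinite(zscore) else math.nan
    )

    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_permutations):
        I_perm = _moran_stat(rng.permutation(x), w, s0)
        if abs(I_perm - e_i) >= abs(I - e_i) - 1e-15:
            extreme += 1
    p_perm = (1 + extreme) / (1 + n_permutations)
    return MoranResult(
        I=I,
        expected=e_i,
        z=float(zscore),
        p_analytic=float(p_analytic),
        p_permutation=float(p_perm),
        n_permutations=n_permutations,
        seed=seed,
        threshold_m=weights.threshold_m,
    )


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def one_way_anova(groups: dict[object, list[float]]) -> AnovaResult:
    """One-way ANOVA over labelled groups.

    Degenerate case: zero within-group variance with unequal means is
    reported as ``F = inf, p = 0``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    if n_total <= k:
        raise ValueError("need total N > number of groups")
    grand = np.concatenate(arrays).mean()
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        # degenerate decompositions: constant groups
        if ss_between <= 1e-30:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=math.inf, df_between=df_b, df_within=df_w, p=0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(
        F=float(F), df_between=df_b, df_within=df_w, p=float(stats.f.sf(F, df_b, df_w))
    )


@dataclass
class TukeyPair:
    """One pairwise comparison of the Tukey HSD family."""

    group_a: object
    group_b: object
    difference: float  # mean(a) - mean(b)
    half_width: float  # 95% family-wise half-width
    p_adjusted: float


def tukey_hsd(groups: dict[object, list[float]]) -> list[TukeyPair]:
    """All-pairs Tukey HSD (Tukey-Kramer for unequal n).

    Returns one :class:`TukeyPair` per unordered pair, in label order;
    the interval excludes zero exactly when the adjusted p is below
    0.05 (both derive from the same studentized-range distribution).
    """
    labels = list(groups.keys())
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    if sum(((a - a.mean()) ** 2).sum() for a in arrays) == 0:
        # zero pooled within-group variance: intervals collapse to points
        out = []
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                diff = float(arrays[a].mean() - arrays[b].mean())
                out.append(
                    TukeyPair(
                        group_a=labels[a],
                        group_b=labels[b],
                        difference=diff,
                        half_width=0.0,
                        p_adjusted=1.0 if diff == 0 else 0.0,
                    )
                )
        return out
    res = stats.tukey_hsd(*arrays)
    ci = res.confidence_interval(confidence_level=0.95)
    out = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            lo, hi = ci.low[a, b], ci.high[a, b]
            out.append(
                TukeyPair(
                    group_a=labels[a],
                    group_b=labels[b],
                    difference=float(res.statistic[a, b]),
                    half_width=float((hi - lo) / 2.0),
                    p_adjusted=float(res.pvalue[a, b]),
                )
            )
    return out
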