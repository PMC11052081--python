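"""Community-level physiological profiling statistics from a corrected plate series.

The central quantity is the average well color development

    AWCD(t) = (1/n) * sum_i OD_i(t)

over a set of n substrates, where OD_i is the control-corrected color
development of substrate i (replicates averaged first by default).  From the
substrate profile at a reference timepoint the functional-diversity indices
are computed via the relative color development

    P_i = OD_i / sum_j OD_j,

namely richness (number of substrates oxidized past a threshold at two
consecutive reads), the log-form Simpson index D = -ln(sum P_i^2) and the
Shannon index H = -sum P_i ln P_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ecoplate import PlateSeries
from .errors import ClppError, UndefinedIndexError

DEFAULT_RICHNESS_THRESHOLD = 0.5


def _substrate_od(series: PlateSeries, substrates: Sequence[str] | None) -> pd.DataFrame:
    means = series.substrate_means()
    if substrates is None:
        return means
    substrates = list(substrates)
    if not substrates:
        raise ClppError("substrate subset is empty")
    missing = set(substrates) - set(means.index)
    if missing:
        raise ClppError(f"substrates not in series: {sorted(missing)}")
    return means.loc[substrates]


def awcd(series: PlateSeries, time_h: float, substrates: Sequence[str] | None = None) -> float:
    """Average well color development at one timepoint.

    ``substrates`` restricts the average to a subset (e.g. one carbon
    category); n is the number of substrates in the subset, with the three
    replicate wells of each substrate averaged first.
    """
    idx = series.time_index(time_h)
    od = _substrate_od(series, substrates)
    return float(od.iloc[:, idx].mean())


def awcd_series(series: PlateSeries, substrates: Sequence[str] | None = None) -> pd.Series:
    """AWCD at every timepoint of the series (index: time in hours)."""
    if len(series.times) == 0:
        raise ClppError("empty series")
    od = _substrate_od(series, substrates)
    return pd.Series(od.mean(axis=0).to_numpy(), index=series.times, name="awcd")


def richness(
    series: PlateSeries,
    threshold: float = DEFAULT_RICHNESS_THRESHOLD,
    mode: str = "count",
) -> float:
    """Number of oxidized substrates.

    A substrate counts as oxidized when its replicate-averaged corrected OD
    is at least ``threshold`` at two *consecutive* timepoints.  ``mode="sum"``
    instead sums, over oxidized substrates, their maximal OD across
    qualifying consecutive pairs.
    """
    if len(series.times) < 2:
        raise ClppError("richness needs at least 2 timepoints")
    od = series.substrate_means().to_numpy()
    hits = od >= threshold
    consecutive = hits[:, :-1] & hits[:, 1:]
    oxidized = consecutive.any(axis=1)
    if mode == "count":
        return int(oxidized.sum())
    if mode == "sum":
        pair_max = np.maximum(od[:, :-1], od[:, 1:])
        return float(np.where(consecutive, pair_max, 0.0).max(axis=1)[oxidized].sum())
    raise ClppError(f"unknown richness mode {mode!r}")


def substrate_pi(series: PlateSeries, time_h: float) -> pd.Series:
    """Relative color development P_i per substrate at ``time_h`` (sums to 1)."""
    idx = series.time_index(time_h)
    od = series.substrate_means().iloc[:, idx]
    total = float(od.sum())
    if total <= 0:
        raise UndefinedIndexError(
            f"total color development is 0 at t={time_h} h; P_i undefined"
        )
    return od / total


def _check_pi(pi: Sequence[float] | pd.Series) -> np.ndarray:
    p = np.asarray(pi, dtype=float)
    if p.size == 0:
        raise ClppError("empty proportion vector")
    if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ClppError("proportions must be non-negative and sum to 1")
    return p


def simpson_d(pi: Sequence[float] | pd.Series) -> float:
    """Log-form Simpson index D = -ln(sum P_i^2).

    This is the form used throughout the pipeline (0 for a single substrate,
    ln N at uniform P).  For the classical Gini-Simpson see
    :func:`gini_simpson`.
    """
    p = _check_pi(pi)
    return float(-np.log(np.sum(p**2)))


def gini_simpson(pi: Sequence[float] | pd.Series) -> float:
    """Classical Gini-Simpson index 1 - sum P_i^2 (not used by pipeline defaults)."""
    p = _check_pi(pi)
    return float(1.0 - np.sum(p**2))


def shannon_h(pi: Sequence[float] | pd.Series) -> float:
    """Shannon entropy H = -sum P_i ln P_i; zero entries contribute 0.

    Shared by the plate indices and the ASV-table diversity routines.
    """
    p = _check_pi(pi)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def category_utilization(series: PlateSeries, time_h: float) -> pd.Series:
    """Per-category AWCD at ``time_h`` (n = substrates in the category)."""
    if not series.categories:
        raise ClppError("series carries no category map")
    cats = sorted(set(series.categories.values()))
    out = {}
    for cat in cats:
        subs = [s for s in series.substrates if series.categories.get(s) == cat]
        if not subs:
            raise ClppError(f"category {cat!r} has no substrates in the series")
        out[cat] = awcd(series, time_h, substrates=subs)
    return pd.Series(out, name=f"awcd@{time_h}h")


@dataclass(frozen=True)
class PhaseTimes:
    """Onset of exponential color development and of the stable plateau, in hours.

    Either entry is None when the curve never exhibits that phase.
    """

    t_exp_start: float | None
    t_stable_start: float | None


def detect_phases(
    awcd_curve: pd.Series | Mapping[float, float],
    slope_eps: float | None = None,
    window: int = 3,
) -> PhaseTimes:
    """Locate the exponential-growth and stable periods of an AWCD curve.

    Slopes are taken between consecutive timepoints (per hour).  The
    exponential phase starts at the first timepoint whose forward slope
    exceeds ``slope_eps``; the stable period starts at the first timepoint
    after which slopes stay below ``slope_eps`` for at least ``window``
    consecutive steps and never exceed it again.  ``slope_eps`` defaults to
    2% of the final AWCD per 24 h.
    """
    if not isinstance(awcd_curve, pd.Series):
        awcd_curve = pd.Series(dict(awcd_curve))
    t = awcd_curve.index.to_numpy(dtype=float)
    y = awcd_curve.to_numpy(dtype=float)
    if len(t) < window + 1:
        raise ClppError(f"need at least window+1={window + 1} timepoints")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ClppError("time grid must be strictly increasing")
    if slope_eps is None:
        slope_eps = 0.02 * y[-1] / 24.0
    slopes = np.diff(y) / dt

    above = np.nonzero(slopes > slope_eps)[0]
    if above.size == 0:
        return PhaseTimes(None, None)
    t_exp = float(t[above[0]])

    # first timepoint after which no slope ever exceeds eps again
    stable_idx = above[-1] + 1
    if len(slopes) - stable_idx < window:
        # fewer than `window` quiet steps observed: plateau not established
        return PhaseTimes(t_exp, None)
    return PhaseTimes(t_exp, float(t[stable_idx]))


@dataclass(frozen=True)
class ClppProfile:
    """Bundle of plate-level metabolic statistics for one sample."""

    sample_id: str
    awcd_series: pd.Series  # time_h -> AWCD over all 31 substrates
    awcd_by_category: pd.DataFrame  # categories x time_h
    richness_r: int
    simpson_d: float | None  # None when the plate shows no color development
    shannon_h: float | None
    pi: pd.Series | None  # substrate -> P_i at the reference timepoint
    reference_time_h: float
    phase: PhaseTimes


def profile(
    series: PlateSeries,
    reference_time_h: float | str = "auto",
    richness_threshold: float = DEFAULT_RICHNESS_THRESHOLD,
    slope_eps: float | None = None,
    window: int = 3,
) -> ClppProfile:
    """Compute the full CLPP statistic set for one plate.

    ``reference_time_h="auto"`` uses the detected stable-phase onset, falling
    back to the final timepoint when no plateau is found.
    """
    curve = awcd_series(series)
    cats = sorted(set(series.categories.values()))
    by_cat = pd.DataFrame(
        {t: category_utilization(series, t) for t in series.times}
    ).reindex(cats)
    phase = detect_phases(curve, slope_eps=slope_eps, window=window)
    if reference_time_h == "auto":
        ref = phase.t_stable_start if phase.t_stable_start is not None else float(series.times[-1])
    else:
        ref = float(reference_time_h)
    try:
        pi = substrate_pi(series, ref)
        d, h = simpson_d(pi), shannon_h(pi)
    except UndefinedIndexError:
        pi, d, h = None, None, None
    return ClppProfile(
        sample_id=series.sample_id,
        awcd_series=curve,
        awcd_by_category=by_cat,
        richness_r=int(richness(series, threshold=richness_threshold)),
        simpson_d=d,
        shannon_h=h,
        pi=pi,
        reference_time_h=ref,
        phase=phase,
    )
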