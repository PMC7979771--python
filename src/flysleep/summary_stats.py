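"""Descriptive and comparative outputs: profiles, correlations, group tests.

Activity and sleep profiles use the field's standard 30-minute Zeitgeber-time
bins, averaged across recording days. The sleep profile thresholds bouts at
the per-fly fitted latency K by default; the legacy fixed 5-minute criterion
is a threshold choice away. Parameter structure across flies is summarized
with Spearman rank correlations and average-linkage hierarchical clustering
on 1 - rho, and group differences with two-sample t tests (Student or
Welch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .tracking import LightSchedule, Trajectory, virtual_beam_crossings

__all__ = [
    "sleep_profile",
    "activity_profile",
    "parameter_correlations",
    "group_compare",
    "sleep_history_correlation",
    "SleepHistoryResult",
]

DAY_S = 86400.0


def _fold_to_zt(values: np.ndarray, bin_s: float, t0_zt: float, n_days: int) -> pd.DataFrame:
    """Fold absolute-time bin values onto a 24 h ZT grid, averaging over days."""
    bins_per_day = int(round(DAY_S / bin_s))
    folded = np.zeros(bins_per_day)
    for k, v in enumerate(values):
        folded[k % bins_per_day] += v
    start_zt = (t0_zt + np.arange(bins_per_day) * bin_s / 3600.0) % 24.0
    order = np.argsort(start_zt, kind="stable")
    return pd.DataFrame({"bin_start_zt": start_zt[order],
                         "value": folded[order] / n_days})


def sleep_profile(
    bouts: pd.DataFrame,
    threshold_s: float,
    schedule: LightSchedule | None = None,
    bin_minutes: float = 30.0,
    total_duration_s: float | None = None,
) -> pd.DataFrame:
    """Minutes asleep per 30-min ZT bin, averaged across recording days.

    A bout qualifies as sleep when its duration exceeds ``threshold_s``
    (the fly's fitted K, or 300 s for the legacy 5-minute convention);
    qualifying bouts contribute to every bin they overlap, proportionally.
    """
    if threshold_s <= 0:
        raise ValueError("threshold_s must be positive")
    bin_s = bin_minutes * 60.0
    sleep = bouts[bouts["duration_s"] > threshold_s]
    if total_duration_s is None:
        total_duration_s = float((bouts["onset_s"] + bouts["duration_s"]).max()) if len(bouts) else DAY_S
    n_bins = int(np.ceil(total_duration_s / bin_s))
    cover = np.zeros(max(n_bins, 1))
    for onset, dur in zip(sleep["onset_s"], sleep["duration_s"]):
        lo, hi = onset, onset + dur
        first, last = int(lo // bin_s), int(np.ceil(hi / bin_s))
        for b in range(first, min(last, cover.size)):
            cover[b] += max(0.0, min(hi, (b + 1) * bin_s) - max(lo, b * bin_s))
    n_days = max(int(np.ceil(total_duration_s / DAY_S)), 1)
    t0 = schedule.t0_zt if schedule is not None else 0.0
    out = _fold_to_zt(cover / 60.0, bin_s, t0, n_days)
    out = out.rename(columns={"value": "sleep_min"})
    if schedule is not None:
        out["is_light"] = schedule.is_light((out["bin_start_zt"] - schedule.t0_zt) * 3600.0)
    return out


def activity_profile(
    source: Trajectory | pd.DataFrame,
    schedule: LightSchedule | None = None,
    bin_minutes: float = 30.0,
    n_days: int | None = None,
) -> pd.DataFrame:
    """Beam crossings per 30-min ZT bin, averaged across recording days.

    ``source`` is either a trajectory (crossings are counted at the virtual
    midline beam) or an already-binned crossing table with columns
    ``bin_start_zt, crossings`` on the recording's absolute bin grid.
    """
    if isinstance(source, Trajectory):
        counts = virtual_beam_crossings(source, bin_minutes=bin_minutes)
        if n_days is None:
            n_days = max(int(np.ceil((source.times[-1] + 1) / DAY_S)), 1)
    else:
        counts = source
        if n_days is None:
            n_days = max(int(np.ceil(len(counts) * bin_minutes * 60.0 / DAY_S)), 1)
    t0 = schedule.t0_zt if schedule is not None else 0.0
    out = _fold_to_zt(counts["crossings"].to_numpy(dtype=float),
                      bin_minutes * 60.0, t0, n_days)
    out = out.rename(columns={"value": "crossings"})
    if schedule is not None:
        out["is_light"] = schedule.is_light((out["bin_start_zt"] - schedule.t0_zt) * 3600.0)
    return out


def parameter_correlations(
    param_table: pd.DataFrame, min_flies: int = 5
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Spearman correlation structure of per-fly sleep parameters.

    Returns the tie-corrected Spearman rho matrix (as a DataFrame), the leaf
    order from average-linkage hierarchical clustering on 1 - rho, and the
    scipy linkage matrix. Constant columns have undefined correlations;
    their entries are NaN and a warning is emitted (NaN distances are set to
    the maximum, 2, for clustering).
    """
    if len(param_table) < min_flies:
        raise ValueError(f"need at least {min_flies} flies")
    cols = param_table.columns
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # spearmanr warns on constant input
        rho = stats.spearmanr(param_table.to_numpy(), axis=0).statistic
    rho = np.atleast_2d(rho)
    if np.isnan(rho).any():
        warnings.warn("constant column(s): some correlations are undefined (NaN)")
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    dist = 1.0 - np.nan_to_num(rho, nan=-1.0)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(Z)
    return rho_df, order, Z


def group_compare(sample_a, sample_b, equal_var: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t test: Welch by default, Student if ``equal_var``."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SleepHistoryResult:
    """Sleep-history independence check for one fly."""

    rho: float
    p: float
    n: int
    rho_day_to_night: float = float("nan")
    rho_night_to_next_day: float = float("nan")


def sleep_history_correlation(
    bouts: pd.DataFrame, K: float, min_bouts: int = 5
) -> SleepHistoryResult:
    """Correlate each sleep bout's duration with the sleep accumulated before it.

    Sleep bouts are those longer than K; under the memoryless two-phase
    pattern the Spearman rho should be near zero (no homeostatic carry-over
    in undisturbed flies). When the table carries ``phase`` labels, the
    correlations between consecutive day/night sleep totals are reported too.
    """
    sleep = bouts[bouts["duration_s"] > K].sort_values("onset_s")
    n = len(sleep)
    if n < min_bouts:
        raise ValueError(f"need at least {min_bouts} sleep bouts, got {n}")
    dur = sleep["duration_s"].to_numpy()
    prior = np.concatenate(([0.0], np.cumsum(dur)[:-1]))
    rho, p = stats.spearmanr(dur, prior)
    res = SleepHistoryResult(rho=float(rho), p=float(p), n=n)

    if "phase" in sleep.columns:
        day_idx = (sleep["onset_s"] // DAY_S).astype(int)
        totals = sleep.groupby([day_idx, "phase"])["duration_s"].sum()
        days = sorted({d for d, _ in totals.index})
        d_tot = np.array([totals.get((d, "day"), np.nan) for d in days])
        n_tot = np.array([totals.get((d, "night"), np.nan) for d in days])
        pair = ~(np.isnan(d_tot) | np.isnan(n_tot))
        if pair.sum() >= 3:
            res.rho_day_to_night = float(stats.spearmanr(d_tot[pair], n_tot[pair])[0])
        pair2 = ~(np.isnan(n_tot[:-1]) | np.isnan(d_tot[1:]))
        if pair2.sum() >= 3:
            res.rho_night_to_next_day = float(
                stats.spearmanr(n_tot[:-1][pair2], d_tot[1:][pair2])[0])
    return res
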