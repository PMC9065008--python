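"""Diversity trajectories and discrete-bin (per-capita) rate cross-checks.

Two complementary views of the same fossil record:

* a continuous one — range-through lineage counts on a fine (default
  0.1 Myr) age grid from per-species [Te, Ts] intervals, with slope
  (rate of diversity change) series; and
* a binned one — species classified per 1-Myr time bin into Foote's
  boundary-crosser categories, from which per-capita origination and
  extinction rates follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._piecewise import bin_index, one_myr_bins
from .errors import ConfigError, DomainError

__all__ = [
    "DiversityTrajectory",
    "SlopeSeries",
    "range_through",
    "diversity_slope",
    "bin_occurrence_ranges",
    "foote_rates",
]


@dataclass(frozen=True)
class DiversityTrajectory:
    """Range-through lineage counts on a descending age grid."""

    ages: np.ndarray  # descending, Ma
    counts: np.ndarray  # integer lineage counts
    replicate_index: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts))
        if np.any(self.counts < 0):
            raise DomainError("counts must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"age": self.ages, "count": self.counts})
        if self.replicate_index is not None:
            df["replicate"] = self.replicate_index
        return df


@dataclass(frozen=True)
class SlopeSeries:
    """Diversity change per grid step, assigned to the younger age of each pair."""

    ages: np.ndarray
    slopes: np.ndarray


def range_through(lifespans: pd.DataFrame, step: float = 0.1,
                  replicate_index: int | None = None) -> DiversityTrajectory:
    """Count lineages whose [te, ts] interval covers each grid age.

    The grid spans [0, ceil(max ts)] at ``step`` Myr; intervals are
    closed, so a lineage whose endpoint equals a grid age counts as
    present there.
    """
    ts = lifespans["ts"].to_numpy(float) if len(lifespans) else np.empty(0)
    te = lifespans["te"].to_numpy(float) if len(lifespans) else np.empty(0)
    top = float(np.ceil(ts.max())) if ts.size else 1.0
    n_steps = int(round(top / step))
    grid = np.linspace(top, 0.0, n_steps + 1)  # descending
    if ts.size:
        # count via sorted endpoints: present at t  <=>  ts >= t and te <= t
        ts_sorted = np.sort(ts)
        te_sorted = np.sort(te)
        n_ts_ge = ts.size - np.searchsorted(ts_sorted, grid, side="left")
        n_te_gt = te.size - np.searchsorted(te_sorted, grid, side="right")
        counts = n_ts_ge - n_te_gt
    else:
        counts = np.zeros(grid.size, dtype=int)
    return DiversityTrajectory(grid, counts.astype(int), replicate_index)


def diversity_slope(trajectory: DiversityTrajectory, window=None):
    """Slope series (species per grid step) and its mean over a window.

    The slope at the younger age of each adjacent pair is
    ``D(younger) - D(older)`` — diversity change moving toward the
    present.  ``window`` is an age interval (young_edge, old_edge) in Ma
    over which the mean slope is reported; default is the whole grid.

    Returns ``(SlopeSeries, mean_slope)``.
    """
    ages, counts = trajectory.ages, trajectory.counts
    if ages.size < 2:
        raise DomainError("trajectory needs at least 2 grid points")
    slopes = counts[1:].astype(float) - counts[:-1].astype(float)
    slope_ages = ages[1:]
    if window is None:
        sel = np.ones(slope_ages.size, dtype=bool)
    else:
        lo, hi = sorted(float(x) for x in window)
        if hi > ages[0] or lo < ages[-1]:
            raise ConfigError(f"window {window} outside trajectory grid "
                              f"[{ages[-1]}, {ages[0]}]")
        sel = (slope_ages >= lo) & (slope_ages <= hi)
    return SlopeSeries(slope_ages, slopes), float(slopes[sel].mean())


def bin_occurrence_ranges(table: pd.DataFrame, ages=None, bounds_desc=None,
                          dt: float = 1.0) -> pd.DataFrame:
    """Classify species into Foote boundary-crosser counts per time bin.

    ``table`` is an occurrence table; ``ages`` optionally supplies
    replicate-resolved point ages (a Series indexed by occurrence_id, as
    produced by :func:`fossilbd.occurrences.resample_ages`), otherwise
    ``min_ma`` must equal ``max_ma``.  Each species' binned range runs
    from its first (oldest) to last (youngest) appearance bin; within a
    bin a species is a both-boundary crosser (N_bt), bottom-only crosser
    (N_bL: last appearance here), top-only crosser (N_Ft: first
    appearance here), or a singleton confined to the bin (N_FL).

    Returns one row per bin with columns ``bin_top`` (younger bound),
    ``bin_bottom`` (older), ``N_bt``, ``N_bL``, ``N_Ft``, ``N_FL``, ``dt``.
    """
    if ages is not None:
        point_ages = table["occurrence_id"].map(ages).to_numpy(float)
    else:
        if not np.allclose(table["min_ma"], table["max_ma"]):
            raise DomainError("need point ages (pass `ages` or min_ma == max_ma)")
        point_ages = table["min_ma"].to_numpy(float)
    if bounds_desc is None:
        bounds_desc = one_myr_bins(point_ages.max()) if dt == 1.0 else np.arange(
            np.ceil(point_ages.max() / dt) * dt, -dt / 2, -dt
        )
    bounds = np.asarray(bounds_desc, dtype=float)
    asc = bounds[::-1]
    n_bins = asc.size - 1
    idx = bin_index(point_ages, bounds)  # 0 = youngest bin
    species = table["species"].to_numpy()
    df = pd.DataFrame({"species": species, "bin": idx})
    by = df.groupby("species")["bin"].agg(["min", "max"])
    young, old = by["min"].to_numpy(), by["max"].to_numpy()

    n_bt = np.zeros(n_bins, dtype=int)
    n_bl = np.zeros(n_bins, dtype=int)
    n_ft = np.zeros(n_bins, dtype=int)
    n_fl = np.zeros(n_bins, dtype=int)
    for y, o in zip(young, old):
        if y == o:
            n_fl[y] += 1
            continue
        n_ft[o] += 1          # first appearance: crosses the top only
        n_bl[y] += 1          # last appearance: crosses the bottom only
        if o - y > 1:
            n_bt[y + 1 : o] += 1
    widths = np.diff(asc)
    return pd.DataFrame(
        {
            "bin_top": asc[:-1],
            "bin_bottom": asc[1:],
            "N_bt": n_bt,
            "N_bL": n_bl,
            "N_Ft": n_ft,
            "N_FL": n_fl,
            "dt": widths,
        }
    )


def foote_rates(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-capita origination (p_hat) and extinction (q_hat) rates per bin.

    ``q_hat = ln((N_bt + N_bL) / N_bt) / dt`` and
    ``p_hat = ln((N_bt + N_Ft) / N_bt) / dt``; bins with no
    both-boundary crossers get NaN rates and ``defined = False``.
    Singletons (N_FL) enter neither numerator nor denominator.
    """
    n_bt = counts["N_bt"].to_numpy(float)
    n_bl = counts["N_bL"].to_numpy(float)
    n_ft = counts["N_Ft"].to_numpy(float)
    dt = counts["dt"].to_numpy(float)
    defined = n_bt > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        q_hat = np.where(defined, np.log((n_bt + n_bl) / n_bt) / dt, np.nan)
        p_hat = np.where(defined, np.log((n_bt + n_ft) / n_bt) / dt, np.nan)
    out = counts[["bin_top", "bin_bottom"]].copy()
    out["p_hat"] = p_hat
    out["q_hat"] = q_hat
    out["defined"] = defined
    return out
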