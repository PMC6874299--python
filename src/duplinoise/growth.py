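"""Growth-curve and competition analytics.

Time to exponential growth is read off an OD trace as the time of the
maximal finite-difference slope (the inflection of a logistic curve, at
lag + ln(K/x0 - 1)/r for a lag-shifted logistic). Competition fitness is
expressed as percent of the WT division rate, recovered from the slope of
the log2 mutant/WT odds against cumulative generations, with generations
counted from the dilution factors (g = log2 dilution per passage).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GrowthCurve, ParameterError


@dataclass
class TimeToGrowth:
    time: float  # hours at maximal slope
    slope: float  # OD/h at that time
    no_growth: bool = False


def time_to_growth(
    curve: GrowthCurve,
    smooth_window: int = 3,
    no_growth_slope: float = 0.01,
) -> TimeToGrowth:
    """Time of the maximal OD slope (earliest on ties).

    OD is smoothed with a centered ``smooth_window``-point moving average
    (set to 1 for raw differences), slopes are central finite differences
    against time, and curves whose maximal slope stays below
    ``no_growth_slope`` OD/h are flagged as non-growing.
    """
    if smooth_window < 1:
        raise ParameterError("smooth_window must be >= 1")
    od = curve.od
    if smooth_window > 1:
        od = (
            pd.Series(od).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
        )
    slope = np.gradient(od, curve.time)
    i = int(np.argmax(slope))  # argmax returns the first (earliest) maximum
    return TimeToGrowth(
        time=float(curve.time[i]),
        slope=float(slope[i]),
        no_growth=bool(slope[i] < no_growth_slope),
    )


def threshold_crossing_time(
    curve: GrowthCurve, delta: float = 0.05, baseline_points: int = 3
) -> float | None:
    """Alternative readout: first time OD exceeds baseline + delta.

    The baseline is the mean of the first ``baseline_points`` OD values.
    Returns None when the threshold is never crossed.
    """
    base = float(curve.od[:baseline_points].mean())
    above = np.flatnonzero(curve.od > base + delta)
    return float(curve.time[above[0]]) if above.size else None


@dataclass
class ReplicateSummary:
    median_time: float
    sd_time: float
    fraction_surviving: float
    n_replicates: int
    flagged: bool = False  # SD undefined (a single survivor)


def summarize_replicates(results: list[TimeToGrowth]) -> ReplicateSummary:
    """Median/SD of time-to-growth over surviving replicates + survival rate."""
    if not results:
        raise ParameterError("need at least one replicate")
    survivors = [r.time for r in results if not r.no_growth]
    frac = len(survivors) / len(results)
    if not survivors:
        return ReplicateSummary(np.nan, np.nan, 0.0, len(results), flagged=True)
    median = float(np.median(survivors))
    if len(survivors) < 2:
        return ReplicateSummary(median, np.nan, frac, len(results), flagged=True)
    return ReplicateSummary(median, float(np.std(survivors, ddof=1)), frac, len(results))


def competition_fitness(series: pd.DataFrame) -> tuple[float, float]:
    """Total generations and percent-of-WT division rate from a competition.

    ``series`` holds one row per passage with columns passage,
    dilution_factor (the dilution applied before that measurement; 1 for the
    initial sample) and freq_mutant. Generations per passage are
    log2(dilution factor); the mutant's relative division rate is
    1 + slope of log2(mutant/WT odds) regressed on cumulative generations,
    reported as a percentage of WT.
    """
    if len(series) < 2:
        raise ParameterError("need >= 2 passages")
    f = series["freq_mutant"].to_numpy(dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ParameterError("frequencies of 0 or 1 leave the odds undefined")
    d = series["dilution_factor"].to_numpy(dtype=float)
    if np.any(d[1:] <= 1):
        raise ParameterError("dilution factors after the initial sample must exceed 1")
    g = np.log2(d)
    g[0] = 0.0  # the initial sample precedes any dilution
    G = np.cumsum(g)
    log_odds = np.log2(f / (1.0 - f))
    slope = np.polyfit(G, log_odds, 1)[0] if G[-1] > 0 else 0.0
    total_generations = float(G[-1])
    percent_wt = float(100.0 * (1.0 + slope))
    return total_generations, percent_wt
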