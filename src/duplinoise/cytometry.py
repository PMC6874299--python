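"""Flow-cytometry processing: gating, background regression, noise.

The pipeline mirrors a standard single-color yeast workflow: keep G1 cells
by thresholding the bimodal FSC-W width channel at the density valley,
drop scatter outliers with two reciprocal FSC-A/SSC-A regressions, regress
background autofluorescence of an unlabeled control on cell size and
culture density, and summarize expression noise as CV^2 = variance/mean^2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .datatypes import EventTable, NoiseSummary, ParameterError


def cell_density(N: float, R: float, T: float, C: float = 1.0) -> float:
    """Cells per microliter from acquisition metadata: N / (R*T) * C.

    R is the flow rate (ul/s), T the total flow time (s), so V = R*T is the
    volume read; C is the dilution fix constant (1 undiluted, 1.8333 for the
    standard DDW dilution).
    """
    if R <= 0 or T <= 0:
        raise ParameterError("flow rate and flow time must be positive")
    return N / (R * T) * C


def gate_g1(
    table: EventTable, channel: str = "FSC-W", grid_points: int = 512,
    bw_method: str = "silverman",
) -> tuple[EventTable, float | None]:
    """Keep G1 cells: threshold FSC-W at the KDE valley between its two modes.

    FSC-W is bimodal in an asynchronous culture (G1 small, G2/M large). The
    threshold is the density minimum between the two highest modes; events
    below it are retained. When no interior valley exists the distribution
    is treated as unimodal: a warning is emitted and all events are kept.
    """
    if table.n_events < 100:
        raise ParameterError("G1 gating needs >= 100 events")
    x = table.events[channel].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        warnings.warn("FSC-W constant; unimodal, keeping all events")
        return table, None
    kde = gaussian_kde(x, bw_method=bw_method)
    pad = 3.0 * kde.factor * x.std(ddof=1)  # so boundary modes become interior maxima
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_points)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if len(maxima) < 2:
        warnings.warn("FSC-W appears unimodal; keeping all events")
        return table, None
    top2 = np.sort(maxima[np.argsort(dens[maxima])[-2:]])
    valley = top2[0] + int(np.argmin(dens[top2[0] : top2[1] + 1]))
    threshold = float(grid[valley])
    keep = table.events[x < threshold]
    return EventTable(events=keep.reset_index(drop=True),
                      meta={**table.meta, "N": len(keep)}), threshold


def remove_scatter_outliers(table: EventTable, resid_k: float = 2.5) -> EventTable:
    """Drop events far from the FSC-A~SSC-A and SSC-A~FSC-A regression lines.

    Two sequential OLS fits; after each, events with |residual| beyond
    ``resid_k`` residual standard deviations are removed.
    """
    if table.n_events < 10:
        raise ParameterError("outlier removal needs >= 10 events")
    df = table.events
    for y_col, x_col in (("FSC-A", "SSC-A"), ("SSC-A", "FSC-A")):
        x = df[x_col].to_numpy(dtype=float)
        y = df[y_col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"{x_col} constant; skipping the {y_col}~{x_col} round")
            continue
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        sd = resid.std(ddof=2) if resid.size > 2 else resid.std()
        if sd <= 1e-9 * max(1.0, float(np.abs(y).mean())):
            continue  # (numerically) perfect fit; nothing is an outlier
        df = df[np.abs(resid) <= resid_k * sd]
    return EventTable(events=df.reset_index(drop=True), meta={**table.meta, "N": len(df)})


@dataclass
class BackgroundModel:
    """OLS autofluorescence model: fluor ~ intercept + FSC-W + SSC-W + density."""

    coef: np.ndarray  # (intercept, fscw, sscw, density)
    channel: str
    n_events: int
    feature_names: tuple = ("intercept", "FSC-W", "SSC-W", "density")

    def predict(self, events: pd.DataFrame, density: float) -> np.ndarray:
        X = _design(events, density)
        return X @ self.coef


def _design(events: pd.DataFrame, density: float) -> np.ndarray:
    n = len(events)
    return np.column_stack(
        [np.ones(n), events["FSC-W"].to_numpy(float), events["SSC-W"].to_numpy(float),
         np.full(n, float(density))]
    )


def fit_background_model(
    controls: EventTable | list[EventTable],
    densities: float | list[float],
    channel: str,
) -> BackgroundModel:
    """Fit background fluorescence of unlabeled control cells.

    ``controls`` may be one control sample or several (e.g. at different
    culture densities, each with its own density covariate). The fit is
    least squares with a minimum-norm solution when the design is rank
    deficient (a single sample makes the density column collinear with the
    intercept, which is harmless when correcting at the same density).
    """
    if isinstance(controls, EventTable):
        controls = [controls]
        densities = [densities]
    if len(controls) != len(densities):
        raise ParameterError("one density per control sample required")
    n_total = sum(t.n_events for t in controls)
    if n_total < 500:
        raise ParameterError("need >= 500 control events for the background fit")
    X = np.vstack([_design(t.events, d) for t, d in zip(controls, densities)])
    y = np.concatenate([t.events[channel].to_numpy(float) for t in controls])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return BackgroundModel(coef=coef, channel=channel, n_events=n_total)


def subtract_background(
    table: EventTable, model: BackgroundModel, density: float, channel: str
) -> EventTable:
    """Corrected fluorescence = measured - model prediction (negatives kept)."""
    if channel != model.channel:
        raise ParameterError(
            f"background model was trained on {model.channel!r}, not {channel!r}"
        )
    pred = model.predict(table.events, density)
    out = table.events.copy()
    out[channel] = out[channel].to_numpy(float) - pred
    return EventTable(events=out, meta=dict(table.meta))


def expression_noise(table: EventTable, channel: str) -> NoiseSummary:
    """Population noise CV^2 = unbiased variance / mean^2 on one channel.

    Expected on gated, outlier-removed, background-corrected events. A
    non-positive mean leaves CV^2 undefined (flagged).
    """
    y = table.events[channel].to_numpy(dtype=float)
    if y.size == 0:
        raise ParameterError("no events")
    mean = float(y.mean())
    if mean <= 0:
        return NoiseSummary(mean=mean, cv2=np.nan, n_events=y.size, flagged=True)
    var = float(y.var(ddof=1)) if y.size > 1 else 0.0
    return NoiseSummary(mean=mean, cv2=var / mean**2, n_events=y.size)
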