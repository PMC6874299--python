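"""Distribution statistics of per-cell mRNA counts.

Implements the Poisson maximum-likelihood fit with a chi-square
goodness-of-fit test, the Fano factor (variance/mean), bias-corrected
sample skewness, and the Poisson-normalized skewness
(sample skewness divided by lambda^(-1/2), the skewness of a Poisson
with the same mean). Fano = 1 and normalized skewness = 1 are the
expectations for an unregulated, constitutively transcribed gene; bursty
transcription pushes both above 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountVector, EmptyInputError, ParameterError


@dataclass
class PoissonFit:
    lambda_hat: float
    gof_p: float
    df: int
    degenerate: bool = False


@dataclass
class CountStats:
    mean: float
    variance: float
    fano: float
    skewness: float
    skew_norm: float
    lambda_hat: float
    gof_p: float
    n_cells: int
    flagged: bool = False


def fit_poisson(cv: CountVector, min_expected: float = 5.0) -> PoissonFit:
    """Poisson MLE (the sample mean) plus a chi-square goodness-of-fit test.

    Observed count frequencies are compared against Poisson(lambda_hat)
    expectations; bins are merged inward from both tails until every
    expected frequency reaches ``min_expected``, and one degree of freedom
    is subtracted for the estimated rate.
    """
    counts = cv.counts
    if counts.size < 2:
        raise ParameterError("need at least 2 cells for a Poisson fit")
    lam = float(counts.mean())
    if lam == 0.0:
        return PoissonFit(lambda_hat=0.0, gof_p=np.nan, df=0, degenerate=True)

    kmax = int(counts.max())
    observed = np.bincount(counts, minlength=kmax + 1).astype(float)
    expected = counts.size * stats.poisson.pmf(np.arange(kmax + 1), lam)
    # open right tail so the expectations sum to n
    expected[-1] += counts.size * stats.poisson.sf(kmax, lam)

    obs_bins, exp_bins = _merge_bins(observed, expected, min_expected)
    if len(obs_bins) < 3:  # after df loss for lambda there is nothing to test
        return PoissonFit(lambda_hat=lam, gof_p=np.nan, df=0, degenerate=True)
    chi2 = float(np.sum((obs_bins - exp_bins) ** 2 / exp_bins))
    df = len(obs_bins) - 1 - 1
    return PoissonFit(lambda_hat=lam, gof_p=float(stats.chi2.sf(chi2, df)), df=df)


def _merge_bins(observed: np.ndarray, expected: np.ndarray, min_expected: float):
    """Merge adjacent bins inward from both tails until expected >= threshold."""
    obs = list(observed)
    exp = list(expected)
    while len(exp) > 1 and exp[0] < min_expected:
        exp[1] += exp[0]
        obs[1] += obs[0]
        del exp[0], obs[0]
    while len(exp) > 1 and exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        del exp[-1], obs[-1]
    return np.asarray(obs), np.asarray(exp)


def count_stats(cv: CountVector) -> CountStats:
    """Mean, unbiased variance, Fano, and (Poisson-normalized) skewness."""
    counts = cv.counts
    if counts.size < 3:
        raise ParameterError("need at least 3 cells for count statistics")
    mean = float(counts.mean())
    var = float(counts.var(ddof=1))
    fit = fit_poisson(cv)
    if mean == 0.0:
        return CountStats(
            mean=mean, variance=var, fano=np.nan, skewness=np.nan, skew_norm=np.nan,
            lambda_hat=fit.lambda_hat, gof_p=fit.gof_p, n_cells=counts.size, flagged=True,
        )
    fano = var / mean
    skew = float(stats.skew(counts, bias=False))
    skew_norm = skew * np.sqrt(mean)  # Poisson skewness is lambda^(-1/2)
    return CountStats(
        mean=mean, variance=var, fano=fano, skewness=skew, skew_norm=skew_norm,
        lambda_hat=fit.lambda_hat, gof_p=fit.gof_p, n_cells=counts.size,
    )


def noise_vs_mean_table(vectors: list[CountVector]) -> pd.DataFrame:
    """One row of count statistics per vector, ordering preserved.

    The resulting (condition, mean, fano, skew_norm) table is the basis of
    noise-versus-abundance curves.
    """
    if not vectors:
        raise EmptyInputError("no count vectors supplied")
    rows = []
    for cv in vectors:
        st = count_stats(cv)
        rows.append(
            {
                "gene": cv.gene,
                "condition": cv.condition,
                "n_cells": st.n_cells,
                "mean": st.mean,
                "variance": st.variance,
                "fano": st.fano,
                "skewness": st.skewness,
                "skew_norm": st.skew_norm,
                "lambda_hat": st.lambda_hat,
                "gof_p": st.gof_p,
            }
        )
    return pd.DataFrame(rows)
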