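"""Residual ('sampling-corrected') diversity estimation.

The residual method regresses observed taxic diversity on a sampling proxy
(e.g. counts of fossil-bearing collections per bin) after independently
rank-sorting both log-transformed series from low to high.  The fitted line
models how much diversity the level of sampling alone would predict; applying
it to the proxy in original bin order and subtracting from observed diversity
leaves residuals — the diversity that sampling cannot explain.  Confidence
bands are placed at +/- k standard deviations of the model residuals.

All series are log10(x+1)-transformed first so zero counts remain usable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chrono import BinSeries
from .errors import DegenerateModelError, InsufficientDataError, TableValidationError


def log_transform(series: BinSeries | np.ndarray) -> np.ndarray:
    """Elementwise log10(x+1); NaN (missing) propagates, negatives are rejected."""
    x = series.value if isinstance(series, BinSeries) else np.asarray(series, dtype=float)
    if np.any(x[~np.isnan(x)] < 0):
        raise ValueError("log_transform requires non-negative values")
    return np.log10(x + 1.0)


@dataclass(frozen=True)
class RankModel:
    """OLS fit of ascending-sorted diversity on ascending-sorted proxy."""

    slope: float
    intercept: float
    model_sd: float
    n: int

    def predict(self, proxy_log: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(proxy_log, dtype=float)


def fit_rank_model(diversity_log: np.ndarray, proxy_log: np.ndarray) -> RankModel:
    """Fit the sampling model on independently sorted log series.

    Bins missing either value are removed pairwise before sorting.  The
    model SD is the ddof=1 sample standard deviation of the fit residuals
    (zero when the sorted series coincide).
    """
    d = np.asarray(diversity_log, dtype=float)
    p = np.asarray(proxy_log, dtype=float)
    if d.shape != p.shape:
        raise ValueError("diversity and proxy series must be aligned")
    mask = ~(np.isnan(d) | np.isnan(p))
    d, p = np.sort(d[mask]), np.sort(p[mask])
    if d.size < 3:
        raise InsufficientDataError(
            f"rank model needs >=3 complete bins, got {d.size}"
        )
    if np.ptp(p) == 0:
        raise DegenerateModelError("sampling proxy has zero variance after sorting")
    fit = sps.linregress(p, d)
    resid = d - (fit.intercept + fit.slope * p)
    model_sd = float(np.std(resid, ddof=1))
    return RankModel(float(fit.slope), float(fit.intercept), model_sd, int(d.size))


@dataclass
class RdeResult:
    """Per-bin residual diversity with its sampling model and bands."""

    labels: list[str]
    observed_log: np.ndarray
    proxy_log: np.ndarray
    predicted_log: np.ndarray
    residual: np.ndarray
    model: RankModel
    k_sd: float
    band_upper: np.ndarray
    band_lower: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.labels,
                "observed_log": self.observed_log,
                "proxy_log": self.proxy_log,
                "predicted_log": self.predicted_log,
                "residual": self.residual,
                "band_lower": self.band_lower,
                "band_upper": self.band_upper,
            }
        )


def residual_diversity(
    diversity: BinSeries, proxy: BinSeries, k_sd: float = 1.0
) -> RdeResult:
    """Residual diversity of *diversity* after removing the proxy-predicted part.

    The rank model is fitted on sorted pairs, then applied to the proxy in
    original bin order; ``residual = observed_log - predicted_log``.  Bands
    sit at ``residual +/- k_sd * model_sd`` (``k_sd=0`` collapses them onto
    the residuals).  Predicted values are reported only for bins with a proxy
    value; residuals additionally require an observed value.
    """
    if list(diversity.labels) != list(proxy.labels):
        raise TableValidationError("diversity and proxy series use different bins")
    obs_log = log_transform(diversity)
    proxy_log = log_transform(proxy)
    model = fit_rank_model(obs_log, proxy_log)
    predicted = np.where(np.isnan(proxy_log), np.nan, model.predict(proxy_log))
    residual = obs_log - predicted
    half_width = k_sd * model.model_sd
    return RdeResult(
        labels=list(diversity.labels),
        observed_log=obs_log,
        proxy_log=proxy_log,
        predicted_log=predicted,
        residual=residual,
        model=model,
        k_sd=float(k_sd),
        band_upper=residual + half_width,
        band_lower=residual - half_width,
    )
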