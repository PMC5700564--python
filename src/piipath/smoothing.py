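"""Temporal autocorrelation of the movement index and PII smoothing.

The lag at which the index's autocorrelation first reaches zero sets the
width of a centered moving average; the smoothed series is the path
identification index (PII).  A fixed override window (the documented
default is 15 fixes, ~2.5 days at 4-h fixes) reproduces the reference
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError, WindowSelectionError

MIN_WINDOW = 3


@dataclass
class AcfResult:
    lags: np.ndarray          # 0..max_lag
    values: np.ndarray        # correlation at each lag
    sig_limit: float          # symmetric 5% band, 1.96/sqrt(n_effective)
    n_effective: int          # count of observed (non-imputed) values
    n_imputed: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"lag": self.lags, "acf": self.values, "sig_limit": self.sig_limit}
        )


@dataclass
class PiiSeries:
    """Movement index values with their centered-moving-average smoothing."""

    values: np.ndarray  # the raw composite index M, NaN where undefined
    window: int         # odd fix count
    pii: np.ndarray     # smoothed series, NaN where the window is too empty
    min_defined: int    # fixes required inside the window

    def __len__(self) -> int:
        return len(self.values)


def acf(series, max_lag: int) -> AcfResult:
    """Mean-removed sample autocorrelation on the regular grid.

    Undefined entries (NaN) are imputed with the series mean for estimation
    only — imputed deviations are exactly zero, so they dilute but never
    reverse the correlation structure; their count is reported.  The biased
    estimator r_k = sum(dev_t * dev_{t+k}) / sum(dev_t^2) is used.
    """
    x = np.asarray(series, dtype=float)
    observed = np.isfinite(x)
    n_obs = int(observed.sum())
    if n_obs < 30:
        raise DataError(f"need >= 30 defined values for the ACF, got {n_obs}")
    n = len(x)
    if max_lag >= n / 2:
        raise DataError(f"max_lag {max_lag} must be < n/2 = {n / 2:g}")
    mean = x[observed].mean()
    dev = np.where(observed, x - mean, 0.0)
    denom = float(np.sum(dev * dev))
    if denom <= 0:
        raise DataError("constant series has zero variance; ACF undefined")
    full = np.correlate(dev, dev, mode="full")[n - 1 : n + max_lag]
    values = full / denom
    return AcfResult(
        lags=np.arange(max_lag + 1),
        values=values,
        sig_limit=1.96 / math.sqrt(n_obs),
        n_effective=n_obs,
        n_imputed=n - n_obs,
    )


def select_window(acf_result: AcfResult, override: int | None = None) -> int:
    """Smoothing window from the first non-positive ACF lag, forced odd.

    ``override`` bypasses selection entirely (it must be odd).  Without an
    override the window is the first lag k >= 1 with acf <= 0, incremented
    to odd, floored at 3.
    """
    if override is not None:
        if override < MIN_WINDOW or override % 2 == 0:
            raise DataError(f"override window must be odd and >= {MIN_WINDOW}")
        return int(override)
    nonpos = np.flatnonzero(acf_result.values[1:] <= 0)
    if len(nonpos) == 0:
        raise WindowSelectionError(
            "ACF never reaches 0 within max_lag; pass an explicit window override"
        )
    k = int(nonpos[0]) + 1
    if k % 2 == 0:
        k += 1
    return max(k, MIN_WINDOW)


def smooth(series, window: int) -> PiiSeries:
    """Centered moving average over defined values.

    A fix whose window holds fewer than half the nominal count of defined
    values (including near record ends and across gap runs) is left
    undefined.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if window % 2 == 0 or window < MIN_WINDOW:
        raise DataError(f"window must be odd and >= {MIN_WINDOW}, got {window}")
    if window > n:
        raise DataError(f"window {window} larger than series length {n}")
    half = window // 2
    min_defined = (window + 1) // 2
    defined = np.isfinite(x)
    filled = np.where(defined, x, 0.0)
    # cumulative sums give O(n) windowed sums and counts
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccnt = np.concatenate([[0], np.cumsum(defined.astype(int))])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1) + 1
    sums = csum[hi] - csum[lo]
    cnts = ccnt[hi] - ccnt[lo]
    pii = np.where(cnts >= min_defined, sums / np.maximum(cnts, 1), np.nan)
    return PiiSeries(values=x, window=window, pii=pii, min_defined=min_defined)


def window_duration_days(window_fixes: int, interval_minutes: float = 240.0) -> float:
    """Span in days of a lag/window of consecutive fixes at a fix interval."""
    return window_fixes * interval_minutes / (60.0 * 24.0)
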