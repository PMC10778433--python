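"""Goodness-of-fit metrics and residual moments for model validation.

Per output the report carries the reduced chi-square, RMSE, mean bias error
(MBE), mean percentage error (MPE), total squared error (SSE), absolute
average relative deviation (AARD), the coefficient of determination, and the
residual moments (skewness, excess kurtosis, mean, standard deviation,
variance):

    chi2 = SSE / (N - n)            RMSE = sqrt(SSE / N)
    MBE  = mean(pred - obs)         MPE  = 100 * mean((pred - obs) / obs)
    SSE  = sum((pred - obs)^2)      AARD = 100 * mean(|pred - obs| / |obs|)

with N observations and n fitted constants (0 by default when applied
per output of a shared network).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .mlp import r_squared

__all__ = ["gof_report", "gof_table", "GOF_COLUMNS"]

GOF_COLUMNS = ("chi2", "rmse", "mbe", "mpe", "sse", "aard", "r2",
               "skew", "kurt", "mean", "stdev", "var")


def gof_report(obs, pred, n_constants: int = 0) -> dict[str, float]:
    """All validation metrics for one output series."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("obs and pred must be equal-length 1-D arrays")
    N = obs.size
    if N < 2:
        raise ValueError("need at least two observations")
    if N <= n_constants:
        raise ValueError("N must exceed the number of fitted constants")
    zero = np.flatnonzero(obs == 0)
    if zero.size:
        raise ValueError("relative metrics (MPE, AARD) undefined: zero "
                         f"observation(s) at indices {zero.tolist()}")
    e = pred - obs
    sse = float(np.sum(e ** 2))
    return {
        "chi2": sse / (N - n_constants),
        "rmse": float(np.sqrt(sse / N)),
        "mbe": float(e.mean()),
        "mpe": float(100.0 * np.mean(e / obs)),
        "sse": sse,
        "aard": float(100.0 * np.mean(np.abs(e) / np.abs(obs))),
        "r2": r_squared(obs, pred),
        "skew": float(stats.skew(e)),
        "kurt": float(stats.kurtosis(e)),     # excess kurtosis
        "mean": float(e.mean()),
        "stdev": float(e.std(ddof=0)),
        "var": float(e.var(ddof=0)),
    }


def gof_table(observed: pd.DataFrame, predicted: pd.DataFrame,
              n_constants: int = 0) -> pd.DataFrame:
    """Per-output metric table (outputs x 12 metrics)."""
    if list(observed.columns) != list(predicted.columns):
        raise ValueError("observed and predicted must share columns")
    rows = {c: gof_report(observed[c], predicted[c], n_constants)
            for c in observed.columns}
    return pd.DataFrame.from_dict(rows, orient="index")[list(GOF_COLUMNS)]
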