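"""Model-performance statistics for measured-vs-simulated SOC series.

Four statistics: the squared Pearson correlation R2, the RMSE in the
original units, the normalized RMSE in percent of the measured mean
(n-RMSE = 100/Mbar * sqrt(sum (S_i - M_i)^2 / n)), and Willmott's index of
agreement d = 1 - sum (M_i - S_i)^2 / sum (|S_i - Mbar| + |M_i - Mbar|)^2,
bounded in [0, 1] with 1 for a perfect fit.  A model run is accepted when
n-RMSE < 15% and d > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PairedSeries", "EvalReport", "rmse", "n_rmse", "willmott_d", "r_squared", "evaluate"]

N_RMSE_THRESHOLD = 15.0  # percent
D_THRESHOLD = 0.5


@dataclass
class PairedSeries:
    """Aligned measured and simulated values on a common time index."""

    measured: np.ndarray
    simulated: np.ndarray
    index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.measured = np.asarray(self.measured, dtype=float)
        self.simulated = np.asarray(self.simulated, dtype=float)
        if self.measured.shape != self.simulated.shape:
            raise ValueError("measured and simulated series differ in length")
        if self.measured.size < 2:
            raise ValueError("need at least 2 paired values")
        if self.index is not None:
            self.index = np.asarray(self.index)
            if self.index.shape != self.measured.shape:
                raise ValueError("time index length mismatch")

    @property
    def mean_measured(self) -> float:
        return float(self.measured.mean())


@dataclass
class EvalReport:
    """One-row performance summary with the acceptance rule applied."""

    r2: float
    rmse: float
    n_rmse: float  # percent
    d: float
    n: int

    @property
    def passed(self) -> bool:
        return self.n_rmse < N_RMSE_THRESHOLD and self.d > D_THRESHOLD


def rmse(series: PairedSeries) -> float:
    """Root mean square error in the units of the data."""
    diff = series.simulated - series.measured
    return float(np.sqrt(np.mean(diff**2)))


def n_rmse(series: PairedSeries) -> float:
    """Normalized RMSE in percent of the measured mean."""
    mbar = series.mean_measured
    if mbar <= 0:
        raise ValueError("mean of measured series must be positive for n-RMSE")
    return 100.0 / mbar * rmse(series)


def willmott_d(series: PairedSeries) -> float:
    """Willmott's index of agreement, in [0, 1]."""
    mbar = series.mean_measured
    s_prime = series.simulated - mbar
    m_prime = series.measured - mbar
    denom = float(np.sum((np.abs(s_prime) + np.abs(m_prime)) ** 2))
    if denom == 0:
        raise ValueError("index of agreement undefined: all values equal the measured mean")
    num = float(np.sum((series.measured - series.simulated) ** 2))
    return 1.0 - num / denom


def r_squared(series: PairedSeries) -> float:
    """Squared Pearson correlation between measured and simulated values."""
    m, s = series.measured, series.simulated
    if np.var(m) == 0 or np.var(s) == 0:
        raise ValueError("R2 undefined for a zero-variance series")
    r = float(np.corrcoef(m, s)[0, 1])
    return r * r


def evaluate(series: PairedSeries) -> EvalReport:
    """All four statistics plus the n-RMSE < 15% and d > 0.5 acceptance rule."""
    return EvalReport(
        r2=r_squared(series),
        rmse=rmse(series),
        n_rmse=n_rmse(series),
        d=willmott_d(series),
        n=series.measured.size,
    )
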