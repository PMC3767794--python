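"""Least-squares plumbing shared by every fitting stage.

Two variants: ordinary least squares with intercept (slope, intercept and the
Pearson correlation r of the raw pairs), and a through-origin fit
(slope = sum(x*y)/sum(x^2)), used where an intercept is theoretically zero.
Degenerate designs raise rather than returning NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = ["RegressionResult", "linear_fit", "linear_fit_origin"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    n: int

    def __post_init__(self) -> None:
        for name in ("slope", "intercept", "r"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite regression {name}")
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"correlation out of range: {self.r}")

    def predict(self, x: float) -> float:
        return self.slope * float(x) + self.intercept


def _as_xy(pairs: Iterable[Sequence[float]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (predictor, response) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite value in regression input")
    return arr[:, 0], arr[:, 1]


def linear_fit(pairs: Iterable[Sequence[float]]) -> RegressionResult:
    """Ordinary least squares of response on predictor.

    r is the plain Pearson correlation of the pairs.  Raises on fewer than
    two points or a constant predictor.
    """
    x, y = _as_xy(pairs)
    if x.size < 2:
        raise ValueError(f"need at least 2 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: constant predictor")
    res = stats.linregress(x, y)
    # a constant response makes Pearson r undefined; the fit itself is fine
    r = float(res.rvalue) if np.ptp(y) > 0 else 0.0
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=r,
        n=int(x.size),
    )


def linear_fit_origin(pairs: Iterable[Sequence[float]]) -> RegressionResult:
    """Least-squares line through the origin: slope = sum(xy)/sum(x^2).

    The reported r is still the Pearson correlation of the pairs when n >= 2
    and the predictor varies; with a single point it is set to 1 by
    convention (the line interpolates it exactly).
    """
    x, y = _as_xy(pairs)
    if x.size < 1:
        raise ValueError("need at least 1 point")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("degenerate design: all predictors zero")
    slope = float(np.dot(x, y)) / sxx
    if x.size >= 2 and np.ptp(x) > 0 and np.ptp(y) > 0:
        r = float(stats.pearsonr(x, y).statistic)
    else:
        r = 1.0
    return RegressionResult(slope=slope, intercept=0.0, r=r, n=int(x.size))
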