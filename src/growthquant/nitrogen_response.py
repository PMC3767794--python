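"""Logistic response of seasonal biomass to applied nitrogen.

Season-total yield of each biomass component responds to applied N
(kg ha^-1) along the logistic

    Y(N) = A_y / (1 + exp(b_y - c_n * N))

with A_y the maximum yield at high N (Mg ha^-1), b_y a dimensionless
intercept and c_n the nitrogen response coefficient (ha kg^-1).  With the
amplitude A fixed (by inspection of the response plot), the model linearizes
through Z = ln(Y/(A - Y)) = -(b_y - c_n*N), so OLS of Z on N estimates
(b_y, c_n) and its Pearson correlation R is the goodness-of-fit surface.
A second component sharing (b_y, c_n) gets its amplitude by one-parameter
least squares; component models sharing parameters sum to a logistic with
amplitude sum(A_y).

Derived scales: N_half = b_y/c_n is the applied N achieving half-maximal
yield (negative when residual soil N alone exceeds that point), and
dN = 1/c_n is the characteristic N width of the response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .linfit import RegressionResult, linear_fit

__all__ = [
    "LogisticFit",
    "logistic_transform",
    "fit_logistic_fixed_A",
    "fit_amplitude_shared",
    "logistic_predict",
    "total_response",
    "derived_quantities",
    "profile_amplitude",
]


@dataclass(frozen=True)
class LogisticFit:
    """One component's logistic N-response parameters."""

    A_y: float
    b_y: float
    c_n: float
    R: float | None = None
    component: str = "total"

    def __post_init__(self) -> None:
        if not (self.A_y > 0):
            raise ValueError(f"amplitude A_y must be positive, got {self.A_y}")
        for name in ("b_y", "c_n"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite {name}")

    @property
    def N_half(self) -> float:
        """Applied N at half-maximal yield, kg ha^-1."""
        return derived_quantities(self.b_y, self.c_n)[0]

    @property
    def dN(self) -> float:
        """Characteristic N of the response, kg ha^-1."""
        return derived_quantities(self.b_y, self.c_n)[1]


def logistic_transform(Y: float, A: float) -> float:
    """Linearizing transform Z = ln(Y/(A - Y)) for fixed amplitude A.

    Defined only for 0 < Y < A; under the model Z = -(b_y - c_n*N), so Z is
    zero at the midpoint Y = A/2 and increases with N when c_n > 0.
    """
    y, a = float(Y), float(A)
    if not (0.0 < y < a):
        raise ValueError(
            f"Y={y} outside logistic range (0, A={a})"
        )
    return math.log(y / (a - y))


def _phi(N, b_y: float, c_n: float):
    return 1.0 / (1.0 + np.exp(b_y - c_n * np.asarray(N, dtype=float)))


def fit_logistic_fixed_A(
    data: Iterable[Sequence[float]], A: float, component: str = "total"
) -> LogisticFit:
    """Estimate (b_y, c_n) by OLS of Z on N with the amplitude fixed.

    The regression slope is c_n and the intercept is -b_y; R is the Pearson
    correlation of (N, Z).  Exact on noiseless logistic data.  Raises if any
    yield lies outside (0, A).
    """
    rows = [(float(n), float(y)) for n, y in data]
    bad = [(n, y) for n, y in rows if not (0.0 < y < A)]
    if bad:
        raise ValueError(
            f"yields outside logistic range (0, {A}): {bad}"
        )
    pairs = [(n, logistic_transform(y, A)) for n, y in rows]
    res = linear_fit(pairs)
    return LogisticFit(
        A_y=float(A),
        b_y=-res.intercept,
        c_n=res.slope,
        R=res.r,
        component=component,
    )


def fit_amplitude_shared(
    data: Iterable[Sequence[float]],
    b_y: float,
    c_n: float,
    component: str = "leaf",
) -> LogisticFit:
    """Least-squares amplitude for a component sharing (b_y, c_n).

    With phi_i = 1/(1 + exp(b_y - c_n*N_i)) fixed, the one-parameter LS
    solution is A_y = sum(Y_i*phi_i)/sum(phi_i^2).
    """
    if c_n == 0:
        raise ValueError("c_n must be nonzero")
    rows = np.asarray([(float(n), float(y)) for n, y in data], dtype=float)
    if rows.size == 0:
        raise ValueError("need at least one (N, Y) point")
    phi = _phi(rows[:, 0], b_y, c_n)
    denom = float(np.dot(phi, phi))
    if denom == 0:
        raise ValueError("all logistic weights are zero; amplitude undetermined")
    a_y = float(np.dot(rows[:, 1], phi)) / denom
    return LogisticFit(A_y=a_y, b_y=b_y, c_n=c_n, R=None, component=component)


def logistic_predict(N: float, fit: LogisticFit) -> float:
    """Predicted yield Y = A_y/(1 + exp(b_y - c_n*N)), Mg ha^-1."""
    n = float(N)
    if math.isinf(n) and n > 0 and fit.c_n > 0:
        return fit.A_y
    return fit.A_y / (1.0 + math.exp(fit.b_y - fit.c_n * n))


def total_response(N: float, fits: Sequence[LogisticFit]) -> float:
    """Summed prediction of components sharing (b_y, c_n).

    Equals (sum A_y) * phi(N).  Raises if the shared-parameter structure is
    violated.  An empty component list predicts zero.
    """
    fits = list(fits)
    if not fits:
        return 0.0
    b0, c0 = fits[0].b_y, fits[0].c_n
    for f in fits[1:]:
        if not (
            math.isclose(f.b_y, b0, rel_tol=0, abs_tol=1e-12)
            and math.isclose(f.c_n, c0, rel_tol=0, abs_tol=1e-12)
        ):
            raise ValueError(
                "components do not share (b_y, c_n): "
                f"({f.b_y}, {f.c_n}) vs ({b0}, {c0})"
            )
    return sum(logistic_predict(N, f) for f in fits)


def derived_quantities(b_y: float, c_n: float) -> tuple[float, float]:
    """(N_half, dN) = (b_y/c_n, 1/c_n), both kg ha^-1.

    N_half is the applied N at 50% of maximum yield; a negative value means
    residual soil N already exceeds it.  dN is the response-width scale.
    """
    if c_n == 0:
        raise ValueError("c_n must be nonzero")
    return b_y / c_n, 1.0 / c_n


def profile_amplitude(
    data: Iterable[Sequence[float]],
    A_grid: Sequence[float],
    component: str = "total",
) -> LogisticFit:
    """Optional profile search over the fixed amplitude.

    Fits (b_y, c_n) at each candidate A (skipping candidates that leave any
    yield outside (0, A)) and returns the fit with maximal linearized |R|.
    The default workflow fixes A by inspection; this search is a convenience
    only.
    """
    rows = [(float(n), float(y)) for n, y in data]
    best: LogisticFit | None = None
    for a in A_grid:
        try:
            fit = fit_logistic_fixed_A(rows, float(a), component=component)
        except ValueError:
            continue
        if best is None or abs(fit.R) > abs(best.R):
            best = fit
    if best is None:
        raise ValueError("no amplitude candidate admits all yields in (0, A)")
    return best
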