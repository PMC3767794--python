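"""Hyperbolic phase relation between nutrient uptake and biomass.

With calendar time eliminated, seasonal plant nutrient uptake N_u (kg ha^-1)
tracks biomass Y (Mg ha^-1) along the rectangular hyperbola

    N_u(Y) = N_um * Y / (K_y + Y)

where N_um is the potential maximum uptake at high yield and K_y is the
biomass at which uptake is half-maximal.  The relation rearranges to the
straight line Y/N_u = K_y/N_um + Y/N_um, so the parameters are estimated by
ordinary least squares of the uptake ratio Y/N_u on Y — exactly the
linearized procedure used in the source field analyses.  An optional
nonlinear refinement (direct least squares on (Y, N_u)) is available but off
by default.

Plant nutrient concentration follows as N_c(Y) = N_u/Y = N_um/(K_y + Y),
in g kg^-1, strictly decreasing in Y (the nutrient-dilution curve).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .linfit import RegressionResult, linear_fit

__all__ = [
    "PhaseFit",
    "phase_transform",
    "fit_phase",
    "uptake_predict",
    "concentration_predict",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhaseFit:
    """Fitted hyperbola: N_um (kg ha^-1), K_y (Mg ha^-1), plus diagnostics
    of the linearized regression that produced them."""

    N_um: float
    K_y: float
    element: str = "N"
    diagnostics: RegressionResult | None = None

    def __post_init__(self) -> None:
        if not (self.N_um > 0):
            raise ValueError(f"N_um must be positive, got {self.N_um}")
        if not (self.K_y > 0):
            raise ValueError(f"K_y must be positive, got {self.K_y}")


def phase_transform(
    trajectory: Iterable[Sequence[float]],
) -> list[tuple[float, float]]:
    """Map (Y, N_u) observations to (Y, Y/N_u) pairs for the linearized fit.

    Zero-yield rows have an undefined ratio in the regression's response
    role only at Y/N_u = 0; they carry no information about the line and are
    skipped with a log message.  Non-positive uptake is a data error.
    """
    out: list[tuple[float, float]] = []
    for row in trajectory:
        y, nu = float(row[0]), float(row[1])
        if nu <= 0:
            raise ValueError(f"nutrient uptake must be positive, got {nu}")
        if y < 0:
            raise ValueError(f"biomass must be non-negative, got {y}")
        if y == 0:
            logger.info("phase_transform: skipping zero-yield row (Y=0, N_u=%g)", nu)
            continue
        out.append((y, y / nu))
    return out


def fit_phase(
    pairs: Iterable[Sequence[float]],
    element: str = "N",
    nonlinear_refine: bool = False,
) -> PhaseFit:
    """Fit the hyperbola from (Y, N_u) observations via the linearization.

    OLS of Y/N_u on Y gives slope = 1/N_um and intercept = K_y/N_um, hence
    N_um = 1/slope and K_y = intercept/slope.  The linearization is exact on
    noiseless hyperbolic data, so a generate -> fit round trip recovers the
    parameters to machine precision.

    With ``nonlinear_refine=True`` the linearized estimate seeds a direct
    nonlinear least squares on (Y, N_u); the default keeps the linearized
    procedure for fidelity to the published analyses.
    """
    pairs = [(float(a), float(b)) for a, b in pairs]
    transformed = phase_transform(pairs)
    if len({y for y, _ in transformed}) < 2:
        raise ValueError("degenerate design: need >= 2 distinct positive Y values")
    diag = linear_fit(transformed)
    if diag.slope <= 0:
        raise ValueError(
            f"no saturation detectable: linearized slope {diag.slope:.4g} <= 0"
        )
    n_um = 1.0 / diag.slope
    k_y = diag.intercept / diag.slope
    if nonlinear_refine:
        ys = np.array([y for y, _ in pairs if y > 0])
        nus = np.array([nu for y, nu in pairs if y > 0])
        popt, _ = curve_fit(
            lambda y, num, ky: num * y / (ky + y), ys, nus, p0=[n_um, max(k_y, 1e-6)]
        )
        n_um, k_y = float(popt[0]), float(popt[1])
    return PhaseFit(N_um=n_um, K_y=k_y, element=element, diagnostics=diag)


def uptake_predict(Y: float, fit: PhaseFit) -> float:
    """Predicted uptake N_u = N_um*Y/(K_y + Y), kg ha^-1.

    Monotone increasing and concave in Y; equals N_um/2 at Y = K_y and
    saturates at N_um.
    """
    y = float(Y)
    if y < 0:
        raise ValueError(f"biomass must be non-negative, got {y}")
    if math.isinf(y):
        return fit.N_um
    return fit.N_um * y / (fit.K_y + y)


def concentration_predict(Y: float, fit: PhaseFit) -> float:
    """Predicted concentration N_c = N_um/(K_y + Y), g kg^-1.

    Strictly decreasing in Y, with N_c(0) = N_um/K_y; satisfies
    ``N_c(Y) * Y == uptake_predict(Y)`` identically.
    """
    y = float(Y)
    if y < 0:
        raise ValueError(f"biomass must be non-negative, got {y}")
    if math.isinf(y):
        return 0.0
    return fit.N_um / (fit.K_y + y)
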