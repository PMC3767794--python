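"""Error-function growth quantifiers for seasonal crop biomass.

The expanded growth model describes seasonal dry-matter accumulation as
``Y(t) = A * Q(x(t))`` where ``A`` is a site/treatment-specific yield factor
(Mg ha^-1) and ``Q`` is a dimensionless *growth quantifier* built from the
error function of a dimensionless time ``x``.  The quantifier splits into a
light-gathering (leaf) part and a structural (stem + fruit) part weighted by
the partition coefficient ``k``:

    Q_L(x) = (1 - k*x_i) * (erf x - erf x_i)
    Q_S(x) = (k/sqrt(pi)) * (exp(-x_i^2) - exp(-x^2))
    Q(x)   = Q_L(x) + Q_S(x)

``x`` is an affine rescaling of calendar time (weeks from Jan 1) combining
the time of the solar-energy peak, its spread, and an aging rate; for the
cotton studies shipped with this package it calibrates to
``x = (t - 21.2)/8.0``.  ``x_i = x(t_i)`` marks the initiation of significant
growth; all calibrations verified here use ``x_i = 0``, for which
``Q_L = erf x`` and ``Q_S = (k/sqrt(pi)) (1 - exp(-x^2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "GrowthParams",
    "QuantifierPoint",
    "YieldFactor",
    "dimensionless_time",
    "erf_value",
    "quantifier",
    "leaf_fraction_model",
    "biomass_predict",
]

_SQRT_PI = math.sqrt(math.pi)


@dataclass(frozen=True)
class GrowthParams:
    """Calibration of the dimensionless-time map and the partition weight.

    Parameters
    ----------
    t_ref : float
        Calendar time (wk) at which ``x = 0``.
    tau : float
        Time spread of the solar-energy distribution (wk); equals
        ``sqrt(2)*sigma`` of the underlying Gaussian.
    k : float
        Partition coefficient weighting the structural component against the
        light-gathering component (dimensionless, >= 0).
    t_i : float
        Time of initiation of significant growth (wk).
    x_i : float
        Dimensionless state at initiation; must equal
        ``dimensionless_time(t_i)``.
    c : float, optional
        Aging coefficient (wk^-1).  Informational: it enters only through the
        shift of ``t_ref`` and is not needed for any calibrated computation.
    mu : float, optional
        Time of the solar-energy peak (wk).  Informational, see ``c``.

    The default calibration, shared by the California and Alabama cotton
    studies, is ``t_ref = 21.2``, ``tau = 8.0``, ``k = 9.0``, ``t_i = 21.2``,
    ``x_i = 0``.
    """

    t_ref: float = 21.2
    tau: float = 8.0
    k: float = 9.0
    t_i: float = 21.2
    x_i: float = 0.0
    c: float | None = field(default=None, compare=False)
    mu: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError(f"time spread tau must be positive, got {self.tau}")
        if self.k < 0:
            raise ValueError(f"partition coefficient k must be >= 0, got {self.k}")
        # x_i must be the image of t_i under the affine map.
        expected_xi = (self.t_i - self.t_ref) / self.tau
        if not math.isclose(self.x_i, expected_xi, abs_tol=1e-9):
            raise ValueError(
                f"x_i={self.x_i} inconsistent with t_i={self.t_i}: "
                f"dimensionless_time(t_i) = {expected_xi}"
            )

    @classmethod
    def from_physical(
        cls,
        mu: float,
        tau: float,
        c: float,
        k: float = 9.0,
        t_i: float | None = None,
    ) -> "GrowthParams":
        """Construct from the physical parameters (mu, tau, c).

        The energy-peak time ``mu``, spread ``tau`` and aging rate ``c``
        combine into the reference time of the affine map,
        ``t_ref = mu - tau**2 * c / 2``; the map itself is unchanged.
        """
        t_ref = mu - tau * tau * c / 2.0
        if t_i is None:
            t_i = t_ref
        return cls(
            t_ref=t_ref,
            tau=tau,
            k=k,
            t_i=t_i,
            x_i=(t_i - t_ref) / tau,
            c=c,
            mu=mu,
        )


@dataclass(frozen=True)
class QuantifierPoint:
    """Growth-quantifier evaluation at one calendar time.

    ``q_total == q_leaf + q_struct`` holds exactly by construction.
    """

    t: float
    x: float
    erf_x: float
    gauss_x: float
    q_leaf: float
    q_struct: float
    q_total: float


@dataclass(frozen=True)
class YieldFactor:
    """Proportionality constant converting the quantifier into biomass.

    ``A`` has units Mg ha^-1 per unit Q; fitted values on real data are
    positive and absorb site, soil, fertilizer and population effects.
    """

    A: float
    component_label: str = "total"

    def __post_init__(self) -> None:
        if not math.isfinite(self.A):
            raise ValueError("yield factor A must be finite")
        if self.component_label not in ("leaf", "structure", "total"):
            raise ValueError(f"unknown component label {self.component_label!r}")


def dimensionless_time(t: float, params: GrowthParams) -> float:
    """Map calendar time (wk from Jan 1) to dimensionless time x.

    ``x = (t - t_ref)/tau``.  ``t = +inf`` is accepted as a symbolic
    end-of-season sentinel and maps to ``+inf``.
    """
    t = float(t)
    if math.isnan(t):
        raise ValueError("calendar time t must not be NaN")
    return (t - params.t_ref) / params.tau


def erf_value(x: float) -> float:
    """Standard error function erf(x), odd, with erf(+inf) = 1."""
    return float(_erf(x))


def quantifier(x: float, k: float = 9.0, x_i: float = 0.0) -> QuantifierPoint:
    """Evaluate leaf, structural and total growth quantifiers at x.

    Requires ``x >= x_i`` (no growth before initiation).  ``x = +inf``
    yields the seasonal limits ``Q_L = (1 - k*x_i)(1 - erf x_i)`` and
    ``Q_S = (k/sqrt(pi)) exp(-x_i^2)``.

    Calibrations with ``x_i != 0`` are extrapolated beyond what the cotton
    studies verify; the ``x_i = 0`` reduction ``Q_L = erf x``,
    ``Q_S = (k/sqrt(pi))(1 - exp(-x^2))`` is the validated form.
    """
    x = float(x)
    if math.isnan(x):
        raise ValueError("dimensionless time x must not be NaN")
    if x < x_i:
        raise ValueError(
            f"x={x} is before growth initiation x_i={x_i}"
        )
    erf_x = erf_value(x)
    gauss_x = 0.0 if math.isinf(x) else math.exp(-x * x)
    q_leaf = (1.0 - k * x_i) * (erf_x - erf_value(x_i))
    q_struct = (k / _SQRT_PI) * (math.exp(-x_i * x_i) - gauss_x)
    return QuantifierPoint(
        t=math.nan,
        x=x,
        erf_x=erf_x,
        gauss_x=gauss_x,
        q_leaf=q_leaf,
        q_struct=q_struct,
        q_total=q_leaf + q_struct,
    )


def quantifier_at_time(t: float, params: GrowthParams) -> QuantifierPoint:
    """Quantifier point at calendar time t under a full calibration."""
    x = math.inf if math.isinf(t) and t > 0 else dimensionless_time(t, params)
    point = quantifier(x, k=params.k, x_i=params.x_i)
    return QuantifierPoint(
        t=t,
        x=point.x,
        erf_x=point.erf_x,
        gauss_x=point.gauss_x,
        q_leaf=point.q_leaf,
        q_struct=point.q_struct,
        q_total=point.q_total,
    )


def leaf_fraction_model(x: float, k: float = 9.0, x_i: float = 0.0) -> float:
    """Model leaf fraction f_L = Q_L/(Q_L + Q_S).

    Strictly decreasing in x for k > 0.  At ``x = x_i`` both quantifiers
    vanish; the right limit of the ratio is 1 for ``x_i = 0`` (the leaf term
    is linear in x while the structural term is quadratic) and that limit is
    returned rather than raising.
    """
    if x == x_i:
        return 1.0
    point = quantifier(x, k=k, x_i=x_i)
    return point.q_leaf / (point.q_leaf + point.q_struct)


def biomass_predict(t: float, A: YieldFactor | float, params: GrowthParams) -> float:
    """Predict biomass Y = A * Q_total(t), Mg ha^-1.

    Monotone non-decreasing in t for t >= t_i (for A >= 0).
    """
    a = A.A if isinstance(A, YieldFactor) else float(A)
    if not math.isinf(t) and t < params.t_i:
        raise ValueError(f"t={t} is before growth initiation t_i={params.t_i}")
    return a * quantifier_at_time(t, params).q_total


def quantifier_table(times: "np.ndarray | list[float]", params: GrowthParams):
    """Quantifier points for a sequence of calendar times (helper for fits)."""
    return [quantifier_at_time(float(t), params) for t in times]
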