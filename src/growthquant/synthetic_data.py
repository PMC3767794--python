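"""Synthetic site-seasons with the statistical structure the analysis assumes.

Generates biomass trajectories Y(t) = A*Q(t), nutrient uptakes along the
hyperbolic phase relation, and N-response tables along the logistic, with a
configurable error model, so every fitting stage can be validated by
parameter recovery with no external data.

Defaults reproduce the study conditions shipped as fixtures: the shared
growth calibration (t_ref = 21.2 wk, tau = 8.0 wk, k = 9), component yield
factors from the California component fits (A_leaf = 1.81, A_struct = 1.84
Mg/ha), N/P/K phase parameters from the Alabama fits, the logistic response
parameters of the California N trial (A = [10.2, 2.3] Mg/ha, b_y = -0.44,
c_n = 0.0085 ha/kg), the seven Alabama sampling dates, and the five applied-N
levels 0..224 kg/ha.  Default noise is additive Gaussian with
sigma = 0.2 Mg/ha on biomass, truncated at zero; nutrient columns receive
additive noise of 20*sigma kg/ha (a nominal 20 g/kg plant-nutrient
concentration keeps the relative noise comparable across variables).  A
multiplicative lognormal model (given CV, unit mean) is available instead.

Reproducibility: one master seed; each replicate draws from an independent
stream spawned by counter offset, so identical configs give identical output
regardless of how replicates are scheduled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .growth_core import GrowthParams, quantifier_at_time
from .linfit import linear_fit_origin
from .nitrogen_response import fit_logistic_fixed_A, logistic_predict, LogisticFit
from .nutrient_phase import PhaseFit, fit_phase, uptake_predict
from .study_data import ResponseTable, Trajectory

__all__ = ["NoiseModel", "SimConfig", "gen_trajectory", "gen_response",
           "recovery_experiment"]

_ALABAMA_TIMES = (21.6, 23.7, 25.9, 28.0, 30.3, 32.4, 34.7)
_N_LEVELS = (0.0, 56.0, 112.0, 168.0, 224.0)
# (N_um kg/ha, K_y Mg/ha) from the Alabama linearized phase fits
_PHASE_DEFAULTS = {
    "N": (227.9, 4.61),
    "P": (31.7, 8.62),
    "K": (247.0, 9.52),
}


@dataclass(frozen=True)
class NoiseModel:
    """Error model: 'none', 'additive_gaussian' (sigma, Mg/ha on biomass;
    uptake sd = 20*sigma kg/ha unless sigma_uptake is given), or
    'multiplicative_lognormal' (cv, unit-mean, scale-free)."""

    kind: str = "additive_gaussian"
    sigma: float = 0.2
    cv: float = 0.1
    sigma_uptake: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive_gaussian", "multiplicative_lognormal"):
            raise ValueError(f"unknown noise model {self.kind!r}")
        if self.sigma < 0 or self.cv < 0:
            raise ValueError("noise scale must be >= 0")

    def apply(self, clean: np.ndarray, rng: np.random.Generator,
              uptake: bool = False) -> np.ndarray:
        clean = np.asarray(clean, dtype=float)
        if self.kind == "none":
            return clean.copy()
        if self.kind == "additive_gaussian":
            sd = (self.sigma_uptake if (uptake and self.sigma_uptake is not None)
                  else (20.0 * self.sigma if uptake else self.sigma))
            return np.maximum(0.0, clean + rng.normal(0.0, sd, clean.shape))
        # lognormal with unit mean and the requested coefficient of variation
        if self.cv == 0:
            return clean.copy()
        s2 = math.log(1.0 + self.cv**2)
        factor = rng.lognormal(-s2 / 2.0, math.sqrt(s2), clean.shape)
        return clean * factor


@dataclass(frozen=True)
class SimConfig:
    growth: GrowthParams = field(default_factory=GrowthParams)
    A_leaf: float = 1.81
    A_struct: float = 1.84
    phase: dict = field(default_factory=lambda: dict(_PHASE_DEFAULTS))
    logistic_A: tuple = (10.2, 2.3)
    b_y: float = -0.44
    c_n: float = 0.0085
    noise: NoiseModel = field(default_factory=NoiseModel)
    sample_times: tuple = _ALABAMA_TIMES
    n_levels: tuple = _N_LEVELS
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.growth.t_i, self.growth.t_i + 20.0
        for t in self.sample_times:
            if not (lo <= t <= hi):
                raise ValueError(
                    f"sample time {t} outside [{lo}, {hi}] (one growing season)"
                )
        for el, (num, ky) in self.phase.items():
            if num <= 0 or ky <= 0:
                raise ValueError(f"phase parameters for {el} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["growth"] = {k: v for k, v in asdict(self.growth).items()
                       if v is not None}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "growth" in d:
            d["growth"] = GrowthParams(**d["growth"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        for key in ("logistic_A", "sample_times", "n_levels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _rng_for(config: SimConfig, offset: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed) % (2**31),
                               spawn_key=(offset,))
    )


def gen_trajectory(config: SimConfig, rng: np.random.Generator | None = None
                   ) -> Trajectory:
    """Simulate one site-season trajectory.

    Component biomass follows Y_leaf = A_leaf*Q_L and Y_struct = A_struct*Q_S
    plus noise (truncated at zero); uptake columns follow the configured
    phase hyperbolas evaluated on the noiseless total biomass, plus noise.
    """
    if rng is None:
        rng = _rng_for(config, 0)
    points = [quantifier_at_time(t, config.growth) for t in config.sample_times]
    q_leaf = np.array([p.q_leaf for p in points])
    q_struct = np.array([p.q_struct for p in points])
    leaf_clean = config.A_leaf * q_leaf
    struct_clean = config.A_struct * q_struct
    total_clean = leaf_clean + struct_clean
    cols = {
        "t": np.asarray(config.sample_times, dtype=float),
        "Y_leaf": config.noise.apply(leaf_clean, rng),
        "Y_struct": config.noise.apply(struct_clean, rng),
    }
    cols["Y_total"] = cols["Y_leaf"] + cols["Y_struct"]
    for el, (num, ky) in config.phase.items():
        fit = PhaseFit(N_um=num, K_y=ky, element=el)
        clean = np.array([uptake_predict(y, fit) for y in total_clean])
        cols[f"{el}u"] = config.noise.apply(clean, rng, uptake=True)
    return Trajectory(site="synthetic", data=pd.DataFrame(cols))


def gen_response(config: SimConfig, rng: np.random.Generator | None = None
                 ) -> ResponseTable:
    """Simulate an N-response table: one column per configured amplitude,
    all components sharing (b_y, c_n)."""
    if config.c_n <= 0:
        raise ValueError("c_n must be positive for an N response")
    if rng is None:
        rng = _rng_for(config, 1)
    n = np.asarray(config.n_levels, dtype=float)
    cols = {"N": n}
    for i, a in enumerate(config.logistic_A):
        fit = LogisticFit(A_y=a, b_y=config.b_y, c_n=config.c_n)
        clean = np.array([logistic_predict(v, fit) for v in n])
        cols[f"Y_comp{i}"] = config.noise.apply(clean, rng)
    return ResponseTable(data=pd.DataFrame(cols))


def _fit_one_rep(config: SimConfig, rep: int) -> dict:
    """Refit every stage on one simulated replicate.

    Stages fail independently: a stage whose fit raises contributes no
    estimates for its parameters but the other stages still report.  Rows
    with nonpositive observed uptake (possible under truncated additive
    noise at very small biomass) are unusable for the ratio transform and
    are dropped before the phase fit, as an analyst would drop them.
    """
    rng = _rng_for(config, 1000 + rep)
    est: dict[str, float] = {}
    traj = gen_trajectory(config, rng).data
    points = [quantifier_at_time(t, config.growth) for t in config.sample_times]
    q_leaf = np.array([p.q_leaf for p in points])
    q_struct = np.array([p.q_struct for p in points])
    try:
        est["A_leaf"] = linear_fit_origin(zip(q_leaf, traj["Y_leaf"])).slope
        est["A_struct"] = linear_fit_origin(
            zip(q_struct, traj["Y_struct"])).slope
    except ValueError:
        pass
    element = next(iter(config.phase))
    try:
        usable = traj[traj[f"{element}u"] > 0]
        pfit = fit_phase(zip(usable["Y_total"], usable[f"{element}u"]),
                         element=element)
        est["N_um"], est["K_y"] = pfit.N_um, pfit.K_y
    except ValueError:
        pass
    resp = gen_response(config, rng).data
    try:
        lfit = fit_logistic_fixed_A(zip(resp["N"], resp["Y_comp0"]),
                                    config.logistic_A[0])
        est["b_y"], est["c_n"] = lfit.b_y, lfit.c_n
    except ValueError:
        pass
    return est


def recovery_experiment(config: SimConfig, n_reps: int) -> pd.DataFrame:
    """Generate -> fit loop measuring estimator quality per parameter.

    Each replicate draws its own stream (master seed + counter), simulates a
    trajectory and a response table, refits (A_leaf, A_struct) by
    through-origin regression on the component quantifiers, the first
    element's (N_um, K_y) by the linearized phase fit, and (b_y, c_n) by the
    linearized logistic fit with the true amplitude fixed.  Returns one row
    per parameter with truth, bias, RMSE, median relative error, and the
    number of successful/failed replicates (a replicate whose fit raises is
    counted, never silently dropped).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    element = next(iter(config.phase))
    truth = {
        "A_leaf": config.A_leaf,
        "A_struct": config.A_struct,
        "N_um": config.phase[element][0],
        "K_y": config.phase[element][1],
        "b_y": config.b_y,
        "c_n": config.c_n,
    }
    estimates: dict[str, list[float]] = {k: [] for k in truth}
    for rep in range(n_reps):
        est = _fit_one_rep(config, rep)
        for k, v in est.items():
            estimates[k].append(v)
    rows = []
    for k, true_val in truth.items():
        vals = np.asarray(estimates[k], dtype=float)
        err = vals - true_val
        rel = np.abs(err) / abs(true_val) if true_val != 0 else np.abs(err)
        rows.append({
            "parameter": k,
            "truth": true_val,
            "bias": float(err.mean()) if vals.size else math.nan,
            "rmse": float(np.sqrt((err**2).mean())) if vals.size else math.nan,
            "median_rel_err": float(np.median(rel)) if vals.size else math.nan,
            "n_ok": int(vals.size),
            "n_failed": int(n_reps - vals.size),
        })
    return pd.DataFrame(rows)
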