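"""Packaged study fixtures: cotton biomass/nutrient tables with loaders.

Two site-seasons ship with the package — a San Joaquin Valley, CA trajectory
(component biomass at N = 168 kg/ha, 2000) and a northern Alabama trajectory
(total biomass plus N/P/K uptake, 1987) — together with the California
end-of-season N-response table.  Column semantics, units and provenance live
in ``data/fixtures_metadata.yaml`` next to the CSVs.  Missing cells load as
NaN, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Trajectory",
    "ResponseTable",
    "load_fixture",
    "fixture_metadata",
    "leaf_fraction_observed",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = (
    "california_trajectory",
    "alabama_trajectory",
    "california_response",
)


@dataclass
class Trajectory:
    """Sampled time series for one site-season.

    ``data`` holds one row per sampling time with column ``t`` (wk from
    Jan 1) and whichever of Y_leaf, Y_stem, Y_fruit, Y_total (Mg/ha) and
    Nu, Pu, Ku (kg/ha) the study measured; absent cells are NaN.
    Times are strictly increasing.
    """

    site: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.data["t"].to_numpy()
        if not (pd.Series(t).diff().dropna() > 0).all():
            raise ValueError("sampling times must be strictly increasing")
        numeric = self.data.select_dtypes("number")
        if (numeric.fillna(0) < 0).any().any():
            raise ValueError("negative value in trajectory data")

    @property
    def measured(self) -> pd.DataFrame:
        """Rows carrying at least one measurement (drops anchor rows)."""
        value_cols = [c for c in self.data.columns if c != "t"]
        return self.data.dropna(subset=value_cols, how="all")


@dataclass
class ResponseTable:
    """End-of-season component biomass versus applied nitrogen."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "N" not in self.data.columns:
            raise ValueError("response table needs an applied-N column 'N'")


def _read_csv(name: str) -> pd.DataFrame:
    ref = resources.files("growthquant.data").joinpath(f"{name}.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def fixture_metadata() -> dict:
    """Units, provenance and column-mapping notes for the fixtures."""
    ref = resources.files("growthquant.data").joinpath("fixtures_metadata.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_fixture(name: str) -> Trajectory | ResponseTable:
    """Load a packaged fixture by name.

    Names: ``california_trajectory`` (4 measured dates + initiation anchor),
    ``alabama_trajectory`` (7 measured dates + initiation anchor),
    ``california_response`` (5 N levels).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    df = _read_csv(name)
    if name == "california_response":
        return ResponseTable(data=df)
    site = "california" if name.startswith("california") else "alabama"
    return Trajectory(site=site, data=df)


def leaf_fraction_observed(row: Mapping[str, float] | Sequence[float]) -> float:
    """Observed leaf fraction f_L = Y_leaf/(Y_leaf + Y_stem + Y_fruit).

    Accepts a mapping with Y_leaf/Y_stem/Y_fruit keys (e.g. a trajectory
    row) or a (leaf, stem, fruit) triple.  All three components must be
    present; a missing component raises.
    """
    if isinstance(row, Mapping) or isinstance(row, pd.Series):
        comps = [row.get(k, math.nan) for k in ("Y_leaf", "Y_stem", "Y_fruit")]
    else:
        comps = [float(v) for v in row]
        if len(comps) != 3:
            raise ValueError("expected (leaf, stem, fruit) components")
    leaf, stem, fruit = (float(c) for c in comps)
    if any(math.isnan(c) for c in (leaf, stem, fruit)):
        raise ValueError("missing biomass component; cannot form leaf fraction")
    total = leaf + stem + fruit
    if total <= 0:
        raise ValueError("total biomass must be positive")
    return leaf / total
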