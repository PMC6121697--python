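"""Scenario configuration: source, wind, coefficient ranges, units, I/O.

A :class:`Scenario` bundles everything the forward models need apart from
the coefficient state itself.  Concentrations are computed internally in
kg/m^3; sensor data are compared in the unit named by
``observation_unit`` — either ``"kg_m3"`` or ``"ppt"`` (parts per trillion
by volume, i.e. 1e-12 mole fraction).  The kg/m^3 -> ppt conversion uses
the tracer molar mass (SF6: 0.14606 kg/mol) and a configurable molar
volume of air (default 0.02445 m^3/mol, ~25 C at 1 atm).

Scenario files are YAML with the layout::

    source:        {x, y, height, rate_series: [[t, rate_kg_s], ...]}
    wind:          {samples: [[t, speed_m_s, bearing_from_deg], ...]}
    coefficients:  {ranges: {a1: [lo, hi], ...}, initial: {a1: ..., ...}}
    puff:          {dt_release}
    decay:         {lambda}
    units:         {observation: ppt|kg_m3, molar_mass, molar_volume}
    metadata:      {...}

Observation tables are CSV with header
``time_s,sensor_id,x_m,y_m,z_m,concentration``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .dispersion import (
    COEF_NAMES,
    DEFAULT_COEF_RANGES,
    DispersionState,
    SourceTerm,
    WindSeries,
)

__all__ = ["Scenario", "read_observations", "write_observations", "OBS_COLUMNS"]

OBS_COLUMNS = ["time_s", "sensor_id", "x_m", "y_m", "z_m", "concentration"]

#: SF6 molar mass, kg/mol.
SF6_MOLAR_MASS = 0.14606
#: Molar volume of air at ~25 C, 1 atm, m^3/mol.
AIR_MOLAR_VOLUME = 0.02445


@dataclass
class Scenario:
    source: SourceTerm
    wind: WindSeries
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COEF_RANGES))
    initial: DispersionState | None = None
    dt_release: float = 60.0
    lam: float = 0.0
    observation_unit: str = "ppt"
    molar_mass: float = SF6_MOLAR_MASS
    molar_volume: float = AIR_MOLAR_VOLUME
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observation_unit not in ("ppt", "kg_m3"):
            raise ValueError("observation_unit must be 'ppt' or 'kg_m3'")
        if self.dt_release <= 0:
            raise ValueError("dt_release must be > 0")

    @property
    def concentration_scale(self) -> float:
        """Multiplier taking kg/m^3 to the observation unit."""
        if self.observation_unit == "kg_m3":
            return 1.0
        return self.molar_volume / self.molar_mass * 1e12

    def static_state(self) -> DispersionState:
        """The fixed-coefficient state used by the non-assimilated variants."""
        if self.initial is not None:
            return self.initial
        return DispersionState.midrange(self.ranges)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "source": {
                "x": self.source.x,
                "y": self.source.y,
                "height": self.source.height,
                "rate_series": [list(p) for p in self.source.rate_series],
            },
            "wind": {"samples": [list(s) for s in self.wind.samples]},
            "coefficients": {"ranges": {n: list(self.ranges[n]) for n in COEF_NAMES}},
            "puff": {"dt_release": self.dt_release},
            "decay": {"lambda": self.lam},
            "units": {
                "observation": self.observation_unit,
                "molar_mass": self.molar_mass,
                "molar_volume": self.molar_volume,
            },
        }
        if self.initial is not None:
            d["coefficients"]["initial"] = {
                n: getattr(self.initial, n) for n in COEF_NAMES}
        if self.metadata:
            d["metadata"] = dict(self.metadata)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        src = d["source"]
        source = SourceTerm(
            x=float(src.get("x", 0.0)), y=float(src.get("y", 0.0)),
            height=float(src.get("height", 0.0)),
            rate_series=tuple((float(t), float(q)) for t, q in src["rate_series"]))
        wind = WindSeries(samples=tuple(
            (float(t), float(v), float(b)) for t, v, b in d["wind"]["samples"]))
        coeff = d.get("coefficients", {})
        ranges = {n: tuple(map(float, coeff.get("ranges", {}).get(n, DEFAULT_COEF_RANGES[n])))
                  for n in COEF_NAMES}
        initial = None
        if "initial" in coeff:
            initial = DispersionState.from_array(
                [float(coeff["initial"][n]) for n in COEF_NAMES], ranges=ranges)
        units = d.get("units", {})
        return cls(
            source=source, wind=wind, ranges=ranges, initial=initial,
            dt_release=float(d.get("puff", {}).get("dt_release", 60.0)),
            lam=float(d.get("decay", {}).get("lambda", 0.0)),
            observation_unit=units.get("observation", "ppt"),
            molar_mass=float(units.get("molar_mass", SF6_MOLAR_MASS)),
            molar_volume=float(units.get("molar_volume", AIR_MOLAR_VOLUME)),
            metadata=dict(d.get("metadata", {})))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a sensor observation table, validating the required columns."""
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    if (df["concentration"] < 0).any():
        raise ValueError("observed concentrations must be >= 0")
    return df


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=OBS_COLUMNS)
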