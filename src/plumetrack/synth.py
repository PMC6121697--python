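"""Synthetic urban-tracer scenarios emulating the Indianapolis SF6 study.

The real field study released SF6 at a constant 4.65 g/s from an 83.8 m
stack and sampled hourly ground-level concentrations at ~160 monitoring
stations arranged in arcs 0.25-12 km from the source, under a stable wind
of ~1.85 m/s blowing from ~210 deg.  That dataset is not redistributable,
so this module generates scenarios with the same geometry and magnitudes:
an elevated constant-rate point source, arc sensors, hourly wind samples
jittered around the stable mean, true dispersion coefficients that drift
slowly across their legal ranges over the day (standing in for the real
environmental nonstationarity), and additive Gaussian sensor noise at the
assumed 1 ppt instrument error, clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dispersion import (
    COEF_NAMES,
    DEFAULT_COEF_RANGES,
    DispersionState,
    Receptor,
    SourceTerm,
    WindSeries,
    plume_field,
    puff_train_field,
)
from .scenario import OBS_COLUMNS, Scenario

__all__ = [
    "SyntheticScenario",
    "make_arc_sensors",
    "make_default_scenario",
    "simulate_observations",
]

#: Emulated study conditions: stack height (m), release rate (kg/s),
#: mean wind (m/s, deg-from), observation window (s), sensor noise (ppt).
STACK_HEIGHT = 83.8
RELEASE_RATE = 4.65e-3
MEAN_WIND_SPEED = 1.85
MEAN_WIND_BEARING = 210.0
WINDOW_HOURS = 8
NOISE_SD_PPT = 1.0

DEFAULT_RADII = (250.0, 500.0, 1000.0, 2000.0, 3000.0, 5000.0, 8000.0, 12000.0)


@dataclass
class SyntheticScenario:
    """A scenario plus the ground truth used to generate observations."""

    scenario: Scenario
    truth_states: list[tuple[float, DispersionState]]
    sensors: list[Receptor]
    noise_sd: float
    seed: int

    def truth_at(self, t: float) -> DispersionState:
        state = self.truth_states[0][1]
        for ts, st in self.truth_states:
            if ts <= t:
                state = st
            else:
                break
        return state

    @property
    def batch_times(self) -> list[float]:
        return [t for t, _ in self.truth_states]

    def sensor_array(self) -> np.ndarray:
        return np.array([[s.x, s.y, s.z] for s in self.sensors])


def make_arc_sensors(n: int = 160, radii=DEFAULT_RADII,
                     bearing_center: float = 30.0, bearing_span: float = 120.0,
                     source_xy: tuple[float, float] = (0.0, 0.0)) -> list[Receptor]:
    """Ground-level sensors on concentric arcs centred on the source.

    ``n`` sensors are distributed as evenly as possible across the arcs;
    on each arc the bearings are evenly spaced across
    ``bearing_center +/- bearing_span/2``.
    """
    if n <= 0:
        raise ValueError("need at least one sensor")
    radii = tuple(float(r) for r in radii)
    if not radii:
        raise ValueError("need at least one arc radius")
    counts = [n // len(radii)] * len(radii)
    for i in range(n % len(radii)):
        counts[i] += 1
    sensors: list[Receptor] = []
    for ai, (radius, cnt) in enumerate(zip(radii, counts)):
        if cnt == 0:
            continue
        if cnt == 1:
            bearings = np.array([bearing_center])
        else:
            bearings = np.linspace(bearing_center - bearing_span / 2.0,
                                   bearing_center + bearing_span / 2.0, cnt)
        for si, b in enumerate(bearings):
            rad = np.deg2rad(b % 360.0)
            sensors.append(Receptor(
                x=source_xy[0] + radius * np.sin(rad),
                y=source_xy[1] + radius * np.cos(rad),
                z=0.0, id=f"arc{ai}_s{si}"))
    return sensors


def make_default_scenario(seed: int = 0, n_sensors: int = 160,
                          n_batches: int = WINDOW_HOURS,
                          drift: tuple[float, float] = (0.1, 0.9),
                          noise_sd: float = NOISE_SD_PPT,
                          dt_release: float = 60.0) -> SyntheticScenario:
    """Emulated study day: elevated constant release, arc sensors, stable wind.

    ``drift`` gives the start and end positions of the true coefficients as
    fractions of their range widths; the truth drifts linearly between them
    over the observation window (``drift=(f, f)`` for constant truth).
    Hourly wind samples are jittered uniformly by +/-0.2 m/s and +/-10 deg
    around the stable means.  Observation batches fall at the ends of the
    hours: t = 3600, 7200, ..., n_batches*3600 s.
    """
    rng = np.random.default_rng(seed)
    window_end = n_batches * 3600.0
    source = SourceTerm.constant(RELEASE_RATE, height=STACK_HEIGHT, t0=0.0)
    samples = []
    for k in range(n_batches):
        speed = MEAN_WIND_SPEED + rng.uniform(-0.2, 0.2)
        bearing = (MEAN_WIND_BEARING + rng.uniform(-10.0, 10.0)) % 360.0
        samples.append((k * 3600.0, speed, bearing))
    wind = WindSeries(samples=tuple(samples))
    scenario = Scenario(source=source, wind=wind,
                        ranges=dict(DEFAULT_COEF_RANGES),
                        dt_release=dt_release,
                        metadata={"emulates": "urban SF6 tracer study",
                                  "utm_origin_km": {"north": 4401.59, "east": 571.40}})
    truth_states = []
    batch_times = [(k + 1) * 3600.0 for k in range(n_batches)]
    for i, t in enumerate(batch_times):
        frac = drift[0] if n_batches == 1 else (
            drift[0] + (drift[1] - drift[0]) * i / (n_batches - 1))
        vals = [DEFAULT_COEF_RANGES[n][0]
                + frac * (DEFAULT_COEF_RANGES[n][1] - DEFAULT_COEF_RANGES[n][0])
                for n in COEF_NAMES]
        truth_states.append((t, DispersionState.from_array(vals)))
    sensors = make_arc_sensors(n=n_sensors)
    return SyntheticScenario(scenario=scenario, truth_states=truth_states,
                             sensors=sensors, noise_sd=noise_sd, seed=seed)


def simulate_observations(sscen: SyntheticScenario, model: str = "plume",
                          rng: np.random.Generator | int | None = None,
                          noise: str = "absolute",
                          rel_sd: float = 0.01) -> pd.DataFrame:
    """Noisy sensor table from the truth states through the chosen model.

    ``noise="absolute"`` adds iid Gaussian noise with sd ``noise_sd`` (the
    scenario's sensor error, in observation units); ``noise="relative"``
    adds sd ``rel_sd * truth`` per record.  Negative draws are clipped to
    zero (sensors report nonnegative concentrations).  Deterministic for a
    given generator/seed.
    """
    if model not in ("plume", "multipuff"):
        raise ValueError("model must be 'plume' or 'multipuff'")
    if noise not in ("absolute", "relative"):
        raise ValueError("noise must be 'absolute' or 'relative'")
    rng = np.random.default_rng(sscen.seed if rng is None else rng)
    scen = sscen.scenario
    receptors = sscen.sensor_array()
    rows = []
    for t, truth in sscen.truth_states:
        state = truth.as_array()[None, :]
        if model == "plume":
            v, bearing = scen.wind.at(t)
            field_ = plume_field(scen.source, bearing, v, state, receptors,
                                 lam=scen.lam, t=t)[0]
        else:
            field_ = puff_train_field(scen.source, scen.wind, scen.dt_release,
                                      state, receptors, t, lam=scen.lam)[0]
        truth_obs = field_ * scen.concentration_scale
        sd = sscen.noise_sd if noise == "absolute" else rel_sd * truth_obs
        measured = np.clip(truth_obs + rng.normal(0.0, 1.0, truth_obs.size) * sd,
                           0.0, None)
        for s, c in zip(sscen.sensors, measured):
            rows.append((t, s.id, s.x, s.y, s.z, c))
    return pd.DataFrame(rows, columns=OBS_COLUMNS)
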