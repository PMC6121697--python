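"""Sequential importance resampling over the dispersion-coefficient state.

The assimilated state is the coefficient vector X = (a1, b1, a2, b2) of
the power-law dispersion widths.  The state-space model is a bounded
random walk, X_{k+1} = X_k + n_k with n_k zero-mean Gaussian and the
state reflected back into its legal box; the observation operator maps a
state to predicted concentrations at the sensors through the plume or
multi-puff forward model.  Each hourly observation batch drives one
predict -> weight -> (conditional systematic resample) -> estimate cycle.

Weights are computed in the log domain with an independent Gaussian
observation error (a single absolute sd, or a relative sd floored at the
instrument resolution).  With a hundred-plus sensors per batch the joint
likelihood is far sharper than any finite particle cloud, so the default
update anneals it: each batch's log-likelihood is raised to an adaptively
chosen sequence of temperatures (each stage targets an effective sample
size of ``anneal_target * N``), with a systematic resample and a small
roughening move between stages.  Setting ``anneal=False`` recovers the
plain bootstrap update with ESS-triggered resampling at
``resample_threshold * N``.  All randomness flows from a single
:class:`numpy.random.Generator`, so a run is bitwise reproducible given
its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .dispersion import (
    COEF_NAMES,
    DispersionState,
    plume_field,
    puff_train_field,
    ranges_array,
)
from .scenario import OBS_COLUMNS, Scenario

__all__ = [
    "ParticleEnsemble",
    "FilterConfig",
    "AssimilationRun",
    "init_ensemble",
    "predict",
    "observation_operator",
    "weight",
    "effective_sample_size",
    "resample_systematic",
    "estimate",
    "run_assimilation",
]


@dataclass(frozen=True)
class ParticleEnsemble:
    """N coefficient states with normalised importance weights."""

    states: np.ndarray  # (N, 4)
    weights: np.ndarray  # (N,)
    step: int = 0

    @property
    def n(self) -> int:
        return self.states.shape[0]


@dataclass
class FilterConfig:
    """Particle-filter settings (none are prescribed by the physics).

    ``noise_fraction`` sets the per-step random-walk sd as a fraction of
    each coefficient's range width; ``noise_scales`` (4-vector) overrides
    it with absolute sds.  ``obs_noise_sd`` is the Gaussian
    observation-error sd in the observation unit of the scenario; when
    ``obs_noise_rel`` is set the per-record sd is
    ``max(obs_noise_rel * observed, obs_noise_sd)`` instead (relative
    error floored at the instrument resolution).  ``anneal`` selects the
    adaptively tempered update; ``move_fraction`` is the roughening sd
    (fraction of range width) applied between annealing stages.
    """

    n_particles: int = 1000
    noise_fraction: float = 0.02
    noise_scales: np.ndarray | None = None
    obs_noise_sd: float = 1.0
    obs_noise_rel: float | None = None
    resample_threshold: float = 0.5
    anneal: bool = True
    anneal_target: float = 0.5
    move_fraction: float = 0.005
    max_anneal_stages: int = 30
    model: str = "plume"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.obs_noise_sd <= 0:
            raise ValueError("obs_noise_sd must be > 0")
        if not (0.0 < self.resample_threshold <= 1.0):
            raise ValueError("resample_threshold must lie in (0, 1]")
        if not (0.0 < self.anneal_target <= 1.0):
            raise ValueError("anneal_target must lie in (0, 1]")
        if self.obs_noise_rel is not None and self.obs_noise_rel <= 0:
            raise ValueError("obs_noise_rel must be > 0 when set")
        if self.model not in ("plume", "multipuff"):
            raise ValueError("model must be 'plume' or 'multipuff'")

    def scales(self, ranges: np.ndarray) -> np.ndarray:
        if self.noise_scales is not None:
            return np.asarray(self.noise_scales, dtype=float)
        return self.noise_fraction * (ranges[:, 1] - ranges[:, 0])


def init_ensemble(ranges: np.ndarray, n: int,
                  rng: np.random.Generator | int | None = None) -> ParticleEnsemble:
    """States i.i.d. uniform over the coefficient box, uniform weights."""
    if n < 2:
        raise ValueError("need at least 2 particles")
    rng = np.random.default_rng(rng)
    ranges = np.asarray(ranges, dtype=float)
    states = rng.uniform(ranges[:, 0], ranges[:, 1], size=(n, 4))
    return ParticleEnsemble(states=states, weights=np.full(n, 1.0 / n), step=0)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold values back into [lo, hi] by reflection at the boundaries."""
    width = hi - lo
    m = np.mod(x - lo, 2.0 * width)
    return lo + np.where(m <= width, m, 2.0 * width - m)


def predict(ensemble: ParticleEnsemble, noise_scales: np.ndarray,
            ranges: np.ndarray, rng: np.random.Generator) -> ParticleEnsemble:
    """Random-walk transition: Gaussian perturbation, reflected into range."""
    scales = np.asarray(noise_scales, dtype=float)
    noise = rng.normal(0.0, 1.0, size=ensemble.states.shape) * scales
    states = _reflect(ensemble.states + noise,
                      ranges[:, 0][None, :], ranges[:, 1][None, :])
    return replace(ensemble, states=states, step=ensemble.step + 1)


def observation_operator(states: np.ndarray, scenario: Scenario,
                         receptors: np.ndarray, t: float,
                         model: str = "plume", t0: float = 0.0) -> np.ndarray:
    """Predicted concentrations (observation units) for each state at each sensor."""
    if model == "plume":
        v, bearing = scenario.wind.at(t)
        field_ = plume_field(scenario.source, bearing, v, states, receptors,
                             lam=scenario.lam, t=t)
    elif model == "multipuff":
        field_ = puff_train_field(scenario.source, scenario.wind,
                                  scenario.dt_release, states, receptors, t,
                                  lam=scenario.lam, t0=t0)
    else:
        raise ValueError("model must be 'plume' or 'multipuff'")
    return field_ * scenario.concentration_scale


def weight(ensemble: ParticleEnsemble, predicted: np.ndarray,
           observed: np.ndarray, obs_noise_sd: float) -> ParticleEnsemble:
    """Multiply weights by the iid Gaussian likelihood of the batch, renormalise.

    Computed in the log domain.  If every particle's likelihood underflows
    to zero the weights are reset to uniform with a warning (degeneracy
    signal; the observations are then uninformative for this ensemble).
    """
    if np.any(np.asarray(obs_noise_sd) <= 0):
        raise ValueError("obs_noise_sd must be > 0")
    observed = np.asarray(observed, dtype=float)
    resid = (predicted - observed[None, :]) / obs_noise_sd
    loglik = -0.5 * np.sum(resid * resid, axis=1)
    with np.errstate(divide="ignore"):
        logw = np.log(ensemble.weights) + loglik
    norm = logsumexp(logw)
    if not np.isfinite(norm):
        warnings.warn("all particle likelihoods vanished; resetting to uniform "
                      "weights (filter degeneracy)", RuntimeWarning, stacklevel=2)
        w = np.full(ensemble.n, 1.0 / ensemble.n)
    else:
        w = np.exp(logw - norm)
        w /= w.sum()
    return replace(ensemble, weights=w)


def _batch_sd(config: FilterConfig, observed: np.ndarray):
    """Per-record observation-error sd (scalar or vector)."""
    if config.obs_noise_rel is None:
        return config.obs_noise_sd
    return np.maximum(config.obs_noise_rel * observed, config.obs_noise_sd)


def _annealed_update(ens: ParticleEnsemble, scenario: Scenario,
                     receptors: np.ndarray, observed: np.ndarray, t: float,
                     config: FilterConfig, ranges: np.ndarray,
                     rng: np.random.Generator, t0: float) -> tuple[ParticleEnsemble, float, int]:
    """Tempered weight/resample/move cycle for one observation batch.

    Raises the batch likelihood to an increasing sequence of powers; each
    stage's increment is chosen (by bisection) so the stage ESS stays near
    ``anneal_target * N``, after which the ensemble is resampled and
    roughened with a small reflected Gaussian move.  Returns the updated
    ensemble, the ESS the full-power likelihood would have produced at the
    first stage (the degeneracy diagnostic), and the number of stages.
    """
    n = ens.n
    sd = _batch_sd(config, observed)
    move = config.move_fraction * (ranges[:, 1] - ranges[:, 0])
    beta = 0.0
    raw_ess = float(n)
    stages = 0
    while beta < 1.0 and stages < config.max_anneal_stages:
        stages += 1
        predicted = observation_operator(ens.states, scenario, receptors, t,
                                         config.model, t0)
        resid = (predicted - observed[None, :]) / sd
        loglik = -0.5 * np.sum(resid * resid, axis=1)
        if not np.any(np.isfinite(loglik)):
            warnings.warn("all particle likelihoods vanished; skipping batch "
                          "(filter degeneracy)", RuntimeWarning, stacklevel=2)
            return ens, 1.0, stages
        with np.errstate(divide="ignore"):
            logw0 = np.log(ens.weights)

        def ess_at(db: float) -> tuple[float, np.ndarray]:
            logw = logw0 + db * loglik
            norm = logsumexp(logw)
            w = np.exp(logw - norm)
            w /= w.sum()
            return 1.0 / float(np.sum(w * w)), w

        ess_full, w_full = ess_at(1.0 - beta)
        if stages == 1:
            raw_ess = ess_full
        if ess_full >= config.anneal_target * n:
            db, w = 1.0 - beta, w_full
        else:
            lo, hi = 0.0, 1.0 - beta
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                e_mid, _ = ess_at(mid)
                if e_mid > config.anneal_target * n:
                    lo = mid
                else:
                    hi = mid
            db = max(mid, 1e-6)
            _, w = ess_at(db)
        beta += db
        ens = replace(ens, weights=w)
        ens = resample_systematic(ens, rng)
        if beta < 1.0:
            ens = predict(ens, move, ranges, rng)
            ens = replace(ens, step=ens.step - 1)  # roughening, not a time step
    return ens, raw_ess, stages


def effective_sample_size(weights: np.ndarray) -> float:
    """ESS = 1 / sum(w_i^2); N for uniform weights, 1 when degenerate."""
    w = np.asarray(weights, dtype=float)
    return 1.0 / float(np.sum(w * w))


def resample_systematic(ensemble: ParticleEnsemble,
                        rng: np.random.Generator) -> ParticleEnsemble:
    """Systematic (low-variance) resampling; expected copies of i = N * w_i."""
    w = ensemble.weights
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
        raise ValueError("weights must be normalised and nonnegative")
    n = ensemble.n
    positions = (rng.uniform() + np.arange(n)) / n
    idx = np.searchsorted(np.cumsum(w), positions)
    idx = np.clip(idx, 0, n - 1)
    return replace(ensemble, states=ensemble.states[idx].copy(),
                   weights=np.full(n, 1.0 / n))


def estimate(ensemble: ParticleEnsemble, ranges: np.ndarray) -> DispersionState:
    """Posterior mean state (weighted mean per coefficient, clipped to range)."""
    mean = ensemble.weights @ ensemble.states
    mean = np.clip(mean, ranges[:, 0], ranges[:, 1])
    rdict = {n_: tuple(ranges[i]) for i, n_ in enumerate(COEF_NAMES)}
    return DispersionState.from_array(mean, ranges=rdict)


def _ensemble_sd(ensemble: ParticleEnsemble) -> np.ndarray:
    mean = ensemble.weights @ ensemble.states
    var = ensemble.weights @ (ensemble.states - mean) ** 2
    return np.sqrt(np.clip(var, 0.0, None))


@dataclass
class AssimilationRun:
    """Per-step output of one assimilation run."""

    estimates: pd.DataFrame   # step, time_s, a1..b2, sd_a1..sd_b2, ess, resampled
    predictions: pd.DataFrame  # time_s, sensor_id, observed, predicted
    final_ensemble: ParticleEnsemble
    config: FilterConfig


def run_assimilation(scenario: Scenario, observations: pd.DataFrame,
                     config: FilterConfig | None = None,
                     initial_states: np.ndarray | None = None,
                     t0: float = 0.0) -> AssimilationRun:
    """Assimilate each observation batch in time order.

    ``observations`` is the standard sensor table; one batch per distinct
    ``time_s``.  Per batch: predict -> weight (annealed by default) ->
    resample -> estimate.  The recorded ``ess`` is the effective sample
    size the full-power batch likelihood produced before any resampling
    (the degeneracy diagnostic).  The per-sensor predictions recorded for
    a batch are evaluated at that batch's posterior-mean state.

    ``initial_states`` (N, 4) replaces the uniform initial draw, e.g. to
    start the filter at a known state.
    """
    config = config or FilterConfig()
    missing = [c for c in OBS_COLUMNS if c not in observations.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    if len(observations) == 0:
        raise ValueError("observation table is empty")
    times = observations["time_s"].to_numpy()
    if np.any(np.diff(times) < 0):
        raise ValueError("observation times must be non-decreasing")

    ranges = ranges_array(scenario.ranges)
    rng = np.random.default_rng(config.seed)
    if initial_states is not None:
        states = np.atleast_2d(np.asarray(initial_states, dtype=float))
        ens = ParticleEnsemble(states=states.copy(),
                               weights=np.full(states.shape[0], 1.0 / states.shape[0]))
    else:
        ens = init_ensemble(ranges, config.n_particles, rng)
    scales = config.scales(ranges)

    est_rows = []
    pred_frames = []
    for step, (t, batch) in enumerate(observations.groupby("time_s", sort=True)):
        receptors = batch[["x_m", "y_m", "z_m"]].to_numpy(dtype=float)
        observed = batch["concentration"].to_numpy(dtype=float)
        ens = predict(ens, scales, ranges, rng)
        if config.anneal:
            ens, ess, stages = _annealed_update(ens, scenario, receptors,
                                                observed, float(t), config,
                                                ranges, rng, t0)
            resampled = stages > 0
        else:
            predicted = observation_operator(ens.states, scenario, receptors,
                                             float(t), config.model, t0)
            ens = weight(ens, predicted, observed,
                         _batch_sd(config, observed))
            ess = effective_sample_size(ens.weights)
            resampled = ess < config.resample_threshold * ens.n
            if resampled:
                ens = resample_systematic(ens, rng)
        est = estimate(ens, ranges)
        sd = _ensemble_sd(ens)
        est_rows.append({"step": step, "time_s": float(t),
                         **{n_: getattr(est, n_) for n_ in COEF_NAMES},
                         **{f"sd_{n_}": sd[i] for i, n_ in enumerate(COEF_NAMES)},
                         "ess": ess, "resampled": resampled})
        pred = observation_operator(est.as_array()[None, :], scenario, receptors,
                                    float(t), config.model, t0)[0]
        pred_frames.append(pd.DataFrame({
            "time_s": float(t), "sensor_id": batch["sensor_id"].to_numpy(),
            "observed": observed, "predicted": pred}))
    return AssimilationRun(estimates=pd.DataFrame(est_rows),
                           predictions=pd.concat(pred_frames, ignore_index=True),
                           final_ensemble=ens, config=config)
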