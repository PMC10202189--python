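"""Recursive daily crop simulation from environment and an initial state.

After training, the only inputs are the hourly environment and the growth
factors at transplanting: each day the model's own output recursively
replaces the previous-growth window.  To produce day d the decoder window
holds the L days preceding the target window [d-L+1, d]; the last position
of the output sequence is the day-d prediction.  Days before the
cultivation start are padded by holding the initial state (and the first
day's environment features) constant.

With guidance on (the default, as in practical use), the two cumulative
status factors in the fed-back growth window — total cumulative radiation
and cumulative growing degree days — are replaced by values computed from
the measured environment instead of the model's own status outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import factors as F
from .env_features import EnvSeries, FeatureSettings, feature_tensor
from .growth_records import GrowthObservation
from .training import TrainedModel

GUIDED_FACTORS = ("cum_radiation_mj", "cum_gdd")


@dataclass
class SimulationRun:
    """Daily predicted growth trajectory."""

    trajectory: pd.DataFrame      # (n_days, factors), indexed by date
    initial: np.ndarray
    guidance: bool
    sanitized: bool


def initialize_state(
    initial, memory_length: int, factors: tuple[str, ...] = F.FACTORS
) -> np.ndarray:
    """Seed (L, n_factors) window by holding the initial state constant."""
    if isinstance(initial, GrowthObservation):
        initial = initial.means
    if isinstance(initial, pd.Series):
        missing = [f for f in factors if f not in initial.index]
        if missing:
            raise ValueError(f"initial state missing factors {missing}")
        initial = initial[list(factors)].to_numpy(dtype=float)
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (len(factors),):
        raise ValueError(
            f"initial state must have {len(factors)} factors, got {initial.shape}"
        )
    return np.tile(initial, (memory_length, 1))


def _guidance_values(daily: pd.DataFrame, day: int) -> tuple[float, float]:
    """Env-derived (cum_radiation_mj, cum_gdd) for 1-based day; 0 before start."""
    if day < 1:
        return 0.0, 0.0
    row = daily.iloc[min(day, len(daily)) - 1]
    return float(row["cum_radiation_mj"]), float(row["cum_gdd"])


def step_day(
    states: np.ndarray,
    day: int,
    features: np.ndarray,
    daily: pd.DataFrame,
    trained: TrainedModel,
    guidance: bool = True,
) -> np.ndarray:
    """Predict the growth state of 1-based ``day``.

    ``states`` holds the initial state at row 0 and predictions for days
    1..day-1 in rows 1..day-1.  ``features`` is the (n_days, 24, 7) feature
    tensor of the cultivation.  Returns the day's factor vector in natural
    units.
    """
    cfg = trained.cfg
    L = cfg.memory_length
    idx = F.factor_index(cfg.factors)

    prev_days = np.arange(day - 2 * L + 1, day - L + 1)
    prev = states[np.clip(prev_days, 0, day - 1)].copy()
    if guidance:
        for offset, d in enumerate(prev_days):
            rad, gdd = _guidance_values(daily, int(d))
            prev[offset, idx["cum_radiation_mj"]] = rad
            prev[offset, idx["cum_gdd"]] = gdd

    env_days = np.clip(np.arange(day - L, day), 0, features.shape[0] - 1)
    env_window = features[env_days].reshape(1, 24 * L, features.shape[2])

    env_std = trained.feature_scaler.transform(env_window)
    prev_std = trained.factor_scaler.transform(prev)[None, :, :]
    preds = trained.model.predict(env_std, prev_std)

    state = np.empty(len(cfg.factors))
    for name, cols in cfg.decoder_map.items():
        last = preds[name][0, -1, :]
        for pos, factor in enumerate(cols):
            state[idx[factor]] = last[pos]
    state = trained.factor_scaler.inverse(state)
    if not np.isfinite(state).all():
        raise FloatingPointError(f"non-finite prediction at day {day}")
    return state


def run_simulation(
    initial,
    env: EnvSeries,
    trained: TrainedModel,
    n_days: int | None = None,
    guidance: bool = True,
    sanitize: bool = False,
    feature_settings: FeatureSettings | None = None,
) -> SimulationRun:
    """Roll the trained model forward one day at a time.

    ``initial`` is the day-0 growth factor vector (Series, array or
    GrowthObservation).  The environment must cover the simulated span.
    With ``sanitize`` on, negative predictions are clipped to zero and
    cumulative-harvest factors are made non-decreasing before being fed
    back; off by default.
    """
    cfg = trained.cfg
    features, dates, daily = feature_tensor(env, feature_settings)
    if cfg.zero_features:
        feat_idx = [i for i, f in enumerate(F.FEATURES) if f in cfg.zero_features]
        features = features.copy()
        features[:, :, feat_idx] = 0.0
    if n_days is None:
        n_days = features.shape[0]
    if n_days > features.shape[0]:
        raise ValueError(
            f"environment covers {features.shape[0]} days, requested {n_days}"
        )
    seed = initialize_state(initial, cfg.memory_length, cfg.factors)
    states = np.empty((n_days + 1, len(cfg.factors)))
    states[0] = seed[0]
    cum_idx = [i for i, f in enumerate(cfg.factors) if f in F.CUMULATIVE_FACTORS]

    for day in range(1, n_days + 1):
        state = step_day(states, day, features, daily, trained, guidance)
        if sanitize:
            state = np.clip(state, 0.0, None)
            state[cum_idx] = np.maximum(state[cum_idx], states[day - 1][cum_idx])
        states[day] = state

    trajectory = pd.DataFrame(
        states[1:], index=dates[:n_days], columns=list(cfg.factors)
    )
    trajectory.index.name = "date"
    return SimulationRun(
        trajectory=trajectory,
        initial=seed[0],
        guidance=guidance,
        sanitized=sanitize,
    )
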