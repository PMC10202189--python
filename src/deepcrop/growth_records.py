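"""Sparse destructive growth observations -> daily training labels.

Destructive investigations yield per-plant factor means and standard
deviations on a handful of dates per cultivation.  Training needs daily
labels, so means and SDs are linearly interpolated to every day, anchored
at cultivation start by a virtual day-0 observation equal to 50% of the
first real observation.  The interpolated series is then stochastically
augmented: each draw samples every (day, factor) label from
Normal(mean, SD) truncated at zero, and cumulative-harvest columns are
re-monotonized with a running maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factors import CUMULATIVE_FACTORS, FACTORS, FW_DW_PAIRS


@dataclass
class GrowthObservation:
    """One destructive investigation: per-plant means and SDs per factor."""

    date: pd.Timestamp
    means: pd.Series        # indexed by factor name
    sds: pd.Series
    n_plants: int

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date).normalize()
        missing = [f for f in FACTORS if f not in self.means.index]
        if missing:
            raise ValueError(f"observation at {self.date.date()} missing factors {missing}")
        if (self.means[list(FACTORS)] < 0).any():
            raise ValueError("negative factor mean")
        if (self.sds[list(FACTORS)] < 0).any():
            raise ValueError("negative factor SD")
        for fw, dw in FW_DW_PAIRS:
            if self.means[fw] < self.means[dw]:
                raise ValueError(f"{fw} < {dw} at {self.date.date()}")


@dataclass
class DailyLabelSeries:
    """Daily interpolated label means and SDs for one cultivation."""

    dates: pd.DatetimeIndex                  # consecutive days from start
    label_matrix: np.ndarray                 # (n_days, n_factors)
    sd_matrix: np.ndarray                    # (n_days, n_factors)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.label_matrix, index=self.dates, columns=list(FACTORS))


def read_growth_csv(path) -> list[GrowthObservation]:
    """Read long-format growth CSV: date, factor, mean, sd, n_plants."""
    table = pd.read_csv(path, parse_dates=["date"])
    unknown = set(table["factor"]) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown growth factors in {path}: {sorted(unknown)}")
    obs = []
    for date, block in table.groupby("date"):
        block = block.set_index("factor")
        obs.append(
            GrowthObservation(
                date=date,
                means=block["mean"].astype(float),
                sds=block["sd"].astype(float),
                n_plants=int(block["n_plants"].iloc[0]),
            )
        )
    return sorted(obs, key=lambda o: o.date)


def write_growth_csv(observations: list[GrowthObservation], path) -> None:
    rows = []
    for o in observations:
        for f in FACTORS:
            rows.append((o.date.date().isoformat(), f, o.means[f], o.sds[f], o.n_plants))
    pd.DataFrame(rows, columns=["date", "factor", "mean", "sd", "n_plants"]).to_csv(
        path, index=False, float_format="%.6g"
    )


def interpolate_growth_daily(
    observations: list[GrowthObservation],
    start_date: pd.Timestamp,
    start_rule: float = 0.5,
) -> DailyLabelSeries:
    """Linearly interpolate sparse observations to daily labels.

    A virtual day-0 anchor at ``start_date`` is prepended with every factor
    (mean and SD) at ``start_rule`` (default 50%) of the first observation.
    Means and SDs are interpolated independently per factor to every day
    between the anchor and the last observation.
    """
    if not observations:
        raise ValueError("no observations")
    dates = [o.date for o in observations]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("observation dates not strictly increasing")
    start_date = pd.Timestamp(start_date).normalize()
    if start_date >= dates[0]:
        raise ValueError("start_date must precede the first observation")

    first = observations[0]
    anchor_means = first.means[list(FACTORS)] * start_rule
    anchor_sds = first.sds[list(FACTORS)] * start_rule
    node_dates = [start_date] + dates
    node_days = np.array([(d - start_date).days for d in node_dates], dtype=float)
    means = np.vstack(
        [anchor_means.to_numpy()] + [o.means[list(FACTORS)].to_numpy() for o in observations]
    )
    sds = np.vstack(
        [anchor_sds.to_numpy()] + [o.sds[list(FACTORS)].to_numpy() for o in observations]
    )

    all_days = np.arange(node_days[-1] + 1)
    label = np.empty((all_days.size, len(FACTORS)))
    sd = np.empty_like(label)
    for j in range(len(FACTORS)):
        label[:, j] = np.interp(all_days, node_days, means[:, j])
        sd[:, j] = np.interp(all_days, node_days, sds[:, j])
    if (label < 0).any():
        warnings.warn("negative interpolated labels clipped to 0", stacklevel=2)
        label = np.clip(label, 0.0, None)
    daily_dates = pd.date_range(start_date, periods=all_days.size, freq="D")
    return DailyLabelSeries(daily_dates, label, sd)


def augment_labels(
    daily: DailyLabelSeries, n_draws: int, seed: int
) -> np.ndarray:
    """Stochastic label augmentation.

    Returns an array of shape (n_draws, n_days, n_factors).  Each draw
    samples labels from Normal(mean, SD) truncated at 0; cumulative columns
    are re-monotonized by a running maximum along days.  Deterministic under
    ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not np.isfinite(daily.sd_matrix).all():
        raise ValueError("non-finite SDs")
    rng = np.random.default_rng(seed)
    draws = rng.normal(
        loc=daily.label_matrix, scale=daily.sd_matrix,
        size=(n_draws,) + daily.label_matrix.shape,
    )
    np.clip(draws, 0.0, None, out=draws)
    cum_idx = [i for i, f in enumerate(FACTORS) if f in CUMULATIVE_FACTORS]
    draws[:, :, cum_idx] = np.maximum.accumulate(draws[:, :, cum_idx], axis=1)
    return draws


@dataclass
class WindowSample:
    """One training sample: an env window, the preceding growth window and
    the target growth window (the L days immediately after it)."""

    features: np.ndarray      # (24*L, 7)
    prev_growth: np.ndarray   # (L, n_factors)
    target: np.ndarray        # (L, n_factors)
    cultivation: str = ""
    draw: int = 0
    start_day: int = 0        # day offset of the prev window start


@dataclass
class WindowDataset:
    """Stacked window samples for batched training."""

    env: np.ndarray           # (N, 24*L, 7)
    prev: np.ndarray          # (N, L, F)
    target: np.ndarray        # (N, L, F)
    meta: pd.DataFrame        # columns cultivation, draw, start_day

    def __len__(self) -> int:
        return self.env.shape[0]

    @staticmethod
    def from_samples(samples: list[WindowSample]) -> "WindowDataset":
        if not samples:
            raise ValueError("no window samples")
        return WindowDataset(
            env=np.stack([s.features for s in samples]),
            prev=np.stack([s.prev_growth for s in samples]),
            target=np.stack([s.target for s in samples]),
            meta=pd.DataFrame(
                {
                    "cultivation": [s.cultivation for s in samples],
                    "draw": [s.draw for s in samples],
                    "start_day": [s.start_day for s in samples],
                }
            ),
        )


def window_samples(
    feature_values: np.ndarray,
    label_sets: np.ndarray,
    memory_length: int,
    cultivation: str = "",
) -> list[WindowSample]:
    """Slide daily windows over one cultivation.

    ``feature_values`` is the (n_days, 24, 7) feature tensor aligned with
    ``label_sets`` of shape (n_draws, n_days, n_factors).  A sample at
    offset i pairs prev days [i, i+L) with target days [i+L, i+2L) and the
    env window of the target days; there are n_days - 2L + 1 offsets.
    """
    L = memory_length
    n_days = min(feature_values.shape[0], label_sets.shape[1])
    n_windows = n_days - 2 * L + 1
    if n_windows < 1:
        raise ValueError(
            f"cultivation too short: {n_days} aligned days < minimum {2 * L}"
        )
    samples = []
    for draw in range(label_sets.shape[0]):
        labels = label_sets[draw]
        for i in range(n_windows):
            samples.append(
                WindowSample(
                    features=feature_values[i + L : i + 2 * L].reshape(-1, feature_values.shape[2]),
                    prev_growth=labels[i : i + L],
                    target=labels[i + L : i + 2 * L],
                    cultivation=cultivation,
                    draw=draw,
                    start_day=i,
                )
            )
    return samples


def make_training_windows(
    per_cultivation: dict[str, tuple[np.ndarray, np.ndarray]],
    memory_length: int,
    split: float,
    seed: int,
) -> tuple[WindowDataset, WindowDataset]:
    """Build train/validation window datasets.

    ``per_cultivation`` maps cultivation name -> (feature tensor
    (n_days, 24, 7), label sets (n_draws, n_days, F)).  Samples are pooled
    and split randomly at the sample level by fraction ``split`` (train
    share); windows never mix days across cultivations.
    """
    if not 0.0 < split < 1.0:
        raise ValueError("split must be in (0, 1)")
    samples: list[WindowSample] = []
    for name, (features, labels) in per_cultivation.items():
        samples.extend(window_samples(features, labels, memory_length, name))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(split * len(samples)))
    n_train = min(max(n_train, 1), len(samples) - 1)
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:]]
    return WindowDataset.from_samples(train), WindowDataset.from_samples(val)
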