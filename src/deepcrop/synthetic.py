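"""Synthetic greenhouse environment and reference crop growth.

Provides the study conditions end-to-end without any external data: an
hourly greenhouse environment generator (diurnal + seasonal temperature,
humidity and radiation with noise), a deliberately simple process-based
reference grower (radiation-use-efficiency assimilation with Beer-law light
interception from a Gompertz leaf-area-index curve, thermal-time dependent
partitioning to organs, discrete harvest events), and a destructive-
observation sampler that turns the daily truth into the sparse mean/SD
records a real cultivation would yield.

The grower is the internally consistent signal the attention model learns;
it is a minimal RUE + partitioning model in the spirit of generic simple
crop models, not a pepper physiology model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .env_features import (
    DEFAULT_T_BASE,
    EnvSeries,
    FeatureSettings,
    compute_daily_features,
    write_env_csv,
)
from .factors import FACTORS
from .growth_records import GrowthObservation, write_growth_csv


def derive_seed(base_seed: int, name: str) -> int:
    """Stable sub-seed (< 2**31) for a named randomness stream."""
    digest = hashlib.sha256(f"{base_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class CultivationScenario:
    """Season-level description of one greenhouse cultivation."""

    name: str = "cultivation"
    year: int = 2020
    start_day_of_year: int = 57          # late February transplanting
    n_days: int = 120
    planting_density: float = 4.0        # plants m-2
    temp_mean: float = 21.0              # season-mean greenhouse temperature, degC
    temp_seasonal_amp: float = 2.5       # seasonal drift amplitude over the run
    temp_diurnal_amp: float = 4.5        # day-night swing amplitude
    rh_mean: float = 72.0                # %
    rh_diurnal_amp: float = 10.0
    radiation_peak: float = 450.0        # clear-sky noon inside-greenhouse W m-2
    temp_noise_sd: float = 0.6
    rh_noise_sd: float = 3.0
    radiation_noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 30:
            raise ValueError("n_days must be >= 30")
        if self.planting_density <= 0:
            raise ValueError("planting density must be positive")

    @property
    def start_date(self) -> pd.Timestamp:
        return pd.Timestamp(f"{self.year}-01-01") + pd.Timedelta(
            days=self.start_day_of_year - 1
        )


@dataclass
class ReferenceParams:
    """Parameters of the reference process-based grower."""

    lai_init: float = 0.10               # m2 m-2 at transplant
    lai_max: float = 3.5
    c_plai: float = 0.0035               # Gompertz rate per degC day
    t_base: float = DEFAULT_T_BASE
    rue: float = 1.9                     # g DW per MJ intercepted global radiation
    k_ext: float = 0.65                  # Beer-law extinction coefficient
    # thermal-time dependent partitioning: fruit share rises logistically
    fruit_share_max: float = 0.65
    fruit_share_ts50: float = 380.0      # degC day at half the fruit share
    fruit_share_slope: float = 90.0
    veg_split: tuple[float, float, float] = (0.45, 0.35, 0.20)  # leaf/stem/petiole
    # dry-matter content per organ (FW = DW / dmc)
    dmc: dict = field(
        default_factory=lambda: {
            "leaf": 0.105, "stem": 0.13, "petiole": 0.09, "fruit": 0.085
        }
    )
    # specific dimensions
    sla_m2_per_g: float = 0.020          # leaf area per leaf DW
    dw_per_leaf_g: float = 0.45
    dw_per_node_g: float = 1.2
    node_length_cm: float = 5.5
    node_diameter_mm: float = 9.0
    n_stems: int = 2                     # main stems kept per plant
    dw_per_fruit_g: float = 11.0
    fruit_height_cm: float = 7.5
    fruit_width_cm: float = 7.0
    # harvest rule: every `harvest_interval` days once ripening has begun,
    # a fraction of the fruit pool moves to cumulative harvest
    harvest_ts_onset: float = 420.0      # degC day before first harvest
    harvest_interval: int = 3            # days (2-3 pickings per week)
    harvest_fraction: float = 0.7
    # initial per-plant organ DW at transplant, g
    init_dw: dict = field(
        default_factory=lambda: {"leaf": 1.6, "stem": 1.1, "petiole": 0.4}
    )

    def __post_init__(self) -> None:
        self.veg_split = tuple(self.veg_split)

    def validate(self) -> None:
        if not 0 < self.lai_init < self.lai_max:
            raise ValueError("require 0 < lai_init < lai_max")
        if abs(sum(self.veg_split) - 1.0) > 1e-9:
            raise ValueError("vegetative split must sum to 1")
        for organ, v in self.dmc.items():
            if not 0 < v < 1:
                raise ValueError(f"dry matter content of {organ} outside (0, 1)")
        if not 0 <= self.fruit_share_max < 1:
            raise ValueError("fruit_share_max must be in [0, 1)")


def generate_environment(scenario: CultivationScenario) -> EnvSeries:
    """Hourly greenhouse environment for one cultivation, seeded."""
    rng = np.random.default_rng(derive_seed(scenario.seed, f"env:{scenario.name}"))
    index = pd.date_range(scenario.start_date, periods=scenario.n_days * 24, freq="h")
    doy = index.dayofyear.to_numpy().astype(float)
    hour = index.hour.to_numpy().astype(float)

    season = np.sin(2.0 * np.pi * (doy - 110.0) / 365.0)
    diurnal = -np.cos(2.0 * np.pi * (hour - 2.0) / 24.0)  # peak ~14:00, low ~02:00
    temp = (
        scenario.temp_mean
        + scenario.temp_seasonal_amp * season
        + scenario.temp_diurnal_amp * diurnal
        + rng.normal(0.0, scenario.temp_noise_sd, len(index))
    )
    rh = (
        scenario.rh_mean
        - scenario.rh_diurnal_amp * diurnal
        + rng.normal(0.0, scenario.rh_noise_sd, len(index))
    ).clip(35.0, 98.0)

    daylength = 12.0 + 3.0 * np.sin(2.0 * np.pi * (doy - 81.0) / 365.0)
    sunrise = 12.0 - daylength / 2.0
    phase = (hour - sunrise) / daylength
    shape = np.where((phase > 0.0) & (phase < 1.0), np.sin(np.pi * phase), 0.0)
    season_rad = 0.75 + 0.25 * np.sin(2.0 * np.pi * (doy - 81.0) / 365.0)
    noise = (1.0 + rng.normal(0.0, scenario.radiation_noise_cv, len(index))).clip(0.0)
    rad = scenario.radiation_peak * season_rad * shape * noise

    frame = pd.DataFrame(
        {
            "temperature_c": temp,
            "relative_humidity_pct": rh,
            "radiation_w_m2": rad.clip(0.0),
        },
        index=index,
    )
    return EnvSeries(frame)


def gompertz_lai(thermal_time, params: ReferenceParams):
    """Gompertz leaf-area-index curve over thermal time TS (degC day).

    LAI(TS) = LAI_max * exp(log(LAI_init / LAI_max) * exp(-C_pLAI * TS));
    equals LAI_init at TS = 0 and approaches LAI_max as TS grows.
    """
    if params.lai_init <= 0 or params.lai_max <= 0:
        raise ValueError("lai_init and lai_max must be positive")
    ts = np.asarray(thermal_time, dtype=float)
    if np.any(ts < 0):
        raise ValueError("thermal time must be non-negative")
    out = params.lai_max * np.exp(
        np.log(params.lai_init / params.lai_max) * np.exp(-params.c_plai * ts)
    )
    return out if out.ndim else float(out)


def _fruit_share(ts: float, p: ReferenceParams) -> float:
    return p.fruit_share_max / (1.0 + np.exp(-(ts - p.fruit_share_ts50) / p.fruit_share_slope))


def simulate_reference_growth(
    env: EnvSeries,
    params: ReferenceParams,
    scenario: CultivationScenario,
    feature_settings: FeatureSettings | None = None,
) -> pd.DataFrame:
    """Daily per-plant truth for all output factors.

    Daily assimilate (g DW m-2) = RUE x intercepted radiation, with Beer-law
    interception from the Gompertz LAI at the day's thermal time; assimilate
    is partitioned to leaf/stem/petiole/fruit, divided by planting density
    to per-plant values, and converted to FW and organ dimensions through
    fixed specific parameters.  Ripe fruit moves to cumulative harvest in
    discrete events every few days.
    """
    params.validate()
    settings = feature_settings or FeatureSettings(t_base=params.t_base)
    daily = compute_daily_features(env, settings)
    n_days = len(daily)

    dw = dict(params.init_dw)           # per-plant vegetative pools, g
    fruit_pool = 0.0                    # unharvested fruit DW per plant
    harvested_dw = 0.0
    harvesting = False
    days_since_harvest = 0
    rows = np.empty((n_days, len(FACTORS)))
    col = {f: i for i, f in enumerate(FACTORS)}

    cum_gdd = daily["cum_gdd"].to_numpy()
    rad_mj = daily["daily_cum_radiation_kj"].to_numpy() / 1000.0
    cum_rad_mj = daily["cum_radiation_mj"].to_numpy()

    for d in range(n_days):
        ts = cum_gdd[d]
        lai = gompertz_lai(ts, params)
        intercepted = rad_mj[d] * (1.0 - np.exp(-params.k_ext * lai))
        assim = params.rue * intercepted / scenario.planting_density  # g/plant/day
        f_fruit = _fruit_share(ts, params)
        f_leaf, f_stem, f_petiole = (v * (1.0 - f_fruit) for v in params.veg_split)
        dw["leaf"] += assim * f_leaf
        dw["stem"] += assim * f_stem
        dw["petiole"] += assim * f_petiole
        fruit_pool += assim * f_fruit

        if not harvesting and ts >= params.harvest_ts_onset:
            harvesting = True
            days_since_harvest = params.harvest_interval  # pick immediately
        if harvesting:
            days_since_harvest += 1
            if days_since_harvest >= params.harvest_interval:
                picked = params.harvest_fraction * fruit_pool
                harvested_dw += picked
                fruit_pool -= picked
                days_since_harvest = 0

        n_nodes = dw["stem"] / params.dw_per_node_g
        n_leaves = dw["leaf"] / params.dw_per_leaf_g
        n_fruits = harvested_dw / params.dw_per_fruit_g
        r = rows[d]
        r[col["cum_radiation_mj"]] = cum_rad_mj[d]
        r[col["cum_gdd"]] = ts
        r[col["node_length_sum_cm"]] = n_nodes * params.node_length_cm
        r[col["plant_height_m"]] = (
            n_nodes / params.n_stems * params.node_length_cm / 100.0
        )
        r[col["max_nodes_per_stem"]] = n_nodes / params.n_stems
        r[col["leaf_area_m2"]] = dw["leaf"] * params.sla_m2_per_g
        r[col["leaf_count"]] = n_leaves
        r[col["leaf_fw_g"]] = dw["leaf"] / params.dmc["leaf"]
        r[col["leaf_dw_g"]] = dw["leaf"]
        r[col["node_diameter_sum_mm"]] = n_nodes * params.node_diameter_mm
        r[col["stem_count"]] = n_nodes
        r[col["stem_fw_g"]] = dw["stem"] / params.dmc["stem"]
        r[col["stem_dw_g"]] = dw["stem"]
        r[col["petiole_count"]] = n_leaves
        r[col["petiole_fw_g"]] = dw["petiole"] / params.dmc["petiole"]
        r[col["petiole_dw_g"]] = dw["petiole"]
        r[col["fruit_height_sum_cm"]] = n_fruits * params.fruit_height_cm
        r[col["fruit_width_sum_cm"]] = n_fruits * params.fruit_width_cm
        r[col["harvest_count"]] = n_fruits
        r[col["harvest_fw_g"]] = harvested_dw / params.dmc["fruit"]
        r[col["harvest_dw_g"]] = harvested_dw

    return pd.DataFrame(rows, index=daily.index, columns=list(FACTORS))


def sample_destructive_observations(
    truth: pd.DataFrame,
    n_dates: int,
    cv: float,
    seed: int,
    n_plants: int = 6,
) -> list[GrowthObservation]:
    """Sparse observations from the daily truth at evenly spaced dates.

    With ``n_dates`` samplings over ``n`` days, sampling days are
    {step, 2*step, ..., n_dates*step} (1-based) with step = n // n_dates.
    Observed means carry multiplicative noise of coefficient of variation
    ``cv``; SDs are cv * mean.
    """
    if n_dates < 1:
        raise ValueError("n_dates must be >= 1")
    n = len(truth)
    step = n // n_dates
    if step < 1:
        raise ValueError("more sampling dates than days")
    day_numbers = [step * (k + 1) for k in range(n_dates)]
    rng = np.random.default_rng(seed)
    obs = []
    for day in day_numbers:
        values = truth.iloc[day - 1]
        noisy = values * (1.0 + cv * rng.standard_normal(len(values)))
        noisy = noisy.clip(lower=0.0)
        # keep FW >= DW after noise by re-deriving FW noise jointly
        for fw, dw in (("leaf_fw_g", "leaf_dw_g"), ("stem_fw_g", "stem_dw_g"),
                       ("petiole_fw_g", "petiole_dw_g"), ("harvest_fw_g", "harvest_dw_g")):
            noisy[fw] = max(noisy[fw], noisy[dw])
        obs.append(
            GrowthObservation(
                date=truth.index[day - 1],
                means=noisy,
                sds=(cv * values).clip(lower=0.0),
                n_plants=n_plants,
            )
        )
    return obs


def default_scenarios(base_seed: int = 0) -> list[CultivationScenario]:
    """Four cultivations: two seasons x two years (spring and autumn runs).

    Mirrors a two-year greenhouse campaign: spring cultivations are longer
    with stronger radiation; autumn cultivations are shorter, dimmer and at
    lower planting density.
    """

    def make(name, year, doy, n_days, density, tmean, rad_peak):
        return CultivationScenario(
            name=name, year=year, start_day_of_year=doy, n_days=n_days,
            planting_density=density, temp_mean=tmean, radiation_peak=rad_peak,
            seed=derive_seed(base_seed, name),
        )

    return [
        make("2020-1", 2020, 57, 120, 4.08, 21.5, 460.0),
        make("2020-2", 2020, 300, 90, 3.06, 19.5, 380.0),
        make("2021-1", 2021, 67, 110, 5.95, 21.0, 450.0),
        make("2021-2", 2021, 296, 90, 3.06, 19.8, 370.0),
    ]


@dataclass
class Cultivation:
    """In-memory bundle for one synthetic cultivation."""

    scenario: CultivationScenario
    env: EnvSeries
    truth: pd.DataFrame
    observations: list[GrowthObservation]


def make_cultivation(
    scenario: CultivationScenario,
    params: ReferenceParams | None = None,
    n_obs_dates: int = 5,
    obs_cv: float = 0.08,
) -> Cultivation:
    """Generate environment, daily truth and sparse observations."""
    params = params or ReferenceParams()
    env = generate_environment(scenario)
    truth = simulate_reference_growth(env, params, scenario)
    obs = sample_destructive_observations(
        truth, n_obs_dates, obs_cv,
        seed=derive_seed(scenario.seed, f"obs:{scenario.name}"),
    )
    return Cultivation(scenario, env, truth, obs)


def generate_dataset(
    scenarios: list[CultivationScenario],
    out_dir,
    params: ReferenceParams | None = None,
    n_obs_dates: int = 5,
    obs_cv: float = 0.08,
) -> Path:
    """Write env/growth/truth CSVs plus a JSON manifest for each scenario."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"scenarios": []}
    for sc in scenarios:
        cult = make_cultivation(sc, params, n_obs_dates, obs_cv)
        base = out_dir / sc.name
        base.mkdir(exist_ok=True)
        write_env_csv(cult.env, base / "env.csv")
        write_growth_csv(cult.observations, base / "growth.csv")
        cult.truth.rename_axis("date").to_csv(base / "truth.csv", float_format="%.6g")
        manifest["scenarios"].append(
            {"name": sc.name, "seed": sc.seed, "params": asdict(sc)}
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out_dir
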