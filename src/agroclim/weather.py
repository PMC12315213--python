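"""Stochastic gridded daily weather generator.

Emulates 5 km downscaled daily climate projections so that every downstream
risk model can be exercised without external data.  The generator follows
the classic WGEN-family structure:

* temperature — a seasonal sinusoid plus a shared AR(1) anomaly, with a
  fixed positive diurnal range splitting the daily mean into tmin/tmax
  (so ``tmax >= tmin`` holds by construction);
* precipitation occurrence — a first-order two-state Markov chain with
  wet->wet and dry->wet transition probabilities;
* wet-day amounts — gamma distributed;
* radiation, relative humidity and wind — climatological sinusoids plus
  bounded noise, clipped to their physical ranges.

Scenarios are represented by :class:`ScenarioPerturbation`: an additive
warming offset (linearly ramped over the series by default, mimicking a
transient pathway) and a multiplicative precipitation scale.  Pseudo-GCM
ensemble members share identical statistics and differ only by RNG stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .climate import VARIABLES, DailyClimateSeries
from .errors import ConfigurationError

#: End-of-century New Zealand-like warming offsets (degC) and precipitation
#: scales for the four concentration pathways; member_count follows the
#: six-model downscaled ensemble convention.
SCENARIOS = {
    "RCP2.6": (0.7, 1.00),
    "RCP4.5": (1.4, 1.02),
    "RCP6.0": (1.8, 1.02),
    "RCP8.5": (3.0, 1.04),
}


@dataclass(frozen=True)
class ScenarioPerturbation:
    """Bulk-change description of one emissions scenario."""

    scenario_id: str
    warming_offset: float = 0.0
    precip_scale: float = 1.0
    member_count: int = 6
    ramp: bool = True  # offset ramps 0 -> full over the series; False = constant

    def __post_init__(self) -> None:
        if self.precip_scale <= 0:
            raise ConfigurationError("precip_scale must be > 0")
        if self.member_count < 1:
            raise ConfigurationError("member_count must be >= 1")

    @classmethod
    def for_rcp(cls, scenario_id: str, member_count: int = 6,
                ramp: bool = True) -> "ScenarioPerturbation":
        if scenario_id not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario_id {scenario_id!r}; choose from {sorted(SCENARIOS)}"
            )
        offset, scale = SCENARIOS[scenario_id]
        return cls(scenario_id, offset, scale, member_count, ramp)

    @classmethod
    def baseline(cls, member_count: int = 6) -> "ScenarioPerturbation":
        return cls("baseline", 0.0, 1.0, member_count, ramp=False)


@dataclass(frozen=True)
class CellSpec:
    """Location and local climatology of one grid cell."""

    cell_id: str
    latitude: float
    temp_mean: float  # annual-mean daily-mean temperature, degC
    temp_amplitude: float = 5.5  # half peak-to-trough seasonal swing, degC
    diurnal_range: float = 9.0  # tmax - tmin, degC


@dataclass
class WeatherGenConfig:
    """Full parameterisation of the synthetic weather generator."""

    seed: int
    n_years: int
    start_year: int = 1981
    cells: tuple[CellSpec, ...] = ()
    # temperature anomaly AR(1)
    ar1_coeff: float = 0.65
    temp_noise_sd: float = 2.2  # stationary anomaly SD, degC
    # precipitation occurrence/amounts
    p_wet_wet: float = 0.60
    p_dry_wet: float = 0.24
    gamma_shape: float = 0.75
    gamma_scale: float = 8.0  # mm
    # radiation climatology (MJ/m2/day)
    rad_mean: float = 15.0
    rad_amplitude: float = 9.0
    rad_noise_sd: float = 3.0
    # relative humidity (%)
    rh_mean: float = 78.0
    rh_noise_sd: float = 9.0
    # wind (m/s)
    wind_mean: float = 4.0
    wind_noise_sd: float = 1.6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_years < 1:
            raise ConfigurationError("n_years must be >= 1")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ConfigurationError("ar1_coeff must be in [0, 1)")
        for name in ("p_wet_wet", "p_dry_wet"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("gamma_shape", "gamma_scale"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("temp_noise_sd", "rad_noise_sd", "rh_noise_sd", "wind_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for cell in self.cells:
            if cell.diurnal_range <= 0:
                raise ConfigurationError(
                    f"diurnal_range must be > 0 (cell {cell.cell_id})"
                )
        if len({c.cell_id for c in self.cells}) != len(self.cells):
            raise ConfigurationError("cells must have unique cell_id values")

    # ------------------------------------------------------------------
    @classmethod
    def grid(
        cls,
        seed: int,
        n_years: int,
        nx: int,
        ny: int,
        lat_min: float = -46.0,
        lat_max: float = -36.0,
        temp_at_lat: tuple[float, float] = (-41.0, 13.0),
        temp_lapse_per_degree: float = 0.6,
        start_year: int = 1981,
        **kwargs,
    ) -> "WeatherGenConfig":
        """Regular ny x nx grid spanning a latitudinal band.

        The annual-mean temperature decreases towards the pole:
        ``temp_mean = T0 + lapse * (lat - lat0)`` with ``(lat0, T0)`` given
        by ``temp_at_lat`` (warmer at low absolute latitude, as for a
        New Zealand-like north-south gradient).
        """
        if nx < 1 or ny < 1:
            raise ConfigurationError("grid dimensions must be >= 1")
        lat0, t0 = temp_at_lat
        lats = np.linspace(lat_max, lat_min, ny)  # row 0 = northernmost
        cells = tuple(
            CellSpec(
                cell_id=f"r{i}c{j}",
                latitude=float(lats[i]),
                temp_mean=float(t0 + temp_lapse_per_degree * (lats[i] - lat0)),
            )
            for i in range(ny)
            for j in range(nx)
        )
        return cls(seed=seed, n_years=n_years, start_year=start_year,
                   cells=cells, **kwargs)

    @classmethod
    def from_yaml(cls, path, seed: int) -> "WeatherGenConfig":
        """Build a gridded config from a YAML document.

        Schema: a ``grid`` mapping (nx, ny, optional lat_min/lat_max),
        top-level ``n_years`` and optional ``start_year``, and an optional
        ``generator`` mapping overriding any generator parameter."""
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            grid = dict(doc["grid"])
            n_years = int(doc["n_years"])
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"config is missing field {exc}") from exc
        kwargs = dict(doc.get("generator", {}))
        return cls.grid(
            seed=seed,
            n_years=n_years,
            nx=int(grid["nx"]),
            ny=int(grid["ny"]),
            lat_min=float(grid.get("lat_min", -46.0)),
            lat_max=float(grid.get("lat_max", -36.0)),
            start_year=int(doc.get("start_year", 1981)),
            **kwargs,
        )

    def cell(self, cell_id: str) -> CellSpec:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise ConfigurationError(f"unknown cell_id {cell_id!r}")


# ----------------------------------------------------------------------
def _rng_for(seed: int, member_id: int, cell_id: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, member, cell).

    The stream deliberately ignores the scenario, so two scenarios differ
    only by their perturbation applied to identical weather noise."""
    cell_key = zlib.crc32(cell_id.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([seed, member_id, cell_key]))


def _seasonal_cycle(doy_frac: np.ndarray, mean: float, amplitude: float,
                    latitude: float) -> np.ndarray:
    """Annual sinusoid peaking in mid-January south of the equator and
    mid-July north of it."""
    peak = 14.0 / 365.25 if latitude < 0 else 196.0 / 365.25
    return mean + amplitude * np.cos(2.0 * np.pi * (doy_frac - peak))


def _markov_occurrence(rng: np.random.Generator, n: int, p_wet_wet: float,
                       p_dry_wet: float) -> np.ndarray:
    """Two-state first-order chain; the initial state is dry."""
    u = rng.random(n)
    wet = np.empty(n, dtype=bool)
    state = False
    for t in range(n):
        state = u[t] < (p_wet_wet if state else p_dry_wet)
        wet[t] = state
    return wet


def markov_stationary_wet_fraction(p_wet_wet: float, p_dry_wet: float) -> float:
    """Stationary wet-day probability p01 / (1 + p01 - p11) of the chain."""
    return p_dry_wet / (1.0 + p_dry_wet - p_wet_wet)


def generate_series(
    config: WeatherGenConfig,
    perturbation: ScenarioPerturbation,
    cell_id: str,
    member_id: int = 0,
) -> DailyClimateSeries:
    """Generate one cell's daily series for one scenario and member.

    Identical ``(config, perturbation, cell_id, member_id)`` always yields
    an identical series.  The warming offset is added to tmin and tmax —
    ramped linearly from zero at the series start to its full value at the
    series end when ``perturbation.ramp`` is set, constant otherwise — and
    wet-day precipitation amounts are multiplied by ``precip_scale``.
    """
    cell = config.cell(cell_id)
    rng = _rng_for(config.seed, member_id, cell_id)

    index = pd.date_range(
        start=f"{config.start_year}-01-01",
        end=f"{config.start_year + config.n_years - 1}-12-31",
        freq="D",
    )
    n = len(index)
    doy_frac = (index.dayofyear.to_numpy() - 1) / 365.25

    # temperature: sinusoid + AR(1) anomaly with stationary SD temp_noise_sd
    seasonal = _seasonal_cycle(doy_frac, cell.temp_mean, cell.temp_amplitude,
                               cell.latitude)
    rho = config.ar1_coeff
    innov = rng.standard_normal(n) * config.temp_noise_sd * np.sqrt(1.0 - rho * rho)
    anomaly = lfilter([1.0], [1.0, -rho], innov)
    if perturbation.ramp and n > 1:
        offset = perturbation.warming_offset * np.arange(n) / (n - 1)
    else:
        offset = np.full(n, perturbation.warming_offset)
    tmean = seasonal + anomaly + offset
    half_range = 0.5 * cell.diurnal_range
    tmax = tmean + half_range
    tmin = tmean - half_range

    # precipitation: Markov occurrence, gamma amounts, scenario scale
    wet = _markov_occurrence(rng, n, config.p_wet_wet, config.p_dry_wet)
    amounts = rng.gamma(config.gamma_shape, config.gamma_scale, n)
    precip = np.where(wet, amounts * perturbation.precip_scale, 0.0)

    # radiation / humidity / wind: climatology + clipped noise
    rad = _seasonal_cycle(doy_frac, config.rad_mean, config.rad_amplitude,
                          cell.latitude)
    rad = np.clip(rad + rng.standard_normal(n) * config.rad_noise_sd, 0.0, None)
    rh = np.clip(config.rh_mean + rng.standard_normal(n) * config.rh_noise_sd,
                 0.0, 100.0)
    wind = np.clip(config.wind_mean + rng.standard_normal(n) * config.wind_noise_sd,
                   0.0, None)

    data = pd.DataFrame(
        dict(zip(VARIABLES, (tmin, tmax, precip, rad, rh, wind))), index=index
    )
    return DailyClimateSeries(
        cell_id=cell_id,
        latitude=cell.latitude,
        data=data,
        scenario_id=perturbation.scenario_id,
        member_id=member_id,
    )


def apply_perturbation(
    series: DailyClimateSeries, perturbation: ScenarioPerturbation
) -> DailyClimateSeries:
    """Apply a scenario perturbation to an existing series.

    Uses the same ramp convention as :func:`generate_series`, so applying
    offsets ``a`` then ``b`` equals generating with a single offset
    ``a + b`` (temperature fields are additive in the perturbation).
    """
    n = len(series.data)
    if perturbation.ramp and n > 1:
        offset = perturbation.warming_offset * np.arange(n) / (n - 1)
    else:
        offset = np.full(n, perturbation.warming_offset)
    df = series.data.copy()
    df["tmin"] += offset
    df["tmax"] += offset
    df["precip"] *= perturbation.precip_scale
    out = DailyClimateSeries(
        cell_id=series.cell_id,
        latitude=series.latitude,
        data=df,
        scenario_id=perturbation.scenario_id,
        member_id=series.member_id,
    )
    return out


def generate_grid(
    config: WeatherGenConfig,
    perturbation: ScenarioPerturbation,
    members: int | None = None,
) -> list[DailyClimateSeries]:
    """All cells x members for one scenario, in (member, cell) order."""
    n_members = perturbation.member_count if members is None else members
    return [
        generate_series(config, perturbation, cell.cell_id, member_id=m)
        for m in range(n_members)
        for cell in config.cells
    ]
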