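"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of their parameters and a seed, so
fixtures are reproduced at test time rather than shipped.  The weather
generator emulates the structure that matters to chill-injury accounting —
an annual cycle, a diurnal cycle, AR(1) weather noise and scheduled cold
snaps — not any particular climatology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accumulator import TemperatureSeries
from .model import ChillParams, SurvivalAssay, survival

__all__ = [
    "WeatherScenario",
    "ColdSnap",
    "gen_survival_experiment",
    "gen_temperature_series",
    "gen_station_network",
    "gen_occurrences",
    "TABLE_DESIGN_THRIPS",
    "TABLE_DESIGN_BEETLE",
]

#: the incomplete-cross thrips assay design: (temperature degC, exposure h,
#: n per cell).  50 individuals per populated cell.
TABLE_DESIGN_THRIPS = tuple(
    (T, t, 50)
    for t, temps in (
        (6, (-3, -6, -9, -12)),
        (12, (-3, -6, -9, -12)),
        (24, (3, 0, -3, -6, -9, -12)),
        (48, (3, 0, -3, -6, -9, -12)),
        (96, (3, 0, -3, -6, -9, -12)),
        (192, (3, 0, -3, -6)),
        (384, (3, 0, -3)),
    )
    for T in temps
)

#: the complete 4x5 beetle design; per-cell n defaults to 68.
TABLE_DESIGN_BEETLE = tuple(
    (T, t, 68) for t in (6, 12, 24, 48, 96) for T in (2, -2, -4, -6)
)


def gen_survival_experiment(p: ChillParams, design, seed: int) -> list[SurvivalAssay]:
    """Binomial assay outcomes at a (temperature, exposure, n) design.

    Deaths per cell are ``Binomial(n, 1 - S(t, T))``, reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    assays = []
    for T, t, n in design:
        if n < 1:
            raise ValueError("each cell needs n >= 1")
        p_dead = 1.0 - survival(t, T, p)
        assays.append(
            SurvivalAssay(temperature=T, exposure=t, n_exposed=n,
                          n_dead=int(rng.binomial(n, p_dead)))
        )
    return assays


def assays_to_frame(assays, species: str = "synthetic") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": species,
            "temperature_c": [a.temperature for a in assays],
            "exposure_h": [a.exposure for a in assays],
            "n_exposed": [a.n_exposed for a in assays],
            "n_dead": [a.n_dead for a in assays],
        }
    )


@dataclass(frozen=True)
class ColdSnap:
    """A scheduled depression of the baseline: `depth` degC for `duration_h`
    hours starting at `start` (Timestamp-like)."""

    start: pd.Timestamp
    duration_h: float
    depth: float


@dataclass
class WeatherScenario:
    """Parameters of the synthetic temperature process.

    temp(t) = annual_mean
              + annual_amplitude * cos(2 pi (doy - 196) / 365.25)   # peak mid-July
              + diurnal_amplitude * cos(2 pi (hour - 15) / 24)      # peak 3 pm
              + AR(1) noise - scheduled snap depths
    """

    annual_mean: float = 14.0
    annual_amplitude: float = 12.0
    diurnal_amplitude: float = 4.0
    noise_sd: float = 2.0
    ar_coef: float = 0.8
    snaps: tuple = ()
    resolution_minutes: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.annual_amplitude < 0 or self.diurnal_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("AR coefficient must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def gen_temperature_series(
    scenario: WeatherScenario, start, end, station_id: str = "SYN"
) -> TemperatureSeries:
    """Deterministic (per seed) synthetic series on [start, end)."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end <= start:
        raise ValueError("end must be after start")
    idx = pd.date_range(start, end, freq=f"{int(scenario.resolution_minutes)}min",
                        inclusive="left")
    doy = idx.dayofyear.to_numpy()
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    temps = (
        scenario.annual_mean
        + scenario.annual_amplitude * np.cos(2 * np.pi * (doy - 196) / 365.25)
        + scenario.diurnal_amplitude * np.cos(2 * np.pi * (hour - 15) / 24.0)
    )
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        innov_sd = scenario.noise_sd * np.sqrt(1 - scenario.ar_coef**2)
        e = rng.normal(0.0, innov_sd, size=len(idx))
        from scipy.signal import lfilter

        noise = lfilter([1.0], [1.0, -scenario.ar_coef], e)
        temps = temps + noise
    for snap in scenario.snaps:
        s0 = pd.Timestamp(snap.start)
        s1 = s0 + pd.Timedelta(hours=snap.duration_h)
        mask = (idx >= s0) & (idx < s1)
        temps = np.where(mask, temps - snap.depth, temps)
    temps = np.clip(temps, -60.0, 60.0)
    return TemperatureSeries(station_id, idx, temps, scenario.resolution_minutes)


def gen_station_network(
    n_stations: int,
    severity_gradient: float = 1.5,
    seed: int = 0,
    n_years: int = 12,
    start_year: int = 2005,
    lat_range=(28.0, 46.0),
    lon_range=(-95.0, -80.0),
    resolution_minutes: float = 60.0,
    noise_sd: float = 1.5,
):
    """A lat/lon station grid whose winters grow colder with latitude.

    ``severity_gradient`` is the drop in annual-mean temperature per degree
    of latitude.  Every station gets ``n_years`` complete July-June years so
    default QC passes.  Returns ``(meta DataFrame, {station_id: series})``.
    """
    if n_stations < 3:
        raise ValueError("need at least 3 stations")
    side = int(np.ceil(np.sqrt(n_stations)))
    lats = np.linspace(lat_range[0], lat_range[1], side)
    lons = np.linspace(lon_range[0], lon_range[1], side)
    coords = [(la, lo) for la in lats for lo in lons][:n_stations]
    rng = np.random.default_rng(seed)
    meta_rows, series = [], {}
    start = pd.Timestamp(start_year, 7, 1)
    end = pd.Timestamp(start_year + n_years, 7, 1)
    for i, (la, lo) in enumerate(coords):
        sid = f"SYN{i:03d}"
        scen = WeatherScenario(
            annual_mean=20.0 - severity_gradient * (la - lat_range[0]),
            annual_amplitude=12.0,
            diurnal_amplitude=4.0,
            noise_sd=noise_sd,
            ar_coef=0.8,
            resolution_minutes=resolution_minutes,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        series[sid] = gen_temperature_series(scen, start, end, station_id=sid)
        meta_rows.append({"station_id": sid, "lat": la, "lon": lo})
    return pd.DataFrame(meta_rows), series


def gen_occurrences(
    n: int,
    clusters=((30.0, -90.0, 5.0),),
    seed: int = 0,
) -> pd.DataFrame:
    """Clustered occurrence points: each cluster is (lat, lon, sd_km); the
    n points are spread evenly over clusters with Gaussian scatter."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        clat, clon, sd_km = clusters[i % len(clusters)]
        dlat = rng.normal(0, sd_km) / 111.32
        dlon = rng.normal(0, sd_km) / (111.32 * np.cos(np.radians(clat)))
        rows.append({"id": f"occ{i:04d}", "lat": clat + dlat, "lon": clon + dlon})
    return pd.DataFrame(rows)
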