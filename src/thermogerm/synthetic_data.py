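"""Synthetic assays and station networks with known ground truth.

Two generators back the test suite and the worked examples:

* a smooth "true" germination surface over (t_cool, t_warm) from which
  binomial assay tables are simulated, so surface-recovery claims can be
  checked against a known target; and
* a synthetic station network with latitude-driven seasonal Tmin/Tmax
  cycles standing in for a national observation network.

Neither generator attempts climate realism; see the methods note for what
they do and do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .germination_data import (
    GerminationObservation,
    GerminationTable,
    TemperatureRegime,
    half_grid_regimes,
)

__all__ = [
    "SurfaceParams",
    "StationRecord",
    "true_surface",
    "simulate_assay",
    "simulate_station_network",
    "stations_to_frame",
]

#: Hours of the cool (16 h) and warm (8 h) period per diurnal cycle.
COOL_HOURS, WARM_HOURS = 16.0, 8.0


@dataclass(frozen=True)
class SurfaceParams:
    """Parameters of the synthetic germination response surface.

    The surface is a product of two Gaussians — one in the duty-cycle
    weighted mean temperature T̄ = (16·t1 + 8·t2)/24, one in the diurnal
    differential Δ = t2 − t1 — with a hard viability window
    [t_base, t_ceiling].  Defaults mimic a cool-season turfgrass: peak
    germination ~85 % near T̄ ≈ 22 °C with a preferred day/night spread of
    ~8 °C, and fluctuation-free (Δ = 0) regimes visibly suppressed.
    """

    g_max: float = 0.85
    mu_t: float = 22.0
    sigma_t: float = 6.0
    mu_d: float = 8.0
    sigma_d: float = 6.0
    t_base: float = 5.0
    t_ceiling: float = 37.0

    def __post_init__(self) -> None:
        if not 0.0 < self.g_max <= 1.0:
            raise ValueError("g_max must be in (0, 1]")
        if self.sigma_t <= 0 or self.sigma_d <= 0:
            raise ValueError("sigma_t and sigma_d must be positive")
        if self.t_base >= self.t_ceiling:
            raise ValueError("t_base must be below t_ceiling")


@dataclass(frozen=True)
class StationRecord:
    """One station-month of a synthetic temperature climatology."""

    station_id: str
    lon: float
    lat: float
    month: int
    tmin_mean: float
    tmax_mean: float

    def __post_init__(self) -> None:
        if self.tmax_mean < self.tmin_mean:
            raise ValueError("tmax_mean must be >= tmin_mean")
        if not 1 <= self.month <= 12:
            raise ValueError("month must be in 1..12")


def true_surface(t1, t2, params: SurfaceParams = SurfaceParams()):
    """Noiseless germination fraction at cool/warm temperatures (t1, t2).

    Vectorized over numpy-broadcastable inputs; returns values in
    [0, g_max], exactly 0 outside the [t_base, t_ceiling] window.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    t_mean = (COOL_HOURS * t1 + WARM_HOURS * t2) / (COOL_HOURS + WARM_HOURS)
    delta = t2 - t1
    g = (
        params.g_max
        * np.exp(-((t_mean - params.mu_t) ** 2) / (2.0 * params.sigma_t**2))
        * np.exp(-((delta - params.mu_d) ** 2) / (2.0 * params.sigma_d**2))
    )
    inside = (
        (t1 >= params.t_base)
        & (t1 <= params.t_ceiling)
        & (t2 >= params.t_base)
        & (t2 <= params.t_ceiling)
    )
    out = np.where(inside, g, 0.0)
    return float(out) if out.ndim == 0 else out


def _regime_rng(seed: int, regime: TemperatureRegime) -> np.random.Generator:
    # Substream keyed on the regime itself so tables are reproducible
    # regardless of regime evaluation order.
    return np.random.default_rng(
        [int(seed), int(round(regime.t_cool * 10)), int(round(regime.t_warm * 10))]
    )


def simulate_assay(
    params: SurfaceParams,
    regimes: Sequence[TemperatureRegime] | None = None,
    n_seeds: int = 50,
    n_reps: int = 3,
    seed: int = 0,
    cultivar: str = "synthetic",
) -> GerminationTable:
    """Simulate one cultivar's assay: Binomial(n_seeds, surface) counts.

    Each replicate's germinated-seed count is drawn from a binomial at the
    true surface value; the stored cell mean and sample SD are computed
    from the simulated replicate percentages.  Same seed → same table.
    """
    if regimes is None:
        regimes = half_grid_regimes()
    temps = tuple(sorted({t for r in regimes for t in r}))
    obs = []
    for regime in regimes:
        p = float(true_surface(regime.t_cool, regime.t_warm, params))
        rng = _regime_rng(seed, regime)
        counts = rng.binomial(n_seeds, p, size=n_reps)
        pcts = counts * 100.0 / n_seeds
        sd = float(np.std(pcts, ddof=1)) if n_reps > 1 else 0.0
        obs.append(
            GerminationObservation(
                regime=regime,
                mean_pct=float(np.mean(pcts)),
                sd_pct=sd,
                n_reps=n_reps,
                n_seeds=n_seeds,
                replicate_pcts=tuple(float(v) for v in pcts),
            )
        )
    return GerminationTable(cultivar=cultivar, observations=obs, temps=temps)


def simulate_station_network(
    n_stations: int,
    lon_range: tuple[float, float] = (75.0, 130.0),
    lat_range: tuple[float, float] = (18.0, 50.0),
    seed: int = 0,
    noise_sd: float = 1.0,
) -> list[StationRecord]:
    """Synthetic monthly Tmin/Tmax climatology for a station network.

    The monthly mean temperature at a station is a latitude-linear annual
    mean plus a sinusoidal seasonal cycle (peaking in July) whose
    amplitude grows with latitude, plus optional station-level noise.
    The diurnal range tmax − tmin is drawn uniformly in [4, 14] °C per
    station.  Deterministic under ``seed``.
    """
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    rng = np.random.default_rng(seed)
    lons = rng.uniform(*lon_range, size=n_stations)
    lats = rng.uniform(*lat_range, size=n_stations)
    diurnal = rng.uniform(4.0, 14.0, size=n_stations)
    offsets = rng.normal(0.0, noise_sd, size=n_stations)
    records: list[StationRecord] = []
    months = np.arange(1, 13)
    for i in range(n_stations):
        annual_mean = 32.0 - 0.55 * lats[i] + offsets[i]
        amplitude = 2.0 + 0.45 * lats[i]
        tmean = annual_mean + amplitude * np.cos(2.0 * np.pi * (months - 7) / 12.0)
        for m, tm in zip(months, tmean):
            records.append(
                StationRecord(
                    station_id=f"S{i:04d}",
                    lon=float(lons[i]),
                    lat=float(lats[i]),
                    month=int(m),
                    tmin_mean=float(tm - diurnal[i] / 2.0),
                    tmax_mean=float(tm + diurnal[i] / 2.0),
                )
            )
    return records


def stations_to_frame(records: Sequence[StationRecord]) -> pd.DataFrame:
    """Station records as a DataFrame in the station CSV column order."""
    return pd.DataFrame(
        [
            {
                "station_id": r.station_id,
                "lon": r.lon,
                "lat": r.lat,
                "month": r.month,
                "tmin_mean_c": r.tmin_mean,
                "tmax_mean_c": r.tmax_mean,
            }
            for r in records
        ]
    )
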