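"""Monthly sowing-suitability grids from a fitted germination model.

Pipeline: station temperature records → per-station monthly climatology →
Cressman successive-correction interpolation of monthly mean daily Tmin
and Tmax onto a lon/lat grid → per-cell model prediction, with the mean
daily minimum as the cool-period input T1 and the mean daily maximum as
the warm-period input T2.  Cells whose temperatures fall outside the
5–40 °C calibration envelope are clamped to it and flagged as
extrapolated.

Cressman analysis: starting from a constant background (the station
mean), each pass with influence radius R corrects every grid value by
Σ wᵢeᵢ / Σ wᵢ over stations within R, where eᵢ is the station residual
against the current analysis and wᵢ = (R² − dᵢ²)/(R² + dᵢ²).  Radii
shrink across passes so large-scale structure is drawn first and local
detail last.  Cells never inside any radius keep the background value
and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_data import StationRecord

__all__ = [
    "GridSpec",
    "Grid",
    "SuitabilityMap",
    "DEFAULT_RADII_KM",
    "CALIBRATION_ENVELOPE",
    "monthly_climatology",
    "cressman",
    "predict_suitability",
    "export_map",
]

EARTH_RADIUS_KM = 6371.0

#: Default successive-correction radii (km), one pass each.
DEFAULT_RADII_KM = (1000.0, 700.0, 400.0, 200.0)

#: Temperature range (°C) covered by the germination assay.
CALIBRATION_ENVELOPE = (5.0, 40.0)


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: origin, step and count per axis."""

    lon0: float
    lat0: float
    step: float
    nlon: int
    nlat: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.nlon < 1 or self.nlat < 1:
            raise ValueError("grid counts must be >= 1")

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.step * np.arange(self.nlon)

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.step * np.arange(self.nlat)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.lons, self.lats)


@dataclass
class Grid:
    """Gridded field: values[ilat, ilon], with a background-only flag."""

    spec: GridSpec
    values: np.ndarray
    background_only: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.nlat, self.spec.nlon):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"grid ({self.spec.nlat}, {self.spec.nlon})"
            )
        if self.background_only is None:
            self.background_only = np.zeros(self.values.shape, dtype=bool)


@dataclass
class SuitabilityMap:
    """Monthly grid of predicted germination fraction for one cultivar."""

    cultivar: str
    month: int
    grid: Grid
    extrapolated: np.ndarray
    provenance: dict = field(default_factory=dict)


def monthly_climatology(records: pd.DataFrame | Sequence[StationRecord]) -> pd.DataFrame:
    """Per-station monthly mean (tmin, tmax) from daily or monthly records.

    Accepts a DataFrame with columns station_id, lon, lat, month,
    tmin_mean_c, tmax_mean_c (extra rows per station-month — e.g. daily
    values or multiple years — are averaged) or a sequence of
    :class:`StationRecord`.  Station-months with no data are simply
    absent from the output; tmax >= tmin is enforced by clipping.
    """
    if not isinstance(records, pd.DataFrame):
        from .synthetic_data import stations_to_frame

        records = stations_to_frame(records)
    required = {"station_id", "lon", "lat", "month", "tmin_mean_c", "tmax_mean_c"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    if records.empty:
        raise ValueError("no station records")
    out = (
        records.groupby(["station_id", "lon", "lat", "month"], as_index=False)[
            ["tmin_mean_c", "tmax_mean_c"]
        ]
        .mean()
        .sort_values(["station_id", "month"], ignore_index=True)
    )
    out["tmax_mean_c"] = np.maximum(out["tmax_mean_c"], out["tmin_mean_c"])
    return out


def _haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (km); inputs in degrees, broadcastable."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _bilinear_at(spec: GridSpec, values: np.ndarray, lon, lat) -> np.ndarray:
    """Bilinear interpolation of the analysis at station locations."""
    fx = np.clip((np.asarray(lon) - spec.lon0) / spec.step, 0, spec.nlon - 1)
    fy = np.clip((np.asarray(lat) - spec.lat0) / spec.step, 0, spec.nlat - 1)
    x0 = np.clip(np.floor(fx).astype(int), 0, max(spec.nlon - 2, 0))
    y0 = np.clip(np.floor(fy).astype(int), 0, max(spec.nlat - 2, 0))
    x1 = np.minimum(x0 + 1, spec.nlon - 1)
    y1 = np.minimum(y0 + 1, spec.nlat - 1)
    tx = fx - x0
    ty = fy - y0
    v00 = values[y0, x0]
    v01 = values[y0, x1]
    v10 = values[y1, x0]
    v11 = values[y1, x1]
    return (
        v00 * (1 - tx) * (1 - ty)
        + v01 * tx * (1 - ty)
        + v10 * (1 - tx) * ty
        + v11 * tx * ty
    )


def cressman(
    stations,
    spec: GridSpec,
    radii_km: Sequence[float] = DEFAULT_RADII_KM,
    n_iterations_per_radius: int = 1,
) -> Grid:
    """Cressman successive-correction analysis of station values.

    ``stations`` is an iterable of (lon, lat, value).  Radii must be
    strictly decreasing.  The background field is the station mean; cells
    never within any radius of a station keep it and are flagged via
    ``Grid.background_only``.
    """
    st = np.asarray(list(stations), dtype=float)
    if st.size == 0:
        raise ValueError("cressman needs at least one station")
    if st.ndim != 2 or st.shape[1] != 3:
        raise ValueError("stations must be (lon, lat, value) triples")
    radii = list(radii_km)
    if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])) or not radii:
        raise ValueError("radii must be a non-empty strictly decreasing list")

    lon_g, lat_g = spec.mesh()
    # distances: cells × stations
    d = _haversine_km(
        lon_g.ravel()[:, None],
        lat_g.ravel()[:, None],
        st[None, :, 0],
        st[None, :, 1],
    )
    values = np.full(lon_g.size, st[:, 2].mean())
    touched = np.zeros(lon_g.size, dtype=bool)
    for r in radii:
        w = (r**2 - d**2) / (r**2 + d**2)
        w[d >= r] = 0.0
        wsum = w.sum(axis=1)
        reachable = wsum > 0
        touched |= reachable
        for _ in range(n_iterations_per_radius):
            analysis_at_st = _bilinear_at(
                spec, values.reshape(spec.nlat, spec.nlon), st[:, 0], st[:, 1]
            )
            resid = st[:, 2] - analysis_at_st
            corr = np.zeros_like(values)
            corr[reachable] = (w[reachable] @ resid) / wsum[reachable]
            values = values + corr
    return Grid(
        spec=spec,
        values=values.reshape(spec.nlat, spec.nlon),
        background_only=(~touched).reshape(spec.nlat, spec.nlon),
    )


def predict_suitability(
    model,
    tmin_grid: Grid,
    tmax_grid: Grid,
    cultivar: str = "",
    month: int = 0,
    envelope: tuple[float, float] = CALIBRATION_ENVELOPE,
) -> SuitabilityMap:
    """Evaluate a fitted germination model over aligned Tmin/Tmax grids.

    T1 (cool period) is the monthly mean daily minimum and T2 (warm
    period) the monthly mean daily maximum.  Inputs outside the
    calibration envelope are clamped to it and the cell flagged as
    extrapolated; predictions are clamped to [0, 1].
    """
    if tmin_grid.spec != tmax_grid.spec:
        raise ValueError("tmin and tmax grids are not aligned")
    lo, hi = envelope
    t1 = tmin_grid.values
    t2 = np.maximum(tmax_grid.values, t1)  # enforce warm >= cool
    extrapolated = (t1 < lo) | (t1 > hi) | (t2 < lo) | (t2 > hi)
    t1c = np.clip(t1, lo, hi)
    t2c = np.clip(t2, lo, hi)
    pred = np.clip(model.predict(t1c, t2c), 0.0, 1.0)
    grid = Grid(
        spec=tmin_grid.spec,
        values=pred,
        background_only=tmin_grid.background_only | tmax_grid.background_only,
    )
    return SuitabilityMap(
        cultivar=cultivar,
        month=month,
        grid=grid,
        extrapolated=extrapolated,
        provenance={
            "model": type(model).__name__,
            "envelope_c": envelope,
            "extrapolated_fraction": float(extrapolated.mean()),
        },
    )


def export_map(smap: SuitabilityMap, path, render_png: str | None = None) -> None:
    """Write a suitability map as a deterministic CSV grid.

    Columns: lon, lat, value, extrapolated (0/1).  Optionally also render
    a PNG with a perceptually uniform color ramp (viridis, 0 → unsuitable,
    1 → fully suitable).
    """
    grid = smap.grid
    if grid.values.size == 0:
        raise ValueError("cannot export an empty grid")
    lon_g, lat_g = grid.spec.mesh()
    lines = ["lon,lat,value,extrapolated"]
    for lat_i in range(grid.spec.nlat):
        for lon_i in range(grid.spec.nlon):
            lines.append(
                f"{lon_g[lat_i, lon_i]:.4f},{lat_g[lat_i, lon_i]:.4f},"
                f"{grid.values[lat_i, lon_i]:.6f},"
                f"{int(smap.extrapolated[lat_i, lon_i])}"
            )
    text = "\n".join(lines) + "\n"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(text)
    if render_png:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        im = ax.pcolormesh(
            grid.spec.lons, grid.spec.lats, grid.values, cmap="viridis",
            vmin=0.0, vmax=1.0, shading="nearest",
        )
        fig.colorbar(im, ax=ax, label="predicted germination fraction")
        ax.set_xlabel("longitude (°E)")
        ax.set_ylabel("latitude (°N)")
        ax.set_title(f"{smap.cultivar} — month {smap.month}")
        fig.tight_layout()
        fig.savefig(render_png, dpi=120)
        plt.close(fig)
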