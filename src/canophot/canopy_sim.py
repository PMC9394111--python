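"""Couple light maps and tissue physiology into canopy gas exchange.

Canopy photosynthetic CO2 uptake is the area-weighted sum of the
nonrectangular-hyperbola rates of every patch, normalised by the ground area
of the analysis region.  A diurnal run traces light once per weather step
(dark steps skip tracing), evaluates each patch, and integrates the per-
tissue ledger trapezoidally to daily sums of net and gross photosynthesis
and absorbed light, with tissue shares and light use efficiency
(LUE = daily gross / daily absorbed light).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from canophot.architecture import Canopy, TISSUE_NAMES
from canophot.optics import (
    LightEnvironment,
    LightMap,
    light_environment_from_weather,
    trace_canopy,
)
from canophot.physiology import PhotoParams, assimilation_rate, temperature_multipliers

__all__ = [
    "WeatherSeries",
    "TraceSettings",
    "GasExchangeResult",
    "DailyAccounting",
    "instantaneous_exchange",
    "simulate_day",
    "canopy_temperature_response",
]


@dataclass
class WeatherSeries:
    """Diurnal weather drivers at a fixed cadence.

    ``frame`` columns: time (pandas Timestamp), ppfd_total (umol m-2 s-1),
    direct_fraction in [0, 1], temp_C.
    """

    frame: pd.DataFrame
    latitude: float = 30.945
    longitude: float = 121.134

    def __post_init__(self):
        df = self.frame
        needed = {"time", "ppfd_total", "direct_fraction", "temp_C"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"weather frame lacks columns {sorted(missing)}")
        t = pd.to_datetime(df["time"])
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("weather timestamps must be strictly increasing")
        if (df["ppfd_total"] < 0).any():
            raise ValueError("PPFD must be non-negative")
        if ((df["direct_fraction"] < 0) | (df["direct_fraction"] > 1)).any():
            raise ValueError("direct_fraction must lie in [0, 1]")
        self.frame = df.assign(time=t).reset_index(drop=True)

    @property
    def seconds(self) -> np.ndarray:
        t = self.frame["time"]
        return (t - t.iloc[0]).dt.total_seconds().to_numpy()

    def check_gapless(self):
        dt = np.diff(self.seconds)
        if len(dt) and np.any(dt > 1.5 * np.median(dt)):
            raise ValueError("gap larger than one timestep in weather series")


@dataclass(frozen=True)
class TraceSettings:
    rays_direct: int = 40_000
    rays_diffuse: int = 20_000
    seed: int = 0
    roughness: float = 0.3
    analysis_window: Optional[tuple] = None  # ((x0, x1), (y0, y1)) in m


@dataclass
class GasExchangeResult:
    """Instantaneous per-tissue and per-organ exchange, umol m-2(ground) s-1."""

    per_tissue: pd.DataFrame  # index tissue name; net, gross, respiration, absorbed
    per_organ: pd.DataFrame
    canopy_net: float
    canopy_gross: float
    canopy_respiration: float
    canopy_absorbed: float


@dataclass
class DailyAccounting:
    """Per-tissue daily ledger in mol m-2(ground) day-1 plus shares and LUE."""

    table: pd.DataFrame  # index tissue; an, ag, ia, an_share, ag_share, ia_share, lue
    canopy_an: float
    canopy_ag: float
    canopy_ia: float
    diurnal_an: float  # 6:00-18:00 window
    window: tuple = (6.0, 18.0)


def _region_mask(canopy: Canopy, window):
    if window is None:
        return np.ones(len(canopy.mesh), dtype=bool), canopy.domain[0] * canopy.domain[1]
    (x0, x1), (y0, y1) = window
    cent = canopy.mesh.triangles.mean(axis=1)
    mask = ((cent[:, 0] >= x0) & (cent[:, 0] < x1)
            & (cent[:, 1] >= y0) & (cent[:, 1] < y1))
    return mask, (x1 - x0) * (y1 - y0)


def instantaneous_exchange(canopy: Canopy, lightmap: LightMap,
                           temperature: float,
                           params_by_tissue: Mapping[int, PhotoParams],
                           analysis_window: Optional[tuple] = None,
                           ) -> GasExchangeResult:
    """Evaluate every patch under its absorbed flux and sum per tissue/organ."""
    mesh = canopy.mesh
    if len(lightmap.absorbed_ppfd) != len(mesh):
        raise ValueError("light map does not match the canopy patch set")
    mask, ground_area = _region_mask(canopy, analysis_window)
    areas = mesh.areas()
    rows_t, rows_o = [], []
    for code, p in params_by_tissue.items():
        m = mask & (mesh.tissue == code)
        if not np.any(m):
            continue
        _, q2 = temperature_multipliers(temperature, p)
        net = assimilation_rate(lightmap.absorbed_ppfd[m], temperature, p)
        resp = p.rd_25 * float(q2)
        a = areas[m]
        net_sum = float(np.sum(net * a)) / ground_area
        resp_sum = float(resp * a.sum()) / ground_area
        absorbed = float(np.sum(lightmap.absorbed_ppfd[m] * a)) / ground_area
        rows_t.append((TISSUE_NAMES[code], net_sum, net_sum + resp_sum,
                       resp_sum, absorbed))
        for oid in np.unique(mesh.organ_id[m]):
            mo = m & (mesh.organ_id == oid)
            neto = float(np.sum(assimilation_rate(
                lightmap.absorbed_ppfd[mo], temperature, p) * areas[mo])) / ground_area
            respo = float(resp * areas[mo].sum()) / ground_area
            abso = float(np.sum(lightmap.absorbed_ppfd[mo] * areas[mo])) / ground_area
            rows_o.append((TISSUE_NAMES[code], int(oid), neto, neto + respo,
                           respo, abso))
    per_tissue = pd.DataFrame(
        rows_t, columns=["tissue", "net", "gross", "respiration", "absorbed"]
    ).set_index("tissue")
    per_organ = pd.DataFrame(
        rows_o, columns=["tissue", "organ_id", "net", "gross", "respiration",
                         "absorbed"])
    return GasExchangeResult(
        per_tissue=per_tissue,
        per_organ=per_organ,
        canopy_net=float(per_tissue["net"].sum()),
        canopy_gross=float(per_tissue["gross"].sum()),
        canopy_respiration=float(per_tissue["respiration"].sum()),
        canopy_absorbed=float(per_tissue["absorbed"].sum()),
    )


def _dark_exchange(canopy, temperature, params_by_tissue, analysis_window):
    zero = LightMap(
        absorbed_ppfd=np.zeros(len(canopy.mesh)),
        incident_ppfd=np.zeros(len(canopy.mesh)),
        injected=0.0, canopy_absorbed=0.0, ground_absorbed=0.0, escaped=0.0,
        discarded=0.0, seed=0, rays_direct=0, rays_diffuse=0)
    return instantaneous_exchange(canopy, zero, temperature, params_by_tissue,
                                  analysis_window)


def simulate_day(canopy: Canopy, weather: WeatherSeries,
                 params_by_tissue: Mapping[int, PhotoParams],
                 trace: TraceSettings = TraceSettings(),
                 ) -> tuple:
    """One trace + exchange per weather step; trapezoidal daily integration.

    Returns ``(steps, accounting)`` where ``steps`` is a DataFrame of canopy
    rates per timestep and ``accounting`` the per-tissue DailyAccounting.
    """
    weather.check_gapless()
    df = weather.frame
    secs = weather.seconds
    results = []
    for k, rec in enumerate(df.itertuples()):
        if rec.ppfd_total <= 0:
            res = _dark_exchange(canopy, rec.temp_C, params_by_tissue,
                                 trace.analysis_window)
        else:
            env = light_environment_from_weather(rec, weather.latitude,
                                                 weather.longitude)
            if env.total_ppfd <= 0:
                res = _dark_exchange(canopy, rec.temp_C, params_by_tissue,
                                     trace.analysis_window)
            else:
                lm = trace_canopy(canopy, env, trace.rays_direct,
                                  trace.rays_diffuse, trace.seed + k,
                                  roughness=trace.roughness)
                res = instantaneous_exchange(canopy, lm, rec.temp_C,
                                             params_by_tissue,
                                             trace.analysis_window)
        results.append(res)

    steps = pd.DataFrame({
        "time": df["time"],
        "ppfd_total": df["ppfd_total"],
        "temp_C": df["temp_C"],
        "canopy_net": [r.canopy_net for r in results],
        "canopy_gross": [r.canopy_gross for r in results],
        "canopy_respiration": [r.canopy_respiration for r in results],
        "canopy_absorbed": [r.canopy_absorbed for r in results],
    })

    tissues = sorted({t for r in results for t in r.per_tissue.index})
    rows = []
    hours = df["time"].dt.hour + df["time"].dt.minute / 60.0
    in_window = ((hours >= 6.0) & (hours <= 18.0)).to_numpy()
    for t in tissues:
        series = {}
        for col in ("net", "gross", "absorbed"):
            y = np.array([
                r.per_tissue[col].get(t, 0.0) for r in results])
            series[col] = y
        an = np.trapezoid(series["net"], secs) * 1e-6
        ag = np.trapezoid(series["gross"], secs) * 1e-6
        ia = np.trapezoid(series["absorbed"], secs) * 1e-6
        rows.append((t, an, ag, ia))
    table = pd.DataFrame(rows, columns=["tissue", "an", "ag", "ia"]).set_index("tissue")
    c_an, c_ag, c_ia = table["an"].sum(), table["ag"].sum(), table["ia"].sum()
    table["an_share"] = 100.0 * table["an"] / c_an if c_an != 0 else np.nan
    table["ag_share"] = 100.0 * table["ag"] / c_ag if c_ag != 0 else np.nan
    table["ia_share"] = 100.0 * table["ia"] / c_ia if c_ia != 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        table["lue"] = np.where(table["ia"] > 0, table["ag"] / table["ia"], 0.0)

    net_c = steps["canopy_net"].to_numpy()
    if in_window.sum() >= 2:
        diurnal = np.trapezoid(net_c[in_window], secs[in_window]) * 1e-6
    else:
        diurnal = 0.0
    acc = DailyAccounting(table=table, canopy_an=float(c_an),
                          canopy_ag=float(c_ag), canopy_ia=float(c_ia),
                          diurnal_an=float(diurnal))
    return steps, acc


def canopy_temperature_response(canopy: Canopy,
                                weather_ensemble: Sequence[WeatherSeries],
                                params_by_tissue: Mapping[int, PhotoParams],
                                trace: TraceSettings = TraceSettings(),
                                hl_threshold: float = 1500.0,
                                ) -> tuple:
    """Canopy-level temperature responses from a weather ensemble.

    Collects canopy net rates at steps with incident PPFD above
    ``hl_threshold`` (normalised to 1 at 20 degC) and night respiration
    (normalised to 1 at 10 degC), binned by air temperature.  Identical light
    environments are traced once and re-used across temperatures.
    """
    cache = {}
    hl_rows, rcd_rows = [], []
    for weather in weather_ensemble:
        for k, rec in enumerate(weather.frame.itertuples()):
            t_air = float(rec.temp_C)
            if rec.ppfd_total > hl_threshold:
                key = (round(rec.ppfd_total, 3), round(rec.direct_fraction, 4),
                       rec.time.hour, rec.time.minute)
                if key not in cache:
                    env = light_environment_from_weather(
                        rec, weather.latitude, weather.longitude)
                    cache[key] = trace_canopy(
                        canopy, env, trace.rays_direct, trace.rays_diffuse,
                        trace.seed, roughness=trace.roughness)
                res = instantaneous_exchange(canopy, cache[key], t_air,
                                             params_by_tissue,
                                             trace.analysis_window)
                hl_rows.append((t_air, res.canopy_net))
            elif rec.ppfd_total <= 0:
                res = _dark_exchange(canopy, t_air, params_by_tissue,
                                     trace.analysis_window)
                rcd_rows.append((t_air, -res.canopy_net))

    def _bin(rows, norm_t):
        if not rows:
            return pd.DataFrame(columns=["temp_C", "value", "normalized"])
        df = pd.DataFrame(rows, columns=["temp_C", "value"])
        df["bin"] = df["temp_C"].round(1)
        g = df.groupby("bin", as_index=False).agg(
            temp_C=("temp_C", "mean"), value=("value", "mean"))
        ref_idx = (g["temp_C"] - norm_t).abs().idxmin()
        ref = g.loc[ref_idx, "value"]
        g["normalized"] = g["value"] / ref if ref != 0 else np.nan
        return g[["temp_C", "value", "normalized"]]

    return _bin(rcd_rows, 10.0), _bin(hl_rows, 20.0)
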