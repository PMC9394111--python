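"""In-silico canopy experiments: paired what-if pipelines over canopy_sim.

Every scenario runs a baseline and a perturbed leg with identical seeds and
ray counts, so the difference isolates the treatment from Monte-Carlo noise.
Each result carries a provenance block (config hash, seeds, ray counts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from canophot.architecture import (
    Canopy,
    PerturbationSpec,
    TillerBlueprint,
    apply_perturbation,
    assemble_canopy,
    build_tiller,
)
from canophot.canopy_sim import (
    DailyAccounting,
    TraceSettings,
    WeatherSeries,
    simulate_day,
)
from canophot.physiology import PhotoParams

__all__ = [
    "FilmSpec",
    "SweepSpec",
    "ScenarioContext",
    "film_scenario",
    "spike_removal_scenario",
    "trait_sweep",
    "capacity_sweep",
]


@dataclass(frozen=True)
class FilmSpec:
    """A top cover: transmittance and haze (direct light turned diffuse)."""

    transmittance: float
    haze: float

    def __post_init__(self):
        for name in ("transmittance", "haze"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter scan: what to move and through which values."""

    target: str  # e.g. "lnc", "awn_length", "density", "amax_net", "phi"
    values: tuple
    tissues: tuple = ("leaf",)  # tissue classes moved together

    _TARGETS = ("lnc", "awn_length", "spike_length", "spikelet_size",
                "density", "amax_net", "phi", "height")

    def __post_init__(self):
        if self.target not in self._TARGETS:
            raise ValueError(f"unknown sweep target {self.target!r}")
        if not self.values:
            raise ValueError("sweep needs at least one value")


@dataclass
class ScenarioContext:
    """Everything a scenario needs to (re)build and simulate a canopy."""

    library: Sequence[TillerBlueprint]
    row_spacing: float
    in_row_spacing: float
    domain: tuple
    alpha0: float
    assembly_seed: int
    weather: WeatherSeries
    params_by_tissue: Mapping[int, PhotoParams]
    trace: TraceSettings = field(default_factory=TraceSettings)
    leaf_segments: int = 10
    nitrogen_response: object = None  # NitrogenResponse for LNC sweeps
    _canopy: Optional[Canopy] = None

    def canopy(self) -> Canopy:
        if self._canopy is None:
            meshes = [build_tiller(bp, leaf_segments=self.leaf_segments)
                      for bp in self.library]
            self._canopy = assemble_canopy(
                meshes, self.row_spacing, self.in_row_spacing, self.domain,
                self.alpha0, self.assembly_seed)
        return self._canopy

    def provenance(self, scenario: str, extra: Optional[dict] = None) -> dict:
        cfg = {
            "scenario": scenario,
            "row_spacing": self.row_spacing,
            "in_row_spacing": self.in_row_spacing,
            "domain": list(self.domain),
            "alpha0": self.alpha0,
            "assembly_seed": self.assembly_seed,
            "trace_seed": self.trace.seed,
            "rays_direct": self.trace.rays_direct,
            "rays_diffuse": self.trace.rays_diffuse,
            "n_tillers_library": len(self.library),
            **(extra or {}),
        }
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
        return {"config": cfg, "config_hash": digest}


def _run(ctx: ScenarioContext, canopy: Canopy, weather: WeatherSeries,
         params=None):
    return simulate_day(canopy, weather,
                        params or ctx.params_by_tissue, ctx.trace)


def _filmed_weather(weather: WeatherSeries, film: FilmSpec) -> WeatherSeries:
    df = weather.frame.copy()
    direct = df["ppfd_total"] * df["direct_fraction"] * (1.0 - film.haze)
    diffuse = (df["ppfd_total"] * (1.0 - df["direct_fraction"])
               + df["ppfd_total"] * df["direct_fraction"] * film.haze)
    total = (direct + diffuse) * film.transmittance
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, direct * film.transmittance / total, 0.0)
    df["ppfd_total"] = total
    df["direct_fraction"] = frac
    return WeatherSeries(df, weather.latitude, weather.longitude)


def film_scenario(ctx: ScenarioContext, film: FilmSpec) -> dict:
    """Bare versus top-covered canopy; same canopy, same seeds.

    The film multiplies total PPFD by its transmittance and converts the
    haze share of direct light into diffuse before tracing.
    """
    canopy = ctx.canopy()
    _, bare = _run(ctx, canopy, ctx.weather)
    _, filmed = _run(ctx, canopy, _filmed_weather(ctx.weather, film))
    delta_daily = _pct(filmed.canopy_an, bare.canopy_an)
    delta_diurnal = _pct(filmed.diurnal_an, bare.diurnal_an)
    return {
        "bare": bare, "filmed": filmed,
        "delta_daily_acnet_pct": delta_daily,
        "delta_diurnal_acnet_pct": delta_diurnal,
        "provenance": ctx.provenance("film", {
            "transmittance": film.transmittance, "haze": film.haze}),
    }


def spike_removal_scenario(ctx: ScenarioContext) -> dict:
    """Intact versus spike-removed canopy; percent change in diurnal Acnet."""
    canopy = ctx.canopy()
    if not canopy.has_spikes():
        raise ValueError("canopy has no spikes to remove")
    removed = apply_perturbation(canopy, PerturbationSpec("remove_spikes"))
    _, intact = _run(ctx, canopy, ctx.weather)
    _, despiked = _run(ctx, removed, ctx.weather)
    return {
        "intact": intact, "despiked": despiked,
        "delta_diurnal_acnet_pct": _pct(despiked.diurnal_an, intact.diurnal_an),
        "delta_daily_acnet_pct": _pct(despiked.canopy_an, intact.canopy_an),
        "provenance": ctx.provenance("spike_removal"),
    }


def _pct(new, old):
    if old == 0:
        return float("nan")
    return 100.0 * (new - old) / abs(old)


def trait_sweep(ctx: ScenarioContext, sweep: SweepSpec) -> dict:
    """Scan one trait; one paired simulation per value, shared seeds.

    Returns the response table (value, daily Acnet, diurnal Acnet, spike
    daily gross where spikes exist) and its argmax.
    """
    from canophot.architecture import TISSUE_CODES
    from canophot.physiology import params_from_nitrogen

    rows = []
    skipped = []
    for value in sweep.values:
        try:
            ctx_v = ctx
            params = dict(ctx.params_by_tissue)
            if sweep.target == "density":
                # value = (row_spacing, in_row_spacing)
                row, in_row = value
                canopy = apply_perturbation(
                    ctx.canopy(),
                    PerturbationSpec("set_tiller_density", row_spacing=row,
                                     in_row_spacing=in_row),
                    library_blueprints=ctx.library,
                    leaf_segments=ctx.leaf_segments)
            elif sweep.target in ("awn_length", "spike_length",
                                  "spikelet_size", "height"):
                kind = {"awn_length": "scale_awn_length",
                        "spike_length": "scale_spike_length",
                        "spikelet_size": "scale_spikelet_size",
                        "height": "scale_height"}[sweep.target]
                canopy = apply_perturbation(
                    ctx.canopy(), PerturbationSpec(kind, factor=value),
                    library_blueprints=ctx.library,
                    leaf_segments=ctx.leaf_segments)
            elif sweep.target in ("amax_net", "phi"):
                canopy = ctx.canopy()
                for t in sweep.tissues:
                    code = TISSUE_CODES[t]
                    kw = {"amax_net": value} if sweep.target == "amax_net" \
                        else {"phi": value}
                    params[code] = params[code].with_factor(**kw)
            elif sweep.target == "lnc":
                canopy = ctx.canopy()
                nresp = ctx.nitrogen_response
                if nresp is None:
                    raise ValueError("lnc sweep needs ctx.nitrogen_response")
                for t in sweep.tissues:
                    code = TISSUE_CODES[t]
                    base = params[code]
                    params[code] = params_from_nitrogen(
                        value, nresp, base.temp_amax, base.temp_rd)
            _, acc = _run(ctx_v, canopy, ctx.weather, params)
            spike_ag = float(acc.table["ag"].get("spikelet", 0.0)
                             + acc.table["ag"].get("awn", 0.0))
            rows.append((value, acc.canopy_an, acc.diurnal_an, spike_ag))
        except ValueError as err:
            skipped.append((value, str(err)))
    table = pd.DataFrame(rows, columns=["value", "daily_acnet",
                                        "diurnal_acnet", "spike_daily_ag"])
    argmax = table.loc[table["daily_acnet"].idxmax(), "value"] if len(table) else None
    return {
        "table": table, "argmax": argmax, "skipped": skipped,
        "provenance": ctx.provenance("trait_sweep", {
            "target": sweep.target, "values": list(map(str, sweep.values)),
            "tissues": list(sweep.tissues)}),
    }


def capacity_sweep(ctx: ScenarioContext, which: str, tissues: Sequence[str],
                   factor: float) -> dict:
    """Scale amax_net and/or phi of selected tissues; Rd held fixed.

    ``which`` is one of 'amax_net', 'phi', 'both'.  Reports the percent
    change in daily and diurnal Acnet against the shared-seed baseline.
    """
    from canophot.architecture import TISSUE_CODES

    if factor <= 0:
        raise ValueError("factor must be positive")
    if which not in ("amax_net", "phi", "both"):
        raise ValueError("which must be 'amax_net', 'phi' or 'both'")
    canopy = ctx.canopy()
    _, base = _run(ctx, canopy, ctx.weather)
    params = dict(ctx.params_by_tissue)
    for t in tissues:
        code = TISSUE_CODES[t]
        kw = {}
        if which in ("amax_net", "both"):
            kw["amax_net"] = factor
        if which in ("phi", "both"):
            kw["phi"] = factor
        params[code] = params[code].with_factor(**kw)
    _, mod = _run(ctx, canopy, ctx.weather, params)
    return {
        "baseline": base, "modified": mod,
        "delta_daily_acnet_pct": _pct(mod.canopy_an, base.canopy_an),
        "delta_diurnal_acnet_pct": _pct(mod.diurnal_an, base.diurnal_an),
        "provenance": ctx.provenance("capacity_sweep", {
            "which": which, "tissues": list(tissues), "factor": factor}),
    }
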