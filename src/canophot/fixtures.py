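"""Seeded synthetic-data generators: tiller library, weather days, A-Q curves.

These generators stand in for field measurements: a virtual-tiller library
drawn from growth-stage presets (tillering / heading / milking), diurnal
weather at a 10-minute cadence for sunny, cloudy and overcast days, and
light-response curves forward-simulated from known parameters with the
measurement protocol's light-level sequences.

Preset magnitudes are calibrated to plausible wheat: stem heights 0.25-1.0 m
across stages, flag-leaf light-saturated rates in the 20-35 umol m-2 s-1
range, spikes only from heading onward.  The default maximal tiller lean
angle (15 degrees) is a synthetic choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from canophot.architecture import LeafBlueprint, SpikeBlueprint, TillerBlueprint
from canophot.canopy_sim import WeatherSeries
from canophot.optics import solar_position
from canophot.physiology import AQCurve, PhotoParams, assimilation_rate

__all__ = [
    "StagePreset",
    "STAGE_PRESETS",
    "generate_tiller_library",
    "generate_weather_day",
    "generate_aq_curve",
    "default_params_by_tissue",
    "DEFAULT_TISSUE_PARAMS",
    "TEMP_AMAX_QUAD",
    "TEMP_RD_QUAD",
    "LEAF_LIGHT_LEVELS",
    "SPIKE_LIGHT_LEVELS",
]

#: photosynthesis temperature multiplier: quadratic peaking at 25 degC
#: (1 - 0.0014*(T-25)^2), positive over 0..40 degC
TEMP_AMAX_QUAD = (-0.0014, 0.07, 0.125)
#: respiration multiplier: monotonically increasing, ~2x from 25 to 40 degC
TEMP_RD_QUAD = (0.0008, 0.016, 0.1)

#: plausible per-tissue light-response defaults (rates per unit total tissue
#: area); spike tissue respires strongly relative to its capacity, leaves
#: carry the highest light-saturated rates
DEFAULT_TISSUE_PARAMS = {
    "leaf": dict(amax_net_25=25.0, rd_25=1.2, phi_co2=0.055, theta=0.75),
    "stem": dict(amax_net_25=5.0, rd_25=0.4, phi_co2=0.040, theta=0.70),
    "spikelet": dict(amax_net_25=5.0, rd_25=1.0, phi_co2=0.050, theta=0.85),
    "awn": dict(amax_net_25=7.0, rd_25=0.6, phi_co2=0.050, theta=0.85),
}


def default_nitrogen_response():
    """Synthetic leaf nitrogen-response lines.

    Calibrated so low-nitrogen leaves are capacity-limited (steep Amax line
    with a low intercept) while respiration keeps rising linearly with
    nitrogen -- the regime where canopy daily net photosynthesis has an
    interior nitrogen optimum.
    """
    from canophot.physiology import NitrogenResponse

    return NitrogenResponse(maps={
        "amax_net_25": (12.0, -12.0),
        "rd_25": (1.0, -0.8),
        "phi_co2": (0.012, 0.008),
        "theta": (0.0, 0.75),
    }, lnc_domain=(1.2, 4.5))


def default_params_by_tissue(temp_scaled: bool = True) -> dict:
    """PhotoParams per tissue code with (optionally) the default temperature
    response shapes."""
    from canophot.architecture import TISSUE_CODES

    kw = {}
    if temp_scaled:
        kw = dict(temp_amax=TEMP_AMAX_QUAD, temp_rd=TEMP_RD_QUAD)
    return {TISSUE_CODES[name]: PhotoParams(**vals, **kw)
            for name, vals in DEFAULT_TISSUE_PARAMS.items()}

#: measurement protocol light sequences (umol m-2 s-1, incident)
LEAF_LIGHT_LEVELS = (2000.0, 1500.0, 1000.0, 700.0, 500.0, 300.0, 200.0,
                     100.0, 50.0, 25.0, 0.0)
SPIKE_LIGHT_LEVELS = (2000.0, 1500.0, 1000.0, 700.0, 500.0, 300.0, 200.0,
                      100.0, 50.0, 0.0)


@dataclass(frozen=True)
class StagePreset:
    """Sampling distributions for one growth stage.

    Each entry is (mean, sd, lo, hi) for a truncated-normal draw.
    """

    stage: str
    stem_height: tuple
    n_leaves: int
    flag_leaf_length: tuple
    leaf_width: tuple
    leaf_base_angle: tuple  # degrees from vertical at the leaf base
    leaf_tip_angle: tuple  # degrees from vertical at the tip
    leaf_twist: tuple  # degrees total twist tip vs base
    leaf_lnc: tuple
    stem_lnc: tuple
    has_spike: bool = False
    spike_length: tuple = (0.09, 0.008, 0.06, 0.12)
    spikelet_count: tuple = (18, 2, 12, 24)
    awn_length: tuple = (0.06, 0.01, 0.02, 0.09)
    spike_lnc: tuple = (1.8, 0.2, 1.2, 2.5)
    alpha0: float = 15.0  # maximal tiller lean, degrees (synthetic default)

    def __post_init__(self):
        if self.stage == "tillering" and self.has_spike:
            raise ValueError("tillering preset must not carry spikes")


STAGE_PRESETS = {
    "tillering": StagePreset(
        stage="tillering",
        stem_height=(0.16, 0.03, 0.08, 0.25),
        n_leaves=3,
        flag_leaf_length=(0.16, 0.03, 0.08, 0.25),
        leaf_width=(0.008, 0.001, 0.005, 0.012),
        leaf_base_angle=(25.0, 8.0, 5.0, 50.0),
        leaf_tip_angle=(75.0, 10.0, 40.0, 110.0),
        leaf_twist=(40.0, 15.0, 0.0, 90.0),
        leaf_lnc=(3.2, 0.3, 2.2, 4.2),
        stem_lnc=(1.6, 0.2, 1.0, 2.4),
        has_spike=False,
    ),
    "heading": StagePreset(
        stage="heading",
        stem_height=(0.75, 0.06, 0.55, 0.95),
        n_leaves=4,
        flag_leaf_length=(0.20, 0.03, 0.12, 0.30),
        leaf_width=(0.014, 0.002, 0.008, 0.020),
        leaf_base_angle=(20.0, 6.0, 5.0, 45.0),
        leaf_tip_angle=(65.0, 12.0, 30.0, 110.0),
        leaf_twist=(45.0, 15.0, 0.0, 100.0),
        leaf_lnc=(3.0, 0.3, 2.0, 4.0),
        stem_lnc=(1.5, 0.2, 0.9, 2.2),
        has_spike=True,
    ),
    "milking": StagePreset(
        stage="milking",
        stem_height=(0.80, 0.06, 0.60, 1.00),
        n_leaves=4,
        flag_leaf_length=(0.19, 0.03, 0.11, 0.28),
        leaf_width=(0.013, 0.002, 0.008, 0.019),
        leaf_base_angle=(22.0, 7.0, 5.0, 50.0),
        leaf_tip_angle=(70.0, 12.0, 30.0, 115.0),
        leaf_twist=(50.0, 15.0, 0.0, 100.0),
        leaf_lnc=(2.4, 0.3, 1.5, 3.4),
        stem_lnc=(1.2, 0.2, 0.7, 1.9),
        has_spike=True,
        spike_lnc=(1.6, 0.2, 1.0, 2.2),
    ),
}


def _draw(rng, spec):
    mean, sd, lo, hi = spec
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _leaf(rng, preset: StagePreset, rank: int, insertion: float,
          length_scale: float) -> LeafBlueprint:
    length = _draw(rng, preset.flag_leaf_length) * length_scale
    width = _draw(rng, preset.leaf_width)
    base = _draw(rng, preset.leaf_base_angle)
    tip = _draw(rng, preset.leaf_tip_angle)
    twist = _draw(rng, preset.leaf_twist)
    # lanceolate width profile, zero at the tip
    wp = np.array([[0.0, 0.55], [0.2, 0.95], [0.45, 1.0], [0.8, 0.6],
                   [1.0, 0.0]])
    ip = np.array([[0.0, base], [0.5, 0.5 * (base + tip)], [1.0, tip]])
    tp = np.array([[0.0, 0.0], [1.0, twist]])
    return LeafBlueprint(
        rank=rank, length=length, max_width=width, width_profile=wp,
        inclination_profile=ip, twist_profile=tp,
        insertion_height=insertion, lnc=_draw(rng, preset.leaf_lnc))


def generate_tiller_library(preset: StagePreset, n: int, seed: int,
                            ) -> list:
    """Draw ``n`` independent tiller blueprints; deterministic under seed."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        height = _draw(rng, preset.stem_height)
        nseg = max(preset.n_leaves, 2)
        # internodes lengthen acropetally
        raw = np.linspace(1.0, 2.0, nseg)
        seg_len = raw / raw.sum() * height
        diam = 0.004 if preset.stage != "tillering" else 0.003
        segments = tuple((float(l), diam) for l in seg_len)
        insertions = np.cumsum(seg_len)
        leaves = []
        for rank in range(1, preset.n_leaves + 1):
            # rank 1 = flag leaf at the stem top; lower leaves shorter
            ins = float(insertions[-rank]) if rank <= len(insertions) else 0.0
            scale = 1.0 - 0.12 * (rank - 1)
            leaves.append(_leaf(rng, preset, rank, min(ins, height),
                                max(scale, 0.4)))
        spike = None
        if preset.has_spike:
            spike = SpikeBlueprint(
                length=_draw(rng, preset.spike_length),
                spikelet_count=int(round(_draw(rng, preset.spikelet_count))),
                awn_length=_draw(rng, preset.awn_length),
                lnc=_draw(rng, preset.spike_lnc),
            )
        out.append(TillerBlueprint(
            stem_height=height, stem_segments=segments, leaves=tuple(leaves),
            spike=spike, stem_lnc=_draw(rng, preset.stem_lnc)))
    return out


def generate_weather_day(kind: str, peak_ppfd: float, temp_range: tuple,
                         seed: int, latitude: float = 30.945,
                         longitude: float = 121.134, day_of_year: int = 110,
                         cadence_min: int = 10) -> WeatherSeries:
    """One synthetic day of weather drivers at a fixed cadence.

    sunny: smooth solar-geometry curve peaking at ``peak_ppfd`` at solar
    noon, direct fraction 0.85; cloudy: the sunny curve with multiplicative
    seeded dips; overcast: direct fraction 0 and the total reduced to 30%.
    Air temperature follows a sinusoid peaking at 14:00 within
    ``temp_range``.
    """
    if kind not in ("sunny", "cloudy", "overcast"):
        raise ValueError(f"unknown weather kind {kind!r}")
    if peak_ppfd <= 0:
        raise ValueError("peak_ppfd must be positive")
    rng = np.random.default_rng(seed)
    minutes = np.arange(0, 24 * 60, cadence_min)
    hours = minutes / 60.0
    sin_el = np.array([
        math.sin(math.radians(max(solar_position(latitude, day_of_year, h)[0],
                                  0.0)))
        for h in hours])
    noon = sin_el.max()
    total = peak_ppfd * np.where(sin_el > 0, sin_el / noon, 0.0)
    if kind == "sunny":
        frac = np.where(total > 0, 0.85, 0.0)
    elif kind == "cloudy":
        # slowly varying multiplicative dips
        n_knots = 25
        knots = rng.uniform(0.3, 1.0, n_knots)
        dips = np.interp(np.linspace(0, 1, len(total)),
                         np.linspace(0, 1, n_knots), knots)
        total = total * dips
        frac = np.where(total > 0, 0.5 * dips, 0.0)
    else:  # overcast
        total = total * 0.3
        frac = np.zeros_like(total)
    t_lo, t_hi = temp_range
    temp = (0.5 * (t_lo + t_hi)
            + 0.5 * (t_hi - t_lo) * np.sin(2 * np.pi * (hours - 8.0) / 24.0))
    base = pd.Timestamp("2020-01-01") + pd.Timedelta(days=day_of_year - 1)
    times = base + pd.to_timedelta(minutes, unit="m")
    df = pd.DataFrame({
        "time": times, "ppfd_total": total, "direct_fraction": frac,
        "temp_C": temp})
    return WeatherSeries(df, latitude, longitude)


def study_scenario_context(stage: str = "heading", seed: int = 7,
                           trace_seed: int = 5, library_size: int = 5,
                           cadence_min: int = 120,
                           rays: tuple = (8000, 4000),
                           leaf_segments: int = 8):
    """The default desk-scale study conditions for canopy what-if runs.

    A small periodic domain (0.2 m x 0.0594 m) at the field planting pattern
    (row spacing 0.20 m, in-row spacing 0.0066 m) behaves as a closed canopy
    under the tracer's periodic boundaries; a sunny day at a coarse cadence
    and reduced ray counts keeps a full diurnal scenario tractable on one
    CPU.
    """
    from canophot.scenarios import ScenarioContext

    library = generate_tiller_library(STAGE_PRESETS[stage], library_size, seed)
    weather = generate_weather_day("sunny", 1800.0, (14.0, 26.0), seed,
                                   cadence_min=cadence_min)
    from canophot.canopy_sim import TraceSettings

    return ScenarioContext(
        library=library,
        row_spacing=0.20,
        in_row_spacing=0.0066,
        domain=(0.2, 0.0594),
        alpha0=15.0,
        assembly_seed=seed,
        weather=weather,
        params_by_tissue=default_params_by_tissue(),
        trace=TraceSettings(rays_direct=rays[0], rays_diffuse=rays[1],
                            seed=trace_seed),
        leaf_segments=leaf_segments,
        nitrogen_response=default_nitrogen_response(),
    )


def generate_aq_curve(params: PhotoParams, light_levels: Sequence[float],
                      noise_sd: float, temperature: float, seed: int,
                      absorptance: float = 1.0, tissue_label: str = "leaf",
                      area_basis: float = float("nan")) -> AQCurve:
    """Forward-simulate an A-Q record with seeded Gaussian noise.

    ``light_levels`` are incident PPFDs; the model sees
    ``incident * absorptance``.
    """
    rng = np.random.default_rng(seed)
    levels = np.asarray(light_levels, dtype=float)
    a = assimilation_rate(levels * absorptance, temperature, params)
    a = np.atleast_1d(a)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, len(levels))
    return AQCurve(ppfd=levels, a_net=a, temperature=temperature,
                   tissue_label=tissue_label, area_basis=area_basis)
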