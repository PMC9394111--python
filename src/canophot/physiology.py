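"""Tissue-level gas exchange.

The photosynthetic rate of a small piece of plant tissue is modelled with the
nonrectangular hyperbola (NRH).  The gross rate ``A_g`` is the lower root of

    theta * A_g**2 - (phi*I + Amax(T)) * A_g + phi*I*Amax(T) = 0

where ``I`` is the *absorbed* photosynthetic photon flux density
(umol photons m-2 s-1), ``phi`` the maximal apparent quantum efficiency of
CO2 fixation (mol CO2 / mol absorbed photons), ``theta`` the convexity and
``Amax(T)`` the gross light-saturated rate at tissue temperature ``T``.  Net
assimilation is ``A_g - Rd(T)``.  Temperature scaling is a dimensionless
quadratic multiplier per rate, normalised to 1 at 25 degC:

    Amax_net(T) = amax_net_25 * q1(T),   Rd(T) = rd_25 * q2(T),
    Amax(T)     = Amax_net(T) + Rd(T).

Nitrogen scaling maps tissue nitrogen content (LNC, % dry weight) linearly
onto the four light-response parameters.

All rates are expressed per unit total mesh patch area of the tissue, the
same basis the ray tracer uses for absorbed flux.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "PhotoParams",
    "AQCurve",
    "TempResponseTable",
    "NitrogenResponse",
    "AQFitResult",
    "SpikeInversionResult",
    "assimilation_rate",
    "temperature_multipliers",
    "fit_temp_response",
    "fit_aq_curve",
    "params_from_nitrogen",
    "spike_two_component_inversion",
    "predict_organ_diurnal",
]

#: identity quadratic (a, b, c) with q(T) = a*T**2 + b*T + c == 1 for all T
IDENTITY_QUAD = (0.0, 0.0, 1.0)

# physically plausible bounds used by all fitting routines
PARAM_BOUNDS = {
    "amax_net_25": (0.0, 50.0),
    "rd_25": (0.0, 10.0),
    "phi_co2": (0.0, 0.125),
    "theta": (0.05, 0.99),
}


def _quad(coeffs: Sequence[float], t):
    a, b, c = coeffs
    return a * np.asarray(t, dtype=float) ** 2 + b * np.asarray(t, dtype=float) + c


@dataclass(frozen=True)
class PhotoParams:
    """Light-response parameters of one tissue class, referenced to 25 degC.

    Parameters
    ----------
    amax_net_25
        Net light-saturated assimilation at 25 degC, umol CO2 m-2 s-1.
    rd_25
        Dark respiration at 25 degC, umol CO2 m-2 s-1.
    phi_co2
        Maximal apparent quantum efficiency, mol CO2 per mol absorbed photons.
    theta
        Convexity of the hyperbola, dimensionless, in (0, 1).
    temp_amax, temp_rd
        Quadratic multiplier coefficients ``(a, b, c)`` for Amax_net and Rd
        versus temperature in degC.  Normalised at construction so the
        multiplier equals 1 at 25 degC.
    """

    amax_net_25: float
    rd_25: float
    phi_co2: float
    theta: float
    temp_amax: tuple = IDENTITY_QUAD
    temp_rd: tuple = IDENTITY_QUAD

    def __post_init__(self):
        for name in ("amax_net_25", "rd_25", "phi_co2", "theta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")
        if self.phi_co2 < 0.0:
            raise ValueError(f"phi_co2 must be >= 0, got {self.phi_co2}")
        if self.rd_25 < 0.0:
            raise ValueError(f"rd_25 must be >= 0, got {self.rd_25}")
        if self.amax_net_25 + self.rd_25 <= 0.0:
            raise ValueError("gross Amax (amax_net_25 + rd_25) must be positive")
        for attr in ("temp_amax", "temp_rd"):
            coeffs = tuple(float(x) for x in getattr(self, attr))
            if len(coeffs) != 3:
                raise ValueError(f"{attr} needs 3 coefficients, got {coeffs}")
            q25 = _quad(coeffs, 25.0)
            if q25 <= 0:
                raise ValueError(f"{attr} multiplier non-positive at 25 degC")
            # enforce q(25) == 1 exactly
            coeffs = tuple(c / q25 for c in coeffs)
            object.__setattr__(self, attr, coeffs)
        t_grid = np.linspace(0.0, 40.0, 81)
        for attr in ("temp_amax", "temp_rd"):
            if np.any(_quad(getattr(self, attr), t_grid) <= 0.0):
                raise ValueError(
                    f"{attr} multiplier must stay positive over 0..40 degC"
                )

    def with_factor(self, *, amax_net: float = 1.0, phi: float = 1.0) -> "PhotoParams":
        """Scaled copy: multiply amax_net_25 and/or phi_co2, Rd untouched."""
        return replace(
            self,
            amax_net_25=self.amax_net_25 * amax_net,
            phi_co2=self.phi_co2 * phi,
        )


@dataclass(frozen=True)
class AQCurve:
    """A light-response record: incident PPFD vs measured net assimilation."""

    ppfd: np.ndarray  # incident PPFD on the tissue, umol m-2 s-1
    a_net: np.ndarray  # net assimilation, umol CO2 m-2 s-1 per tissue area
    temperature: float  # degC during measurement
    tissue_label: str = "leaf"
    area_basis: float = float("nan")  # declared reference area, m2

    _LABELS = ("leaf", "stem", "spike_intact", "spike_deawned")

    def __post_init__(self):
        ppfd = np.asarray(self.ppfd, dtype=float)
        a_net = np.asarray(self.a_net, dtype=float)
        object.__setattr__(self, "ppfd", ppfd)
        object.__setattr__(self, "a_net", a_net)
        if ppfd.shape != a_net.shape or ppfd.ndim != 1:
            raise ValueError("ppfd and a_net must be 1-D arrays of equal length")
        if len(ppfd) < 5:
            raise ValueError("an A-Q curve needs at least 5 points")
        if np.any(ppfd < 0):
            raise ValueError("PPFD values must be non-negative")
        d = np.diff(ppfd)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("PPFD values must be strictly monotone")
        if np.count_nonzero(ppfd == 0.0) > 1:
            raise ValueError("at most one dark (PPFD = 0) point allowed")
        if self.tissue_label not in self._LABELS:
            raise ValueError(f"unknown tissue_label {self.tissue_label!r}")

    @property
    def has_dark_point(self) -> bool:
        return bool(np.any(self.ppfd == 0.0))


@dataclass(frozen=True)
class TempResponseTable:
    """Measured temperature responses: A1500 and dark respiration vs T."""

    a1500: np.ndarray  # (n, 2): temperature degC, net rate at PPFD 1500
    rd: np.ndarray  # (m, 2): temperature degC, dark respiration

    def __post_init__(self):
        for name in ("a1500", "rd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must be an (n, 2) array of (T, value)")
            temps = arr[:, 0]
            if len(np.unique(temps)) < 3:
                raise ValueError(f"{name} needs at least 3 distinct temperatures")
            if np.any((temps < 0) | (temps > 40)):
                raise ValueError(f"{name} temperatures must lie in [0, 40] degC")


@dataclass(frozen=True)
class NitrogenResponse:
    """Linear maps from tissue nitrogen content to light-response parameters.

    ``maps`` holds ``(slope, intercept)`` per parameter name; evaluation is
    clipped to the fitting bounds so the resulting PhotoParams are valid, and
    every clip event is logged.
    """

    maps: Mapping[str, tuple]  # name -> (slope, intercept)
    lnc_domain: tuple = (0.5, 5.0)  # % dry weight

    def __post_init__(self):
        needed = set(PARAM_BOUNDS)
        if set(self.maps) != needed:
            raise ValueError(f"maps must cover exactly {sorted(needed)}")
        lo, hi = self.lnc_domain
        if not lo < hi:
            raise ValueError("lnc_domain must be an increasing pair")


def temperature_multipliers(temperature: float, params: PhotoParams):
    """Dimensionless (q_amax, q_rd) multipliers at ``temperature`` (degC).

    Both equal 1 at 25 degC by construction.  Temperatures where either
    multiplier is non-positive are outside the admissible range and rejected.
    """
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    q1 = _quad(params.temp_amax, t)
    q2 = _quad(params.temp_rd, t)
    if np.any(q1 <= 0) or np.any(q2 <= 0):
        raise ValueError(
            f"temperature {temperature!r} degC outside the admissible range: "
            "a quadratic multiplier is non-positive there"
        )
    return q1, q2


def assimilation_rate(absorbed_ppfd, temperature, params: PhotoParams):
    """Net assimilation (umol CO2 m-2 s-1) from the NRH lower root.

    ``absorbed_ppfd`` is the flux actually absorbed by the tissue (not the
    incident flux); scalars and arrays are accepted and broadcast.
    """
    i = np.asarray(absorbed_ppfd, dtype=float)
    if not np.all(np.isfinite(i)):
        raise ValueError("absorbed_ppfd must be finite")
    if np.any(i < 0):
        raise ValueError("absorbed_ppfd must be non-negative")
    q1, q2 = temperature_multipliers(temperature, params)
    amax_net = params.amax_net_25 * q1
    rd = params.rd_25 * q2
    amax = amax_net + rd
    gross = _nrh_lower_root(params.phi_co2 * i, amax, params.theta)
    out = gross - rd
    if np.ndim(absorbed_ppfd) == 0 and np.ndim(temperature) == 0:
        return float(out)
    return out


def _nrh_lower_root(phi_i, amax, theta):
    b = phi_i + amax
    disc = b * b - 4.0 * theta * phi_i * amax
    return (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta)


def fit_temp_response(table: TempResponseTable):
    """Fit quadratic temperature multipliers from a measured table.

    Each series is fitted by least squares with a quadratic in T, then the
    coefficients are divided by the fitted value at 25 degC so the multiplier
    is exactly 1 there.  Returns ``(temp_amax, temp_rd, diagnostics)`` where
    diagnostics holds an R-squared per series.
    """
    out = []
    diags = {}
    for name, arr in (("a1500", table.a1500), ("rd", table.rd)):
        t, v = arr[:, 0], arr[:, 1]
        coeffs = np.polyfit(t, v, deg=min(2, len(np.unique(t)) - 1))
        coeffs = np.pad(coeffs, (3 - len(coeffs), 0))  # ensure (a, b, c)
        v25 = float(np.polyval(coeffs, 25.0))
        if v25 <= 0:
            raise ValueError(f"fitted {name} value at 25 degC is non-positive")
        norm = tuple(float(c) / v25 for c in coeffs)
        resid = v - np.polyval(coeffs, t)
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        diags[name] = {"r_squared": r2}
        out.append(norm)
    return out[0], out[1], diags


@dataclass(frozen=True)
class AQFitResult:
    params: PhotoParams
    residual_norm: float
    converged: bool
    flags: tuple = ()


def fit_aq_curve(
    curve: AQCurve,
    absorptance: float,
    temp_amax: tuple = IDENTITY_QUAD,
    temp_rd: tuple = IDENTITY_QUAD,
    max_nfev: int = 2000,
) -> AQFitResult:
    """Fit NRH parameters to a measured A-Q curve.

    The NRH takes absorbed flux, while A-Q curves record incident flux, so
    incident PPFD is first multiplied by ``absorptance`` (1 - Kr - Kt of the
    tissue).  The fit is referenced to the measurement temperature and
    back-converted to 25 degC with the supplied temperature multipliers
    (identity by default).  Bounded trust-region least squares.
    """
    if not 0.0 < absorptance <= 1.0:
        raise ValueError("absorptance must lie in (0, 1]")
    flags = []
    i_abs = curve.ppfd * absorptance
    a_obs = curve.a_net

    if np.allclose(a_obs, 0.0, atol=1e-12):
        flags.append("degenerate_all_zero")

    rd_hi = PARAM_BOUNDS["rd_25"][1]
    if not curve.has_dark_point:
        rd_hi *= 2.0
        flags.append("no_dark_point")

    lo = np.array([PARAM_BOUNDS["amax_net_25"][0], PARAM_BOUNDS["rd_25"][0],
                   PARAM_BOUNDS["phi_co2"][0], PARAM_BOUNDS["theta"][0]])
    hi = np.array([PARAM_BOUNDS["amax_net_25"][1], rd_hi,
                   PARAM_BOUNDS["phi_co2"][1], PARAM_BOUNDS["theta"][1]])

    def residual(x):
        amax_net, rd, phi, theta = x
        amax = amax_net + rd
        gross = _nrh_lower_root(phi * i_abs, np.maximum(amax, 1e-12), theta)
        return gross - rd - a_obs

    x0 = np.array([
        max(float(a_obs.max()), 0.5),
        max(-float(a_obs.min()), 0.3),
        0.05,
        0.7,
    ])
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
    sol = least_squares(residual, x0, bounds=(lo, hi), max_nfev=max_nfev)
    if not sol.success:
        flags.append("non_convergence")

    amax_net_t, rd_t, phi, theta = sol.x
    # back-convert the temperature-referenced rates to 25 degC
    probe = PhotoParams(1.0, 0.0, 0.0, 0.5, temp_amax, temp_rd)
    q1, q2 = temperature_multipliers(curve.temperature, probe)
    params = PhotoParams(
        amax_net_25=float(amax_net_t / q1),
        rd_25=float(rd_t / q2),
        phi_co2=float(phi),
        theta=float(max(theta, 1e-6)) if theta < 1 else 0.99,
        temp_amax=temp_amax,
        temp_rd=temp_rd,
    )
    return AQFitResult(
        params=params,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        flags=tuple(flags),
    )


def params_from_nitrogen(lnc: float, nresp: NitrogenResponse,
                         temp_amax: tuple = IDENTITY_QUAD,
                         temp_rd: tuple = IDENTITY_QUAD) -> PhotoParams:
    """Evaluate the nitrogen-response lines at ``lnc`` (% dry weight)."""
    lo, hi = nresp.lnc_domain
    if not lo <= lnc <= hi:
        raise ValueError(f"LNC {lnc} outside declared domain [{lo}, {hi}]")
    values = {}
    for name, (slope, intercept) in nresp.maps.items():
        raw = slope * lnc + intercept
        blo, bhi = PARAM_BOUNDS[name]
        clipped = min(max(raw, blo + 1e-6 if name == "theta" else blo), bhi)
        if clipped != raw:
            logger.info("params_from_nitrogen: clipped %s from %g to %g",
                        name, raw, clipped)
        values[name] = clipped
    if values["amax_net_25"] + values["rd_25"] <= 0:
        values["amax_net_25"] = max(values["amax_net_25"], 1e-3)
        logger.info("params_from_nitrogen: raised amax_net_25 to keep gross "
                    "Amax positive")
    return PhotoParams(temp_amax=temp_amax, temp_rd=temp_rd, **values)


# ---------------------------------------------------------------------------
# spike two-component inversion (awn vs non-awn tissue)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeInversionResult:
    awn: PhotoParams | None
    nonawn: PhotoParams
    residual_intact: float
    residual_deawned: float
    converged: bool
    iterations: int
    status: str  # "ok" | "awn_unidentifiable" | "non_convergence"


def _chamber_unit_absorption(mesh, chamber, rays, seed):
    """Per-patch absorbed flux for unit *total* chamber light, split evenly.

    Tracing is linear in the injected flux, so a single unit trace scaled by
    the set light level reproduces any level exactly.
    """
    from canophot.optics import ChamberConfig, trace_chamber

    unit = ChamberConfig(
        size=chamber.size,
        panel_ppfd=(0.5, 0.5),
        panel_axis=chamber.panel_axis,
    )
    lm = trace_chamber(mesh, unit, rays=rays, seed=seed)
    return lm.absorbed_ppfd


def _predict_curve(levels, unit_abs, areas, masks_params, temperature):
    """Area-weighted chamber gas exchange at each set total light level."""
    total_area = float(areas.sum())
    out = np.zeros(len(levels))
    for k, level in enumerate(levels):
        s = 0.0
        for mask, p in masks_params:
            if not np.any(mask):
                continue
            a = assimilation_rate(unit_abs[mask] * level, temperature, p)
            s += float(np.sum(a * areas[mask]))
        out[k] = s / total_area
    return out


def _fit_component(levels, target, unit_abs, areas, fit_mask, fixed, temperature,
                   x0=None):
    """Fit PhotoParams of the patches in ``fit_mask``; others held at ``fixed``."""
    lo = np.array([PARAM_BOUNDS["amax_net_25"][0], PARAM_BOUNDS["rd_25"][0],
                   PARAM_BOUNDS["phi_co2"][0], PARAM_BOUNDS["theta"][0]])
    hi = np.array([PARAM_BOUNDS["amax_net_25"][1], PARAM_BOUNDS["rd_25"][1],
                   PARAM_BOUNDS["phi_co2"][1], PARAM_BOUNDS["theta"][1]])

    def residual(x):
        p = PhotoParams(*x)
        masks_params = [(fit_mask, p)] + list(fixed)
        pred = _predict_curve(levels, unit_abs, areas, masks_params, temperature)
        return pred - target

    if x0 is None:
        x0 = np.array([10.0, 1.0, 0.05, 0.7])
    x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)
    sol = least_squares(residual, x0, bounds=(lo, hi), max_nfev=4000)
    return PhotoParams(*sol.x), float(np.linalg.norm(sol.fun)), bool(sol.success)


def spike_two_component_inversion(
    intact: AQCurve,
    deawned: AQCurve,
    intact_mesh,
    deawned_mesh,
    chamber,
    rays: int = 30_000,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> SpikeInversionResult:
    """Solve the eight awn/non-awn light-response parameters iteratively.

    The deawned spike (non-awn tissue only) is traced in the chamber and the
    non-awn parameters fitted so the area-weighted patch predictions match the
    deawned A-Q curve; the intact spike (awns shading non-awn tissue) then
    yields the awn parameters from the intact curve; the two fits alternate
    until the maximum relative parameter change drops below ``tol``.
    """
    from canophot.architecture import TISSUE_AWN

    awn_mask = intact_mesh.tissue == TISSUE_AWN
    areas_i = intact_mesh.areas()
    areas_d = deawned_mesh.areas()
    awn_frac = float(areas_i[awn_mask].sum() / areas_i.sum()) if len(areas_i) else 0.0

    unit_d = _chamber_unit_absorption(deawned_mesh, chamber, rays, seed)
    nonawn_mask_d = np.ones(len(areas_d), dtype=bool)

    # Step A: non-awn parameters from the deawned configuration
    p_nonawn, res_d, ok_d = _fit_component(
        deawned.ppfd, deawned.a_net, unit_d, areas_d,
        nonawn_mask_d, [], deawned.temperature,
    )

    if awn_frac < 0.01:
        return SpikeInversionResult(
            awn=None, nonawn=p_nonawn, residual_intact=float("nan"),
            residual_deawned=res_d, converged=ok_d, iterations=1,
            status="awn_unidentifiable",
        )

    unit_i = _chamber_unit_absorption(intact_mesh, chamber, rays, seed)
    nonawn_mask_i = ~awn_mask

    p_awn, res_i, ok_i = _fit_component(
        intact.ppfd, intact.a_net, unit_i, areas_i,
        awn_mask, [(nonawn_mask_i, p_nonawn)], intact.temperature,
    )

    def vec(p):
        return np.array([p.amax_net_25, p.rd_25, p.phi_co2, p.theta])

    converged = False
    iterations = 1
    for iterations in range(2, max_iter + 1):
        prev = np.concatenate([vec(p_awn), vec(p_nonawn)])
        p_nonawn, res_d, ok_d = _fit_component(
            deawned.ppfd, deawned.a_net, unit_d, areas_d,
            nonawn_mask_d, [], deawned.temperature, x0=vec(p_nonawn),
        )
        p_awn, res_i, ok_i = _fit_component(
            intact.ppfd, intact.a_net, unit_i, areas_i,
            awn_mask, [(nonawn_mask_i, p_nonawn)], intact.temperature,
            x0=vec(p_awn),
        )
        cur = np.concatenate([vec(p_awn), vec(p_nonawn)])
        rel = np.max(np.abs(cur - prev) / np.maximum(np.abs(prev), 1e-9))
        if rel < tol:
            converged = True
            break

    status = "ok" if (converged and ok_d and ok_i) else "non_convergence"
    return SpikeInversionResult(
        awn=p_awn, nonawn=p_nonawn, residual_intact=res_i,
        residual_deawned=res_d, converged=converged, iterations=iterations,
        status=status,
    )


def predict_organ_diurnal(
    mesh,
    params_by_tissue: Mapping[int, PhotoParams],
    weather,
    chamber=None,
    rays: int = 20_000,
    seed: int = 0,
):
    """Diurnal net gas exchange of one organ, per unit total organ area.

    With ``chamber`` set, the organ sits in the two-panel chamber and each
    timestep's total PPFD drives the (linearly scaled) chamber light field;
    otherwise the organ stands alone under the sky given by the weather
    series.  Dark steps skip tracing and return pure respiration.  Returns a
    DataFrame with columns time, ppfd_total, temp_C, a_net.
    """
    import pandas as pd

    from canophot.optics import light_environment_from_weather, trace_canopy
    from canophot.architecture import Canopy

    df = weather.frame
    if "temp_C" not in df.columns:
        raise ValueError("weather series lacks a temp_C column")
    areas = mesh.areas()
    total_area = float(areas.sum())
    tissues = mesh.tissue

    unit_abs = None
    standalone = None
    if chamber is not None:
        unit_abs = _chamber_unit_absorption(mesh, chamber, rays, seed)
    else:
        lo = mesh.triangles.reshape(-1, 3).min(axis=0)
        hi = mesh.triangles.reshape(-1, 3).max(axis=0)
        pad = max(float(np.max(hi - lo)), 0.05)
        shifted = mesh.translated(
            np.array([pad - lo[0], pad - lo[1], 0.0]))
        standalone = Canopy(
            mesh=shifted,
            row_spacing=float(hi[0] - lo[0] + 2 * pad),
            in_row_spacing=float(hi[1] - lo[1] + 2 * pad),
            domain=(float(hi[0] - lo[0] + 2 * pad), float(hi[1] - lo[1] + 2 * pad)),
            alpha0=0.0,
            seed=seed,
            ground_reflectance=0.0,
        )

    rows = []
    for k, rec in enumerate(df.itertuples()):
        t_air = rec.temp_C
        ppfd = rec.ppfd_total
        if ppfd <= 0:
            a = 0.0
            for code, p in params_by_tissue.items():
                m = tissues == code
                _, q2 = temperature_multipliers(t_air, p)
                a -= p.rd_25 * float(q2) * float(areas[m].sum())
            rows.append((rec.time, ppfd, t_air, a / total_area))
            continue
        if chamber is not None:
            absorbed = unit_abs * ppfd
        else:
            env = light_environment_from_weather(
                rec, weather.latitude, weather.longitude)
            lm = trace_canopy(standalone, env, rays_direct=rays,
                              rays_diffuse=rays // 2, seed=seed + k)
            absorbed = lm.absorbed_ppfd
        a = 0.0
        for code, p in params_by_tissue.items():
            m = tissues == code
            if not np.any(m):
                continue
            vals = assimilation_rate(absorbed[m], t_air, p)
            a += float(np.sum(vals * areas[m]))
        rows.append((rec.time, ppfd, t_air, a / total_area))
    return pd.DataFrame(rows, columns=["time", "ppfd_total", "temp_C", "a_net"])
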