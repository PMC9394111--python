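"""Optical properties and Monte-Carlo light transport.

Tissue optical properties follow an empirical chain: tissue nitrogen content
(LNC, % dry weight) -> SPAD reading -> areal chlorophyll (ug cm-2) ->
reflected/transmitted fractions (Kr, Kt).  Stem, spikelet and awn patches
are opaque (Kt = 0).

Two light geometries are traced: an open canopy under direct (parallel) plus
diffuse (uniform-sky) light with periodic lateral boundaries, and a
two-panel LED measurement chamber with absorbing walls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from canophot import _tracer

__all__ = [
    "OpticalProps",
    "LightEnvironment",
    "ChamberConfig",
    "LightMap",
    "spad_from_lnc",
    "chl_from_spad",
    "optical_props_from_chl",
    "optical_props_from_lnc",
    "sample_reflection",
    "sample_transmission",
    "trace_canopy",
    "trace_chamber",
    "light_environment_from_weather",
    "solar_position",
]

DEFAULT_ROUGHNESS = 0.3
#: termination as a fraction of the primary ray weight; equals the absolute
#: 1 umol m-2 s-1 cutoff at a 2000 umol m-2 s-1 sky
DEFAULT_TERMINATION_FRACTION = 5e-4


@dataclass(frozen=True)
class OpticalProps:
    """Reflected (kr) and transmitted (kt) fractions of incident light."""

    kr: float
    kt: float

    def __post_init__(self):
        if self.kr < 0 or self.kt < 0:
            raise ValueError("kr and kt must be non-negative")
        if self.kr + self.kt >= 1.0:
            raise ValueError("kr + kt must be < 1 (absorptance positive)")

    @property
    def absorptance(self) -> float:
        return 1.0 - self.kr - self.kt


@dataclass(frozen=True)
class LightEnvironment:
    """Above-canopy light: direct beam plus uniform-sky diffuse flux.

    Fluxes are on a horizontal plane (umol m-2 s-1); ``direct_direction``
    points from the sun toward the ground.
    """

    direct_ppfd: float
    direct_direction: np.ndarray
    diffuse_ppfd: float
    sky_model: str = "uniform"

    def __post_init__(self):
        if self.direct_ppfd < 0 or self.diffuse_ppfd < 0:
            raise ValueError("fluxes must be non-negative")
        d = np.asarray(self.direct_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            d = np.array([0.0, 0.0, -1.0])
        else:
            d = d / n
        if self.direct_ppfd > 0 and d[2] >= 0:
            raise ValueError("direct beam must point downward")
        object.__setattr__(self, "direct_direction", d)

    @property
    def total_ppfd(self) -> float:
        return self.direct_ppfd + self.diffuse_ppfd


@dataclass(frozen=True)
class ChamberConfig:
    """Two-panel LED measurement chamber; walls are non-reflective.

    Panels sit on opposite faces along ``panel_axis`` and emit parallel beams
    toward each other at the set PPFDs (per panel area).
    """

    size: tuple = (0.12, 0.12, 0.25)  # m
    panel_ppfd: tuple = (750.0, 750.0)
    panel_axis: str = "x"

    def __post_init__(self):
        if any(s <= 0 for s in self.size):
            raise ValueError("chamber dimensions must be positive")
        if any(p < 0 for p in self.panel_ppfd):
            raise ValueError("panel PPFDs must be non-negative")
        if self.panel_axis not in ("x", "y"):
            raise ValueError("panel_axis must be 'x' or 'y'")


@dataclass
class LightMap:
    """Per-patch light field for one trace plus the energy ledger.

    ``absorbed_ppfd``/``incident_ppfd`` are flux densities per patch area
    (umol m-2 s-1); totals are per m2 of ground (or chamber footprint).
    """

    absorbed_ppfd: np.ndarray
    incident_ppfd: np.ndarray
    injected: float
    canopy_absorbed: float
    ground_absorbed: float
    escaped: float
    discarded: float
    seed: int
    rays_direct: int
    rays_diffuse: int

    def closure_error(self) -> float:
        """Relative energy-balance error of the trace."""
        if self.injected == 0:
            return 0.0
        out = (self.canopy_absorbed + self.ground_absorbed + self.escaped
               + self.discarded)
        return abs(out - self.injected) / self.injected


# ---------------------------------------------------------------------------
# empirical optical-property chain
# ---------------------------------------------------------------------------

def spad_from_lnc(lnc: float) -> float:
    """SPAD reading from tissue nitrogen content (% dry weight)."""
    if lnc < 0:
        raise ValueError("LNC must be non-negative")
    return 9.7 * lnc + 7.13


def chl_from_spad(spad: float) -> float:
    """Areal chlorophyll (ug cm-2) from a SPAD reading."""
    if spad < 0:
        raise ValueError("SPAD must be non-negative")
    return 0.0599 * math.exp(0.0493 * spad) * 100.0


def optical_props_from_chl(chl: float, tissue_class: str = "leaf") -> OpticalProps:
    """Kr/Kt from chlorophyll concentration.

    ``kr = 0.3605 * chl**-0.502``; for leaves
    ``kt = -0.082 * ln(chl) + 0.3761`` (floored at 0); stem, spikelet and awn
    tissue is opaque (kt = 0).
    """
    if chl <= 0:
        raise ValueError("chlorophyll concentration must be positive")
    kr = 0.3605 * chl ** -0.502
    if tissue_class == "leaf":
        kt = max(-0.082 * math.log(chl) + 0.3761, 0.0)
    else:
        kt = 0.0
    if kr + kt >= 1.0:
        raise ValueError(
            f"chl={chl} ug cm-2 outside the fitted domain (kr+kt >= 1)")
    return OpticalProps(kr=kr, kt=kt)


def optical_props_from_lnc(lnc: float, tissue_class: str = "leaf") -> OpticalProps:
    """Convenience chain LNC -> SPAD -> chlorophyll -> Kr/Kt."""
    return optical_props_from_chl(chl_from_spad(spad_from_lnc(lnc)), tissue_class)


# ---------------------------------------------------------------------------
# scatter-direction sampling (library-level mirror of the kernel logic)
# ---------------------------------------------------------------------------

def _frame(n):
    t = np.array([0.0, 1.0, 0.0]) if abs(n[0]) > 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(t, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def sample_reflection(normal, incident_direction, roughness, rng) -> np.ndarray:
    """One outgoing direction from the Cook-Torrance lobe.

    Beckmann half-vector sampling with reflection of the incident ray; draws
    landing below the surface fall back to a cosine-weighted direction about
    the normal.  roughness -> 0 gives the specular mirror direction;
    large roughness approaches a cosine-weighted hemisphere.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = np.asarray(incident_direction, dtype=float)
    d = d / np.linalg.norm(d)
    if np.dot(n, d) > 0:
        n = -n
    if roughness < 1e-6:
        return d - 2.0 * np.dot(d, n) * n
    u, v = _frame(n)
    for _ in range(4):
        u1, u2 = rng.random(2)
        tan2 = -roughness**2 * math.log(max(1.0 - u1, 1e-12))
        c = 1.0 / math.sqrt(1.0 + tan2)
        s = math.sqrt(max(0.0, 1.0 - c * c))
        phi = 2.0 * math.pi * u2
        h = s * math.cos(phi) * u + s * math.sin(phi) * v + c * n
        out = d - 2.0 * np.dot(d, h) * h
        if np.dot(out, n) > 1e-6:
            return out
    return sample_transmission(-n, rng)


def sample_transmission(normal, rng) -> np.ndarray:
    """Cosine-weighted direction in the hemisphere opposite ``normal``."""
    n = np.asarray(normal, dtype=float)
    n = -n / np.linalg.norm(n)
    u, v = _frame(n)
    u1, u2 = rng.random(2)
    r = math.sqrt(u1)
    phi = 2.0 * math.pi * u2
    return (r * math.cos(phi) * u + r * math.sin(phi) * v
            + math.sqrt(max(0.0, 1.0 - u1)) * n)


# ---------------------------------------------------------------------------
# trace drivers
# ---------------------------------------------------------------------------

def _prepare_geometry(mesh, box_lo, box_hi):
    tri = mesh.triangles
    v0 = np.ascontiguousarray(tri[:, 0, :])
    e1 = np.ascontiguousarray(tri[:, 1, :] - tri[:, 0, :])
    e2 = np.ascontiguousarray(tri[:, 2, :] - tri[:, 0, :])
    kr = np.ascontiguousarray(mesh.kr)
    kt = np.ascontiguousarray(mesh.kt)
    # cell size ~ 2x median patch edge, clamped to a sane grid resolution
    if len(v0):
        edge = np.median(np.linalg.norm(e1, axis=1))
        target = max(2.0 * edge, 1e-4)
    else:
        target = 0.1
    dims = []
    for a in range(3):
        span = max(box_hi[a] - box_lo[a], 1e-6)
        dims.append(int(np.clip(round(span / target), 1, 96)))
    nx, ny, nz = dims
    cell_start, cell_items = _tracer.build_grid(v0, e1, e2, box_lo, box_hi,
                                                nx, ny, nz)
    # append total for CSR end lookup
    cell_start = np.append(cell_start, len(cell_items))
    return v0, e1, e2, kr, kt, cell_start, cell_items, nx, ny, nz


def _stratified_grid(n, lx, ly, rng):
    nx = max(int(round(math.sqrt(n * lx / ly))), 1)
    ny = max(n // nx, 1)
    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    u = rng.random((nx, ny))
    v = rng.random((nx, ny))
    xs = (i.ravel() + u.ravel()) / nx * lx
    ys = (j.ravel() + v.ravel()) / ny * ly
    return xs, ys


def trace_canopy(canopy, env: LightEnvironment, rays_direct: int,
                 rays_diffuse: int, seed: int,
                 roughness: float = DEFAULT_ROUGHNESS,
                 termination_fraction: float = DEFAULT_TERMINATION_FRACTION,
                 ) -> LightMap:
    """Trace direct + diffuse light through a canopy with periodic sides.

    Direct rays launch as parallel beams from a stratified grid above the
    canopy; diffuse rays launch from random top positions with
    cosine-weighted (uniform-sky) directions.  Deterministic for a fixed
    seed.  Totals in the returned LightMap are per m2 of ground.
    """
    if rays_direct <= 0 or rays_diffuse <= 0:
        raise ValueError("ray counts must be positive")
    mesh = canopy.mesh
    lx, ly = canopy.domain
    tri = mesh.triangles
    ztop = float(tri[:, :, 2].max()) * 1.001 + 1e-6 if len(tri) else 0.1
    ztop = max(ztop, 0.05)
    box_lo = np.array([0.0, 0.0, 0.0])
    box_hi = np.array([lx, ly, ztop])
    geo = _prepare_geometry(mesh, box_lo, box_hi)
    v0, e1, e2, kr, kt, cell_start, cell_items, nx, ny, nz = geo

    area = lx * ly
    absorbed = np.zeros(len(v0))
    incident = np.zeros(len(v0))
    rng = np.random.default_rng(seed)
    ground = escaped = discarded = injected = 0.0

    if env.direct_ppfd > 0:
        xs, ys = _stratified_grid(rays_direct, lx, ly, rng)
        n = len(xs)
        origins = np.column_stack([xs, ys, np.full(n, ztop + 1e-5)])
        dirs = np.tile(env.direct_direction, (n, 1))
        w = env.direct_ppfd * area / n
        injected += env.direct_ppfd * area
        g, e, d = _tracer.trace_batch(
            v0, e1, e2, kr, kt, cell_start, cell_items, box_lo, box_hi,
            nx, ny, nz, True, canopy.ground_reflectance,
            np.ascontiguousarray(origins), np.ascontiguousarray(dirs),
            w, termination_fraction * w, roughness, seed, absorbed, incident)
        ground += g
        escaped += e
        discarded += d

    if env.diffuse_ppfd > 0:
        n = rays_diffuse
        xs = rng.random(n) * lx
        ys = rng.random(n) * ly
        origins = np.column_stack([xs, ys, np.full(n, ztop + 1e-5)])
        u1 = rng.random(n)
        u2 = rng.random(n)
        r = np.sqrt(u1)
        phi = 2 * np.pi * u2
        dirs = np.column_stack([
            r * np.cos(phi), r * np.sin(phi), -np.sqrt(1.0 - u1)])
        w = env.diffuse_ppfd * area / n
        injected += env.diffuse_ppfd * area
        g, e, d = _tracer.trace_batch(
            v0, e1, e2, kr, kt, cell_start, cell_items, box_lo, box_hi,
            nx, ny, nz, True, canopy.ground_reflectance,
            np.ascontiguousarray(origins), np.ascontiguousarray(dirs),
            w, termination_fraction * w, roughness, seed + 1, absorbed, incident)
        ground += g
        escaped += e
        discarded += d

    areas = mesh.areas() if len(v0) else np.zeros(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        abs_ppfd = np.where(areas > 0, absorbed / np.maximum(areas, 1e-300), 0.0)
        inc_ppfd = np.where(areas > 0, incident / np.maximum(areas, 1e-300), 0.0)
    return LightMap(
        absorbed_ppfd=abs_ppfd,
        incident_ppfd=inc_ppfd,
        injected=injected / area,
        canopy_absorbed=float(absorbed.sum()) / area,
        ground_absorbed=ground / area,
        escaped=escaped / area,
        discarded=discarded / area,
        seed=seed,
        rays_direct=rays_direct,
        rays_diffuse=rays_diffuse,
    )


def trace_chamber(mesh, chamber: ChamberConfig, rays: int, seed: int,
                  roughness: float = DEFAULT_ROUGHNESS,
                  termination_fraction: float = DEFAULT_TERMINATION_FRACTION,
                  ) -> LightMap:
    """Trace the two-panel chamber light field around one organ mesh.

    The organ is centred in the chamber box; both panels emit parallel beams
    toward each other; walls (and floor) absorb.  Wall-absorbed flux is
    reported in ``escaped`` (floor flux in ``ground_absorbed``).  Totals are
    per m2 of chamber footprint.
    """
    if rays <= 0:
        raise ValueError("ray count must be positive")
    sx, sy, sz = chamber.size
    tri = mesh.triangles
    if len(tri):
        lo = tri.reshape(-1, 3).min(axis=0)
        hi = tri.reshape(-1, 3).max(axis=0)
        if np.any(hi - lo > np.array([sx, sy, sz]) + 1e-9):
            raise ValueError("mesh does not fit in the chamber")
        centre_shift = (np.array([sx, sy, sz]) - (hi + lo)) * 0.5
        mesh = mesh.translated(centre_shift)
        tri = mesh.triangles
    box_lo = np.array([0.0, 0.0, 0.0])
    box_hi = np.array([sx, sy, sz])
    geo = _prepare_geometry(mesh, box_lo, box_hi)
    v0, e1, e2, kr, kt, cell_start, cell_items, nx, ny, nz = geo

    absorbed = np.zeros(len(v0))
    incident = np.zeros(len(v0))
    rng = np.random.default_rng(seed)
    ground = escaped = discarded = injected = 0.0
    if chamber.panel_axis == "x":
        panel_area = sy * sz
        launches = [
            (np.array([1.0, 0.0, 0.0]), 1e-6),
            (np.array([-1.0, 0.0, 0.0]), sx - 1e-6),
        ]
    else:
        panel_area = sx * sz
        launches = [
            (np.array([0.0, 1.0, 0.0]), 1e-6),
            (np.array([0.0, -1.0, 0.0]), sy - 1e-6),
        ]
    total_p = sum(chamber.panel_ppfd)
    for (direction, coord), ppfd in zip(launches, chamber.panel_ppfd):
        if ppfd <= 0:
            continue
        n = max(int(round(rays * ppfd / total_p)), 1)
        if chamber.panel_axis == "x":
            a_s, b_s = _stratified_grid(n, sy, sz, rng)
            origins = np.column_stack([np.full(len(a_s), coord), a_s, b_s])
        else:
            a_s, b_s = _stratified_grid(n, sx, sz, rng)
            origins = np.column_stack([a_s, np.full(len(a_s), coord), b_s])
        dirs = np.tile(direction, (len(origins), 1))
        w = ppfd * panel_area / len(origins)
        injected += ppfd * panel_area
        g, e, d = _tracer.trace_batch(
            v0, e1, e2, kr, kt, cell_start, cell_items, box_lo, box_hi,
            nx, ny, nz, False, 0.0,
            np.ascontiguousarray(origins), np.ascontiguousarray(dirs),
            w, termination_fraction * w, roughness, seed, absorbed, incident)
        ground += g
        escaped += e
        discarded += d

    footprint = sx * sy
    areas = mesh.areas() if len(v0) else np.zeros(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        abs_ppfd = np.where(areas > 0, absorbed / np.maximum(areas, 1e-300), 0.0)
        inc_ppfd = np.where(areas > 0, incident / np.maximum(areas, 1e-300), 0.0)
    return LightMap(
        absorbed_ppfd=abs_ppfd,
        incident_ppfd=inc_ppfd,
        injected=injected / footprint,
        canopy_absorbed=float(absorbed.sum()) / footprint,
        ground_absorbed=ground / footprint,
        escaped=escaped / footprint,
        discarded=discarded / footprint,
        seed=seed,
        rays_direct=rays,
        rays_diffuse=0,
    )


# ---------------------------------------------------------------------------
# solar geometry
# ---------------------------------------------------------------------------

def solar_position(latitude: float, day_of_year: int, solar_hour: float):
    """(elevation, azimuth) in degrees; azimuth from north, clockwise.

    Declination from the Spencer Fourier series; hour angle from local solar
    time (12.0 = solar noon).
    """
    gamma = 2.0 * math.pi * (day_of_year - 1) / 365.0
    decl = (0.006918 - 0.399912 * math.cos(gamma) + 0.070257 * math.sin(gamma)
            - 0.006758 * math.cos(2 * gamma) + 0.000907 * math.sin(2 * gamma)
            - 0.002697 * math.cos(3 * gamma) + 0.00148 * math.sin(3 * gamma))
    lat = math.radians(latitude)
    h = math.radians(15.0 * (solar_hour - 12.0))
    sin_el = (math.sin(lat) * math.sin(decl)
              + math.cos(lat) * math.cos(decl) * math.cos(h))
    el = math.asin(max(-1.0, min(1.0, sin_el)))
    cos_az = ((math.sin(decl) - math.sin(lat) * sin_el)
              / max(math.cos(lat) * math.cos(el), 1e-12))
    az = math.acos(max(-1.0, min(1.0, cos_az)))
    if h > 0:
        az = 2.0 * math.pi - az
    return math.degrees(el), math.degrees(az)


def light_environment_from_weather(record, latitude: float, longitude: float,
                                   ) -> LightEnvironment:
    """Build a LightEnvironment from one weather row.

    The row must expose ``ppfd_total``, ``direct_fraction``, and a time (a
    ``time`` attribute as pandas Timestamp or fractional solar hour).  The
    sun below the horizon forces all flux to zero.
    """
    total = float(record.ppfd_total)
    frac = getattr(record, "direct_fraction", None)
    if frac is None or (isinstance(frac, float) and math.isnan(frac)):
        raise ValueError("weather record lacks direct_fraction")
    frac = float(frac)
    t = record.time
    if hasattr(t, "dayofyear"):
        doy = int(t.dayofyear)
        hour = t.hour + t.minute / 60.0 + t.second / 3600.0
    else:
        doy = int(getattr(record, "day_of_year", 80))
        hour = float(t)
    el, az = solar_position(latitude, doy, hour)
    if el <= 0:
        return LightEnvironment(0.0, np.array([0.0, 0.0, -1.0]), 0.0)
    el_r, az_r = math.radians(el), math.radians(az)
    toward_sun = np.array([
        math.sin(az_r) * math.cos(el_r),
        math.cos(az_r) * math.cos(el_r),
        math.sin(el_r),
    ])
    return LightEnvironment(
        direct_ppfd=total * frac,
        direct_direction=-toward_sun,
        diffuse_ppfd=total * (1.0 - frac),
    )
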