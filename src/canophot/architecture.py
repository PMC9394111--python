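"""Parametric 3D reconstruction of wheat organs and canopy assembly.

Organs are collections of triangular patches.  A leaf is a twisted ribbon
built from a midrib polyline (inclination profile), a width profile and a
twist profile; a stem is a chain of square prisms; a spike is a thin rachis
prism carrying box-like spikelet hulls in two alternating ranks, each
optionally bearing a thin prismatic awn.  Tillers are placed on a planting
grid (rows x in-row positions) with a random library draw, a random lean
angle up to alpha0 and a random azimuth per position.

Angles are degrees in blueprints, lengths metres; meshes are in the canopy
frame (z up, ground at z = 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from canophot.optics import optical_props_from_lnc

logger = logging.getLogger(__name__)

__all__ = [
    "TISSUE_LEAF", "TISSUE_STEM", "TISSUE_SPIKELET", "TISSUE_AWN",
    "TISSUE_NAMES", "TISSUE_CODES",
    "LeafBlueprint", "SpikeBlueprint", "TillerBlueprint",
    "OrganMesh", "Canopy", "PerturbationSpec",
    "build_leaf_mesh", "build_spike_mesh", "build_tiller",
    "assemble_canopy", "apply_perturbation",
]

TISSUE_LEAF = 0
TISSUE_STEM = 1
TISSUE_SPIKELET = 2
TISSUE_AWN = 3

TISSUE_NAMES = {TISSUE_LEAF: "leaf", TISSUE_STEM: "stem",
                TISSUE_SPIKELET: "spikelet", TISSUE_AWN: "awn"}
TISSUE_CODES = {v: k for k, v in TISSUE_NAMES.items()}


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

@dataclass
class OrganMesh:
    """A triangle soup with per-patch tissue class, organ id and optics."""

    triangles: np.ndarray  # (n, 3, 3) vertices, m
    tissue: np.ndarray  # (n,) int codes
    organ_id: np.ndarray  # (n,) int
    kr: np.ndarray  # (n,)
    kt: np.ndarray  # (n,)

    def __post_init__(self):
        self.triangles = np.asarray(self.triangles, dtype=float).reshape(-1, 3, 3)
        n = len(self.triangles)
        self.tissue = np.asarray(self.tissue, dtype=np.int8).reshape(n)
        self.organ_id = np.asarray(self.organ_id, dtype=np.int32).reshape(n)
        self.kr = np.asarray(self.kr, dtype=float).reshape(n)
        self.kt = np.asarray(self.kt, dtype=float).reshape(n)
        if n and np.any(self.areas() <= 0):
            raise ValueError("degenerate (zero-area) patch in mesh")
        if np.any(self.kt[self.tissue != TISSUE_LEAF] != 0.0):
            raise ValueError("non-leaf tissue must have kt = 0")

    def __len__(self):
        return len(self.triangles)

    def areas(self) -> np.ndarray:
        e1 = self.triangles[:, 1] - self.triangles[:, 0]
        e2 = self.triangles[:, 2] - self.triangles[:, 0]
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)

    def total_area(self) -> float:
        return float(self.areas().sum())

    def translated(self, offset) -> "OrganMesh":
        return OrganMesh(self.triangles + np.asarray(offset, dtype=float),
                         self.tissue, self.organ_id, self.kr, self.kt)

    def transformed(self, rot: np.ndarray, offset=(0.0, 0.0, 0.0)) -> "OrganMesh":
        tri = self.triangles @ rot.T + np.asarray(offset, dtype=float)
        return OrganMesh(tri, self.tissue, self.organ_id, self.kr, self.kt)

    def subset(self, mask) -> "OrganMesh":
        return OrganMesh(self.triangles[mask], self.tissue[mask],
                         self.organ_id[mask], self.kr[mask], self.kt[mask])

    @staticmethod
    def concatenate(meshes: Sequence["OrganMesh"]) -> "OrganMesh":
        meshes = [m for m in meshes if len(m)]
        if not meshes:
            return OrganMesh(np.zeros((0, 3, 3)), np.zeros(0), np.zeros(0),
                             np.zeros(0), np.zeros(0))
        return OrganMesh(
            np.concatenate([m.triangles for m in meshes]),
            np.concatenate([m.tissue for m in meshes]),
            np.concatenate([m.organ_id for m in meshes]),
            np.concatenate([m.kr for m in meshes]),
            np.concatenate([m.kt for m in meshes]),
        )


# ---------------------------------------------------------------------------
# blueprints
# ---------------------------------------------------------------------------

def _profile(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float).reshape(-1, 2)
    if a[0, 0] != 0.0 or a[-1, 0] != 1.0 or np.any(np.diff(a[:, 0]) <= 0):
        raise ValueError("profile abscissae must increase from 0 to 1")
    return a


@dataclass(frozen=True)
class LeafBlueprint:
    """One leaf: size, shape profiles and attachment on the tiller."""

    rank: int  # 1 = flag leaf
    length: float  # blade length, m
    max_width: float  # m
    width_profile: np.ndarray  # (s, fraction of max width), 0 at the tip
    inclination_profile: np.ndarray  # (s, degrees from vertical)
    twist_profile: np.ndarray  # (s, degrees about the midrib)
    insertion_height: float  # m on the stem
    lnc: float = 2.5  # % dry weight

    def __post_init__(self):
        if self.length <= 0 or self.max_width <= 0:
            raise ValueError("leaf length and width must be positive")
        for name in ("width_profile", "inclination_profile", "twist_profile"):
            object.__setattr__(self, name, _profile(getattr(self, name)))
        w = self.width_profile[:, 1]
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("width profile must lie in [0, 1]")
        if w[-1] != 0.0:
            raise ValueError("width profile must be 0 at the tip")
        if np.all(w[:-1] <= 1e-9):
            raise ValueError("degenerate width profile")


@dataclass(frozen=True)
class SpikeBlueprint:
    """Spike geometry: rachis, two alternating spikelet ranks, awns."""

    length: float  # m
    spikelet_count: int
    spikelet_size: tuple = (0.010, 0.005, 0.004)  # length, width, depth, m
    spikelet_mass: float = 0.031e-3  # mass proxy, kg
    awn_length: float = 0.0  # m per spikelet
    awn_diameter: float = 0.0005  # m
    lnc: float = 1.8

    def __post_init__(self):
        if self.spikelet_count < 0 or self.length < 0:
            raise ValueError("spike counts and lengths must be non-negative")
        if self.awn_length < 0:
            raise ValueError("awn length must be non-negative")


@dataclass(frozen=True)
class TillerBlueprint:
    """One tiller: stem segments, leaves, optional spike, per-tissue LNC."""

    stem_height: float
    stem_segments: tuple  # ((length, diameter), ...)
    leaves: tuple  # LeafBlueprint, ...
    spike: Optional[SpikeBlueprint] = None
    stem_lnc: float = 1.5

    def __post_init__(self):
        segs = tuple((float(l), float(d)) for l, d in self.stem_segments)
        object.__setattr__(self, "stem_segments", segs)
        object.__setattr__(self, "leaves", tuple(self.leaves))
        total = sum(l for l, _ in segs)
        if abs(total - self.stem_height) > 1e-6:
            raise ValueError("stem segments must sum to stem height")
        for leaf in self.leaves:
            if leaf.insertion_height > self.stem_height + 1e-9:
                raise ValueError("leaf insertion above stem height")


# ---------------------------------------------------------------------------
# organ builders
# ---------------------------------------------------------------------------

def build_leaf_mesh(blueprint: LeafBlueprint, segments: int = 16,
                    azimuth_deg: float = 0.0, organ_id: int = 0) -> OrganMesh:
    """Triangulate a leaf ribbon from its blueprint.

    The midrib is integrated from the inclination profile in the vertical
    plane at ``azimuth_deg``; cross ribs take the local width and rotate
    about the midrib tangent by the twist profile.  Produces 2*segments
    patches rooted at the insertion point.
    """
    if segments < 4:
        raise ValueError("need at least 4 segments")
    bp = blueprint
    s_nodes = np.linspace(0.0, 1.0, segments + 1)
    incl = np.radians(np.interp(s_nodes, bp.inclination_profile[:, 0],
                                bp.inclination_profile[:, 1]))
    twist = np.radians(np.interp(s_nodes, bp.twist_profile[:, 0],
                                 bp.twist_profile[:, 1]))
    width = np.interp(s_nodes, bp.width_profile[:, 0],
                      bp.width_profile[:, 1]) * bp.max_width
    az = math.radians(azimuth_deg)
    plane = np.array([math.cos(az), math.sin(az), 0.0])
    ds = bp.length / segments

    # integrate the midrib using mid-segment inclination
    pts = np.zeros((segments + 1, 3))
    for k in range(segments):
        a = 0.5 * (incl[k] + incl[k + 1])
        step = math.sin(a) * plane + np.array([0.0, 0.0, math.cos(a)])
        pts[k + 1] = pts[k] + ds * step
    pts[:, 2] += bp.insertion_height

    # cross direction: horizontal normal to the leaf plane, rotated by twist
    # about the local midrib tangent
    cross0 = np.array([-plane[1], plane[0], 0.0])
    left = np.zeros((segments + 1, 3))
    right = np.zeros((segments + 1, 3))
    tangents = np.gradient(pts, axis=0)
    for k in range(segments + 1):
        t = tangents[k]
        t = t / np.linalg.norm(t)
        c = _rotate_about(cross0, t, twist[k])
        half = 0.5 * width[k]
        left[k] = pts[k] - half * c
        right[k] = pts[k] + half * c

    props = optical_props_from_lnc(bp.lnc, "leaf")
    tris = []
    for k in range(segments):
        quad = (left[k], right[k], right[k + 1], left[k + 1])
        tris.append((quad[0], quad[1], quad[2]))
        tris.append((quad[0], quad[2], quad[3]))
    tris = np.array(tris)
    keep = _nondegenerate(tris)
    tris = tris[keep]
    n = len(tris)
    return OrganMesh(tris, np.full(n, TISSUE_LEAF), np.full(n, organ_id),
                     np.full(n, props.kr), np.full(n, props.kt))


def _rotate_about(v, axis, angle):
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    return (v * c + np.cross(axis, v) * s
            + axis * np.dot(axis, v) * (1.0 - c))


def _nondegenerate(tris, tol=1e-14):
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1) > tol


def _box(centre, size) -> np.ndarray:
    """12 triangles of a closed axis-aligned box (local frame)."""
    cx, cy, cz = centre
    hx, hy, hz = size[0] / 2, size[1] / 2, size[2] / 2
    v = np.array([[cx + sx * hx, cy + sy * hy, cz + sz * hz]
                  for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    faces = [(0, 1, 3), (0, 3, 2), (4, 6, 7), (4, 7, 5),
             (0, 4, 5), (0, 5, 1), (2, 3, 7), (2, 7, 6),
             (0, 2, 6), (0, 6, 4), (1, 5, 7), (1, 7, 3)]
    return v[np.array(faces)]


def _prism(p0, p1, radius, nsides=3) -> np.ndarray:
    """Open triangulated prism from p0 to p1 with a regular polygon section."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    ln = np.linalg.norm(axis)
    if ln < 1e-12:
        return np.zeros((0, 3, 3))
    axis = axis / ln
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    ang = 2 * np.pi * np.arange(nsides) / nsides
    ring = np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w)
    lo = p0 + radius * ring
    hi = p1 + radius * ring
    tris = []
    for i in range(nsides):
        j = (i + 1) % nsides
        tris.append((lo[i], lo[j], hi[j]))
        tris.append((lo[i], hi[j], hi[i]))
    return np.array(tris)


def build_spike_mesh(blueprint: SpikeBlueprint, organ_id: int = 0) -> OrganMesh:
    """Spike mesh in a local frame with the rachis base at the origin.

    The rachis is a thin 4-sided prism along +z; spikelets are closed boxes
    alternating left/right; each spikelet carries one awn (3-sided prism)
    rising outward when awn_length > 0.
    """
    bp = blueprint
    parts, tissues = [], []
    if bp.length > 0:
        rachis = _prism((0, 0, 0), (0, 0, bp.length), 0.0012, nsides=4)
        parts.append(rachis)
        tissues.append(np.full(len(rachis), TISSUE_SPIKELET))
    sl, sw, sd = bp.spikelet_size
    n = bp.spikelet_count
    for k in range(n):
        z = bp.length * (k + 0.5) / max(n, 1)
        side = 1.0 if k % 2 == 0 else -1.0
        centre = (side * (sw / 2 + 0.0012), 0.0, z)
        box = _box(centre, (sw, sd, sl))
        parts.append(box)
        tissues.append(np.full(len(box), TISSUE_SPIKELET))
        if bp.awn_length > 0:
            base = np.array([side * (sw / 2 + 0.0012), 0.0, z + sl / 2])
            tip = base + bp.awn_length * np.array(
                [side * 0.26, 0.0, 0.966])  # ~15 deg off the rachis
            awn = _prism(base, tip, bp.awn_diameter / 2, nsides=3)
            parts.append(awn)
            tissues.append(np.full(len(awn), TISSUE_AWN))
    if not parts:
        return OrganMesh(np.zeros((0, 3, 3)), np.zeros(0), np.zeros(0),
                         np.zeros(0), np.zeros(0))
    tris = np.concatenate(parts)
    tissue = np.concatenate(tissues)
    keep = _nondegenerate(tris)
    tris, tissue = tris[keep], tissue[keep]
    props = optical_props_from_lnc(bp.lnc, "spike")
    m = len(tris)
    return OrganMesh(tris, tissue, np.full(m, organ_id),
                     np.full(m, props.kr), np.zeros(m))


def build_tiller(blueprint: TillerBlueprint, leaf_segments: int = 16,
                 spike_base_height: Optional[float] = None) -> OrganMesh:
    """Assemble stem, leaves and spike into one tiller mesh (base at origin).

    Leaf azimuths alternate by 180 degrees with rank (distichous
    phyllotaxis).  Organ ids: stem 0, leaves 10 + rank, spike 1.
    """
    bp = blueprint
    parts = []
    stem_props = optical_props_from_lnc(bp.stem_lnc, "stem")
    z = 0.0
    stem_tris = []
    for length, diam in bp.stem_segments:
        stem_tris.append(_prism((0, 0, z), (0, 0, z + length), diam / 2, nsides=4))
        z += length
    if stem_tris:
        tris = np.concatenate(stem_tris)
        n = len(tris)
        parts.append(OrganMesh(tris, np.full(n, TISSUE_STEM), np.zeros(n),
                               np.full(n, stem_props.kr), np.zeros(n)))

    heights = [leaf.insertion_height for leaf in bp.leaves]
    if len(set(np.round(heights, 6))) < len(heights):
        logger.info("build_tiller: overlapping leaf insertion heights")
    for leaf in bp.leaves:
        azimuth = 180.0 * (leaf.rank % 2)
        parts.append(build_leaf_mesh(leaf, segments=leaf_segments,
                                     azimuth_deg=azimuth,
                                     organ_id=10 + leaf.rank))
    if bp.spike is not None:
        base = bp.stem_height if spike_base_height is None else spike_base_height
        spike = build_spike_mesh(bp.spike, organ_id=1)
        parts.append(spike.translated((0.0, 0.0, base)))
    return OrganMesh.concatenate(parts)


# ---------------------------------------------------------------------------
# canopy assembly
# ---------------------------------------------------------------------------

@dataclass
class Canopy:
    """Positioned tiller meshes over a periodic ground domain."""

    mesh: OrganMesh
    row_spacing: float
    in_row_spacing: float
    domain: tuple  # (x extent, y extent), m
    alpha0: float  # maximal tiller lean angle, degrees
    seed: int
    ground_reflectance: float = 0.10
    tiller_count: int = 0
    placements: tuple = ()

    def has_spikes(self) -> bool:
        return bool(np.any(self.mesh.tissue == TISSUE_SPIKELET))


def _rot_z(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(a):
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def assemble_canopy(library: Sequence[OrganMesh], row_spacing: float,
                    in_row_spacing: float, domain: tuple, alpha0: float,
                    seed: int, ground_reflectance: float = 0.10) -> Canopy:
    """Plant random library tillers on the planting grid.

    Rows run along y at ``row_spacing`` intervals in x; plants sit at
    ``in_row_spacing`` intervals in y.  Each position draws a library tiller,
    a lean angle uniform on [0, alpha0] and an azimuth uniform on [0, 360).
    Deterministic under the seed.
    """
    if not library:
        raise ValueError("tiller library is empty")
    lx, ly = domain
    if row_spacing > lx + 1e-9 or in_row_spacing > ly + 1e-9:
        raise ValueError("spacing larger than domain")
    n_rows = int(math.floor(lx / row_spacing + 1e-9))
    n_in = int(math.floor(ly / in_row_spacing + 1e-9))
    rng = np.random.default_rng(seed)
    meshes = []
    placements = []
    for i in range(n_rows):
        for j in range(n_in):
            x = (i + 0.5) * row_spacing
            y = (j + 0.5) * in_row_spacing
            pick = int(rng.integers(len(library)))
            lean = math.radians(float(rng.uniform(0.0, alpha0)))
            azim = float(rng.uniform(0.0, 2 * math.pi))
            rot = _rot_z(azim) @ _rot_x(lean)
            m = library[pick].transformed(rot, (x, y, 0.0))
            # re-key organ ids per tiller so organs stay distinguishable
            tiller_idx = i * n_in + j
            m = OrganMesh(m.triangles, m.tissue,
                          m.organ_id + 1000 * tiller_idx, m.kr, m.kt)
            meshes.append(m)
            placements.append((x, y, pick, math.degrees(lean),
                               math.degrees(azim)))
    mesh = OrganMesh.concatenate(meshes)
    # wrap patches into the periodic domain by centroid
    if len(mesh):
        cent = mesh.triangles.mean(axis=1)
        shift = np.zeros_like(cent)
        shift[:, 0] = -np.floor(cent[:, 0] / lx) * lx
        shift[:, 1] = -np.floor(cent[:, 1] / ly) * ly
        mesh = OrganMesh(mesh.triangles + shift[:, None, :], mesh.tissue,
                         mesh.organ_id, mesh.kr, mesh.kt)
    return Canopy(mesh=mesh, row_spacing=row_spacing,
                  in_row_spacing=in_row_spacing, domain=tuple(domain),
                  alpha0=alpha0, seed=seed,
                  ground_reflectance=ground_reflectance,
                  tiller_count=n_rows * n_in, placements=tuple(placements))


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

PERTURBATION_KINDS = (
    "scale_height", "flatten_leaves", "straighten_leaves", "lower_spike",
    "remove_spikes", "scale_awn_length", "scale_spike_length",
    "scale_spikelet_size", "set_tiller_density",
)


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str
    factor: float = 1.0
    row_spacing: Optional[float] = None
    in_row_spacing: Optional[float] = None

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


def perturb_blueprint(bp: TillerBlueprint, spec: PerturbationSpec,
                      ) -> TillerBlueprint:
    """Blueprint-level architectural edit; organ sizes/shapes preserved
    except for the targeted trait."""
    k, f = spec.kind, spec.factor
    if k == "scale_height":
        segs = tuple((l * f, d) for l, d in bp.stem_segments)
        leaves = tuple(replace(leaf, insertion_height=leaf.insertion_height * f)
                       for leaf in bp.leaves)
        return replace(bp, stem_height=bp.stem_height * f, stem_segments=segs,
                       leaves=leaves)
    if k == "flatten_leaves":
        leaves = tuple(replace(leaf, twist_profile=np.array([[0.0, 0.0], [1.0, 0.0]]))
                       for leaf in bp.leaves)
        return replace(bp, leaves=leaves)
    if k == "straighten_leaves":
        leaves = []
        for leaf in bp.leaves:
            base = leaf.inclination_profile[0, 1]
            leaves.append(replace(leaf, inclination_profile=np.array(
                [[0.0, base], [1.0, base]])))
        return replace(bp, leaves=tuple(leaves))
    if k == "scale_awn_length":
        if bp.spike is None:
            return bp
        return replace(bp, spike=replace(bp.spike,
                                         awn_length=bp.spike.awn_length * f))
    if k == "scale_spike_length":
        if bp.spike is None:
            return bp
        return replace(bp, spike=replace(bp.spike, length=bp.spike.length * f))
    if k == "scale_spikelet_size":
        if bp.spike is None:
            return bp
        size = tuple(s * f ** (1.0 / 3.0) for s in bp.spike.spikelet_size)
        return replace(bp, spike=replace(
            bp.spike, spikelet_size=size,
            spikelet_mass=bp.spike.spikelet_mass * f))
    if k in ("remove_spikes",):
        return replace(bp, spike=None)
    if k == "lower_spike":
        # drop the spike base to the flag-leaf insertion by shortening the
        # top internode(s); leaf insertions are unchanged
        if bp.spike is None or not bp.leaves:
            return bp
        new_h = max(leaf.insertion_height for leaf in bp.leaves)
        drop = bp.stem_height - new_h
        segs = []
        for length, d in reversed(bp.stem_segments):
            take = min(length, max(drop, 0.0))
            drop -= take
            if length - take > 1e-9:
                segs.append((length - take, d))
        segs.reverse()
        return replace(bp, stem_height=new_h, stem_segments=tuple(segs))
    raise ValueError(f"perturbation {k!r} is not a blueprint edit")


def apply_perturbation(canopy: Canopy, spec: PerturbationSpec,
                       library_blueprints: Optional[Sequence[TillerBlueprint]] = None,
                       leaf_segments: int = 16) -> Canopy:
    """Apply an architectural what-if and re-assemble with the stored seed.

    ``remove_spikes`` filters patches in place; every other kind edits the
    blueprints (``library_blueprints`` required) and rebuilds the canopy with
    identical placement randomness.
    """
    if spec.kind == "remove_spikes":
        mask = ~np.isin(canopy.mesh.tissue, (TISSUE_SPIKELET, TISSUE_AWN))
        return replace(canopy, mesh=canopy.mesh.subset(mask))
    if library_blueprints is None:
        raise ValueError(f"perturbation {spec.kind!r} needs the blueprint library")
    row = canopy.row_spacing
    in_row = canopy.in_row_spacing
    if spec.kind == "set_tiller_density":
        row = spec.row_spacing or row
        in_row = spec.in_row_spacing or in_row
        bps = list(library_blueprints)
    else:
        bps = [perturb_blueprint(bp, spec) for bp in library_blueprints]
    meshes = [build_tiller(bp, leaf_segments=leaf_segments) for bp in bps]
    return assemble_canopy(meshes, row, in_row, canopy.domain, canopy.alpha0,
                           canopy.seed, canopy.ground_reflectance)
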