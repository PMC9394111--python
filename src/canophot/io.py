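"""Readers and writers for the delimited-text and mesh interchange formats.

A-Q curves, temperature-response tables, weather series and light maps are
tab-separated tables with ``# key: value`` header metadata lines.
Blueprints travel as YAML; meshes as OBJ plus a sidecar table with per-face
tissue class, organ id and optical properties.
"""

from __future__ import annotations

import io as _io
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from canophot.architecture import (
    LeafBlueprint,
    OrganMesh,
    SpikeBlueprint,
    TillerBlueprint,
    TISSUE_NAMES,
    TISSUE_CODES,
)
from canophot.canopy_sim import WeatherSeries
from canophot.optics import LightMap
from canophot.physiology import AQCurve, TempResponseTable

__all__ = [
    "write_aq_curve", "read_aq_curve",
    "write_temp_table", "read_temp_table",
    "write_weather", "read_weather",
    "write_lightmap_table",
    "write_blueprint", "read_blueprint",
    "write_mesh_obj", "read_mesh_obj", "write_mesh_ply",
    "load_run_config",
]


def _write_table(path, df, meta):
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_table(path):
    meta = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            k, _, v = line.lstrip("# ").partition(":")
            meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    try:
        df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])), sep="\t")
    except Exception as err:
        raise ValueError(
            f"{path}: cannot parse table body starting at line "
            f"{body_start + 1}: {err}") from err
    return df, meta


def write_aq_curve(path, curve: AQCurve):
    df = pd.DataFrame({"ppfd_umol_m2_s": curve.ppfd,
                       "a_net_umol_m2_s": curve.a_net})
    _write_table(path, df, {
        "tissue": curve.tissue_label,
        "temperature_C": curve.temperature,
        "area_m2": curve.area_basis,
    })


def read_aq_curve(path) -> AQCurve:
    df, meta = _read_table(path)
    for col in ("ppfd_umol_m2_s", "a_net_umol_m2_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return AQCurve(
        ppfd=df["ppfd_umol_m2_s"].to_numpy(),
        a_net=df["a_net_umol_m2_s"].to_numpy(),
        temperature=float(meta.get("temperature_C", "25")),
        tissue_label=meta.get("tissue", "leaf"),
        area_basis=float(meta.get("area_m2", "nan")),
    )


def write_temp_table(path, table: TempResponseTable):
    temps = sorted(set(table.a1500[:, 0]) | set(table.rd[:, 0]))
    a_map = dict(zip(table.a1500[:, 0], table.a1500[:, 1]))
    r_map = dict(zip(table.rd[:, 0], table.rd[:, 1]))
    df = pd.DataFrame({
        "temp_C": temps,
        "a1500": [a_map.get(t, np.nan) for t in temps],
        "rd": [r_map.get(t, np.nan) for t in temps],
    })
    _write_table(path, df, {})


def read_temp_table(path) -> TempResponseTable:
    df, _ = _read_table(path)
    a = df.dropna(subset=["a1500"])[["temp_C", "a1500"]].to_numpy()
    r = df.dropna(subset=["rd"])[["temp_C", "rd"]].to_numpy()
    return TempResponseTable(a1500=a, rd=r)


def write_weather(path, weather: WeatherSeries):
    df = weather.frame.copy()
    df["time_iso"] = df.pop("time").dt.strftime("%Y-%m-%dT%H:%M:%S")
    df = df[["time_iso", "ppfd_total", "direct_fraction", "temp_C"]]
    _write_table(path, df, {
        "latitude": weather.latitude, "longitude": weather.longitude})


def read_weather(path) -> WeatherSeries:
    df, meta = _read_table(path)
    for col in ("time_iso", "ppfd_total", "direct_fraction", "temp_C"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    frame = df.rename(columns={"time_iso": "time"})
    frame["time"] = pd.to_datetime(frame["time"])
    return WeatherSeries(frame,
                         latitude=float(meta.get("latitude", "30.945")),
                         longitude=float(meta.get("longitude", "121.134")))


def write_lightmap_table(path, mesh: OrganMesh, lightmap: LightMap):
    df = pd.DataFrame({
        "patch_id": np.arange(len(mesh)),
        "tissue_class": [TISSUE_NAMES[int(t)] for t in mesh.tissue],
        "organ_id": mesh.organ_id,
        "area_m2": mesh.areas(),
        "incident_ppfd": lightmap.incident_ppfd,
        "absorbed_ppfd": lightmap.absorbed_ppfd,
    })
    _write_table(path, df, {
        "injected": lightmap.injected,
        "canopy_absorbed": lightmap.canopy_absorbed,
        "ground_absorbed": lightmap.ground_absorbed,
        "escaped": lightmap.escaped,
        "discarded": lightmap.discarded,
        "seed": lightmap.seed,
        "rays_direct": lightmap.rays_direct,
        "rays_diffuse": lightmap.rays_diffuse,
    })


# ---------------------------------------------------------------------------
# blueprints (YAML)
# ---------------------------------------------------------------------------

def _leaf_to_dict(leaf: LeafBlueprint) -> dict:
    d = asdict(leaf)
    for k in ("width_profile", "inclination_profile", "twist_profile"):
        d[k] = np.asarray(d[k]).tolist()
    return d


def write_blueprint(path, bp: TillerBlueprint):
    d = {
        "stem_height": bp.stem_height,
        "stem_segments": [list(s) for s in bp.stem_segments],
        "stem_lnc": bp.stem_lnc,
        "leaves": [_leaf_to_dict(l) for l in bp.leaves],
        "spike": None if bp.spike is None else asdict(bp.spike),
    }
    if d["spike"] is not None:
        d["spike"]["spikelet_size"] = list(d["spike"]["spikelet_size"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_blueprint(path) -> TillerBlueprint:
    d = yaml.safe_load(Path(path).read_text())
    leaves = tuple(LeafBlueprint(**leaf) for leaf in d.get("leaves", []))
    spike = d.get("spike")
    if spike is not None:
        spike["spikelet_size"] = tuple(spike["spikelet_size"])
        spike = SpikeBlueprint(**spike)
    return TillerBlueprint(
        stem_height=d["stem_height"],
        stem_segments=tuple(tuple(s) for s in d["stem_segments"]),
        leaves=leaves, spike=spike, stem_lnc=d.get("stem_lnc", 1.5))


# ---------------------------------------------------------------------------
# meshes (OBJ + sidecar face table)
# ---------------------------------------------------------------------------

def write_mesh_obj(path, mesh: OrganMesh):
    """OBJ vertices+faces plus ``<path>.faces.tsv`` with per-face attributes."""
    import trimesh

    n = len(mesh)
    verts = mesh.triangles.reshape(-1, 3)
    faces = np.arange(3 * n).reshape(-1, 3)
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    tm.export(str(path), file_type="obj")
    side = pd.DataFrame({
        "face_id": np.arange(n),
        "tissue_class": [TISSUE_NAMES[int(t)] for t in mesh.tissue],
        "organ_id": mesh.organ_id,
        "kr": mesh.kr,
        "kt": mesh.kt,
    })
    side.to_csv(str(path) + ".faces.tsv", sep="\t", index=False)


def write_mesh_ply(path, mesh: OrganMesh, face_scalar=None):
    """ASCII PLY for visualization; optional per-face scalar (e.g. absorbed
    PPFD) exported as a face quality attribute."""
    import trimesh

    n = len(mesh)
    verts = mesh.triangles.reshape(-1, 3)
    faces = np.arange(3 * n).reshape(-1, 3)
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if face_scalar is not None:
        scal = np.asarray(face_scalar, dtype=float)
        lo, hi = scal.min(), scal.max()
        t = (scal - lo) / (hi - lo) if hi > lo else np.zeros(n)
        colors = np.column_stack([
            (255 * t).astype(np.uint8),
            np.full(n, 64, dtype=np.uint8),
            (255 * (1 - t)).astype(np.uint8),
            np.full(n, 255, dtype=np.uint8)])
        tm.visual.face_colors = colors
    data = tm.export(file_type="ply", encoding="ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def read_mesh_obj(path) -> OrganMesh:
    import trimesh

    tm = trimesh.load(str(path), file_type="obj", process=False)
    side = pd.read_csv(str(path) + ".faces.tsv", sep="\t")
    tris = tm.vertices[tm.faces]
    if len(tris) != len(side):
        raise ValueError(f"{path}: sidecar face table does not match OBJ")
    return OrganMesh(
        triangles=np.asarray(tris, dtype=float),
        tissue=np.array([TISSUE_CODES[t] for t in side["tissue_class"]]),
        organ_id=side["organ_id"].to_numpy(),
        kr=side["kr"].to_numpy(),
        kt=side["kt"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

RUN_CONFIG_KEYS = {
    "seed", "rays_direct", "rays_diffuse", "timestep_min", "stage",
    "library_size", "row_spacing", "in_row_spacing", "domain", "alpha0",
    "weather_kind", "peak_ppfd", "temp_range", "out_dir", "leaf_segments",
    "analysis_window",
}


def load_run_config(path) -> dict:
    """Load a run config; unknown keys are rejected, seeds must be explicit."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(cfg) - RUN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ValueError("config must set an explicit seed")
    return cfg
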