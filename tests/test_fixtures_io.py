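"""Synthetic-data generators, file round-trips and the CLI."""

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from canophot import io as cio
from canophot.architecture import build_tiller
from canophot.cli import main as cli_main
from canophot.fixtures import (
    LEAF_LIGHT_LEVELS,
    SPIKE_LIGHT_LEVELS,
    STAGE_PRESETS,
    generate_aq_curve,
    generate_tiller_library,
    generate_weather_day,
)
from canophot.optics import LightEnvironment, trace_canopy
from canophot.physiology import PhotoParams, TempResponseTable, fit_aq_curve


class TestTillerLibrary:
    def test_heading_preset_all_spiked(self):
        lib = generate_tiller_library(STAGE_PRESETS["heading"], 12, seed=0)
        assert len(lib) == 12
        assert all(bp.spike is not None for bp in lib)

    def test_tillering_preset_no_spikes(self):
        lib = generate_tiller_library(STAGE_PRESETS["tillering"], 8, seed=0)
        assert all(bp.spike is None for bp in lib)

    def test_seeded_determinism(self):
        a = generate_tiller_library(STAGE_PRESETS["milking"], 5, seed=3)
        b = generate_tiller_library(STAGE_PRESETS["milking"], 5, seed=3)
        assert all(x.stem_height == y.stem_height for x, y in zip(a, b))
        c = generate_tiller_library(STAGE_PRESETS["milking"], 5, seed=4)
        assert any(x.stem_height != y.stem_height for x, y in zip(a, c))

    def test_blueprints_buildable(self):
        for stage in STAGE_PRESETS:
            lib = generate_tiller_library(STAGE_PRESETS[stage], 2, seed=1)
            for bp in lib:
                mesh = build_tiller(bp, leaf_segments=6)
                assert len(mesh) > 0
                assert np.all(mesh.areas() > 0)


class TestWeatherGenerator:
    def test_overcast_has_no_direct(self):
        w = generate_weather_day("overcast", 1500.0, (10, 20), seed=0)
        assert (w.frame["direct_fraction"] == 0).all()

    def test_midnight_dark(self):
        w = generate_weather_day("sunny", 2000.0, (10, 20), seed=0)
        night = w.frame[w.frame["time"].dt.hour < 3]
        assert (night["ppfd_total"] == 0).all()

    def test_sunny_peak_at_noon(self):
        w = generate_weather_day("sunny", 2000.0, (10, 20), seed=0)
        assert w.frame["ppfd_total"].max() == pytest.approx(2000.0)
        idx = w.frame["ppfd_total"].idxmax()
        assert w.frame.loc[idx, "time"].hour == 12

    def test_cadence_and_temperature_range(self):
        w = generate_weather_day("cloudy", 1500.0, (8.0, 22.0), seed=1,
                                 cadence_min=10)
        dt = w.frame["time"].diff().dropna().dt.total_seconds()
        assert (dt == 600).all()
        assert w.frame["temp_C"].between(8.0 - 1e-9, 22.0 + 1e-9).all()

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            generate_weather_day("hail", 1000.0, (5, 10), seed=0)


class TestAQGenerator:
    def test_noiseless_matches_forward_model(self):
        p = PhotoParams(24.0, 1.1, 0.05, 0.8)
        c = generate_aq_curve(p, SPIKE_LIGHT_LEVELS, 0.0, 25.0, seed=0)
        res = fit_aq_curve(c, absorptance=1.0)
        assert res.params.amax_net_25 == pytest.approx(24.0, rel=1e-5)

    def test_seeded_noise_reproducible(self):
        p = PhotoParams(24.0, 1.1, 0.05, 0.8)
        a = generate_aq_curve(p, LEAF_LIGHT_LEVELS, 0.3, 25.0, seed=9)
        b = generate_aq_curve(p, LEAF_LIGHT_LEVELS, 0.3, 25.0, seed=9)
        assert np.array_equal(a.a_net, b.a_net)


class TestRoundTrips:
    def test_aq_curve(self, tmp_path):
        p = PhotoParams(24.0, 1.1, 0.05, 0.8)
        c = generate_aq_curve(p, LEAF_LIGHT_LEVELS, 0.2, 23.5, seed=2,
                              tissue_label="stem", area_basis=0.003)
        f = tmp_path / "aq.tsv"
        cio.write_aq_curve(f, c)
        c2 = cio.read_aq_curve(f)
        assert np.allclose(c2.ppfd, c.ppfd)
        assert np.allclose(c2.a_net, c.a_net)
        assert c2.temperature == c.temperature
        assert c2.tissue_label == "stem"

    def test_temp_table(self, tmp_path):
        t = TempResponseTable(
            a1500=np.array([[7.0, 10.0], [15.0, 18.0], [25.0, 24.0],
                            [28.0, 23.0]]),
            rd=np.array([[7.0, 0.4], [15.0, 0.7], [25.0, 1.0]]))
        f = tmp_path / "temp.tsv"
        cio.write_temp_table(f, t)
        t2 = cio.read_temp_table(f)
        assert np.allclose(t2.a1500, t.a1500)
        assert np.allclose(t2.rd, t.rd)

    def test_weather(self, tmp_path):
        w = generate_weather_day("sunny", 1800.0, (12, 25), seed=5)
        f = tmp_path / "w.tsv"
        cio.write_weather(f, w)
        w2 = cio.read_weather(f)
        pd.testing.assert_frame_equal(
            w.frame, w2.frame, check_exact=False, rtol=1e-12)
        assert w2.latitude == w.latitude

    def test_blueprint(self, tmp_path):
        bp = generate_tiller_library(STAGE_PRESETS["heading"], 1, seed=6)[0]
        f = tmp_path / "tiller.yaml"
        cio.write_blueprint(f, bp)
        bp2 = cio.read_blueprint(f)
        assert bp2.stem_height == pytest.approx(bp.stem_height)
        assert len(bp2.leaves) == len(bp.leaves)
        assert bp2.spike.awn_length == pytest.approx(bp.spike.awn_length)
        assert np.array_equal(build_tiller(bp2).triangles,
                              build_tiller(bp).triangles)

    def test_mesh_obj(self, tmp_path):
        bp = generate_tiller_library(STAGE_PRESETS["heading"], 1, seed=6)[0]
        mesh = build_tiller(bp, leaf_segments=6)
        f = tmp_path / "tiller.obj"
        cio.write_mesh_obj(f, mesh)
        mesh2 = cio.read_mesh_obj(f)
        assert np.allclose(mesh2.triangles, mesh.triangles, atol=1e-6)
        assert np.array_equal(mesh2.tissue, mesh.tissue)
        assert np.allclose(mesh2.kr, mesh.kr)

    def test_mesh_ply_ascii(self, tmp_path):
        bp = generate_tiller_library(STAGE_PRESETS["heading"], 1, seed=6)[0]
        mesh = build_tiller(bp, leaf_segments=6)
        f = tmp_path / "tiller.ply"
        cio.write_mesh_ply(f, mesh, face_scalar=mesh.areas())
        head = f.read_bytes()[:200]
        assert head.startswith(b"ply")
        assert b"ascii" in head

    def test_lightmap_table(self, tmp_path):
        from conftest import black_patch_layer, layer_canopy

        mesh = black_patch_layer(0.5, seed=1)
        can = layer_canopy(mesh)
        env = LightEnvironment(1000.0, np.array([0, 0, -1.0]), 0.0)
        lm = trace_canopy(can, env, 2000, 1, seed=1)
        f = tmp_path / "lightmap.tsv"
        cio.write_lightmap_table(f, mesh, lm)
        text = f.read_text()
        assert "# injected:" in text
        df = pd.read_csv(f, sep="\t", comment="#")
        assert len(df) == len(mesh)


class TestRunConfig:
    def test_unknown_keys_rejected(self, tmp_path):
        f = tmp_path / "cfg.yaml"
        f.write_text(yaml.safe_dump({"seed": 1, "frobnicate": 2}))
        with pytest.raises(ValueError, match="unknown"):
            cio.load_run_config(f)

    def test_missing_seed_rejected(self, tmp_path):
        f = tmp_path / "cfg.yaml"
        f.write_text(yaml.safe_dump({"rays_direct": 100}))
        with pytest.raises(ValueError, match="seed"):
            cio.load_run_config(f)


class TestCLI:
    def test_fixtures_then_simulate_day(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({
            "seed": 3, "stage": "heading", "library_size": 2,
            "out_dir": str(tmp_path), "timestep_min": 180,
            "rays_direct": 1500, "rays_diffuse": 800,
            "domain": [0.2, 0.0198], "in_row_spacing": 0.0066,
            "leaf_segments": 6,
        }))
        runner = CliRunner()
        r1 = runner.invoke(cli_main, ["make-fixtures", "--config", str(cfg)])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(cli_main, ["simulate-day", "--config", str(cfg)])
        assert r2.exit_code == 0, r2.output
        assert (tmp_path / "daily_accounting.tsv").exists()
        table = pd.read_csv(tmp_path / "daily_accounting.tsv", sep="\t")
        assert {"an", "ag", "ia", "lue"} <= set(table.columns)

    def test_fit_subcommand(self, tmp_path):
        p = PhotoParams(24.0, 1.1, 0.05, 0.8)
        c = generate_aq_curve(p, LEAF_LIGHT_LEVELS, 0.0, 25.0, seed=0)
        f = tmp_path / "aq.tsv"
        cio.write_aq_curve(f, c)
        runner = CliRunner()
        r = runner.invoke(cli_main, ["fit", "aq", str(f),
                                     "--absorptance", "1.0"])
        assert r.exit_code == 0, r.output
        import json

        fitted = json.loads(r.output)
        assert fitted["amax_net_25"] == pytest.approx(24.0, rel=1e-5)
        assert fitted["converged"] is True

    def test_corrupt_weather_nonzero_exit(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({
            "seed": 3, "out_dir": str(tmp_path), "library_size": 1,
        }))
        runner = CliRunner()
        runner.invoke(cli_main, ["make-fixtures", "--config", str(cfg)])
        (tmp_path / "weather.tsv").write_text("garbage\nno\tcolumns\n")
        r = runner.invoke(cli_main, ["simulate-day", "--config", str(cfg)])
        assert r.exit_code != 0
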