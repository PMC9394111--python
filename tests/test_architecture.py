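"""Organ meshing, canopy assembly and architectural perturbations."""

import numpy as np
import pytest

from canophot.architecture import (
    Canopy,
    LeafBlueprint,
    OrganMesh,
    PerturbationSpec,
    SpikeBlueprint,
    TillerBlueprint,
    TISSUE_AWN,
    TISSUE_LEAF,
    TISSUE_SPIKELET,
    TISSUE_STEM,
    apply_perturbation,
    assemble_canopy,
    build_leaf_mesh,
    build_spike_mesh,
    build_tiller,
    perturb_blueprint,
)
from canophot.fixtures import STAGE_PRESETS, generate_tiller_library


def flat_leaf(length=0.2, width=0.02, insertion=0.0, incl=90.0):
    """A planar leaf: constant inclination, no twist."""
    return LeafBlueprint(
        rank=1, length=length, max_width=width,
        width_profile=np.array([[0.0, 1.0], [0.9, 1.0], [1.0, 0.0]]),
        inclination_profile=np.array([[0.0, incl], [1.0, incl]]),
        twist_profile=np.array([[0.0, 0.0], [1.0, 0.0]]),
        insertion_height=insertion, lnc=2.5)


class TestLeafMesh:
    def test_area_matches_width_quadrature(self):
        bp = flat_leaf()
        mesh = build_leaf_mesh(bp, segments=40)
        s = np.linspace(0, 1, 2001)
        w = np.interp(s, bp.width_profile[:, 0], bp.width_profile[:, 1])
        expected = np.trapezoid(w, s) * bp.length * bp.max_width
        assert mesh.total_area() == pytest.approx(expected, rel=0.01)

    def test_horizontal_leaf_projected_equals_total(self):
        mesh = build_leaf_mesh(flat_leaf(incl=90.0), segments=20)
        # all patches lie in a horizontal plane
        z = mesh.triangles[:, :, 2]
        assert np.ptp(z) < 1e-9
        e1 = mesh.triangles[:, 1] - mesh.triangles[:, 0]
        e2 = mesh.triangles[:, 2] - mesh.triangles[:, 0]
        projected = 0.5 * np.abs(np.cross(e1, e2)[:, 2]).sum()
        assert projected == pytest.approx(mesh.total_area(), rel=1e-9)

    def test_mesh_convergence_in_segments(self):
        bp = flat_leaf(incl=45.0)
        a1 = build_leaf_mesh(bp, segments=24).total_area()
        a2 = build_leaf_mesh(bp, segments=48).total_area()
        assert abs(a2 - a1) / a1 < 0.005

    def test_degenerate_width_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            LeafBlueprint(
                rank=1, length=0.2, max_width=0.02,
                width_profile=np.array([[0.0, 0.0], [1.0, 0.0]]),
                inclination_profile=np.array([[0.0, 45.0], [1.0, 45.0]]),
                twist_profile=np.array([[0.0, 0.0], [1.0, 0.0]]),
                insertion_height=0.0)


class TestSpikeMesh:
    def test_zero_awn_length_no_awn_patches(self):
        mesh = build_spike_mesh(SpikeBlueprint(length=0.09, spikelet_count=12,
                                               awn_length=0.0))
        assert not np.any(mesh.tissue == TISSUE_AWN)

    def test_spikelet_groups_match_count(self):
        n = 9
        mesh = build_spike_mesh(SpikeBlueprint(length=0.09, spikelet_count=n,
                                               awn_length=0.05))
        assert np.count_nonzero(mesh.tissue == TISSUE_AWN) == 6 * n  # 3-sided prisms
        # 12 box faces per spikelet + rachis patches
        assert np.count_nonzero(mesh.tissue == TISSUE_SPIKELET) == 12 * n + 8

    def test_spikelet_area_scales_quadratically(self):
        small = build_spike_mesh(SpikeBlueprint(length=0.09, spikelet_count=10,
                                                awn_length=0.0))
        bp = SpikeBlueprint(length=0.09, spikelet_count=10, awn_length=0.0,
                            spikelet_size=(0.011, 0.0055, 0.0044))
        big = build_spike_mesh(bp)
        m_small = small.tissue == TISSUE_SPIKELET
        m_big = big.tissue == TISSUE_SPIKELET
        # rachis area identical; compare spikelet boxes only
        a_small = small.areas()[m_small][8:].sum()
        a_big = big.areas()[m_big][8:].sum()
        assert a_big / a_small == pytest.approx(1.21, rel=0.01)


class TestTiller:
    def _tiller(self, spike=True):
        leaves = (flat_leaf(insertion=0.3, incl=40.0),)
        sp = SpikeBlueprint(length=0.08, spikelet_count=10,
                            awn_length=0.04) if spike else None
        return TillerBlueprint(stem_height=0.6,
                               stem_segments=((0.3, 0.004), (0.3, 0.004)),
                               leaves=leaves, spike=sp)

    def test_no_spike_no_spikelet_patches(self):
        mesh = build_tiller(self._tiller(spike=False))
        assert not np.any(np.isin(mesh.tissue, (TISSUE_SPIKELET, TISSUE_AWN)))

    def test_bounding_height(self):
        bp = self._tiller()
        mesh = build_tiller(bp)
        top = mesh.triangles[:, :, 2].max()
        # stem + spike length, plus the awn of the topmost spikelet
        assert top >= bp.stem_height + bp.spike.length - 1e-6
        assert top <= bp.stem_height + bp.spike.length + bp.spike.awn_length

    def test_patch_count_is_sum_of_organs(self):
        bp = self._tiller()
        mesh = build_tiller(bp)
        stem = build_tiller(TillerBlueprint(
            stem_height=0.6, stem_segments=bp.stem_segments, leaves=()))
        leaf = build_leaf_mesh(bp.leaves[0], segments=16)
        spike = build_spike_mesh(bp.spike)
        assert len(mesh) == len(stem) + len(leaf) + len(spike)

    def test_segments_must_sum_to_height(self):
        with pytest.raises(ValueError, match="sum"):
            TillerBlueprint(stem_height=0.7,
                            stem_segments=((0.3, 0.004), (0.3, 0.004)),
                            leaves=())


class TestCanopyAssembly:
    def _library(self):
        return [build_tiller(bp, leaf_segments=6) for bp in
                generate_tiller_library(STAGE_PRESETS["heading"], 3, seed=2)]

    def test_single_tiller_domain(self):
        can = assemble_canopy(self._library(), 0.2, 0.0066,
                              (0.2, 0.0066), 15.0, seed=1)
        assert can.tiller_count == 1

    def test_field_density_grid_count(self):
        # 20 cm rows x 0.66 cm in-row over 1 m2:
        # floor(1/0.2) * floor(1/0.0066) = 5 * 151
        lib = [build_tiller(TillerBlueprint(
            stem_height=0.1, stem_segments=((0.1, 0.003),), leaves=()))]
        can = assemble_canopy(lib, 0.20, 0.0066, (1.0, 1.0), 10.0, seed=0)
        assert can.tiller_count == 5 * 151

    def test_seeded_reassembly_bit_identical(self):
        lib = self._library()
        a = assemble_canopy(lib, 0.2, 0.02, (0.2, 0.06), 15.0, seed=9)
        b = assemble_canopy(lib, 0.2, 0.02, (0.2, 0.06), 15.0, seed=9)
        assert np.array_equal(a.mesh.triangles, b.mesh.triangles)
        c = assemble_canopy(lib, 0.2, 0.02, (0.2, 0.06), 15.0, seed=10)
        assert not np.array_equal(a.mesh.triangles, c.mesh.triangles)

    def test_spacing_larger_than_domain_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            assemble_canopy(self._library(), 0.5, 0.02, (0.2, 0.06), 15.0, 0)


class TestPerturbations:
    def _bp(self):
        return generate_tiller_library(STAGE_PRESETS["heading"], 1, seed=4)[0]

    def test_scale_height_identity(self):
        bp = self._bp()
        same = perturb_blueprint(bp, PerturbationSpec("scale_height", 1.0))
        assert np.array_equal(build_tiller(same).triangles,
                              build_tiller(bp).triangles)

    def test_scale_height_preserves_leaf_and_spike_area(self):
        bp = self._bp()
        for f in (0.5, 1.5):
            mod = perturb_blueprint(bp, PerturbationSpec("scale_height", f))
            m0, m1 = build_tiller(bp), build_tiller(mod)
            for tissue in (TISSUE_LEAF, TISSUE_SPIKELET, TISSUE_AWN):
                a0 = m0.areas()[m0.tissue == tissue].sum()
                a1 = m1.areas()[m1.tissue == tissue].sum()
                assert a1 == pytest.approx(a0, rel=1e-9)
            s0 = m0.areas()[m0.tissue == TISSUE_STEM].sum()
            s1 = m1.areas()[m1.tissue == TISSUE_STEM].sum()
            assert s1 / s0 == pytest.approx(f, rel=1e-9)

    def test_remove_spikes_only_drops_spike_patches(self):
        lib = [build_tiller(self._bp(), leaf_segments=6)]
        can = assemble_canopy(lib, 0.2, 0.02, (0.2, 0.06), 10.0, seed=3)
        removed = apply_perturbation(can, PerturbationSpec("remove_spikes"))
        assert not np.any(np.isin(removed.mesh.tissue,
                                  (TISSUE_SPIKELET, TISSUE_AWN)))
        keep = ~np.isin(can.mesh.tissue, (TISSUE_SPIKELET, TISSUE_AWN))
        assert np.array_equal(removed.mesh.triangles, can.mesh.triangles[keep])

    def test_flatten_already_flat_is_noop(self):
        bp = self._bp()
        flat = perturb_blueprint(bp, PerturbationSpec("flatten_leaves"))
        flat2 = perturb_blueprint(flat, PerturbationSpec("flatten_leaves"))
        assert np.array_equal(build_tiller(flat).triangles,
                              build_tiller(flat2).triangles)

    def test_straighten_flatten_preserve_leaf_area(self):
        bp = self._bp()
        base = build_tiller(bp)
        for kind in ("straighten_leaves", "flatten_leaves"):
            mod = build_tiller(perturb_blueprint(bp, PerturbationSpec(kind)))
            a0 = base.areas()[base.tissue == TISSUE_LEAF].sum()
            a1 = mod.areas()[mod.tissue == TISSUE_LEAF].sum()
            assert abs(a1 - a0) / a0 < 0.01

    def test_lower_spike_moves_base_to_flag_leaf(self):
        bp = self._bp()
        mod = perturb_blueprint(bp, PerturbationSpec("lower_spike"))
        flag = max(l.insertion_height for l in bp.leaves)
        assert mod.stem_height == pytest.approx(flag)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PerturbationSpec("shrink_roots")
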