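import numpy as np
import pytest

from canophot.architecture import (
    Canopy,
    OrganMesh,
    SpikeBlueprint,
    TISSUE_AWN,
    build_spike_mesh,
)


def black_patch_layer(area_index: float, side: float = 0.01,
                      domain: float = 1.0, depth: float = 1.0,
                      seed: int = 0, z0: float = 0.5) -> OrganMesh:
    """Random horizontal black square patches with uniform coverage.

    Corners are drawn over an extended region so the expected one-sided area
    index over the ray domain is exactly ``area_index`` (Poisson coverage:
    interception 1 - exp(-area_index) for a vertical beam).
    """
    rng = np.random.default_rng(seed)
    n = int(round(area_index * (domain + side) ** 2 / side ** 2))
    xy = rng.uniform(-side, domain, size=(n, 2))
    z = rng.uniform(z0, z0 + depth, n)
    a = np.stack([xy[:, 0], xy[:, 1], z], 1)
    b = a + [side, 0, 0]
    c = a + [side, side, 0]
    d = a + [0, side, 0]
    tris = np.concatenate([np.stack([a, b, c], 1), np.stack([a, c, d], 1)])
    m = len(tris)
    return OrganMesh(tris, np.ones(m), np.zeros(m), np.zeros(m), np.zeros(m))


def layer_canopy(mesh: OrganMesh, domain: float = 1.0,
                 ground_reflectance: float = 0.0) -> Canopy:
    return Canopy(mesh=mesh, row_spacing=domain, in_row_spacing=domain,
                  domain=(domain, domain), alpha0=0.0, seed=0,
                  ground_reflectance=ground_reflectance)


def random_scatter_canopy(seed: int, n_patches: int = 400) -> Canopy:
    """A box of randomly oriented scattering patches for closure checks."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, (n_patches, 3)) * [0.3, 0.3, 0.5]
    e1 = rng.normal(0, 0.02, (n_patches, 3))
    e2 = rng.normal(0, 0.02, (n_patches, 3))
    tris = np.stack([p, p + e1, p + e2], axis=1)
    areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
    tris = tris[areas > 1e-9]
    m = len(tris)
    mesh = OrganMesh(tris, np.zeros(m), np.zeros(m),
                     rng.uniform(0.02, 0.10, m), rng.uniform(0.0, 0.08, m))
    return Canopy(mesh=mesh, row_spacing=0.3, in_row_spacing=0.3,
                  domain=(0.3, 0.3), alpha0=0.0, seed=0,
                  ground_reflectance=0.10)


@pytest.fixture(scope="session")
def toy_spike():
    """A small awned spike and its deawned counterpart."""
    intact = build_spike_mesh(
        SpikeBlueprint(length=0.09, spikelet_count=14, awn_length=0.06))
    deawned = intact.subset(intact.tissue != TISSUE_AWN)
    return intact, deawned
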