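import numpy as np
import pytest
from hypothesis import settings

import plumetrace as pt
from plumetrace import synthgeom as sg

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

RIG_TILTS = (45.0, 0.0, -45.0)
N_RAYS = 100_000


@pytest.fixture(scope="session")
def params():
    return sg.BarbuleParams()


@pytest.fixture(scope="session")
def normal_mesh(params):
    return pt.generate_normal_barbule_array(params, seed=11)


@pytest.fixture(scope="session")
def superblack_mesh(params):
    return pt.generate_superblack_barbule_array(params, seed=12)


@pytest.fixture(scope="session")
def flat_plate_big():
    # wide enough that every directional-source ray lands on the top face
    return pt.generate_flat_plate(1200.0, 10.0)


@pytest.fixture(scope="session")
def flat_sim_dir0(flat_plate_big):
    """Flat keratin plate under the 0-degree directional rig, far-field
    termination sphere so detector-cone membership equals exit angle."""
    cfg = pt.SourceConfig(kind="directional", n_rays=N_RAYS, tilt_deg=0.0,
                          seed=5, hemisphere_radius_um=1e6)
    bundle = pt.make_directional_source(cfg)
    return pt.run_simulation(flat_plate_big, bundle, config=cfg)


def _directional_run(mesh, tilt, seed):
    cfg = pt.SourceConfig(kind="directional", n_rays=N_RAYS, tilt_deg=tilt,
                          seed=seed)
    bundle = pt.make_directional_source(cfg)
    return pt.run_simulation(mesh, bundle, config=cfg)


@pytest.fixture(scope="session")
def rig_results(normal_mesh, superblack_mesh):
    """The three directional rigs against both barbule arrays."""
    out = {}
    for name, mesh in (("normal", normal_mesh), ("superblack",
                                                 superblack_mesh)):
        accel = pt.build_accel(mesh)
        for tilt in RIG_TILTS:
            out[(name, tilt)] = _directional_run(accel, tilt, seed=7)
    return out


@pytest.fixture(scope="session")
def corner_sim():
    """Vertical rays confined to the interior of a 45-degree V-groove."""
    mesh = pt.generate_corner_reflector(500.0, 45.0)
    rng = np.random.default_rng(3)
    n = 5000
    x = rng.uniform(20.0, 200.0, n) * rng.choice([-1.0, 1.0], n)
    y = rng.uniform(-200.0, 200.0, n)
    origins = np.column_stack([x, y, np.full(n, 400.0)])
    dirs = np.tile([0.0, 0.0, -1.0], (n, 1))
    bundle = pt.RayBundle(origins, dirs, np.ones(n), np.full(n, 550.0))
    cfg = pt.SourceConfig(kind="directional", n_rays=n,
                          hemisphere_radius_um=1e6)
    return pt.run_simulation(mesh, bundle, config=cfg)
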