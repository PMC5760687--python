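import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import plumetrace as pt
from plumetrace.raytrace import FATE_LABELS


R_NORMAL = ((1.56 - 1.0) / (1.56 + 1.0)) ** 2  # normal-incidence Fresnel


class TestFresnel:
    def test_normal_incidence_closed_form(self):
        assert abs(pt.fresnel_unpolarized(1.0, 1.56, 1.0) - R_NORMAL) < 1e-9

    def test_grazing_limit(self):
        assert pt.fresnel_unpolarized(1.0, 1.56, 0.0) == 1.0

    def test_index_matched(self):
        for c in (0.0, 0.3, 0.7, 1.0):
            assert pt.fresnel_unpolarized(1.5, 1.5, c) == pytest.approx(0.0)

    def test_total_internal_reflection(self):
        # n1 > n2 beyond the critical angle
        assert pt.fresnel_unpolarized(1.56, 1.0, 0.1) == 1.0

    @given(st.floats(0.0, 1.0), st.floats(1.0, 3.0), st.floats(1.0, 3.0))
    def test_bounded(self, cos_i, n1, n2):
        r = pt.fresnel_unpolarized(n1, n2, cos_i)
        assert 0.0 <= r <= 1.0

    def test_vectorized_matches_scalar(self):
        c = np.linspace(0, 1, 11)
        vec = pt.fresnel_unpolarized(1.0, 1.56, c)
        assert np.allclose(vec, [pt.fresnel_unpolarized(1.0, 1.56, x)
                                 for x in c])


class TestSpecularReflect:
    def test_normal_incidence(self):
        out = pt.specular_reflect([0, 0, -1.0], [0, 0, 1.0])
        assert np.allclose(out, [0, 0, 1.0])

    def test_45_degree_mirror(self):
        s = math.sqrt(0.5)
        out = pt.specular_reflect([s, 0, -s], [0, 0, 1.0])
        assert np.allclose(out, [s, 0, s])

    @given(st.integers(0, 10_000))
    def test_law_of_reflection(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        if np.dot(d, n) >= -1e-3:
            d = d - 2 * max(np.dot(d, n), 0) * n - 1e-2 * n
            d /= np.linalg.norm(d)
        out = pt.specular_reflect(d, n)
        assert abs(np.linalg.norm(out) - 1) < 1e-12
        assert abs(np.dot(out, n) + np.dot(d, n)) < 1e-12


class TestSources:
    def test_directional_count_small_grid(self):
        cfg = pt.SourceConfig(kind="directional", n_rays=100, seed=0)
        assert len(pt.make_directional_source(cfg)) == 78  # floor(25 pi)

    def test_directional_cone_and_axis(self):
        cfg = pt.SourceConfig(kind="directional", n_rays=10_000, tilt_deg=0.0,
                              seed=1)
        b = pt.make_directional_source(cfg)
        ang = np.degrees(np.arccos(np.clip(-b.directions[:, 2], -1, 1)))
        assert ang.max() <= 14.0 + 1e-9
        mean = b.directions.mean(axis=0)
        assert np.allclose(mean / np.linalg.norm(mean), [0, 0, -1],
                           atol=0.01)

    def test_directional_tilt_moves_source_proximally(self):
        cfg = pt.SourceConfig(kind="directional", n_rays=10_000,
                              tilt_deg=45.0, seed=1)
        b = pt.make_directional_source(cfg)
        center = b.origins.mean(axis=0)
        assert center[0] < -400  # over the proximal (-x) end
        assert center[2] > 400

    def test_directional_nonsquare_n(self):
        cfg = pt.SourceConfig(kind="directional", n_rays=90, seed=0)
        b = pt.make_directional_source(cfg)
        assert len(b) == int(math.floor(math.pi * 90 / 4))

    def test_omni_origins_on_upper_hemisphere(self):
        cfg = pt.SourceConfig(kind="omni", n_rays=5000, seed=2)
        b = pt.make_omni_source(cfg)
        r = np.linalg.norm(b.origins, axis=1)
        assert np.allclose(r, cfg.hemisphere_radius_um)
        assert (b.origins[:, 2] >= 0).all()
        assert ((b.wavelengths >= 300) & (b.wavelengths <= 700)).all()

    def test_omni_rays_aim_at_constraint_square(self):
        cfg = pt.SourceConfig(kind="omni", n_rays=100_000, seed=2)
        b = pt.make_omni_source(cfg)
        t = -b.origins[:, 2] / b.directions[:, 2]
        pts = b.origins[:, :2] + t[:, None] * b.directions[:, :2]
        half = cfg.constraint_square_side_um / 2
        assert (np.abs(pts) <= half + 1e-6).all()
        # uniformity over the square: chi-square on a 4x4 grid
        ix = np.clip(((pts[:, 0] + half) // (half / 2)).astype(int), 0, 3)
        iy = np.clip(((pts[:, 1] + half) // (half / 2)).astype(int), 0, 3)
        counts = np.bincount(ix * 4 + iy, minlength=16)
        assert stats.chisquare(counts).pvalue > 0.001


class TestTraceRay:
    def test_flat_plate_single_bounce(self):
        accel = pt.build_accel(pt.generate_flat_plate(500.0, 10.0))
        rec = pt.trace_ray(accel, pt.Ray(np.array([0.0, 0, 100.0]),
                                         np.array([0.0, 0, -1.0])))
        assert rec.fate == "reflected"
        assert rec.n_scatter == 1
        assert rec.terminal_power == pytest.approx(R_NORMAL, abs=1e-9)
        assert rec.absorbed_power + rec.terminal_power \
            == pytest.approx(rec.initial_power, rel=1e-12)

    def test_miss_is_no_interaction(self):
        accel = pt.build_accel(pt.generate_flat_plate(10.0, 10.0))
        rec = pt.trace_ray(accel, pt.Ray(np.array([500.0, 0, 100.0]),
                                         np.array([0.0, 0, -1.0])))
        assert rec.fate == "no_interaction"
        assert rec.n_scatter == 0 and rec.absorbed_power == 0.0

    def test_corner_reflector_power_product(self, corner_sim):
        r45 = pt.fresnel_unpolarized(1.0, 1.56, math.cos(math.radians(45)))
        assert np.allclose(corner_sim.terminal_power, r45 ** 2, rtol=1e-12)

    def test_reference_path_matches_batch_kernel(self, superblack_mesh):
        accel = pt.build_accel(superblack_mesh)
        cfg = pt.SourceConfig(kind="directional", n_rays=100, tilt_deg=0.0,
                              seed=9)
        bundle = pt.make_directional_source(cfg)
        batch = pt.run_simulation(accel, bundle, config=cfg)
        for i in range(0, len(bundle), 7):
            rec = pt.trace_ray(accel, bundle[i],
                               hemisphere_radius=cfg.hemisphere_radius_um)
            assert rec.n_scatter == batch.n_scatter[i]
            assert rec.terminal_power == pytest.approx(
                batch.terminal_power[i], rel=1e-9, abs=1e-300)
            assert FATE_LABELS[batch.fate[i]] == rec.fate


class TestRunSimulation:
    def test_flat_plate_all_reflected_once(self, flat_sim_dir0):
        interacting = flat_sim_dir0.n_scatter > 0
        assert interacting.all()
        assert (flat_sim_dir0.fate[interacting] == 2).all()
        assert (flat_sim_dir0.n_scatter == 1).all()

    def test_rays_past_mesh_are_no_interaction(self):
        mesh = pt.generate_flat_plate(10.0, 5.0)
        origins = np.array([[300.0, 0, 50.0]])
        dirs = np.array([[0.0, 0, -1.0]])
        bundle = pt.RayBundle(origins, dirs, np.ones(1), np.array([550.0]))
        r = pt.run_simulation(mesh, bundle, config=pt.SourceConfig())
        assert r.fate[0] == 0 and r.n_scatter[0] == 0

    def test_wavelength_does_not_affect_outcomes(self, flat_plate_big):
        cfg = pt.SourceConfig(kind="directional", n_rays=2000, seed=8)
        b = pt.make_directional_source(cfg)
        r1 = pt.run_simulation(flat_plate_big, b, config=cfg)
        b550 = pt.RayBundle(b.origins, b.directions, b.powers,
                            np.full(len(b), 550.0))
        r2 = pt.run_simulation(flat_plate_big, b550, config=cfg)
        assert np.array_equal(r1.n_scatter, r2.n_scatter)
        assert np.array_equal(r1.terminal_power, r2.terminal_power)

    def test_deterministic_given_seed(self, superblack_mesh):
        accel = pt.build_accel(superblack_mesh)
        runs = []
        for _ in range(2):
            cfg = pt.SourceConfig(kind="directional", n_rays=2000,
                                  tilt_deg=0.0, seed=13)
            b = pt.make_directional_source(cfg)
            runs.append(pt.run_simulation(accel, b, config=cfg))
        assert np.array_equal(runs[0].theta, runs[1].theta)
        assert np.array_equal(runs[0].terminal_power,
                              runs[1].terminal_power)


class TestEnergyAudit:
    def test_hand_built_totals(self):
        r = pt.SimulationResult(
            fate=np.array([2, 1], dtype=np.int8),
            n_scatter=np.array([1, 3]),
            theta=np.array([0.1, 2.0]), phi=np.array([0.0, 1.0]),
            terminal_power=np.array([0.3, 0.1]),
            absorbed_power=np.array([0.7, 0.9]),
            initial_power=np.array([1.0, 1.0]),
            wavelengths=np.array([500.0, 600.0]),
            source=pt.SourceConfig())
        audit = pt.energy_audit(r)
        assert audit.emitted == 2.0
        assert audit.reflected_total == 0.3
        assert audit.transmitted_total == 0.1
        assert audit.absorbed_total == pytest.approx(1.6)
        assert audit.relative_residual < 1e-12

    def test_conservation_on_simulation(self, rig_results):
        for r in rig_results.values():
            assert pt.energy_audit(r).relative_residual < 1e-9

    def test_index_matched_absorbs_every_interacting_ray(self):
        # n1 = n2 forces R = 0: a single interaction absorbs everything, so
        # the only surviving power is from rays that never hit the mesh
        mesh = pt.generate_flat_plate(300.0, 10.0)
        rng = np.random.default_rng(4)
        origins = np.column_stack([rng.uniform(-400, 400, 3000),
                                   rng.uniform(-400, 400, 3000),
                                   np.full(3000, 100.0)])
        dirs = np.tile([0.0, 0.0, -1.0], (3000, 1))
        bundle = pt.RayBundle(origins, dirs, np.ones(3000),
                              np.full(3000, 550.0))
        r = pt.run_simulation(mesh, bundle,
                              constants=pt.OpticalConstants(1.0, 1.0),
                              config=pt.SourceConfig())
        hit = r.n_scatter > 0
        assert np.allclose(r.terminal_power[hit], 0.0)
        totals = r.totals
        assert totals["reflected_total"] == 0.0
        assert totals["transmitted_total"] == pytest.approx((~hit).sum())
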