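import math

import numpy as np
import pytest

import plumetrace as pt
from plumetrace import photostats as ps


def _synthetic_result(theta, phi, power, n_scatter=None, emitted=None):
    n = len(theta)
    if n_scatter is None:
        n_scatter = np.ones(n, dtype=np.int64)
    initial = np.ones(n) if emitted is None else np.full(n, emitted / n)
    return pt.SimulationResult(
        fate=np.full(n, 2, dtype=np.int8),
        n_scatter=np.asarray(n_scatter),
        theta=np.asarray(theta, dtype=float),
        phi=np.asarray(phi, dtype=float),
        terminal_power=np.asarray(power, dtype=float),
        absorbed_power=initial - power,
        initial_power=initial,
        wavelengths=np.full(n, 550.0),
        source=pt.SourceConfig())


class TestDirectionalReflectance:
    def test_monotone_in_cone_angle(self, flat_sim_dir0):
        pcts = [ps.directional_reflectance(flat_sim_dir0, a).percent
                for a in (10.0, 27.0, 60.0, 180.0)]
        assert all(a <= b + 1e-12 for a, b in zip(pcts, pcts[1:]))

    def test_full_hemisphere_equals_total_reflected(self, flat_sim_dir0):
        dr = ps.directional_reflectance(flat_sim_dir0, 180.0)
        expect = 100.0 * flat_sim_dir0.totals["reflected_total"] \
            / flat_sim_dir0.emitted_power
        assert dr.percent == pytest.approx(expect, rel=1e-12)
        assert dr.absorbance_percent == pytest.approx(100 - dr.percent)

    def test_no_reflected_rays_gives_zero(self):
        r = _synthetic_result([0.1], [0.0], [0.5])
        r.fate[:] = 0  # no interaction
        assert ps.directional_reflectance(r).percent == 0.0

    def test_zero_emitted_rejected(self):
        r = _synthetic_result([0.1], [0.0], [0.0])
        r.initial_power[:] = 0.0
        with pytest.raises(ValueError, match="emitted"):
            ps.directional_reflectance(r)


class TestMultipleScatterFraction:
    def test_counts_rays_not_power(self):
        r = _synthetic_result([0.1, 0.1, 0.1], [0, 0, 0],
                              [0.9, 0.001, 0.001], n_scatter=[1, 2, 5])
        assert ps.multiple_scatter_fraction(r, "all_reflected") \
            == pytest.approx(200.0 / 3.0)

    def test_flat_plate_is_zero(self, flat_sim_dir0):
        assert ps.multiple_scatter_fraction(flat_sim_dir0, "in_cone") == 0.0
        assert ps.multiple_scatter_fraction(flat_sim_dir0,
                                            "all_reflected") == 0.0

    def test_corner_reflector_is_hundred(self, corner_sim):
        assert ps.multiple_scatter_fraction(corner_sim,
                                            "all_reflected") == 100.0

    def test_empty_selection_rejected(self):
        r = _synthetic_result([0.1], [0.0], [0.5])
        r.fate[:] = 1
        with pytest.raises(ValueError, match="no reflected"):
            ps.multiple_scatter_fraction(r, "all_reflected")


class TestQuadrants:
    def test_powers_sum_to_total_reflected(self, rig_results):
        r = rig_results[("superblack", 0.0)]
        q = ps.quadrant_summary(r)
        assert sum(q.power_by_quadrant.values()) \
            == pytest.approx(r.totals["reflected_total"], rel=1e-9)
        assert sum(q.halves.values()) \
            == pytest.approx(r.totals["reflected_total"], rel=1e-9)

    def test_flat_plate_zero_tilt_symmetric(self, flat_sim_dir0):
        q = ps.quadrant_summary(flat_sim_dir0)
        p, d = q.power_by_quadrant["proximal"], q.power_by_quadrant["distal"]
        # per-ray power is ~R_MAX, so Var(p - d) ~ (p + d) * R_MAX
        se = math.sqrt((p + d) * R_MAX)
        assert abs(p - d) < 3 * max(se, 1.0)

    def test_proximal_tilted_source_throws_light_distally(self,
                                                          flat_plate_big):
        cfg = pt.SourceConfig(kind="directional", n_rays=20_000,
                              tilt_deg=45.0, seed=6)
        r = pt.run_simulation(flat_plate_big,
                              pt.make_directional_source(cfg), config=cfg)
        q = ps.quadrant_summary(r)
        assert max(q.power_by_quadrant,
                   key=q.power_by_quadrant.get) == "distal"
        assert q.halves["proximal_half"] < q.halves["distal_half"]

    def test_tie_flag_lexicographic(self):
        r = _synthetic_result([0.3, 0.3], [0.0, math.pi], [0.5, 0.5])
        q = ps.quadrant_summary(r)
        assert q.tie  # both laterals are exactly zero
        assert q.darkest == "left_lateral"


R_MAX = 0.05  # rough per-ray power scale for the symmetry tolerance above


class TestHemisphereMap:
    def test_uniform_records_give_flat_map(self):
        n = 100_000
        u = ps.fibonacci_hemisphere(n)
        theta = np.arccos(u[:, 2])
        phi = np.arctan2(u[:, 1], u[:, 0])
        r = _synthetic_result(theta, phi, np.full(n, 0.5))
        hmap = ps.hemisphere_map(r)
        cv = hmap.values.std() / hmap.values.mean()
        assert cv < 0.05

    def test_point_source_peaks_at_nearest_direction(self):
        target = np.array([0.3, 0.2, math.sqrt(1 - 0.13)])
        theta = [math.acos(target[2])]
        phi = [math.atan2(target[1], target[0])]
        r = _synthetic_result(theta * 20, phi * 20, np.full(20, 1.0))
        hmap = ps.hemisphere_map(r, bandwidth=0.15)
        nearest = np.argmax(hmap.eval_directions @ target)
        assert np.argmax(hmap.values) == nearest

    def test_wide_bandwidth_flattens_to_mean(self):
        rng = np.random.default_rng(0)
        n = 2000
        theta = np.arccos(rng.uniform(0, 1, n))
        phi = rng.uniform(-np.pi, np.pi, n)
        power = rng.uniform(0, 1, n)
        r = _synthetic_result(theta, phi, power)
        hmap = ps.hemisphere_map(r, bandwidth=50.0)
        expect = power.sum() / (2 * np.pi * r.emitted_power)
        assert np.allclose(hmap.values, expect, rtol=1e-2)

    def test_too_few_rays_rejected(self):
        r = _synthetic_result([0.1] * 5, [0.0] * 5, [0.5] * 5)
        with pytest.raises(ValueError, match="at least 10"):
            ps.hemisphere_map(r)

    def test_bad_bandwidth_rejected(self, flat_sim_dir0):
        with pytest.raises(ValueError, match="bandwidth"):
            ps.hemisphere_map(flat_sim_dir0, bandwidth=0.0)


class TestOlsFit:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = ps.ols_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.se_slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_response(self):
        fit = ps.ols_fit([1.0, 2, 3, 4], [5.0, 5, 5, 5])
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 8)
        y = rng.uniform(0, 10, 8)
        fit = ps.ols_fit(x, y)
        n = len(x)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        s2 = (resid ** 2).sum() / (n - 2)
        se = math.sqrt(s2 / sxx)
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        from scipy import stats as sps
        p = 2 * sps.t.sf(abs(slope / se), n - 2)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.r_squared == pytest.approx(r2, abs=1e-12)
        assert fit.se_slope == pytest.approx(se, abs=1e-12)
        assert fit.p_value == pytest.approx(p, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="n >= 3"):
            ps.ols_fit([1.0, 2], [1.0, 2])
        with pytest.raises(ValueError, match="constant"):
            ps.ols_fit([1.0, 1, 1], [1.0, 2, 3])
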