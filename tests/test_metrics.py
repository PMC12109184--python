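"""Metric suite: cycle statistics, loop areas, energetics, derived indices."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from shapely.geometry import Polygon

from cardioloop.chambers import ActivationTiming, ChamberParams
from cardioloop.metrics import (
    atrial_loop_area,
    compute_reports,
    cycle_stats,
    effective_arterial_elastance,
    loop_area,
    pcwp,
    percentage_change,
    potential_energy,
    svri,
)


class TestCycleStats:
    def test_constant_signal(self):
        t = np.linspace(0, 1, 11)
        assert cycle_stats(t, np.full(11, 7.0)) == (7.0, pytest.approx(7.0), 7.0)

    def test_two_point_trapezoid(self):
        lo, mean, hi = cycle_stats(np.array([0.0, 1.0]), np.array([0.0, 10.0]))
        assert (lo, hi) == (0.0, 10.0)
        assert mean == pytest.approx(5.0)

    def test_random_signal_matches_brute_force(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 1, 40))
        t[0], t[-1] = 0.0, 1.0
        x = rng.normal(size=40)
        _, mean, _ = cycle_stats(t, x)
        brute = sum(
            0.5 * (x[i] + x[i + 1]) * (t[i + 1] - t[i]) for i in range(39)
        ) / (t[-1] - t[0])
        assert mean == pytest.approx(brute, rel=1e-12)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            cycle_stats(np.array([0.0]), np.array([1.0]))


def _random_convex_loop(rng, n=30):
    """Closed convex polygon as (P, V) samples via sorted angles."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(5, 20)
    v = 100 + r * np.cos(ang)
    p = 60 + r * np.sin(ang)
    v = np.append(v, v[0])
    p = np.append(p, p[0])
    return p, v


class TestLoopArea:
    def test_rectangle(self):
        p = np.array([10.0, 110.0, 110.0, 10.0, 10.0])
        v = np.array([50.0, 50.0, 100.0, 100.0, 50.0])
        assert loop_area(p, v) == pytest.approx(5000.0)

    def test_degenerate_point(self):
        p = np.full(5, 20.0)
        v = np.full(5, 80.0)
        assert loop_area(p, v) == 0.0

    def test_open_loop_raises(self):
        p = np.array([0.0, 50.0, 100.0])
        v = np.array([50.0, 100.0, 140.0])
        with pytest.raises(ValueError):
            loop_area(p, v)

    def test_hundred_random_loops_match_polygon_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p, v = _random_convex_loop(rng)
            oracle = Polygon(zip(v, p)).area
            assert loop_area(p, v) == pytest.approx(oracle, rel=1e-9)

    def test_smooth_loop_matches_greens_theorem_oracle(self):
        t = np.linspace(0, 2 * np.pi, 2001)
        v = 120 + 30 * np.cos(t)
        p = 70 + 45 * np.sin(t) + 5 * np.sin(2 * t)
        # Green's theorem: A = 0.5 * |integral (x dy - y dx)|
        oracle = 0.5 * abs(np.trapezoid(v * np.gradient(p, t) - p * np.gradient(v, t), t))
        assert loop_area(p, v) == pytest.approx(oracle, rel=1e-3)

    def test_figure_eight_atrial_split(self):
        # two opposed unit-ish triangles sharing a crossing point
        v = np.array([0.0, 2.0, 2.0, 0.0, 0.0])
        p = np.array([0.0, 2.0, 0.0, 2.0, 0.0])
        # each sub-triangle of the bow-tie has area 1 -> total 2
        assert atrial_loop_area(p, v) == pytest.approx(2.0)


TIMING = ActivationTiming(0.8, 0.0, 0.3)


class TestPotentialEnergy:
    def test_zero_at_v0(self):
        ch = ChamberParams("LV", 2.0, 15.0, 0.5, 0.02, TIMING)
        assert potential_energy(15.0, ch) == 0.0

    def test_triangle_with_flat_edpvr(self):
        ch = ChamberParams("LV", 2.0, 10.0, 0.0, 0.0, TIMING)
        # pure triangle: Ees * x^2 / 2 with x = 40
        assert potential_energy(50.0, ch) == pytest.approx(2.0 * 40.0**2 / 2.0)

    def test_exponential_edpvr_matches_quadrature(self):
        ch = ChamberParams("LV", 1.8, 12.0, 0.4, 0.03, TIMING)
        v_es = 95.0
        espvr_area = 0.5 * ch.ees * (v_es - ch.v0) ** 2
        edpvr_area, _ = quad(
            lambda v: ch.edpvr_a * math.expm1(ch.edpvr_b * (v - ch.v0)), ch.v0, v_es
        )
        assert potential_energy(v_es, ch) == pytest.approx(
            espvr_area - edpvr_area, rel=1e-9
        )

    def test_below_v0_clamped_to_zero(self):
        ch = ChamberParams("LV", 2.0, 50.0, 0.5, 0.02, TIMING)
        assert potential_energy(30.0, ch) == 0.0


class TestIndices:
    def test_ea_arithmetic(self):
        assert effective_arterial_elastance(90.0, 45.0) == pytest.approx(2.0)

    def test_ea_halves_when_sv_doubles(self):
        assert effective_arterial_elastance(90.0, 90.0) == pytest.approx(
            effective_arterial_elastance(90.0, 45.0) / 2
        )

    def test_ea_requires_ejection(self):
        with pytest.raises(ValueError):
            effective_arterial_elastance(90.0, 0.0)

    def test_svri_arithmetic(self):
        assert svri(65.0, 5.0, 3.0, 1.5) == pytest.approx(79.9 * 60.0 / 2.0)

    def test_svri_zero_gradient(self):
        assert svri(10.0, 10.0, 4.0, 1.8) == 0.0

    def test_svri_random_matches_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m, c = rng.uniform(40, 110), rng.uniform(0, 15)
            co, bsa = rng.uniform(1, 8), rng.uniform(1.2, 2.3)
            assert svri(m, c, co, bsa) == pytest.approx(79.9 * (m - c) * bsa / co)

    def test_svri_rejects_nonpositive_co(self):
        with pytest.raises(ValueError):
            svri(65.0, 5.0, 0.0, 1.8)

    @pytest.mark.parametrize(
        "assisted,base,expected", [(110.0, 100.0, 10.0), (100.0, 100.0, 0.0), (86.0, 100.0, -14.0)]
    )
    def test_percentage_change(self, assisted, base, expected):
        assert percentage_change(assisted, base) == pytest.approx(expected)

    def test_percentage_change_zero_baseline_raises(self):
        with pytest.raises(ValueError):
            percentage_change(5.0, 0.0)


class TestBeatReports:
    def test_pressure_triples_ordered(self, cs_beat):
        h, _ = compute_reports(cs_beat)
        for name in ("lap", "aop", "pap", "lvp"):
            d = h.as_dict()
            assert d[f"{name}_min"] <= d[f"{name}_mean"] <= d[f"{name}_max"]

    def test_esv_not_above_edv(self, cs_beat):
        h, _ = compute_reports(cs_beat)
        assert h.lvesv <= h.lvedv
        assert h.rvesv <= h.rvedv
        assert h.laesv <= h.laedv

    def test_pva_identity(self, cs_beat):
        _, e = compute_reports(cs_beat)
        assert e.lv_pva == pytest.approx(e.lv_ew + e.lv_pe, rel=1e-12)
        assert e.rv_pva == pytest.approx(e.rv_ew + e.rv_pe, rel=1e-12)

    def test_cardiac_index_identity(self, cs_beat):
        h, _ = compute_reports(cs_beat)
        assert h.cardiac_index == pytest.approx(
            h.cardiac_output / cs_beat.patient.bsa, rel=1e-12
        )

    def test_total_flow_reconstruction(self, cs_beat):
        """Total flow = native output + mean pump flow, rebuilt from signals."""
        h, _ = compute_reports(cs_beat)
        t, q = cs_beat.t, cs_beat.signals["Q_ecmo"]
        pump = float(np.trapezoid(q, t) / (t[-1] - t[0])) * 60 / 1000
        v = cs_beat.signals["V_LV"]
        native = float(v.max() - v.min()) * cs_beat.heart_rate / 1000
        assert h.total_flow == pytest.approx(native + pump, rel=1e-9)

    def test_pcwp_at_least_min_lap(self, cs_beat):
        h, _ = compute_reports(cs_beat)
        assert pcwp(cs_beat) >= h.lap_min

    def test_pcwp_matches_trapezoid_oracle(self, cs_beat):
        t = cs_beat.t
        x = cs_beat.signals["P_pulmonary_veins"]
        assert pcwp(cs_beat) == pytest.approx(
            float(np.trapezoid(x, t) / (t[-1] - t[0])), rel=1e-12
        )

    def test_coronary_branch_flow_matches_integration_oracle(self, cs_beat):
        h, _ = compute_reports(cs_beat)
        t, q = cs_beat.t, cs_beat.signals["Q_aorta_to_coronary"]
        assert h.coronary_flow == pytest.approx(
            60.0 * float(np.trapezoid(q, t) / (t[-1] - t[0])), rel=1e-12
        )

    def test_ea_over_ees_above_one_in_shock(self, cs_beat):
        """The uncoupled failing ventricle: Ea/Ees > 1 on the CS fixture."""
        _, e = compute_reports(cs_beat)
        assert e.ea_over_ees_systemic > 1.0

    def test_cerebral_flow_is_upper_body_branch_tap(self, cs_beat):
        h, _ = compute_reports(cs_beat)
        t, q = cs_beat.t, cs_beat.signals["Q_arch_to_upper_body"]
        assert h.cerebral_flow == pytest.approx(
            60.0 * float(np.trapezoid(q, t) / (t[-1] - t[0])), rel=1e-12
        )
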