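"""Migration cycle state machine, chemotactic force law, active force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomib import chemofield as cf
from gliomib import ib_structures as ib
from gliomib import motility as mo


def make_cell():
    mem = ib.circle_curve((0.005, 0.005), 5e-4, 64, 3.8e-5)
    nuc = ib.circle_curve((0.005, 0.005), 3e-4, 32, 3.8e-5)
    cell = ib.GliomaCell(membrane=mem, nucleus=nuc, ct=1500.0)
    cell.select_arcs((0.0, 1.0), 60.0)
    return cell


class TestMigrationDirection:
    def test_uniform_gradient(self):
        fld = cf.make_chem_field(64, 0.01)
        x = fld.cell_centers()
        fld.C[:] = 5.0 * x[None, :]     # C = a*y
        d = mo.migration_direction(fld, (0.005, 0.005), 0.4e-4)
        assert np.allclose(d, [0.0, 1.0], atol=1e-10)

    def test_constant_field_retains_previous_direction(self):
        fld = cf.make_chem_field(32, 0.01)
        fld.C[:] = 1.0
        prev = np.array([0.6, 0.8])
        d = mo.migration_direction(fld, (0.005, 0.005), 0.4e-4,
                                   prev_dir=prev)
        assert np.allclose(d, prev)

    def test_point_source_against_quadrature_oracle(self):
        # brute-force midpoint quadrature of grad C over the sensing disk
        fld = cf.make_chem_field(128, 0.01)
        cf.place_source(fld, (0.0071, 0.0088))
        for _ in range(40):
            fld = cf.step_chem(fld, 500.0)
        xq = np.array([0.0048, 0.0051])
        Rsc = 4e-4                       # force the disk-quadrature branch
        grad = cf.gradient(fld)
        d = mo.migration_direction(fld, xq, Rsc, grad=grad)
        # oracle: dense uniform samples in the disk, bilinear grad
        rng = np.random.default_rng(7)
        pts = []
        while len(pts) < 10_000:
            cand = xq + Rsc * rng.uniform(-1, 1, (20_000, 2))
            keep = np.linalg.norm(cand - xq, axis=1) <= Rsc
            pts.extend(cand[keep].tolist())
        gavg = cf.gradient_at(fld, grad, np.array(pts[:10_000])).mean(axis=0)
        oracle = gavg / np.linalg.norm(gavg)
        angle = np.degrees(np.arccos(np.clip(np.dot(d, oracle), -1, 1)))
        assert angle < 1.0


class TestChemotacticForce:
    def test_zero_gradient_basal_strength(self):
        p = mo.ActiveForceParams()
        Fc, ca = mo.chemotactic_force_strength((0.0, 0.0), p)
        assert Fc == 0.0
        assert ca == pytest.approx(0.7 * 0.15)   # = 0.105

    def test_maximum_at_critical_gradient(self):
        # |F_C| peaks at |grad C| = 1/sqrt(lambda_s), value 1/(2 sqrt(l_s))
        p = mo.ActiveForceParams()
        g = 1.0 / np.sqrt(p.lambda_s)
        Fc, _ = mo.chemotactic_force_strength((g, 0.0), p)
        assert Fc == pytest.approx(1.0 / (2.0 * np.sqrt(20.0)))

    def test_bounded_and_vanishing_at_large_gradient(self):
        p = mo.ActiveForceParams()
        Fc_huge, _ = mo.chemotactic_force_strength((1e9, 0.0), p)
        assert Fc_huge < 1e-6

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    def test_bound_holds_for_any_gradient(self, gx, gy):
        p = mo.ActiveForceParams()
        Fc, _ = mo.chemotactic_force_strength((gx, gy), p)
        assert Fc <= 1.0 / (2.0 * np.sqrt(p.lambda_s)) + 1e-12


class TestActiveForce:
    def test_retraction_phase_zero(self):
        cell = make_cell()
        cyc = mo.MigrationCycle(phase=mo.RETRACTION)
        F = mo.active_force(cell, cyc, 0.105, (0.0, 1.0))
        assert np.all(F == 0.0)

    def test_elongation_front_nodes_only(self):
        cell = make_cell()
        cyc = mo.MigrationCycle(phase=mo.ELONGATION)
        F = mo.active_force(cell, cyc, 0.105, (0.0, 1.0))
        assert np.allclose(F[cell.front_nodes], [0.0, 0.105])
        others = np.setdiff1d(np.arange(cell.membrane.m), cell.front_nodes)
        assert np.all(F[others] == 0.0)

    def test_linear_in_chi(self):
        p1 = mo.ActiveForceParams(chi=0.7)
        p2 = mo.ActiveForceParams(chi=1.4)
        _, ca1 = mo.chemotactic_force_strength((0.1, 0.0), p1)
        _, ca2 = mo.chemotactic_force_strength((0.1, 0.0), p2)
        assert ca2 == pytest.approx(2 * ca1)


class TestUpdatePhase:
    def _feed(self, cyc, ts, Ls):
        events = []
        for t, L in zip(ts, Ls):
            if mo.update_phase(cyc, L, t):
                events.append((t, cyc.phase))
        return events

    def test_fast_growth_no_switch(self):
        cyc = mo.MigrationCycle(delta_ret_plus=1.0, delta_ret_minus=-1.0,
                                max_phase_duration=1e9)
        ts = np.arange(0, 50, 0.5)
        events = self._feed(cyc, ts, 2.0 * ts)   # L' = 2 > delta+
        assert events == []

    def test_switch_when_rate_decays_below_retention(self):
        # synthetic ramp: L' = 2 - 0.1 t crosses delta+ = 1 at t = 10
        cyc = mo.MigrationCycle(delta_ret_plus=1.0, delta_ret_minus=-1.0,
                                max_phase_duration=1e9)
        ts = np.arange(0, 30, 0.25)
        Ls = 2.0 * ts - 0.05 * ts ** 2
        events = self._feed(cyc, ts, Ls)
        assert events
        t_switch, phase = events[0]
        assert phase == mo.RETRACTION
        assert abs(t_switch - 10.0) < 2.0   # within the smoothing window

    def test_phases_strictly_alternate(self):
        cyc = mo.MigrationCycle(max_phase_duration=5.0)
        ts = np.arange(0, 200, 0.5)
        Ls = np.ones_like(ts)
        events = self._feed(cyc, ts, Ls)
        phases = [p for _, p in events]
        assert len(events) >= 10
        for a, b in zip(phases, phases[1:]):
            assert a != b

    def test_forced_switch_at_max_duration(self):
        cyc = mo.MigrationCycle(delta_ret_plus=1e-9, delta_ret_minus=-1e-9,
                                max_phase_duration=10.0)
        ts = np.arange(0, 25, 0.5)
        events = self._feed(cyc, ts, 100.0 * ts)   # rate never decays
        assert events and events[0][0] == pytest.approx(10.0, abs=0.5)

    def test_invalid_retention_rates_rejected(self):
        with pytest.raises(ValueError):
            mo.MigrationCycle(delta_ret_plus=-1.0, delta_ret_minus=-2.0)


class TestGliomaMembraneForce:
    def test_sum_of_independent_terms(self, rng):
        cell = make_cell()
        cell.membrane.X += 1e-5 * rng.standard_normal(cell.membrane.X.shape)
        cell.Zr = cell.membrane.X[cell.rear_nodes] \
            + 1e-5 * rng.standard_normal((len(cell.rear_nodes), 2))
        cyc = mo.MigrationCycle(phase=mo.ELONGATION)
        d = np.array([0.0, 1.0])
        F = mo.glioma_membrane_force(cell, cyc, 0.105, d)
        expected = ib.elastic_force(cell.membrane)
        expected[cell.rear_nodes] += ib.tether_force(
            cell.membrane.X[cell.rear_nodes], cell.Zr, cell.ct)
        expected += mo.active_force(cell, cyc, 0.105, d)
        assert np.allclose(F, expected, rtol=0, atol=1e-12 *
                           np.abs(expected).max())

    def test_removing_active_term_is_pure_mechanics(self):
        cell = make_cell()
        cell.Zr = cell.membrane.X[cell.rear_nodes].copy()
        cyc = mo.MigrationCycle(phase=mo.ELONGATION)
        F_active = mo.glioma_membrane_force(cell, cyc, 0.105, (0, 1))
        F_passive = mo.glioma_membrane_force(cell, cyc, 0.0, (0, 1))
        diff = F_active - F_passive
        assert np.allclose(diff[cell.front_nodes], [0.0, 0.105])

    def test_rest_circle_net_force_zero(self):
        cell = make_cell()
        cell.Zr = cell.membrane.X[cell.rear_nodes].copy()
        cyc = mo.MigrationCycle(phase=mo.ELONGATION)
        F = mo.glioma_membrane_force(cell, cyc, 0.0, (0, 1))
        # at anchors with no active force: only the radial pre-tension,
        # which sums to zero over the closed curve
        assert np.linalg.norm(F.sum(axis=0)) < 1e-10 * np.abs(F).max()
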