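"""Delta kernel moments, spread/interpolate adjointness, elastic oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomib import ib_structures as ib


def periodic_offsets(x, n, h):
    j = np.arange(n) * h
    return ((j - x + n * h / 2) % (n * h)) - n * h / 2


class TestDeltaKernel:
    def test_partition_of_unity_and_first_moment(self, rng):
        n, h = 64, 0.13
        for _ in range(1000):
            x = rng.uniform(0, n * h)
            r = periodic_offsets(x, n, h)
            w = ib.delta_kernel(r, h) * h
            assert abs(w.sum() - 1.0) < 1e-14
            assert abs(np.sum(r * w)) < 1e-14

    def test_symmetry(self, rng):
        r = rng.uniform(-2, 2, 100)
        assert np.allclose(ib.delta_kernel(r, 1.0),
                           ib.delta_kernel(-r, 1.0), atol=0, rtol=0)

    def test_compact_support(self):
        assert ib.delta_kernel(np.array([2.0, -2.0, 3.5]), 1.0).max() == 0.0


class TestSpreadInterpolate:
    def test_zero_force_spreads_to_zero(self):
        c = ib.circle_curve((0.5, 0.5), 0.2, 16, 1.0)
        f = ib.spread_forces(np.zeros((16, 2)), c, 32, 1 / 32)
        assert np.all(f == 0.0)

    def test_total_force_conserved(self, rng):
        n, h = 48, 0.021
        c = ib.circle_curve((0.5, 0.5), 0.3, 33, 1.0)
        F = rng.standard_normal((33, 2))
        f = ib.spread_forces(F, c, n, h)
        assert np.allclose(h * h * f.sum(axis=(1, 2)),
                           F.sum(axis=0) * c.ds, rtol=1e-12)

    def test_adjointness(self, rng):
        n, h = 40, 0.025
        c = ib.circle_curve((0.47, 0.52), 0.31, 57, 1.0)
        F = rng.standard_normal((57, 2))
        u = rng.standard_normal((2, n, n))
        f = ib.spread_forces(F, c, n, h)
        U = ib.interpolate_velocity(u, c, h)
        lhs = np.sum(F * U) * c.ds
        rhs = h * h * np.sum(f * u)
        assert abs(lhs - rhs) < 1e-12 * max(abs(rhs), 1.0)

    def test_uniform_velocity_interpolates_exactly(self):
        n, h = 32, 1 / 32
        c = ib.circle_curve((0.5, 0.5), 0.2, 24, 1.0)
        u = np.ones((2, n, n))
        u[1] = -2.0
        U = ib.interpolate_velocity(u, c, h)
        assert np.allclose(U[:, 0], 1.0, atol=1e-12)
        assert np.allclose(U[:, 1], -2.0, atol=1e-12)

    def test_linear_velocity_reproduced(self):
        # first-moment condition => linear fields interpolate exactly away
        # from the periodic seam
        n, h = 64, 1 / 64
        x = np.arange(n) * h
        u = np.zeros((2, n, n))
        u[0] = x[:, None] * np.ones(n)[None, :]
        c = ib.circle_curve((0.5, 0.5), 0.15, 40, 1.0)
        U = ib.interpolate_velocity(u, c, h)
        assert np.allclose(U[:, 0], c.X[:, 0], atol=1e-12)

    def test_nonfinite_force_rejected(self):
        c = ib.circle_curve((0.5, 0.5), 0.2, 16, 1.0)
        F = np.zeros((16, 2))
        F[3, 1] = np.inf
        with pytest.raises(ValueError, match="node"):
            ib.spread_forces(F, c, 32, 1 / 32)


class TestElasticForce:
    def test_circle_symmetric_inward_net_zero(self):
        c = ib.circle_curve((0.0, 0.0), 1.0, 64, 2.5)
        F = ib.elastic_force(c)
        mags = np.linalg.norm(F, axis=1)
        assert np.allclose(mags, mags[0], rtol=1e-10)
        # all point radially inward
        inward = -c.X / np.linalg.norm(c.X, axis=1, keepdims=True)
        assert np.allclose(F / mags[:, None], inward, atol=1e-9)
        assert np.linalg.norm(F.sum(axis=0)) * c.ds < 1e-12

    def test_closed_curve_force_sums_to_zero(self, rng):
        X = _random_closed_curve(rng, 31)
        c = ib.BoundaryCurve(X=X, ds=2 * np.pi / 31, c=1.3)
        F = ib.elastic_force(c)
        assert np.linalg.norm(F.sum(axis=0)) * c.ds < 1e-12 * \
            np.abs(F).max()

    def test_matches_energy_gradient_oracle(self, rng):
        # independent oracle: central finite differences of the discrete
        # stretching energy
        m = 24
        X = _random_closed_curve(rng, m)
        curve = ib.BoundaryCurve(X=X, ds=2 * np.pi / m, c=1.7)
        F = ib.elastic_force(curve)
        eps = 1e-7
        G = np.zeros_like(X)
        for i in range(m):
            for d in range(2):
                Xp = X.copy()
                Xp[i, d] += eps
                Xm = X.copy()
                Xm[i, d] -= eps
                ep = ib.elastic_energy(
                    ib.BoundaryCurve(X=Xp, ds=curve.ds, c=1.7))
                em = ib.elastic_energy(
                    ib.BoundaryCurve(X=Xm, ds=curve.ds, c=1.7))
                G[i, d] = -(ep - em) / (2 * eps)
        rel = np.max(np.abs(F - G / curve.ds)) / np.max(np.abs(F))
        assert rel < 1e-6

    def test_coincident_nodes_rejected(self):
        X = np.zeros((10, 2))
        X[:, 0] = np.arange(10.0)
        X[5] = X[4]
        c = ib.BoundaryCurve(X=X, ds=1.0, c=1.0)
        with pytest.raises(ValueError, match="spacing"):
            ib.elastic_force(c)


class TestTetherForce:
    def test_at_anchor_zero_and_linearity(self, rng):
        X = rng.standard_normal((12, 2))
        assert np.all(ib.tether_force(X, X, 400.0) == 0.0)
        Z = X + rng.standard_normal((12, 2))
        F1 = ib.tether_force(X, Z, 400.0)
        F2 = ib.tether_force(2 * X - Z, Z, 400.0)   # doubled displacement
        assert np.allclose(F2, 2 * F1)

    def test_normal_cell_unit_displacement(self):
        # tabulated normal-cell tether stiffness: unit displacement -> 400
        X = np.array([[0.0, 0.0]])
        Z = np.array([[1.0, 0.0]])
        assert np.allclose(ib.tether_force(X, Z, 400.0), [[400.0, 0.0]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ib.tether_force(np.zeros((3, 2)), np.zeros((4, 2)), 1.0)


class TestEnclosedArea:
    def test_circle_area(self):
        c = ib.circle_curve((0.3, 0.4), 1.0, 2000, 1.0)
        assert abs(ib.enclosed_area(c) - np.pi) < 1e-4

    def test_glioma_sized_circle(self):
        # 5 um cell radius in CGS
        r = 5e-4
        c = ib.circle_curve((0.005, 0.005), r, 500, 1.0)
        assert abs(ib.enclosed_area(c) - np.pi * r * r) < 1e-3 * np.pi * r * r

    def test_translation_invariant(self, rng):
        X = _random_closed_curve(rng, 30)
        c1 = ib.BoundaryCurve(X=X, ds=0.1, c=1.0)
        c2 = ib.BoundaryCurve(X=X + [5.0, -3.0], ds=0.1, c=1.0)
        assert np.isclose(ib.enclosed_area(c1), ib.enclosed_area(c2))


class TestResampleCurve:
    def test_uniform_curve_unchanged(self):
        c = ib.circle_curve((0.0, 0.0), 1.0, 40, 1.0)
        c2 = ib.resample_curve(c)
        assert c2.m == c.m
        assert np.allclose(c2.X, c.X, atol=1e-10)

    def test_stretched_curve_respaced(self, rng):
        th = np.concatenate([np.linspace(0, np.pi, 120, endpoint=False),
                             np.linspace(np.pi, 2 * np.pi, 40,
                                         endpoint=False)])
        X = np.column_stack([np.cos(th), np.sin(th)])
        c = ib.BoundaryCurve(X=X, ds=2 * np.pi / 160, c=1.0)
        c2 = ib.resample_curve(c)
        sp = c2.spacing()
        assert sp.max() / sp.min() < 1.05
        assert abs(ib.enclosed_area(c2) / ib.enclosed_area(c) - 1) < 1e-3


class TestGliomaCell:
    def test_nucleus_outside_membrane_rejected(self):
        mem = ib.circle_curve((0.0, 0.0), 1.0, 32, 1.0)
        nuc = ib.circle_curve((5.0, 5.0), 0.5, 16, 1.0)
        with pytest.raises(ValueError, match="inside"):
            ib.GliomaCell(membrane=mem, nucleus=nuc, ct=1.0)

    def test_arc_selection_disjoint_and_oriented(self):
        mem = ib.circle_curve((0.0, 0.0), 1.0, 64, 1.0)
        nuc = ib.circle_curve((0.0, 0.0), 0.5, 32, 1.0)
        cell = ib.GliomaCell(membrane=mem, nucleus=nuc, ct=1.0)
        cell.select_arcs((0.0, 1.0), 60.0)
        assert np.intersect1d(cell.front_nodes, cell.rear_nodes).size == 0
        assert np.all(mem.X[cell.front_nodes, 1] > 0)
        assert np.all(mem.X[cell.rear_nodes, 1] < 0)

    def test_markers_initialized_perpendicular(self):
        mem = ib.circle_curve((0.0, 0.0), 1.0, 64, 1.0)
        nuc = ib.circle_curve((0.0, 0.0), 0.5, 32, 1.0)
        cell = ib.GliomaCell(membrane=mem, nucleus=nuc, ct=1.0)
        cell.init_markers((0.0, 1.0))
        c, w, e = cell.markers
        assert np.allclose(c, [0.0, 0.0], atol=1e-12)
        assert w[0] < c[0] < e[0]
        assert np.allclose(cell.marker_ref, 0.5, atol=1e-3)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_adjointness_property(seed):
    """Spread and interpolate are exact adjoints for random data."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(24, 56))
    h = float(rng.uniform(0.01, 0.1))
    m = int(rng.integers(9, 60))
    c = ib.circle_curve(rng.uniform(0.3, 0.7, 2) * n * h,
                        0.2 * n * h, m, 1.0)
    F = rng.standard_normal((m, 2))
    u = rng.standard_normal((2, n, n))
    f = ib.spread_forces(F, c, n, h)
    U = ib.interpolate_velocity(u, c, h)
    lhs = np.sum(F * U) * c.ds
    rhs = h * h * np.sum(f * u)
    assert abs(lhs - rhs) < 1e-12 * max(abs(rhs), 1.0)


def _random_closed_curve(rng, m):
    th = 2 * np.pi * np.arange(m) / m
    radii = 1.0 + 0.25 * rng.standard_normal(m)
    return np.column_stack([radii * np.cos(th), radii * np.sin(th)])
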