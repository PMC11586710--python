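import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sugausspb import build_grid, default_params, make_born_ion, make_two_atom
from sugausspb.dielectric import (
    atom_density,
    eps,
    eps_g,
    fields_on_grid,
    grad_atom_density,
    grad_eps,
    grad_eps_g,
    grad_surface,
    grad_total_density,
    surface,
    total_density,
)
from tests.conftest import numeric_gradient


class TestDensity:
    def test_atom_density_values(self, born_ion):
        a = born_ion.atoms[0]
        assert atom_density(a, (0, 0, 0), 1.0, 2) == pytest.approx(1.0)
        # at |r - r_j| = sigma*R the bracket is 1 for any m
        for m in (1, 2, 3, 8):
            assert atom_density(a, (2.0, 0, 0), 1.0, m) == pytest.approx(math.exp(-1))
        # m=2, sigma=1, R=2, d=1: exp(-(1/4)^2)
        assert atom_density(a, (1.0, 0, 0), 1.0, 2) == pytest.approx(math.exp(-0.0625))

    def test_total_density_combination(self, born_ion, two_atom):
        pt = (0.5, 0.3, -0.2)
        assert total_density(born_ion, pt, 1.0, 2) == pytest.approx(
            atom_density(born_ion.atoms[0], pt, 1.0, 2)
        )
        # overlapping tails at the midpoint region of the two-atom fixture
        assert total_density(two_atom, (0.1, 0, 0), 1.0, 2) > 0
        assert total_density(two_atom, (50.0, 0, 0), 1.0, 2) < 1e-12

    def test_two_half_densities_combine_to_three_quarters(self):
        # place a probe where each atom contributes exactly 1/2:
        # g = 1 - (1-1/2)(1-1/2) = 3/4
        from sugausspb.structio import Atom, Solute

        d = math.sqrt(math.sqrt(math.log(2.0)))  # (d^2)^2 = ln 2 for sigma=R=1
        s = Solute(atoms=(Atom("a", (-d, 0, 0), 0.0, 1.0), Atom("b", (d, 0, 0), 0.0, 1.0)))
        assert total_density(s, (0, 0, 0), 1.0, 2) == pytest.approx(0.75, rel=1e-12)

    def test_density_exceeds_each_contribution(self, two_atom):
        pts = np.array([[0.0, 0.3, 0.1], [1.0, 0.0, 0.0], [-1.0, 1.0, 0.0]])
        g = total_density(two_atom, pts, 1.0, 2)
        for atom in two_atom.atoms:
            assert np.all(g >= atom_density(atom, pts, 1.0, 2) - 1e-15)


class TestSurface:
    @given(
        g=st.floats(min_value=1e-6, max_value=1 - 1e-6),
        eta=st.floats(min_value=0.2, max_value=8.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_midpoint(self, g, eta):
        S = surface(g, eta)
        assert 0.0 <= S <= 1.0
        assert surface(0.5, eta) == pytest.approx(0.5)

    @given(eta=st.floats(min_value=0.2, max_value=8.0), data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_density(self, eta, data):
        g1 = data.draw(st.floats(min_value=1e-6, max_value=1 - 2e-6))
        g2 = data.draw(st.floats(min_value=g1, max_value=1 - 1e-6))
        assert surface(g2, eta) >= surface(g1, eta)

    def test_limits_and_example(self):
        assert surface(1.0, 3.3) == 1.0
        assert surface(0.0, 3.3) == 0.0
        assert surface(0.25, 2.0) == pytest.approx(0.1)


class TestEps:
    def test_eps_g_limits(self, born_ion, params):
        assert eps_g(born_ion, (0, 0, 0), params) == pytest.approx(params.eps_ref)
        assert eps_g(born_ion, (40, 0, 0), params) == pytest.approx(params.eps_gap)

    def test_eps_g_interpolates_product(self, params):
        # single atom at the distance where 1-g = 0.5: eps_g = 1 + 21*0.5
        from sugausspb.structio import Atom, Solute

        d = math.sqrt(math.sqrt(math.log(2.0)))
        s = Solute(atoms=(Atom("a", (0, 0, 0), 0.0, 1.0),))
        assert eps_g(s, (d, 0, 0), params) == pytest.approx(1 + 21 * 0.5, rel=1e-12)

    def test_eps_phase_limits(self, born_ion, params):
        assert eps(born_ion, (0, 0, 0), params, 80.0) == pytest.approx(1.0)
        assert eps(born_ion, (40, 0, 0), params, 80.0) == pytest.approx(80.0)
        assert eps(born_ion, (40, 0, 0), params, 1.0) == pytest.approx(1.0)

    def test_vacuum_phase_interior_hump(self, born_ion, params):
        """In the vacuum phase with eps_gap=22 the dielectric profile rises
        above 1 between the center (eps_ref=1) and the far field (1)."""
        r = np.linspace(0.0, 10.0, 200)
        pts = np.stack([r, np.zeros_like(r), np.zeros_like(r)], axis=-1)
        vals = eps(born_ion, pts, params, 1.0)
        assert vals.max() > 1.5
        assert vals[0] == pytest.approx(1.0)
        assert vals[-1] == pytest.approx(1.0)

    def test_convex_combination_bounds(self, two_atom, params):
        rng = np.random.default_rng(7)
        pts = rng.uniform(-10, 10, size=(500, 3))
        for phase_out in (80.0, 1.0):
            vals = eps(two_atom, pts, params, phase_out)
            lo = min(params.eps_ref, params.eps_gap, phase_out)
            hi = max(params.eps_ref, params.eps_gap, phase_out)
            assert np.all(vals >= lo - 1e-12) and np.all(vals <= hi + 1e-12)

    def test_hard_sphere_limit_with_growing_exponent(self, born_ion, params):
        """As m grows the Born-ion dielectric approaches a step at R: the
        deviation from the step, measured outside a 1 A band around R,
        decreases monotonically over m = 2, 4, 8."""
        r = np.concatenate([np.linspace(0.05, 1.5, 60), np.linspace(2.5, 8.0, 60)])
        pts = np.stack([r, np.zeros_like(r), np.zeros_like(r)], axis=-1)
        step = np.where(r < 2.0, 1.0, 80.0)
        devs = []
        for m in (2, 4, 8):
            p = params.replace(m=m, eps_gap=1.0)
            devs.append(np.abs(eps(born_ion, pts, p, 80.0) - step).max())
        assert devs[0] > devs[1] > devs[2]


class TestGradients:
    """Analytic gradients vs the central-difference oracle (the module's
    master correctness check)."""

    def test_grad_atom_density_center_and_direction(self, born_ion):
        a = born_ion.atoms[0]
        assert np.allclose(grad_atom_density(a, (0, 0, 0), 1.0, 2), 0.0)
        g = grad_atom_density(a, (1.3, 0.4, -0.2), 1.0, 2)
        dr = np.array([1.3, 0.4, -0.2])
        assert np.dot(g, dr) < 0  # density decreases outward

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_grad_atom_density_matches_numeric(self, born_ion, m):
        a = born_ion.atoms[0]
        pt = np.array([1.3, 0.7, -0.4])
        num = numeric_gradient(lambda p: atom_density(a, p, 1.0, m), pt)
        ana = grad_atom_density(a, pt, 1.0, m)
        assert np.allclose(ana, num, rtol=1e-6, atol=1e-10)

    def test_grad_eps_g_single_atom_reduces(self, born_ion, params):
        pt = np.array([1.8, 0.2, 0.0])
        expected = -(params.eps_gap - params.eps_ref) * grad_atom_density(
            born_ion.atoms[0], pt, params.sigma, params.m
        )
        assert np.allclose(grad_eps_g(born_ion, pt, params), expected, rtol=1e-12)

    def test_gradient_oracle_suite(self, born_ion, two_atom, tripeptide_like, params):
        """All four analytic gradients match central differences to 1e-6
        relative at random points around every fixture."""
        rng = np.random.default_rng(1234)
        for solute in (born_ion, two_atom, tripeptide_like):
            lo = solute.positions.min(axis=0) - 4.0
            hi = solute.positions.max(axis=0) + 4.0
            pts = rng.uniform(lo, hi, size=(120, 3))
            for pt in pts:
                g = total_density(solute, pt, params.sigma, params.m, cutoff=False)
                if g > 1 - 1e-9 or g < 1e-6:
                    continue  # plateau/deep tail: gradients at noise level, checked elsewhere
                checks = [
                    (grad_total_density(solute, pt, params.sigma, params.m, cutoff=False),
                     lambda p: total_density(solute, p, params.sigma, params.m, cutoff=False)),
                    (grad_eps_g(solute, pt, params, cutoff=False),
                     lambda p: eps_g(solute, p, params, cutoff=False)),
                    (grad_surface(solute, pt, params, cutoff=False),
                     lambda p: surface(total_density(solute, p, params.sigma, params.m, cutoff=False), params.eta)),
                    (grad_eps(solute, pt, params, 80.0, cutoff=False),
                     lambda p: eps(solute, p, params, 80.0, cutoff=False)),
                ]
                for ana, func in checks:
                    num = numeric_gradient(func, pt)
                    # 1e-8 floor: central differences of eps ~ 80 carry
                    # subtraction noise ~ |f| * eps_machine / h_fd ~ 1e-9
                    scale = max(np.linalg.norm(num), np.linalg.norm(ana), 1e-8)
                    assert np.allclose(ana, num, atol=1e-6 * scale + 1e-8), (
                        f"{solute.id} at {pt}: analytic {ana} vs numeric {num}"
                    )

    def test_grad_surface_plateaus(self, born_ion, params):
        assert np.allclose(grad_surface(born_ion, (0.0, 0.0, 0.05), params), 0.0)
        assert np.allclose(grad_surface(born_ion, (30.0, 0, 0), params), 0.0)

    def test_born_interface_dielectric_rises_outward(self, born_ion, params):
        """Water phase, eps_gap=22 < eps_out=80: radial component of grad
        eps is >= 0 through the interface."""
        r = np.linspace(0.5, 8.0, 80)
        pts = np.stack([r, np.zeros_like(r), np.zeros_like(r)], axis=-1)
        ge = grad_eps(born_ion, pts, params, 80.0)
        assert np.all(ge[:, 0] >= -1e-10)

    def test_cutoff_matches_exact_evaluation(self, two_atom, params):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-6, 6, size=(200, 3))
        a = total_density(two_atom, pts, params.sigma, params.m, cutoff=True)
        b = total_density(two_atom, pts, params.sigma, params.m, cutoff=False)
        assert np.allclose(a, b, atol=1e-13)


class TestFieldsOnGrid:
    def test_born_symmetry_and_bounds(self, born_ion, params):
        # scale 2, padding 15 puts the ion exactly on a node
        grid = build_grid(born_ion, 2.0, 15.0)
        f = fields_on_grid(born_ion, grid, params, 80.0)
        c = np.round(grid.world_to_index((0, 0, 0))).astype(int)
        d = 6
        vals = [
            f.S.values[c[0] + d, c[1], c[2]], f.S.values[c[0] - d, c[1], c[2]],
            f.S.values[c[0], c[1] + d, c[2]], f.S.values[c[0], c[1] - d, c[2]],
            f.S.values[c[0], c[1], c[2] + d], f.S.values[c[0], c[1], c[2] - d],
        ]
        assert np.allclose(vals, vals[0], atol=1e-12)
        assert f.eps_nodes.values.min() >= 1.0 - 1e-12
        assert f.eps_nodes.values.max() <= 80.0 + 1e-12

    def test_grid_gradient_matches_pointwise(self, two_atom, params):
        grid = build_grid(two_atom, 2.0, 8.0)
        f = fields_on_grid(two_atom, grid, params, 80.0)
        rng = np.random.default_rng(99)
        idx = rng.integers(0, grid.dims, size=(100, 3))
        pts = grid.index_to_world(idx)
        expected = grad_eps(two_atom, pts, params, 80.0)
        got = f.grad_eps.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_midpoint_eps_is_analytic_not_averaged(self, two_atom, params):
        grid = build_grid(two_atom, 2.0, 8.0)
        f = fields_on_grid(two_atom, grid, params, 80.0)
        i, j, k = 10, 12, 14
        mid = np.asarray(grid.index_to_world((i, j, k))) + np.array([grid.h / 2, 0, 0])
        assert f.eps_mid_x[i, j, k] == pytest.approx(
            float(eps(two_atom, mid, params, 80.0)), rel=1e-12
        )
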