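"""Pressure solve, Darcy velocities, conservative transport, adhesion."""

import numpy as np
import pytest

from lymphsim.grids import TissueState, make_grid, make_node
from lymphsim.kinetics import SourceTerms, source_terms
from lymphsim.mechanics import (CFLError, VelocityField, adhesion_energy,
                                advance_fractions, apply_adhesion_relaxation,
                                cell_velocity, equilibrium_interface_width,
                                solve_pressure)
from lymphsim.params import ModelParameters


class TestPressure:
    def test_zero_source_zero_pressure(self):
        g = make_grid(3.2, 200.0, dim=2)
        p, res = solve_pressure(g.zeros(), np.ones(g.shape), g)
        assert np.allclose(p, 0.0, atol=1e-12)

    def test_radial_source_matches_quadrature_oracle(self):
        """Uniform disc source: p from the independent radial flux
        integration (quadratic inside, log-like outside with the uniform
        compensating sink) within 2%."""
        g = make_grid(6.4, 100.0, dim=2)   # h = R/8
        R = 0.8
        r = g.radius_from()
        S = (r <= R).astype(float)
        p, _ = solve_pressure(S, np.ones(g.shape), g)

        # oracle: radial integration of flux(r) = (1/r) int (S - S_mean) r dr,
        # with the disc radius matched to the voxelised source area
        S_mean = S.mean()
        R_eff = np.sqrt(S.sum() * g.h**2 / np.pi)
        rr = np.linspace(1e-6, 3.0, 3000)
        src = np.where(rr <= R_eff, 1.0, 0.0) - S_mean
        flux_r = np.cumsum(src * rr) * (rr[1] - rr[0]) / rr
        p_oracle = -np.cumsum(flux_r) * (rr[1] - rr[0])

        p0 = p[r < g.h].mean()
        scale = abs(np.interp(1.8, rr, p_oracle) - p_oracle[0])
        for rad in np.arange(0.2, 1.81, 0.2):   # away from box corners
            sel = np.abs(r - rad) < 0.5 * g.h
            p_num = p[sel].mean() - p0
            p_exp = np.interp(rad, rr, p_oracle) - p_oracle[0]
            assert abs(p_num - p_exp) / scale < 0.02

    def test_mobility_jump_scales_gradient(self):
        """Fixed flux through a mobility step: |grad p| jumps ~10x."""
        g = make_grid(6.4, 100.0, dim=2)
        k = np.ones(g.shape)
        k[g.n_cells // 2:, :] /= 10.0
        S = np.zeros(g.shape)
        S[:8, :] = 1.0      # drive flux left to right
        S[-8:, :] = -1.0
        p, _ = solve_pressure(S, k, g)
        prof = p.mean(axis=1)
        grad = np.diff(prof)
        i = g.n_cells // 2
        g_in = np.mean(grad[i - 10:i - 2])
        g_out = np.mean(grad[i + 2:i + 10])
        assert g_out / g_in == pytest.approx(10.0, rel=0.05)

    def test_nonpositive_mobility_rejected(self):
        g = make_grid(3.2, 200.0, dim=2)
        with pytest.raises(ValueError, match="mobility"):
            solve_pressure(g.zeros(), np.zeros(g.shape), g)


class TestCellVelocity:
    def _setup(self):
        g = make_grid(3.2, 200.0, dim=2)
        p = ModelParameters()
        shape = g.shape
        return g, p, np.zeros(shape), np.ones(shape)

    def test_uniform_fields_no_motion(self):
        g, p, zero, one = self._setup()
        vf = cell_velocity(zero, one * 0.5, one, one * 0.5, zero, zero,
                           p, one, g)
        for sp in ("V", "D", "H"):
            for uf in vf.faces[sp]:
                assert np.allclose(uf, 0.0)

    def test_chemotaxis_on_linear_ramp_is_exact(self):
        g, p, zero, one = self._setup()
        p = p.replace(chi_n=2.0)
        n = np.tile(np.linspace(0, 1, g.n_cells)[:, None], (1, g.n_cells))
        slope = (n[1, 0] - n[0, 0]) / g.h
        vf = cell_velocity(zero, n, one, one * 0.5, zero, zero, p, one, g)
        assert np.allclose(vf.faces["V"][0], p.chi_n * slope)
        assert np.allclose(vf.faces["V"][1], 0.0)
        # host never chemotaxes
        assert np.allclose(vf.faces["H"][0], 0.0)

    def test_adhesion_velocity_decreases_interface_energy(self):
        """Advecting a 1D interface with the adhesive velocity alone lowers
        the adhesion energy (the sign convention of gamma grad(mu))."""
        g = make_grid(6.4, 100.0, dim=2)
        p = ModelParameters(gamma=0.5)
        zero, one = np.zeros(g.shape), np.ones(g.shape)
        x = g.axis_centers()
        st_ = TissueState.empty(g)
        st_.rho_V = np.tile(0.5 * (1 - np.tanh((x - 3.2) / 0.4))[:, None],
                            (1, g.n_cells))
        e0 = adhesion_energy(st_.rho_V, p, g.h, g.dim)
        for _ in range(10):
            vf = cell_velocity(zero, one, one, st_.rho_V, st_.rho_D, zero,
                               p, one, g, include_adhesion=True)
            advance_fractions(st_, vf, _zero_sources(g), 0.005)
        e1 = adhesion_energy(st_.rho_V + st_.rho_D, p, g.h, g.dim)
        assert e1 < e0


class TestAdhesionRelaxation:
    def test_energy_decreases_and_mass_conserved(self):
        g = make_grid(3.2, 100.0, dim=2)
        p = ModelParameters(gamma=0.5)
        st_ = TissueState.empty(g)
        rng = np.random.default_rng(0)
        st_.rho_V = np.clip(0.5 + 0.3 * rng.standard_normal(g.shape), 0, 1)
        m0 = st_.rho_V.sum() + st_.rho_D.sum()
        e0 = adhesion_energy(st_.rho_V + st_.rho_D, p, g.h, g.dim)
        for _ in range(5):
            apply_adhesion_relaxation(st_, p, 0.01)
        e1 = adhesion_energy(st_.rho_V + st_.rho_D, p, g.h, g.dim)
        m1 = st_.rho_V.sum() + st_.rho_D.sum()
        assert e1 < e0
        assert m1 == pytest.approx(m0, rel=1e-6)

    def test_interface_width_formula(self):
        p = ModelParameters(eps_int_vox=1.0)
        w = equilibrium_interface_width(p, 0.1)
        assert w == pytest.approx(2 * np.sqrt(2) * np.arctanh(0.8) * 0.1)


def _uniform_velocity(grid, speed, axis=0):
    vf = VelocityField(grid=grid)
    for sp in ("V", "D", "H"):
        faces = []
        for ax in range(grid.dim):
            shape = list(grid.shape)
            shape[ax] -= 1
            faces.append(np.full(shape, speed if ax == axis else 0.0))
        vf.faces[sp] = faces
    return vf


def _zero_sources(grid):
    z = grid.zeros()
    return SourceTerms(S_V=z.copy(), S_D=z.copy(), S_H=z.copy(),
                       proliferating=z > 1, quiescent=z > 1)


class TestAdvanceFractions:
    def test_identity_with_no_flow_no_sources(self):
        g = make_grid(3.2, 200.0, dim=2)
        st_ = TissueState.empty(g)
        st_.rho_V = np.random.default_rng(0).random(g.shape) * 0.5
        before = st_.rho_V.copy()
        advance_fractions(st_, _uniform_velocity(g, 0.0), _zero_sources(g), 0.01)
        assert np.array_equal(st_.rho_V, before)

    def test_exponential_growth_one_step(self):
        g = make_grid(3.2, 200.0, dim=2)
        p = ModelParameters(lambda_A=0.0, lambda_N_nd=0.0, lambda_D=0.0)
        st_ = TissueState.empty(g)
        st_.rho_V = np.full(g.shape, 0.4)
        st_.n = np.ones(g.shape)
        src = source_terms(st_.rho_V, st_.rho_D, st_.rho_H, st_.n, p)
        dt = 0.01
        advance_fractions(st_, _uniform_velocity(g, 0.0), src, dt)
        assert np.allclose(st_.rho_V, 0.4 * (1 + p.lambda_M * dt))

    def test_translation_conserves_mass_and_bounds(self):
        """One tumor diameter of uniform translation: exact mass balance,
        no new extrema (monotone upwind)."""
        g = make_grid(6.4, 100.0, dim=2)
        st_ = TissueState.empty(g)
        st_.rho_V = (g.radius_from() <= 0.5).astype(float)
        m0 = st_.rho_V.sum()
        u, dt = 0.5, 0.01
        steps = int(1.0 / (u * dt))    # travel 1 mm
        vf = _uniform_velocity(g, u)
        src = _zero_sources(g)
        for _ in range(steps):
            advance_fractions(st_, vf, src, dt)
        assert st_.rho_V.sum() == pytest.approx(m0, abs=1e-10 * m0)
        assert st_.rho_V.max() <= 1.0 + 1e-12
        assert st_.rho_V.min() >= -1e-15
        # the profile drifted by ~1 mm
        com = (st_.rho_V * g.axis_centers()[:, None]).sum() / st_.rho_V.sum()
        assert com == pytest.approx(3.2 + 1.0, abs=2 * g.h)

    def test_cfl_violation_rejected_with_suggestion(self):
        g = make_grid(3.2, 200.0, dim=2)
        st_ = TissueState.empty(g)
        with pytest.raises(CFLError) as e:
            advance_fractions(st_, _uniform_velocity(g, 50.0),
                              _zero_sources(g), 0.01)
        assert e.value.dt_suggested <= g.h / 50.0

    def test_mass_identity_reported(self):
        g = make_grid(3.2, 200.0, dim=2)
        st_ = TissueState.empty(g)
        st_.rho_V = np.random.default_rng(1).random(g.shape) * 0.3
        src = _zero_sources(g)
        src.S_V = np.random.default_rng(2).standard_normal(g.shape) * 0.1
        diag = advance_fractions(st_, _uniform_velocity(g, 0.2), src, 0.01)
        assert diag.mass_residual < 1e-8
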