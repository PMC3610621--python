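"""Quasi-steady substrate/VEGF solves against closed forms and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import k0

from lymphsim.grids import TissueState, make_grid
from lymphsim.params import ModelParameters
from lymphsim.transport import (EmptyTumorError, delta_scale,
                                hypoxic_fraction_of_tumor, hypoxic_mask,
                                solve_substrate, solve_vegf)


class TestSubstrate:
    def test_saturation_fixed_point(self):
        """Vessels everywhere and no uptake pin n at the supply level."""
        g = make_grid(3.2, 200.0, dim=2)
        p = ModelParameters(lambda_upt_H_rel=0.0)
        zero = g.zeros()
        n, _ = solve_substrate(g, np.ones(g.shape), zero, zero, p)
        assert np.allclose(n, 1.0, atol=1e-7)

    def test_1d_exponential_profile(self):
        """A vessel plane feeding a uniform slab gives n ~ exp(-x/L)."""
        # L = 0.8 mm resolved at h = L/8
        p = ModelParameters(L_hypoxia_um=800.0, lambda_upt_H_rel=0.0)
        g = make_grid(12.8, 100.0, dim=2)
        delta = g.zeros()
        delta[0, :] = 1.0
        rho_V = np.ones(g.shape)
        n, _ = solve_substrate(g, delta, rho_V, g.zeros(), p)
        x = g.axis_centers()
        prof = n.mean(axis=1)
        L = 0.8
        # compare in the interior, away from the source voxel and far wall
        sl = slice(2, 60)
        expected = prof[2] * np.exp(-(x[sl] - x[2]) / L)
        assert np.max(np.abs(prof[sl] - expected) / expected[0]) < 0.01

    def test_hypoxia_onset_near_80_um(self):
        """With the anchored uptake, n crosses n_N about 80 µm from a vessel."""
        p = ModelParameters(lambda_upt_H_rel=0.0)   # L = 80 um
        g = make_grid(1.28, 20.0, dim=2)            # fine grid, 64^2
        delta = g.zeros()
        delta[0, :] = 1.0
        n, _ = solve_substrate(g, delta, np.ones(g.shape), g.zeros(), p)
        prof = n.mean(axis=1)
        x = g.axis_centers()
        crossing = np.interp(-p.n_N, -prof, x) - x[0]
        assert 0.060 <= crossing <= 0.100   # 80 +/- 20 um

    def test_grid_refinement_second_order(self):
        """Halving h cuts the 1D profile error by about four."""
        p = ModelParameters(L_hypoxia_um=800.0, lambda_upt_H_rel=0.0)
        errs = []
        for spacing in (200.0, 100.0):
            g = make_grid(12.8, spacing, dim=2)
            delta = g.zeros()
            delta[0, :] = 1.0
            n, _ = solve_substrate(g, delta, np.ones(g.shape), g.zeros(), p)
            x = g.axis_centers()
            prof = n.mean(axis=1)
            i0 = int(1.6 / g.h)              # compare from x = 1.6 mm inward
            sl = slice(i0, int(8.0 / g.h))
            expected = prof[i0] * np.exp(-(x[sl] - x[i0]) / 0.8)
            errs.append(np.max(np.abs(prof[sl] - expected)))
        ratio = errs[0] / errs[1]
        assert 2.5 < ratio < 6.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), nu_nd=st.floats(0.1, 50.0))
    def test_maximum_principle(self, seed, nu_nd):
        """Solutions stay in [0, 1] for any non-negative configuration."""
        rng = np.random.default_rng(seed)
        g = make_grid(3.2, 200.0, dim=2)
        p = ModelParameters(nu_nd=nu_nd)
        delta = (rng.random(g.shape) < 0.1).astype(float)
        rho_V = rng.random(g.shape)
        rho_H = rng.random(g.shape) * (1 - rho_V)
        n, _ = solve_substrate(g, delta, rho_V, rho_H, p)
        assert np.all(n >= 0.0) and np.all(n <= 1.0)

    def test_monotone_in_uptake_and_delivery(self):
        g = make_grid(3.2, 200.0, dim=2)
        rng = np.random.default_rng(0)
        delta = (rng.random(g.shape) < 0.1).astype(float)
        rho_V = np.ones(g.shape) * 0.5
        base, _ = solve_substrate(g, delta, rho_V, g.zeros(), ModelParameters())
        more_uptake, _ = solve_substrate(g, delta, 2 * rho_V, g.zeros(),
                                         ModelParameters())
        more_supply, _ = solve_substrate(g, delta, rho_V, g.zeros(),
                                         ModelParameters(nu_nd=20.0))
        assert np.all(more_uptake <= base + 1e-9)
        assert np.all(more_supply >= base - 1e-9)


class TestVegf:
    def test_no_hypoxia_no_vegf(self):
        g = make_grid(3.2, 200.0, dim=2)
        n_V, _ = solve_vegf(g, g.zeros(), np.zeros(g.shape, bool),
                            np.ones(g.shape), ModelParameters())
        assert np.allclose(n_V, 0.0)

    def test_uniform_hypoxic_source_saturates(self):
        """With no sinks and zero decay the saturating source drives n_V -> 1."""
        g = make_grid(3.2, 200.0, dim=2)
        n_V, _ = solve_vegf(g, g.zeros(), np.ones(g.shape, bool),
                            np.ones(g.shape), ModelParameters())
        assert np.allclose(n_V, 1.0, atol=1e-6)

    def test_point_source_matches_bessel_profile(self):
        """A single secreting voxel with uniform decay follows the 2D
        screened Green's function K0(r/l) away from the source."""
        p = ModelParameters(lambda_dec_nV=5.0)
        g = make_grid(12.8, 100.0, dim=2)
        hyp = np.zeros(g.shape, bool)
        hyp[64, 64] = True
        n_V, _ = solve_vegf(g, g.zeros(), hyp, np.ones(g.shape) * 1e-3, p)
        ell = np.sqrt(p.D_nV_mm2_day / p.lambda_dec_nV)   # 0.42 mm, resolved
        r = g.radius_from()
        # angle-averaged annuli vs the K0 shape (averaged over the same
        # voxel radii), from 4 voxels out to ~4 screening lengths
        ratios = []
        for rr in np.arange(0.4, 4 * ell, 0.2):
            sel = np.abs(r - rr) < g.h
            ratios.append(n_V[sel].mean() / k0(r[sel] / ell).mean())
        ratios = np.asarray(ratios)
        assert np.max(np.abs(ratios / ratios.mean() - 1.0)) < 0.05


class TestHypoxicFraction:
    def _state(self, n):
        g = make_grid(3.2, 200.0, dim=2)
        st = TissueState.empty(g)
        st.rho_V = np.ones(g.shape)
        st.n = n if isinstance(n, np.ndarray) else np.full(g.shape, n)
        return st

    def test_fully_oxygenated_is_zero(self):
        assert hypoxic_fraction_of_tumor(self._state(1.0), ModelParameters()) == 0.0

    def test_fully_anoxic_is_one(self):
        assert hypoxic_fraction_of_tumor(self._state(0.0), ModelParameters()) == 1.0

    def test_half_space_construction(self):
        st = self._state(1.0)
        st.n[: st.grid.n_cells // 2, :] = 0.0
        frac = hypoxic_fraction_of_tumor(st, ModelParameters())
        assert frac == pytest.approx(0.5, abs=1.0 / st.grid.n_cells)

    def test_empty_tumor_signalled(self):
        st = self._state(1.0)
        st.rho_V[:] = 0.0
        with pytest.raises(EmptyTumorError):
            hypoxic_fraction_of_tumor(st, ModelParameters())


def test_delta_scale_is_squared_length_ratio():
    g = make_grid(6.4, 100.0, dim=2)
    assert delta_scale(g, ModelParameters()) == pytest.approx(0.64)


def test_hypoxic_mask_requires_viable_tissue():
    g = make_grid(3.2, 200.0, dim=2)
    n = np.zeros(g.shape)
    rho = np.zeros(g.shape)
    rho[0, 0] = 0.5
    m = hypoxic_mask(n, rho, 0.3)
    assert m[0, 0] and m.sum() == 1
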