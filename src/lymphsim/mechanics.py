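"""Darcy tissue mechanics: pressure, cell velocities, conservative transport.

Mixture closure: cells + water fill space, water moves freely through the
ECM, so net cell-volume creation must be evacuated by the mass-averaged cell
velocity.  With the generalized Darcy law ``u = -k grad p`` this yields the
pressure Poisson problem ``div(k grad p) = -S_total``.  On a closed box the
source is projected to zero mean (uniform water efflux) and p is gauged to
zero mean — the spec of the problem only determines p up to a constant.

Cell-cell adhesion derives from a Ginzburg–Landau energy on the total tumor
fraction, ``E = int gamma [ W(rho_T) + (eps^2/2)|grad rho_T|^2 ]`` with the
double well ``W(r) = r^2 (1-r)^2 / 4``.  Tumor species feel the chemical
potential mu = dE/drho through their velocity; the sign convention moves
tissue down the potential gradient so that E decreases along trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import elliptic
from .grids import Grid, NodeGeometry, TissueState
from .kinetics import SourceTerms
from .params import ModelParameters


class CFLError(ValueError):
    def __init__(self, dt, dt_max):
        super().__init__(
            f"advective CFL violated: dt={dt:.3e} day exceeds the stable "
            f"bound; use dt <= {dt_max:.3e} day")
        self.dt_suggested = dt_max


def double_well_prime(r: np.ndarray) -> np.ndarray:
    # d/dr [ r^2 (1-r)^2 / 4 ]
    return 0.5 * r * (1.0 - r) * (1.0 - 2.0 * r)


def adhesion_potential(rho_T: np.ndarray, params: ModelParameters,
                       h: float) -> np.ndarray:
    """Variational derivative mu = W'(rho_T) - eps^2 lap rho_T (zero-flux)."""
    eps = params.eps_int_vox * h
    return double_well_prime(rho_T) - eps**2 * elliptic.laplacian_neumann(rho_T, h)


def adhesion_energy(rho_T: np.ndarray, params: ModelParameters,
                    h: float, dim: int) -> float:
    """Total adhesion energy; monitored by tests, not by the solver."""
    eps = params.eps_int_vox * h
    W = 0.25 * rho_T**2 * (1.0 - rho_T) ** 2
    grad2 = np.zeros_like(rho_T)
    for ax in range(rho_T.ndim):
        g = np.gradient(rho_T, h, axis=ax)
        grad2 += g**2
    return float(params.gamma * np.sum(W + 0.5 * eps**2 * grad2) * h**dim)


def equilibrium_interface_width(params: ModelParameters, h: float) -> float:
    """10-90% width of the equilibrium tanh interface of the adhesion energy.

    The double well W(r) = r^2(1-r)^2/4 with gradient coefficient eps^2/2
    has the standing profile rho = (1 - tanh((x)/(sqrt(2) eps)))/2, giving a
    10-90 width of 2 sqrt(2) atanh(0.8) eps.
    """
    eps = params.eps_int_vox * h
    return 2.0 * np.sqrt(2.0) * np.arctanh(0.8) * eps


def apply_adhesion_relaxation(state: TissueState, params: ModelParameters,
                              dt: float) -> float:
    """Operator-split Cahn–Hilliard step of the adhesion flux.

    The adhesion contribution to the species flux J is fourth-order and
    stiff; it is applied as its own substep with the standard linear
    stabilisation: the biharmonic part is implicit (diagonal in DCT space
    under zero-flux boundaries), the double-well part explicit.  The step
    conserves tumor mass and compacts the tumor-host interface to a width
    of order ``eps_int_vox`` voxels; the change in total tumor fraction is
    redistributed between viable and dead tissue by their local share.
    Returns the (small) mass clipped when enforcing fractions in [0, 1].
    """
    gamma = params.gamma
    if gamma <= 0.0:
        return 0.0
    from scipy import fft as sfft

    h = state.grid.h
    eps = params.eps_int_vox * h
    kappa = params.k_V * gamma          # constant interface mobility
    stab = 1.0                          # >= max|W''|, Eyre-type stabilisation
    rho_T = state.rho_V + state.rho_D
    rhs = rho_T + dt * kappa * elliptic.laplacian_neumann(
        double_well_prime(rho_T) - stab * rho_T, h)
    eig = elliptic._dct_eigenvalues(rho_T.shape, h)
    rho_hat = sfft.dctn(rhs, type=2, norm="ortho")
    rho_hat /= 1.0 + dt * kappa * (eps**2 * eig**2 + stab * eig)
    rho_new = sfft.idctn(rho_hat, type=2, norm="ortho")

    # Enforce 0 <= rho_T <= 1 - rho_H conservatively: the mass removed by
    # the capacity clip is restored into the remaining capacity of the
    # tumor body so the substep keeps its mass-conservation contract.
    cap = np.maximum(1.0 - state.rho_H, 0.0)
    target_mass = rho_new.sum()                 # == rho_T.sum() up to fft eps
    rho_clip = np.clip(rho_new, 0.0, cap)
    deficit = target_mass - rho_clip.sum()
    body = rho_clip > 1e-6
    for _ in range(3):
        if abs(deficit) < 1e-13 * max(target_mass, 1.0):
            break
        if deficit > 0:
            room = np.where(body, cap - rho_clip, 0.0)
            total_room = room.sum()
            if total_room <= 0:
                break
            rho_clip = rho_clip + room * min(1.0, deficit / total_room)
        else:
            total = rho_clip.sum()
            if total <= 0:
                break
            rho_clip = rho_clip * (1.0 + deficit / total)
            rho_clip = np.clip(rho_clip, 0.0, cap)
        deficit = target_mass - rho_clip.sum()
    clipped = float(abs(deficit))
    rho_new = rho_clip
    share_V = np.where(rho_T > 1e-12, state.rho_V / np.maximum(rho_T, 1e-12), 1.0)
    delta = rho_new - rho_T
    state.rho_V = np.clip(state.rho_V + delta * share_V, 0.0, 1.0)
    state.rho_D = np.clip(state.rho_D + delta * (1.0 - share_V), 0.0, 1.0)
    return clipped * state.grid.cell_volume


def solve_pressure(S_total: np.ndarray, mobility: np.ndarray, grid: Grid,
                   rtol: float = 1e-8, maxiter: int = 2000):
    """Pressure from ``div(k grad p) = -S_total`` (zero-flux, zero-mean)."""
    return elliptic.solve_pressure(mobility, -S_total, grid.h,
                                   rtol=rtol, maxiter=maxiter)


def _face_avg(a: np.ndarray, ax: int) -> np.ndarray:
    lo = np.take(a, range(a.shape[ax] - 1), axis=ax)
    hi = np.take(a, range(1, a.shape[ax]), axis=ax)
    return 0.5 * (lo + hi)


def _face_harmonic(a: np.ndarray, ax: int) -> np.ndarray:
    lo = np.take(a, range(a.shape[ax] - 1), axis=ax)
    hi = np.take(a, range(1, a.shape[ax]), axis=ax)
    return 2.0 * lo * hi / (lo + hi)


@dataclass
class VelocityField:
    """Interior-face velocities per species and axis (zero-flux at the box).

    ``faces[species][ax]`` has one fewer entry along ``ax`` than the grid;
    ``cell_centered(species)`` averages back for output and diagnostics.
    """

    grid: Grid
    faces: dict = field(default_factory=dict)

    def cell_centered(self, species: str) -> list:
        out = []
        for ax, uf in enumerate(self.faces[species]):
            u = np.zeros(self.grid.shape)
            lo = [slice(None)] * self.grid.dim
            hi = [slice(None)] * self.grid.dim
            lo[ax] = slice(1, None)
            hi[ax] = slice(None, -1)
            u[tuple(hi)] += 0.5 * uf
            u[tuple(lo)] += 0.5 * uf
            out.append(u)
        return out

    def max_speed_sum(self) -> float:
        """Sum over axes of the maximum face speed (CFL-relevant norm)."""
        tot = 0.0
        for ax in range(self.grid.dim):
            m = 0.0
            for sp in self.faces:
                m = max(m, float(np.abs(self.faces[sp][ax]).max()))
            tot += m
        return tot


def cell_velocity(p: np.ndarray, n: np.ndarray, f_ecm: np.ndarray,
                  rho_V: np.ndarray, rho_D: np.ndarray, rho_H: np.ndarray,
                  params: ModelParameters, mobility: np.ndarray,
                  grid: Grid, include_adhesion: bool = True) -> VelocityField:
    """Generalized Darcy velocities.

    Tumor species: ``u = -k (grad p + gamma grad mu) + chi_n grad n
    + chi_h grad f``; dead tissue advects with pressure and adhesion but does
    not chemotax; host feels pressure only (chi_n = chi_h = 0).

    ``include_adhesion=False`` drops the stiff gamma grad(mu) term; the
    simulator then applies it separately via
    :func:`apply_adhesion_relaxation` (operator splitting).
    """
    h = grid.h
    vf = VelocityField(grid=grid)
    mu = None
    if params.gamma > 0 and include_adhesion:
        mu = adhesion_potential(rho_V + rho_D, params, h)

    species_mob = {"V": params.k_V, "D": params.k_D, "H": params.k_H}
    for sp, k_sp in species_mob.items():
        faces = []
        for ax in range(grid.dim):
            k_face = k_sp * _face_harmonic(mobility, ax)
            u = -k_face * np.diff(p, axis=ax) / h
            if sp in ("V", "D") and mu is not None:
                u = u - params.gamma * k_face * np.diff(mu, axis=ax) / h
            if sp == "V":
                if params.chi_n != 0.0:
                    u = u + params.chi_n * np.diff(n, axis=ax) / h
                if params.chi_h != 0.0:
                    u = u + params.chi_h * np.diff(f_ecm, axis=ax) / h
            faces.append(u)
        vf.faces[sp] = faces
    return vf


def _upwind_div(rho: np.ndarray, faces: list, h: float) -> np.ndarray:
    """Divergence of the upwind flux u*rho, zero flux across the boundary."""
    div = np.zeros_like(rho)
    for ax, uf in enumerate(faces):
        lo = [slice(None)] * rho.ndim
        hi = [slice(None)] * rho.ndim
        lo[ax] = slice(1, None)
        hi[ax] = slice(None, -1)
        rho_lo = rho[tuple(hi)]   # cell below the face
        rho_hi = rho[tuple(lo)]   # cell above the face
        flux = np.where(uf > 0, uf * rho_lo, uf * rho_hi)
        div[tuple(hi)] += flux
        div[tuple(lo)] -= flux
    return div / h


@dataclass
class AdvanceDiagnostics:
    clipped_mass: float = 0.0          # voxel-fraction mass removed by clipping
    mass_residual: float = 0.0         # |d(mass) - dt*int S| of the discrete identity


def advance_fractions(state: TissueState, velocities: VelocityField,
                      sources: SourceTerms, dt: float,
                      enforce_cfl: bool = True) -> AdvanceDiagnostics:
    """Conservative explicit update of rho_V, rho_D, rho_H (in place).

    First-order in time, upwind in space; clipping to [0, 1] and to total
    solid fraction <= 1 is logged so mass bookkeeping stays auditable.
    """
    h = state.grid.h
    speed = velocities.max_speed_sum()
    if enforce_cfl and speed > 0:
        dt_max = h / speed
        if dt > dt_max:
            raise CFLError(dt, dt_max)

    updates = {}
    expected_change = 0.0
    for sp, rho, S in (("V", state.rho_V, sources.S_V),
                       ("D", state.rho_D, sources.S_D),
                       ("H", state.rho_H, sources.S_H)):
        new = rho + dt * (S - _upwind_div(rho, velocities.faces[sp], h))
        updates[sp] = new
        expected_change += dt * float(S.sum())

    mass_before = float(state.rho_V.sum() + state.rho_D.sum() + state.rho_H.sum())
    pre_clip_mass = float(sum(u.sum() for u in updates.values()))
    # discrete identity: advection is conservative, so the pre-clip mass
    # change must equal dt * int S exactly (up to float roundoff)
    residual = abs((pre_clip_mass - mass_before) - expected_change)

    clipped = 0.0
    for sp, new in updates.items():
        lo_clip = np.minimum(new, 0.0)
        hi_clip = np.maximum(new - 1.0, 0.0)
        clipped += float(np.abs(lo_clip).sum() + hi_clip.sum())
        updates[sp] = np.clip(new, 0.0, 1.0)

    total = updates["V"] + updates["D"] + updates["H"]
    over = total > 1.0
    if np.any(over):
        scale = np.where(over, 1.0 / np.maximum(total, 1.0), 1.0)
        clipped += float((total[over] - 1.0).sum())
        for sp in updates:
            updates[sp] = updates[sp] * scale

    state.rho_V, state.rho_D, state.rho_H = (updates["V"], updates["D"],
                                             updates["H"])
    state.t_day += dt
    return AdvanceDiagnostics(clipped_mass=clipped * state.grid.cell_volume,
                              mass_residual=residual * state.grid.cell_volume)
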