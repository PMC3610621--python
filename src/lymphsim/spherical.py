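"""Radially symmetric reduced growth model and terminal-size analysis.

The tumor is a uniform-density ball of radius R(t).  The substrate obeys the
same quasi-steady reaction–diffusion balance as the full model, reduced to
the radial coordinate, and the radius evolves by the integrated mass
balance::

    dR/dt = (1/R^{d-1}) * int_0^R [ lambda_M n H(n - n_N) - lambda_A
                                    - lambda_N H(n_N - n) ] r^{d-1} dr

so that a uniform integrand g gives the exponential law dR/dt = g R / d.
The terminal radius is reached when rim proliferation balances the apoptotic
(and, below n_N, necrotic) loss of the interior; for the distributed-supply
closure it depends on the apoptosis-to-proliferation ratio A = lambda_A /
lambda_M and on the vascular support fraction, not on the initial substrate
level, which only shapes the growth phase through the supply ramp.

Supply modes
------------
``core``
    Delivery ``nu (n_sup - n)`` only on the pre-existing central vascular
    ball (radius ``root_radius_mm``); the configuration of the spherically
    symmetric full-model oracle runs.
``distributed``
    The angiogenic steady state: tumor tissue receives a volumetric source
    at the fraction ``vascular_support`` of its maximal demand
    (flux-limited capillary delivery), while the densely vascularized host
    clamps to the supply level over a short screening length.  Mirrors the
    simulator's ``supply_mode="distributed"``; this is the closure used for
    the terminal-size analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

from .params import ModelParameters

HOST_SUPPORT_STRENGTH = 20.0  # host delivery rate, units of lambda_upt_V


class UnboundedGrowthError(RuntimeError):
    """Terminal-size integration hit the radius cap while still growing."""


@dataclass
class RadialProfile:
    r: np.ndarray        # cell-centered radial mesh, mm
    n: np.ndarray        # substrate level
    R: float             # tumor radius, mm


def _radial_solve(r_faces: np.ndarray, c: np.ndarray, s: np.ndarray,
                  D: float, dim: int,
                  dirichlet: float | None = None) -> np.ndarray:
    """Finite-volume solve of (1/r^{d-1})(r^{d-1} D n')' - c n + s = 0.

    Cell-centered mesh; symmetry (zero flux) at r=0; outer boundary zero-flux,
    or Dirichlet value when given.
    """
    dr = r_faces[1] - r_faces[0]
    r_c = 0.5 * (r_faces[:-1] + r_faces[1:])
    M = len(r_c)
    area = r_faces ** (dim - 1)          # face "areas" (r^{d-1})
    vol = r_c ** (dim - 1) * dr          # cell measures

    lower = np.zeros(M)
    diag = c * vol
    upper = np.zeros(M)
    rhs = s * vol
    # interior faces j = 1..M-1 couple cells j-1, j
    w = D * area[1:-1] / dr
    diag[:-1] += w
    diag[1:] += w
    lower[:-1] = -w       # sub-diagonal entries for rows 1..M-1
    upper[1:] = -w        # super-diagonal entries for rows 0..M-2
    if dirichlet is not None:
        wb = D * area[-1] / (0.5 * dr)
        diag[-1] += wb
        rhs[-1] += wb * dirichlet
    ab = np.zeros((3, M))
    ab[0, 1:] = upper[1:]
    ab[1, :] = diag
    ab[2, :-1] = lower[:-1]
    return solve_banded((1, 1), ab, rhs)


class SphericalTumorModel:
    """Reduced spherically symmetric growth model.

    ``A`` overrides the apoptosis-to-proliferation ratio (lambda_A is set to
    ``A * lambda_M``); ``dim`` selects a sphere (3) or a disc (2), the latter
    matching planar full-model runs.
    """

    def __init__(self, params: ModelParameters | None = None,
                 supply: str = "distributed", A: float | None = None,
                 dim: int = 3, R_max_mm: float = 6.0,
                 mesh_mm: float = 0.01, closure: str = "host"):
        p = (params or ModelParameters())
        if A is not None:
            p = p.replace(lambda_A=A * p.lambda_M)
        p.validate()
        if supply not in ("core", "distributed"):
            raise ValueError(f"unknown supply mode {supply!r}")
        if closure not in ("host", "normoxic"):
            raise ValueError(f"unknown interface closure {closure!r}")
        self.params = p
        self.supply = supply
        self.closure = closure
        self.dim = dim
        self.R_max = R_max_mm
        self.dr = mesh_mm
        #: 0 -> sharp uniform-density ball (the classic reduction); > 0 ->
        #: a tanh density profile of this 10-90% width, matching the
        #: diffuse-interface equilibrium of the full model for oracle runs
        self.interface_width_mm = 0.0

    # ---------------------------------------------------------------- fields
    def _coverage(self, r_c: np.ndarray, dr: float, R: float) -> np.ndarray:
        """Tumor density kernel: sharp cell coverage, or a tanh interface."""
        w = self.interface_width_mm
        if w > 0.0:
            # tanh profile with 10-90% width w, half-density point at R
            return 0.5 * (1.0 - np.tanh(2.0 * np.arctanh(0.8) * (r_c - R) / w))
        return np.clip((R - (r_c - 0.5 * dr)) / dr, 0.0, 1.0)

    def substrate_profile(self, R: float, t_day: float | None = None) -> RadialProfile:
        """Quasi-steady radial substrate for tumor radius R."""
        if R <= 0:
            raise ValueError("tumor radius must be positive")
        p = self.params
        n_sup = p.supply_level(t_day if t_day is not None else p.t_end_day)
        D = p.D_n_mm2_day

        if self.supply == "distributed" and self.closure == "normoxic":
            # terminal-size theory closure: the host is fully supported right
            # up to the interface, so solve inside the tumor only with a
            # normoxic Dirichlet condition at r = R
            M = max(int(np.ceil(R / self.dr)), 8)
            r_faces = np.linspace(0.0, R, M + 1)
            r_c = 0.5 * (r_faces[:-1] + r_faces[1:])
            c = np.full(M, p.lambda_upt_V)
            s = np.full(M, p.lambda_upt_V * p.vascular_support * n_sup)
            n = _radial_solve(r_faces, c, s, D, self.dim, dirichlet=n_sup)
            return RadialProfile(r=r_c, n=np.clip(n, 0.0, 1.0), R=R)

        M = max(int(np.ceil(self.R_max / self.dr)), 8)
        r_faces = np.linspace(0.0, self.R_max, M + 1)
        r_c = 0.5 * (r_faces[:-1] + r_faces[1:])
        w = self._coverage(r_c, r_faces[1] - r_faces[0], R)

        rho_V = w
        rho_H = p.host_density * (1.0 - w)
        c = p.lambda_upt_V * rho_V + p.lambda_upt_H * rho_H
        if self.supply == "core":
            deliver = np.where(r_c <= p.root_radius_mm, p.nu, 0.0)
            c = c + deliver
            s = deliver * n_sup
        else:
            nu_host = HOST_SUPPORT_STRENGTH * p.lambda_upt_V * rho_H
            c = c + nu_host
            s = n_sup * (p.lambda_upt_V * p.vascular_support * rho_V
                         + p.lambda_upt_H * rho_H + nu_host)
        n = np.clip(_radial_solve(r_faces, c, s, D, self.dim), 0.0, 1.0)
        return RadialProfile(r=r_c, n=n, R=R)

    # ------------------------------------------------------------------ rate
    def radius_rate(self, R: float, t_day: float | None = None,
                    profile: RadialProfile | None = None) -> float:
        """dR/dt from the integrated mass balance, mm/day."""
        p = self.params
        R = max(R, 0.25 * p.seed_radius_mm)   # growth floor near R=0
        prof = profile or self.substrate_profile(R, t_day)
        r, n = prof.r, prof.n
        dr = r[1] - r[0]
        w = self._coverage(r, dr, R)
        g = (p.lambda_M * n * (n > p.n_N)
             - p.lambda_A
             - p.lambda_N * (n < p.n_N))
        integral = float(np.sum(g * w * r ** (self.dim - 1)) * dr)
        return integral / R ** (self.dim - 1)

    # ------------------------------------------------------------------ runs
    def run(self, t_end_day: float | None = None,
            R0_mm: float | None = None, max_step: float = 0.25):
        """Integrate R(t) from seeding; returns a SphericalResults object."""
        p = self.params
        t_end = p.t_end_day if t_end_day is None else t_end_day
        R0 = p.seed_radius_mm if R0_mm is None else R0_mm

        sol = solve_ivp(lambda t, y: [self.radius_rate(y[0], t)],
                        (p.t_seed_day, t_end), [R0], method="RK45",
                        rtol=1e-6, atol=1e-9, max_step=max_step,
                        dense_output=True)
        if not sol.success:
            raise RuntimeError(f"radius integration failed: {sol.message}")
        return SphericalResults(model=self, t=sol.t, R=sol.y[0], sol=sol)

    def terminal_diameter(self, tol_mm_day: float = 1e-4,
                          t_max_day: float = 4000.0,
                          R0_mm: float | None = None) -> float:
        """Integrate until |dR/dt| < tol; returns 2 R_terminal in mm.

        Raises :class:`UnboundedGrowthError` if the radius reaches the mesh
        extent or is still changing at ``t_max_day``.
        """
        p = self.params
        R0 = p.seed_radius_mm if R0_mm is None else R0_mm

        # no-growth case: death dominates already at the seed radius
        if self.radius_rate(R0, p.t_seed_day + 1e3) < 0 and \
           self.radius_rate(R0, p.t_seed_day) < 0:
            return 2.0 * R0

        def stationary(t, y):
            return abs(self.radius_rate(y[0], t)) - tol_mm_day
        stationary.terminal = True
        stationary.direction = -1

        def hit_cap(t, y):
            return y[0] - 0.98 * self.R_max
        hit_cap.terminal = True

        sol = solve_ivp(lambda t, y: [self.radius_rate(y[0], t)],
                        (p.t_seed_day, t_max_day), [R0], method="RK45",
                        rtol=1e-6, atol=1e-9, max_step=5.0,
                        events=[stationary, hit_cap])
        if not sol.success:
            raise RuntimeError(f"terminal integration failed: {sol.message}")
        if len(sol.t_events[1]):
            raise UnboundedGrowthError(
                f"radius reached the mesh extent {self.R_max} mm while growing")
        if not len(sol.t_events[0]):
            raise UnboundedGrowthError(
                f"|dR/dt| still above {tol_mm_day} mm/day at t={t_max_day} day")
        return 2.0 * float(sol.y_events[0][0][0])


@dataclass
class SphericalResults:
    model: SphericalTumorModel
    t: np.ndarray
    R: np.ndarray
    sol: object = None

    @property
    def diameter(self) -> np.ndarray:
        return 2.0 * self.R

    def radius_at(self, t_day) -> np.ndarray:
        return self.sol.sol(np.asarray(t_day))[0]

    def summary(self) -> str:
        m = self.model
        return "\n".join([
            "Reduced spherical growth model",
            "==============================",
            f"supply={m.supply}  dim={m.dim}  A={m.params.A_ratio:.3f}",
            f"R({self.t[0]:.1f} d) = {self.R[0]:.3f} mm -> "
            f"R({self.t[-1]:.1f} d) = {self.R[-1]:.3f} mm",
            f"final diameter: {self.diameter[-1]:.2f} mm",
        ])


def terminal_diameter(A: float, params: ModelParameters | None = None,
                      supply: str = "distributed", closure: str = "normoxic",
                      **kw) -> float:
    """Terminal tumor diameter (mm) at apoptosis/proliferation ratio A.

    Uses the distributed-supply, normoxic-interface closure of the
    terminal-size theory by default.
    """
    return SphericalTumorModel(params, supply=supply, A=A,
                               closure=closure).terminal_diameter(**kw)
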