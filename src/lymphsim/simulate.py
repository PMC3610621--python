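"""The lymph-node lymphoma growth simulator.

`LymphomaGrowthModel` couples, per time step: the quasi-steady substrate and
VEGF solves, one angiogenesis step, the cell-kinetic source terms, the
pressure solve, the generalized Darcy velocities, and the conservative
volume-fraction update.  `simulate()` returns a `GrowthResults` object
carrying the growth trajectory (equivalent diameter, compartment volumes,
hypoxic fraction, vessel counts), the final tissue state, and diagnostics.

The simulation clock runs in days from nodal seeding (Day 9, the
bioluminescence-detected arrival of lymphoma cells in the inguinal node) to
Day 21, when the tumors were excised.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import angiogenesis as ang
from . import kinetics, mechanics, transport
from .grids import Grid, NodeGeometry, TissueState, equivalent_diameter, make_grid, make_node
from .params import ModelParameters

TRAJECTORY_COLUMNS = ["t_day", "diameter_mm", "viable_volume", "dead_volume",
                      "hypoxic_fraction", "vessel_voxels", "mean_n"]


@dataclass
class GrowthResults:
    """Results of one simulated growth history."""

    params: ModelParameters
    trajectory: pd.DataFrame
    final_state: TissueState
    network: ang.VesselNetwork | None
    seed: int | None
    clipped_mass_total: float
    max_mass_residual: float
    stage_seconds: dict = field(default_factory=dict)

    @property
    def final_diameter_mm(self) -> float:
        return float(self.trajectory["diameter_mm"].iloc[-1])

    @property
    def mean_substrate(self) -> float:
        """Time-averaged tumor-mean substrate <n> over the recorded history."""
        m = self.trajectory["mean_n"].dropna()
        return float(m.mean()) if len(m) else float("nan")

    def summary(self) -> str:
        tr = self.trajectory
        lines = [
            "Lymphoma growth simulation",
            "==========================",
            f"grid: {self.final_state.grid.n_cells}^{self.final_state.grid.dim}"
            f" at h={self.final_state.grid.h * 1e3:.0f} um, "
            f"days {tr['t_day'].iloc[0]:.1f} -> {tr['t_day'].iloc[-1]:.1f}",
            f"lambda_M={self.params.lambda_M:.3f}/d  "
            f"lambda_A={self.params.lambda_A:.3f}/d  "
            f"A={self.params.A_ratio:.3f}  lambda_N={self.params.lambda_N:.2f}/d",
            f"final equivalent diameter: {self.final_diameter_mm:.2f} mm",
            f"final viable volume: {tr['viable_volume'].iloc[-1]:.2f} "
            f"mm^{self.final_state.grid.dim}",
            f"tumor mean substrate <n>: {self.mean_substrate:.3f}",
            f"final hypoxic fraction: {tr['hypoxic_fraction'].iloc[-1]:.3f}",
            f"vessel voxels: {int(tr['vessel_voxels'].iloc[-1])}",
        ]
        return "\n".join(lines)


class SimulationStageError(RuntimeError):
    def __init__(self, stage, t_day, cause):
        super().__init__(f"stage '{stage}' failed at t={t_day:.3f} day: {cause}")
        self.stage = stage
        self.t_day = t_day


class LymphomaGrowthModel:
    """Mixture-model tumor growth in a spherical lymph node.

    Parameters
    ----------
    params
        Model parameters (baselines are the calibrated murine setup).
    supply_mode
        ``"vessels"``: substrate delivered by the discrete vessel network
        with sprouting angiogenesis (the full model).
        ``"distributed"``: angiogenesis-free volumetric supply — the tumor
        is fed at the fraction of its demand the vasculature can support
        (``params.vascular_support``) and the host is fully supported.
        ``"core"``: delivery only from the pre-existing central vascular
        ball (no stems, no angiogenesis); the spherically symmetric
        configuration used for oracle comparisons with the radial model.
    """

    def __init__(self, params: ModelParameters | None = None,
                 supply_mode: str = "vessels"):
        self.params = params or ModelParameters()
        self.params.validate()
        if supply_mode not in ("vessels", "distributed", "core"):
            raise ValueError(f"unknown supply_mode {supply_mode!r}")
        self.supply_mode = supply_mode
        self.grid = make_grid(self.params.extent_mm, self.params.spacing_um,
                              self.params.dim)
        self.node = make_node(self.grid, self.params.node_radius_mm,
                              self.params.mobility_reduction)

    @classmethod
    def from_config(cls, path, **kw) -> "LymphomaGrowthModel":
        from .params import load_config
        return cls(load_config(path), **kw)

    # ------------------------------------------------------------------ setup
    def initial_state(self) -> TissueState:
        """Tumor seed at the node center, host tissue elsewhere.

        With adhesion active the seed carries the equilibrium tanh interface
        profile (a sharp ball would spend the first day relaxing to it).
        """
        p = self.params
        state = TissueState.empty(self.grid, t_day=p.t_seed_day)
        r = self.grid.radius_from()
        if p.gamma > 0:
            w = mechanics.equilibrium_interface_width(p, self.grid.h)
            k = 2.0 * np.arctanh(0.8) / w
            seed = 0.5 * (1.0 - np.tanh(k * (r - p.seed_radius_mm)))
            seed[seed < 1e-6] = 0.0
        else:
            seed = (r <= p.seed_radius_mm).astype(float)
        state.rho_V = seed
        state.rho_H = p.host_density * (1.0 - seed)
        state.f_ecm = np.ones(self.grid.shape)
        return state

    def _distributed_supply(self, state: TissueState, n_sup: float):
        """Volumetric delivery (source, extra uptake) of the angiogenic
        steady state: tumor supported at the vascular support fraction,
        host clamped to the supply level over a short screening length."""
        from .spherical import HOST_SUPPORT_STRENGTH

        p = self.params
        nu_host = HOST_SUPPORT_STRENGTH * p.lambda_upt_V * state.rho_H
        source = n_sup * (p.lambda_upt_V * p.vascular_support * state.rho_V
                          + p.lambda_upt_H * state.rho_H + nu_host)
        return source, nu_host

    # -------------------------------------------------------------- stepping
    def _timed(self, timers, state, stage, fn):
        t0 = _time.perf_counter()
        try:
            out = fn()
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise SimulationStageError(stage, state.t_day, e) from e
        if timers is not None:
            timers[stage] = timers.get(stage, 0.0) + _time.perf_counter() - t0
        return out

    def refresh_fields(self, state: TissueState,
                       net: ang.VesselNetwork | None,
                       timers: dict | None = None) -> None:
        """Quasi-steady substrate and VEGF solves for the current tissue."""
        p = self.params
        n_sup = p.supply_level(state.t_day)
        if self.supply_mode == "vessels":
            delta = ang.rasterize(net, self.grid,
                                  perfused_only=p.perfusion_gated)
            state.n, _ = self._timed(timers, state, "substrate",
                                     lambda: transport.solve_substrate(
                self.grid, delta, state.rho_V, state.rho_H, p, n_sup=n_sup))
            hyp = transport.hypoxic_mask(state.n, state.rho_V, p.n_N)
            state.n_V, _ = self._timed(timers, state, "vegf",
                                       lambda: transport.solve_vegf(
                self.grid, delta, hyp, state.rho_V, p))
        elif self.supply_mode == "core":
            # a resolved volumetric source region: undo the thin-vessel
            # Dirac-delta scaling so the delivery rate is nu per unit volume
            ball = (self.grid.radius_from() <= p.root_radius_mm).astype(float)
            delta = ball / transport.delta_scale(self.grid, p)
            state.n, _ = self._timed(timers, state, "substrate",
                                     lambda: transport.solve_substrate(
                self.grid, delta, state.rho_V, state.rho_H, p, n_sup=n_sup))
            state.n_V = np.zeros(self.grid.shape)
        else:
            delta = np.zeros(self.grid.shape)
            source, uptake = self._distributed_supply(state, n_sup)
            state.n, _ = self._timed(timers, state, "substrate",
                                     lambda: transport.solve_substrate(
                self.grid, delta, state.rho_V, state.rho_H, p,
                n_sup=n_sup, extra_source=source, extra_uptake=uptake))
            state.n_V = np.zeros(self.grid.shape)

    def step(self, state: TissueState, net: ang.VesselNetwork | None,
             rng: np.random.Generator, dt: float,
             timers: dict | None = None) -> mechanics.AdvanceDiagnostics:
        """Advance the coupled system by one time step of length dt."""
        p = self.params

        def timed(stage, fn):
            return self._timed(timers, state, stage, fn)

        self.refresh_fields(state, net, timers)
        if self.supply_mode == "vessels":
            timed("angiogenesis",
                  lambda: ang.sprout_step(net, state.n_V, p, rng, dt))

        src = timed("sources", lambda: kinetics.source_terms(
            state.rho_V, state.rho_D, state.rho_H, state.n, p))
        mobility = self.node.mobility_field()
        state.p, _ = timed("pressure", lambda: mechanics.solve_pressure(
            src.total, mobility, self.grid,
            rtol=p.solver_rtol, maxiter=p.solver_maxiter))
        vel = timed("velocity", lambda: mechanics.cell_velocity(
            state.p, state.n, state.f_ecm, state.rho_V, state.rho_D,
            state.rho_H, p, mobility, self.grid, include_adhesion=False))

        # advect under the CFL bound: substep with frozen sources/velocities
        speed = vel.max_speed_sum()
        n_sub = max(1, int(np.ceil(dt * speed / (0.9 * self.grid.h))))
        diag = mechanics.AdvanceDiagnostics()
        for _ in range(n_sub):
            d = timed("advance", lambda: mechanics.advance_fractions(
                state, vel, src, dt / n_sub))
            diag.clipped_mass += d.clipped_mass
            diag.mass_residual = max(diag.mass_residual, d.mass_residual)
        # adhesion (operator-split Cahn–Hilliard compaction of the interface)
        diag.clipped_mass += timed("adhesion", lambda:
                                   mechanics.apply_adhesion_relaxation(
                                       state, p, dt))
        return diag

    def _record(self, state: TissueState, net, rows: list) -> None:
        p = self.params
        vol = self.grid.cell_volume
        try:
            hyp = transport.hypoxic_fraction_of_tumor(state, p)
        except transport.EmptyTumorError:
            hyp = np.nan
        w = np.where(state.rho_V > 1e-3, state.rho_V, 0.0)
        mean_n = float((state.n * w).sum() / w.sum()) if w.sum() > 0 else np.nan
        rows.append({
            "t_day": state.t_day,
            "diameter_mm": equivalent_diameter(state),
            "viable_volume": float(state.rho_V.sum()) * vol,
            "dead_volume": float(state.rho_D.sum()) * vol,
            "hypoxic_fraction": hyp,
            "vessel_voxels": net.n_voxels if net is not None else 0,
            "mean_n": mean_n,
        })

    def simulate(self, seed: int | None = 0,
                 t_end_day: float | None = None) -> GrowthResults:
        """Run from Day-9 seeding to ``t_end_day`` (default Day 21)."""
        p = self.params
        t_end = p.t_end_day if t_end_day is None else t_end_day
        rng = np.random.default_rng(seed)
        state = self.initial_state()
        net = None
        if self.supply_mode == "vessels":
            net = ang.initialize_vasculature(self.node, self.grid, p)

        rows: list = []
        timers: dict = {}
        clipped = 0.0
        max_res = 0.0
        self.refresh_fields(state, net, timers)
        self._record(state, net, rows)
        next_out = state.t_day + p.output_interval_day
        while state.t_day < t_end - 1e-12:
            dt = min(p.dt_max_day, t_end - state.t_day)
            diag = self.step(state, net, rng, dt, timers)
            clipped += diag.clipped_mass
            max_res = max(max_res, diag.mass_residual)
            if state.t_day >= next_out - 1e-12 or state.t_day >= t_end - 1e-12:
                self._record(state, net, rows)
                next_out += p.output_interval_day

        traj = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
        return GrowthResults(params=p, trajectory=traj, final_state=state,
                             network=net, seed=seed,
                             clipped_mass_total=clipped,
                             max_mass_residual=max_res,
                             stage_seconds=timers)
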