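"""Quasi-steady reaction–diffusion of the substrate n and VEGF n_V.

Both species are non-dimensionalised by their maximum intravascular level, so
solutions lie in [0, 1]; they equilibrate orders of magnitude faster than the
tissue evolves (substrate relaxation ~ L^2/D ~ seconds against a mitosis time
of ~1 day), hence each is re-solved to steady state every time step.

The vasculature enters through the voxelised indicator delta_vessel.  A voxel
crossed by a vessel delivers at rate ``nu * (L/h)^2 * (n_sup - n)``: the
(L/h)^2 factor realises the line-source Dirac delta on the grid (one factor
1/h per transverse dimension, measured in units of the diffusion length L),
and the saturating ``(n_sup - n)`` form guarantees levels never exceed the
intravascular supply.
"""

from __future__ import annotations

import numpy as np

from .elliptic import solve_screened
from .grids import Grid, TissueState
from .params import ModelParameters


class EmptyTumorError(ValueError):
    """Raised when a tumor-conditional statistic is requested of an empty tumor."""


def delta_scale(grid: Grid, params: ModelParameters) -> float:
    """Voxel realisation factor of the vessel line-source Dirac delta."""
    return (params.L_hypoxia_mm / grid.h) ** 2


def solve_substrate(grid: Grid, delta_vessel: np.ndarray, rho_V: np.ndarray,
                    rho_H: np.ndarray, params: ModelParameters,
                    n_sup: float = 1.0,
                    extra_source: np.ndarray | None = None,
                    extra_uptake: np.ndarray | None = None):
    """Steady substrate field n in [0, 1].

    Solves ``0 = D_n lap n + nu_eff delta (n_sup - n)
    - (lambda_upt_V rho_V + lambda_upt_H rho_H) n - lambda_dec_n n``
    plus optional volumetric delivery terms used by the distributed-supply
    (angiogenesis-free) configurations.  Returns ``(n, residuals)``.
    """
    nu_eff = params.nu * delta_scale(grid, params)
    deliver = nu_eff * np.asarray(delta_vessel, dtype=float)
    c = deliver + params.lambda_upt_V * rho_V + params.lambda_upt_H * rho_H \
        + params.lambda_dec_n
    s = deliver * n_sup
    if extra_uptake is not None:
        c = c + extra_uptake
    if extra_source is not None:
        s = s + extra_source
    n, res = solve_screened(params.D_n_mm2_day, c, s, grid.h,
                            rtol=params.solver_rtol,
                            maxiter=params.solver_maxiter)
    return np.clip(n, 0.0, 1.0), res


def hypoxic_mask(n: np.ndarray, rho_V: np.ndarray, n_N: float,
                 rho_floor: float = 1e-3) -> np.ndarray:
    """Voxels holding viable tumor below the quiescence threshold."""
    return (n < n_N) & (rho_V > rho_floor)


def solve_vegf(grid: Grid, delta_vessel: np.ndarray, hyp_mask: np.ndarray,
               rho_V: np.ndarray, params: ModelParameters):
    """Steady VEGF field n_V in [0, 1].

    Hypoxic viable tumor secretes at rate ``lambda_sec_V rho_V (1 - n_V)``
    (saturating toward the normalisation level); vessels take VEGF up through
    the same voxelised delta with their own rate constant.
    """
    secrete = params.lambda_sec_V * rho_V * hyp_mask.astype(float)
    uptake = params.vessel_uptake_V_nd * params.lambda_sec_V \
        * delta_scale(grid, params) * np.asarray(delta_vessel, dtype=float)
    c = secrete + uptake + params.lambda_dec_nV
    if not np.any(c > 0):
        return np.zeros(grid.shape), [0.0]
    n_V, res = solve_screened(params.D_nV_mm2_day, c, secrete, grid.h,
                              rtol=params.solver_rtol,
                              maxiter=params.solver_maxiter)
    return np.clip(n_V, 0.0, 1.0), res


def hypoxic_fraction_of_tumor(state: TissueState, params: ModelParameters,
                              rho_floor: float = 1e-3) -> float:
    """measure{rho_V > 0 and n < n_N} / measure{rho_V > 0}.

    ``rho_floor`` discards advection-smeared trace fractions.  Raises
    :class:`EmptyTumorError` for an empty tumor (distinct from returning 0).
    """
    tumor = state.rho_V > rho_floor
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise EmptyTumorError("hypoxic fraction undefined: no viable tumor")
    return float((tumor & (state.n < params.n_N)).sum()) / n_tumor
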