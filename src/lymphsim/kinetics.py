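"""Source terms of the species conservation laws.

Viable tumor proliferates in proportion to the substrate level above the
quiescence threshold n_N, and loses mass to apoptosis (always on) and to
necrosis (below n_N); both death routes transfer volume into the dead
species, which degrades at rate lambda_D as lysed material releases its
water.  Host tissue never proliferates; its death rates default to zero
(homeostatic resident tissue) but are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters
from .transport import EmptyTumorError


def heaviside(x: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Switch function with H(0) = 0; optional smoothing of width eps."""
    if eps > 0.0:
        return np.clip(0.5 * (1.0 + x / eps), 0.0, 1.0) * (x != -eps)
    return (x > 0.0).astype(float)


@dataclass
class SourceTerms:
    S_V: np.ndarray
    S_D: np.ndarray
    S_H: np.ndarray
    proliferating: np.ndarray   # mask: n > n_N and viable tumor present
    quiescent: np.ndarray       # mask: n <= n_N and viable tumor present

    @property
    def total(self) -> np.ndarray:
        return self.S_V + self.S_D + self.S_H


def source_terms(rho_V: np.ndarray, rho_D: np.ndarray, rho_H: np.ndarray,
                 n: np.ndarray, params: ModelParameters,
                 eps_switch: float = 0.0) -> SourceTerms:
    """Evaluate S_V, S_D, S_H (day^-1 volume-fraction rates).

    Death terms appear with opposite signs in S_V (or S_H) and S_D: they
    transfer mass, only mitosis creates it and only degradation removes it.
    """
    for name, r in (("rho_V", rho_V), ("rho_D", rho_D), ("rho_H", rho_H)):
        if np.any(r < 0):
            raise ValueError(f"negative volume fraction in {name}")
    H_up = heaviside(n - params.n_N, eps_switch)
    H_dn = heaviside(params.n_N - n, eps_switch)

    # the proliferation floor keeps advection-smeared trace fractions from
    # bootstrapping a spurious growth front; it is a numerical regularisation
    # standing in for the interface-compacting role of cell adhesion
    compact = heaviside(rho_V - params.rho_prolif_floor)
    mitosis = params.lambda_M * n * H_up * rho_V * compact
    apop_V = params.lambda_A * rho_V
    necro_V = params.lambda_N * H_dn * rho_V
    apop_H = params.lambda_A_H * rho_H
    necro_H = params.lambda_N_H * H_dn * rho_H

    S_V = mitosis - apop_V - necro_V
    S_H = -apop_H - necro_H
    S_D = apop_V + necro_V + apop_H + necro_H - params.lambda_D * rho_D

    viable = rho_V > 0
    return SourceTerms(S_V=S_V, S_D=S_D, S_H=S_H,
                       proliferating=(H_up > 0) & viable,
                       quiescent=(H_up == 0) & viable)


def average_apoptosis_rate(rho_V: np.ndarray, params: ModelParameters,
                           lambda_A_field: np.ndarray | None = None,
                           rho_floor: float = 1e-3) -> float:
    """Tumor-volume-weighted mean apoptotic loss rate per unit viable fraction.

    With a uniform rate this is simply lambda_A; a per-voxel rate field (for
    species-specific phenotypes) is averaged with rho_V weights.
    """
    w = np.where(rho_V > rho_floor, rho_V, 0.0)
    total = float(w.sum())
    if total == 0.0:
        raise EmptyTumorError("average apoptosis rate undefined: no viable tumor")
    lam = params.lambda_A if lambda_A_field is None else lambda_A_field
    return float(np.sum(lam * w)) / total
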