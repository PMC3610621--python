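"""Virtual histology: the five-section scheme applied to simulation output.

Five section planes (S1–S5) are placed at equal spacing spanning the tumor
extent along one axis — S1 and S5 at the tumor top and bottom, S3 central —
and per-plane statistics are computed on the tumor region, split into a core
and a periphery (the shell within 200 µm of the tumor boundary).  The
proliferation/apoptosis "stain" proxies invert the IHC calibration formulas
(rate x detectability window), so virtual sections and calibration are
mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import APOP_WINDOW_H, PROLIF_CYCLE_H
from .grids import TissueState
from .params import ModelParameters

SECTION_NAMES = ("S1", "S2", "S3", "S4", "S5")
METRICS = ("viable_fraction", "hypoxic_fraction", "vessel_density",
           "proliferating_fraction", "apoptotic_fraction")


def tumor_mask(state: TissueState, threshold: float = 0.5) -> np.ndarray:
    return state.tumor_fraction >= threshold


def periphery_mask(state: TissueState, width_mm: float = 0.2,
                   threshold: float = 0.5) -> np.ndarray:
    """Tumor voxels within ``width_mm`` of the tumor boundary (0.5 level set)."""
    mask = tumor_mask(state, threshold)
    if not mask.any() or width_mm <= 0:
        return np.zeros_like(mask)
    dist = ndimage.distance_transform_edt(mask, sampling=state.grid.h)
    return mask & (dist <= width_mm)


@dataclass
class SectionStats:
    """Per-section, per-region statistics in long form."""

    table: pd.DataFrame   # columns: section, region, metric, value
    axis: int
    plane_indices: tuple

    def value(self, section: str, metric: str, region: str = "all") -> float:
        t = self.table
        row = t[(t["section"] == section) & (t["metric"] == metric)
                & (t["region"] == region)]
        if row.empty:
            raise KeyError((section, metric, region))
        return float(row["value"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def extract_sections(state: TissueState, params: ModelParameters,
                     axis: int = 0, n_sections: int = 5,
                     delta_vessel: np.ndarray | None = None,
                     periphery_width_mm: float = 0.2) -> SectionStats:
    """Compute the five-section statistics of a simulated tumor."""
    mask = tumor_mask(state)
    if not mask.any():
        raise ValueError("empty tumor: no voxels at the 0.5 tumor level set")
    present = np.any(mask, axis=tuple(a for a in range(state.grid.dim)
                                      if a != axis))
    idx = np.nonzero(present)[0]
    lo, hi = int(idx[0]), int(idx[-1])
    if hi - lo + 1 < n_sections:
        raise ValueError(
            f"tumor spans {hi - lo + 1} voxels along axis {axis}; "
            f"needs at least {n_sections} for sectioning")
    planes = np.unique(np.round(np.linspace(lo, hi, n_sections)).astype(int))
    if len(planes) < n_sections:   # defensive; spacing guaranteed above
        planes = np.linspace(lo, hi, n_sections).astype(int)

    peri = periphery_mask(state, periphery_width_mm)
    core = mask & ~peri
    if delta_vessel is None:
        delta_vessel = np.zeros(state.grid.shape)

    tot = state.tumor_fraction
    with np.errstate(invalid="ignore", divide="ignore"):
        viable = np.where(tot > 0, state.rho_V / np.maximum(tot, 1e-12), 0.0)
    hyp = (state.n < params.n_N).astype(float)
    prolif = np.clip(params.lambda_M * state.n * (state.n > params.n_N)
                     * PROLIF_CYCLE_H / 24.0, 0.0, 1.0)
    apop = np.clip(params.lambda_A * APOP_WINDOW_H / 24.0, 0.0, 1.0) \
        * np.ones(state.grid.shape)
    values = {"viable_fraction": viable, "hypoxic_fraction": hyp,
              "vessel_density": np.asarray(delta_vessel, dtype=float),
              "proliferating_fraction": prolif, "apoptotic_fraction": apop}

    rows = []
    for name, plane in zip(SECTION_NAMES[:n_sections], planes):
        sl = [slice(None)] * state.grid.dim
        sl[axis] = int(plane)
        sl = tuple(sl)
        regions = {"all": mask[sl], "core": core[sl], "periphery": peri[sl]}
        for region, rmask in regions.items():
            for metric, fieldv in values.items():
                v = float(fieldv[sl][rmask].mean()) if rmask.any() else np.nan
                rows.append({"section": name, "region": region,
                             "metric": metric, "value": v})
    return SectionStats(table=pd.DataFrame(rows), axis=axis,
                        plane_indices=tuple(int(p) for p in planes))


def central_plane_viable_fraction(state: TissueState, axis: int = 0,
                                  threshold: float = 0.5) -> float:
    """Viable fraction rho_V/(rho_V+rho_D) on the central cross-section.

    The plane is the domain's central plane perpendicular to ``axis``,
    restricted to voxels where the total tumor fraction meets ``threshold``.
    """
    sl = [slice(None)] * state.grid.dim
    sl[axis] = state.grid.n_cells // 2
    sl = tuple(sl)
    tot = state.tumor_fraction[sl]
    m = tot >= threshold
    if not m.any():
        raise ValueError("no tumor on the central plane")
    return float((state.rho_V[sl][m] / tot[m]).mean())
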