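"""Cartesian grid, tissue state fields, and the spherical lymph-node geometry.

Coordinates are cell-centered with 0-based indices; the physical origin sits
at the corner of the box, so cell ``i`` along an axis is centered at
``(i + 0.5) * h``.  The baseline domain is a 6.4 mm isotropic box at 100 µm
spacing (64 cells per axis in 3D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid:
    extent_mm: float
    spacing_mm: float
    dim: int

    def __post_init__(self):
        if self.dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.dim}")
        n = self.extent_mm / self.spacing_mm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"extent {self.extent_mm} mm is not divisible by spacing "
                f"{self.spacing_mm} mm")

    @property
    def n_cells(self) -> int:
        return int(round(self.extent_mm / self.spacing_mm))

    @property
    def shape(self) -> tuple:
        return (self.n_cells,) * self.dim

    @property
    def h(self) -> float:
        return self.spacing_mm

    @property
    def cell_volume(self) -> float:
        """Voxel measure: mm^3 in 3D, mm^2 in 2D."""
        return self.spacing_mm**self.dim

    def axis_centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.spacing_mm

    def center(self) -> np.ndarray:
        return np.full(self.dim, 0.5 * self.extent_mm)

    def radius_from(self, point=None) -> np.ndarray:
        """Distance of every cell center from ``point`` (default: box center)."""
        if point is None:
            point = self.center()
        ax = self.axis_centers()
        grids = np.meshgrid(*([ax] * self.dim), indexing="ij")
        return np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, point)))

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)


def make_grid(extent_mm: float, spacing_um: float, dim: int = 3) -> Grid:
    """Build the simulation grid; extent must be divisible by the spacing."""
    return Grid(extent_mm=extent_mm, spacing_mm=spacing_um * 1e-3, dim=dim)


@dataclass(frozen=True)
class NodeGeometry:
    """Spherical lymph node: mobility is reduced beyond the node radius.

    The reduced mobility outside the sphere delineates the node boundary and
    mimics the resistance of surrounding tissue; ``mobility_reduction=1``
    removes the confinement.
    """

    grid: Grid
    radius_mm: float
    mobility_reduction: float = 10.0
    center_mm: tuple = None

    def __post_init__(self):
        if self.radius_mm >= 0.5 * self.grid.extent_mm:
            raise ValueError("node sphere does not fit inside the domain")
        if self.mobility_reduction < 1.0:
            raise ValueError("mobility_reduction must be >= 1")
        if self.center_mm is None:
            object.__setattr__(self, "center_mm",
                               tuple(self.grid.center()))

    def inside(self) -> np.ndarray:
        return self.grid.radius_from(np.asarray(self.center_mm)) <= self.radius_mm

    def mobility_field(self, k: float = 1.0) -> np.ndarray:
        """k inside the node, k/mobility_reduction outside; strictly positive."""
        m = np.where(self.inside(), k, k / self.mobility_reduction)
        return m.astype(float)


def make_node(grid: Grid, radius_mm: float,
              mobility_reduction: float = 10.0) -> NodeGeometry:
    return NodeGeometry(grid=grid, radius_mm=radius_mm,
                        mobility_reduction=mobility_reduction)


@dataclass
class TissueState:
    """Volume fractions, ECM, substrate, VEGF and pressure on one grid.

    Invariants (enforced by the integrator, checked in tests): each fraction
    lies in [0, 1]; the summed solid fraction rho_V + rho_D + rho_H <= 1
    (the remainder is freely moving interstitial water); n, n_V in [0, 1].
    """

    grid: Grid
    rho_V: np.ndarray
    rho_D: np.ndarray
    rho_H: np.ndarray
    f_ecm: np.ndarray
    n: np.ndarray
    n_V: np.ndarray
    p: np.ndarray
    t_day: float = 0.0

    @classmethod
    def empty(cls, grid: Grid, t_day: float = 0.0) -> "TissueState":
        z = grid.zeros
        return cls(grid=grid, rho_V=z(), rho_D=z(), rho_H=z(),
                   f_ecm=np.ones(grid.shape), n=z(), n_V=z(), p=z(),
                   t_day=t_day)

    @property
    def tumor_fraction(self) -> np.ndarray:
        return self.rho_V + self.rho_D

    def field_dict(self) -> dict:
        return {"rho_V": self.rho_V, "rho_D": self.rho_D, "rho_H": self.rho_H,
                "f_ecm": self.f_ecm, "n": self.n, "n_V": self.n_V, "p": self.p}

    def copy(self) -> "TissueState":
        return TissueState(grid=self.grid,
                           **{k: v.copy() for k, v in self.field_dict().items()},
                           t_day=self.t_day)


def ball_diameter_from_measure(measure: float, dim: int) -> float:
    """Diameter of the ball (disc in 2D) with the given volume (area)."""
    if measure <= 0:
        return 0.0
    if dim == 2:
        return 2.0 * np.sqrt(measure / np.pi)
    return 2.0 * (measure * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def equivalent_diameter(state: TissueState, threshold: float = 0.5) -> float:
    """Equivalent spherical (circular) diameter of the tumor, in mm.

    The tumor is the region where the total tumor fraction rho_V + rho_D
    meets the threshold (0.5 level set by default); the diameter is that of
    the ball of equal measure.  Returns 0 for an empty region.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mask = state.tumor_fraction >= threshold
    measure = float(mask.sum()) * state.grid.cell_volume
    return ball_diameter_from_measure(measure, state.grid.dim)
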