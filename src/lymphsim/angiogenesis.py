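"""Sprouting angiogenesis on the simulation lattice.

The vessel network is discrete: voxel-resolution segments grown from the
node's pre-existing vasculature (a central ball at the intersection of the
large nodal vessels, plus radial stems).  Hypoxic tumor tissue secretes VEGF;
perfused vessel voxels above a VEGF threshold initiate sprout tips, tips
take biased random-walk steps up the VEGF gradient (softmax weights, no
immediate backtracking), branch with probability increasing in local VEGF,
and anastomose — retire, closing a loop that is marked perfused — when they
step into a voxel already occupied by another segment.

Vessels are permanent (no regression) and by default every vessel voxel
delivers substrate; gating delivery on perfused loops is a configuration
flag.  Every segment voxel stores its parent, so the network is a forest
rooted in the pre-existing vasculature by construction and connectivity can
be audited by traversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Grid, NodeGeometry
from .params import ModelParameters


@dataclass
class Tip:
    pos: tuple
    prev: tuple | None = None
    stalled: bool = False


@dataclass
class VesselNetwork:
    grid: Grid
    parents: dict = field(default_factory=dict)   # voxel -> parent voxel (roots -> None)
    perfused: dict = field(default_factory=dict)  # voxel -> bool
    roots: list = field(default_factory=list)
    tips: list = field(default_factory=list)
    stalled_moves: int = 0
    max_active_tips: int = 256   # numerical guard on the tip population

    # ------------------------------------------------------------------ info
    @property
    def n_voxels(self) -> int:
        return len(self.parents)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def is_connected(self) -> bool:
        """Every voxel must reach a root through parent links."""
        for vox in self.parents:
            seen = set()
            cur = vox
            while cur is not None:
                if cur in seen:
                    return False
                seen.add(cur)
                cur = self.parents.get(cur, "missing")
                if cur == "missing":
                    return False
        return True

    def path_to_root(self, vox: tuple) -> list:
        path = []
        cur = vox
        while cur is not None:
            path.append(cur)
            cur = self.parents[cur]
        return path

    # ------------------------------------------------------------- mutation
    def add_voxel(self, vox: tuple, parent: tuple | None,
                  perfused: bool = False) -> None:
        if vox not in self.parents:
            self.parents[vox] = parent
            self.perfused[vox] = perfused

    def mark_perfused_path(self, vox: tuple) -> None:
        for v in self.path_to_root(vox):
            self.perfused[v] = True


def _ball_voxels(grid: Grid, center_mm: np.ndarray, radius_mm: float):
    r = grid.radius_from(center_mm)
    return [tuple(int(i) for i in idx) for idx in np.argwhere(r <= radius_mm)]


def _stem_directions(dim: int) -> list:
    """Three radial stem directions (visual parity with the nodal hilum)."""
    angles = [np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3]
    if dim == 2:
        return [np.array([np.cos(a), np.sin(a)]) for a in angles]
    return [np.array([np.cos(a), np.sin(a), 0.0]) for a in angles]


def initialize_vasculature(node: NodeGeometry, grid: Grid,
                           params: ModelParameters) -> VesselNetwork:
    """Pre-existing vasculature: central perfused ball plus three stems."""
    net = VesselNetwork(grid=grid)
    center = np.asarray(node.center_mm)
    ball = _ball_voxels(grid, center, params.root_radius_mm)
    for vox in sorted(ball):
        net.add_voxel(vox, None, perfused=True)
        net.roots.append(vox)

    h = grid.h
    for direction in _stem_directions(grid.dim):
        prev = None
        for step in np.arange(0.0, node.radius_mm, 0.5 * h):
            pt = center + direction * step
            vox = tuple(int(np.clip(np.floor(p / h), 0, grid.n_cells - 1))
                        for p in pt)
            if vox in net.parents:
                prev = vox
                continue
            net.add_voxel(vox, prev, perfused=True)
            if prev is None:
                net.roots.append(vox)
            prev = vox
    return net


def _neighbors(vox: tuple, shape: tuple):
    for ax in range(len(vox)):
        for d in (-1, 1):
            nb = list(vox)
            nb[ax] += d
            if 0 <= nb[ax] < shape[ax]:
                yield tuple(nb)


def sprout_step(net: VesselNetwork, n_V: np.ndarray,
                params: ModelParameters, rng: np.random.Generator,
                dt: float) -> VesselNetwork:
    """One angiogenesis step (in place; the network is also returned)."""
    shape = net.grid.shape

    # (i) sprout initiation on perfused segments above the VEGF threshold
    if net.n_tips < net.max_active_tips:
        tip_positions = {t.pos for t in net.tips}
        candidates = [v for v in net.parents
                      if net.perfused[v] and v not in tip_positions
                      and n_V[v] > params.theta_sprout]
        for vox in sorted(candidates):
            if net.n_tips >= net.max_active_tips:
                break
            if rng.random() < params.p_sprout_per_day * dt:
                net.tips.append(Tip(pos=vox))

    # (ii) biased migration with anastomosis on contact
    p_move = min(params.tip_speed_mm_day * dt / net.grid.h, 1.0)
    survivors = []
    for tip in net.tips:
        if rng.random() >= p_move:
            survivors.append(tip)
            continue
        options = [nb for nb in _neighbors(tip.pos, shape) if nb != tip.prev]
        if not options:
            tip.stalled = True
            net.stalled_moves += 1
            survivors.append(tip)
            continue
        dv = np.array([n_V[nb] - n_V[tip.pos] for nb in options])
        w = np.exp(params.beta_chemotaxis * (dv - dv.max()))
        w /= w.sum()
        nb = options[int(rng.choice(len(options), p=w))]
        if nb in net.parents:                       # anastomosis: close the loop
            net.mark_perfused_path(nb)
            net.mark_perfused_path(tip.pos)
            continue                                # tip retires
        net.add_voxel(nb, tip.pos, perfused=False)
        tip.prev, tip.pos = tip.pos, nb
        survivors.append(tip)
    net.tips = survivors

    # (iii) branching, linear in local VEGF
    new_tips = []
    for tip in net.tips:
        if net.n_tips + len(new_tips) >= net.max_active_tips:
            break
        if rng.random() < params.branch_per_day * float(n_V[tip.pos]) * dt:
            new_tips.append(Tip(pos=tip.pos))
    net.tips.extend(new_tips)
    return net


def rasterize(net: VesselNetwork, grid: Grid,
              perfused_only: bool = False) -> np.ndarray:
    """Binary vessel indicator field delta_vessel on the grid."""
    delta = np.zeros(grid.shape)
    for vox, parent in net.parents.items():
        if perfused_only and not net.perfused[vox]:
            continue
        delta[vox] = 1.0
    return delta
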