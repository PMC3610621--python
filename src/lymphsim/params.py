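"""Model parameters, baseline values, units, and non-dimensionalisation.

Unit conventions used throughout the package
--------------------------------------------
lengths        mm        (grid spacing is often quoted in µm; converted on input)
time           day       (the simulation clock runs in days post tumor-cell injection)
rates          day^-1
diffusivities  configured in cm^2/s (the conventional unit for oxygen/VEGF
               diffusion constants) and converted internally to mm^2/day
substrate n, VEGF n_V    non-dimensional, scaled by the intravascular maximum,
               hence bounded by [0, 1]

The oxygen/nutrient uptake rate of viable tumor tissue is never set directly:
it is anchored to the measurable oxygen diffusion distance L (the distance from
a vessel at which hypoxia is first detected, HIF-1α staining, 80 ± 20 µm) via
``lambda_upt_V = D_n / L**2``, and recomputed whenever the anchor changes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

CM2_PER_S_TO_MM2_PER_DAY = 100.0 * 86400.0  # 1 cm^2/s = 100 mm^2/s

# fields whose value must be strictly positive
_POSITIVE = {
    "D_n", "D_nV", "prolif_cycle_h", "apop_window_h", "L_hypoxia_um",
    "node_radius_mm", "seed_radius_mm", "extent_mm", "spacing_um",
    "tau_vasc_day", "k_V", "k_D", "k_H", "mobility_reduction", "dt_max_day",
}
# fields that must be non-negative (rates, coefficients)
_NONNEG = {
    "lambda_M", "lambda_A", "lambda_N_nd", "lambda_D", "nu_nd",
    "lambda_upt_H_rel", "lambda_dec_n", "lambda_dec_nV", "lambda_sec_V",
    "gamma", "eps_int_vox", "chi_n", "chi_h", "vessel_uptake_V_nd",
    "theta_sprout", "p_sprout_per_day", "beta_chemotaxis", "branch_per_day",
    "tip_speed_mm_day", "root_radius_mm", "host_density", "vascular_support",
    "output_interval_day", "rho_prolif_floor",
}
_UNIT_INTERVAL_OPEN = {"n_N"}          # in (0, 1)
_UNIT_INTERVAL_HALFOPEN = {"n_init"}   # in (0, 1]


@dataclass
class ModelParameters:
    """All rate constants, thresholds, mobilities and geometry of the model.

    Baseline values reproduce the calibrated murine nodal lymphoma setup;
    every field can be overridden through a flat ``key=value`` configuration.
    """

    # --- cell kinetics -----------------------------------------------------
    # calibrated baseline: lambda_M * <n> = 1.14/day (Ki-67 fraction 0.95 on a
    # 20 h cycle) at the model's converged tumor mean substrate <n> ~ 0.76
    lambda_M: float = 1.5          # mitosis rate coefficient, day^-1 per unit n
    lambda_A: float = 0.6          # apoptosis rate, day^-1 (A = lambda_A/lambda_M = 0.4)
    lambda_N_nd: float = 6.0       # necrosis rate, non-dim (units of lambda_M)
    lambda_D: float = 12.0         # dead-cell degradation, day^-1 (~2 h clearance)
    lambda_A_H: float = 0.0        # host apoptosis rate, day^-1 (homeostatic host)
    lambda_N_H_nd: float = 0.0     # host necrosis rate, non-dim
    n_N: float = 0.3               # quiescence/necrosis substrate threshold
    n_init: float = 1.0            # initially available substrate (supply at seeding)
    tau_vasc_day: float = 3.0      # vascular maturation time for the supply ramp

    # --- transport ---------------------------------------------------------
    D_n: float = 1.0e-5            # oxygen/nutrient diffusivity, cm^2/s
    D_nV: float = 1.0e-7           # VEGF diffusivity, cm^2/s
    L_hypoxia_um: float = 80.0     # oxygen diffusion distance anchor, µm (60-100)
    nu_nd: float = 10.0            # vessel delivery rate, units of lambda_upt_V
    lambda_upt_H_rel: float = 0.5  # host uptake relative to viable-tumor uptake
    lambda_dec_n: float = 0.0      # substrate decay, day^-1 (zero in the model)
    lambda_dec_nV: float = 0.0     # VEGF decay, day^-1 (zero in the model)
    lambda_sec_V: float = 50.0     # VEGF secretion by hypoxic tumor, day^-1
    vessel_uptake_V_nd: float = 1.0   # VEGF uptake at vessels, units of lambda_sec_V

    # --- mechanics ---------------------------------------------------------
    k_V: float = 1.0               # cell mobilities (non-dim)
    k_D: float = 1.0
    k_H: float = 1.0
    gamma: float = 0.1             # cell-cell adhesion strength
    eps_int_vox: float = 1.0       # adhesion interface width, voxels
    chi_n: float = 0.0             # chemotaxis coefficient (tumor species)
    chi_h: float = 0.0             # haptotaxis coefficient (tumor species)
    host_density: float = 0.8      # initial host volume fraction inside the domain

    # --- geometry / timeline ----------------------------------------------
    node_radius_mm: float = 1.5    # lymph node sphere radius
    mobility_reduction: float = 10.0  # mobility drop factor outside the node
    seed_radius_mm: float = 0.5    # initial tumor seed radius
    t_seed_day: float = 9.0        # bioluminescence-detected nodal seeding day
    t_end_day: float = 21.0
    extent_mm: float = 6.4         # domain edge length (isotropic box)
    spacing_um: float = 100.0      # grid spacing
    dim: int = 3

    # --- angiogenesis ------------------------------------------------------
    root_radius_mm: float = 0.3    # pre-existing vascular ball in the node core
    theta_sprout: float = 0.01     # VEGF level required to initiate a sprout
    p_sprout_per_day: float = 2.0  # sprout initiations per eligible voxel per day
    beta_chemotaxis: float = 50.0  # softmax bias of tip steps on the VEGF gradient
    branch_per_day: float = 1.0    # branching probability slope in local n_V
    tip_speed_mm_day: float = 0.3  # endothelial tip migration speed
    perfusion_gated: bool = False  # gate substrate delivery on perfused loops

    # --- reduced / calibration ---------------------------------------------
    vascular_support: float = (1.0 - 0.5) ** 1.5  # (1-f_CD31)^{3/2} at preset f=0.5

    # --- numerics ----------------------------------------------------------
    rho_prolif_floor: float = 0.01  # no mitosis below this viable fraction
    dt_max_day: float = 0.01
    output_interval_day: float = 0.25
    solver_rtol: float = 1.0e-8
    solver_maxiter: int = 2000

    # ------------------------------------------------------------------ api
    @property
    def D_n_mm2_day(self) -> float:
        return self.D_n * CM2_PER_S_TO_MM2_PER_DAY

    @property
    def D_nV_mm2_day(self) -> float:
        return self.D_nV * CM2_PER_S_TO_MM2_PER_DAY

    @property
    def L_hypoxia_mm(self) -> float:
        return self.L_hypoxia_um * 1.0e-3

    @property
    def lambda_upt_V(self) -> float:
        """Viable-tumor substrate uptake, day^-1, from the 80 µm anchor."""
        return self.D_n_mm2_day / self.L_hypoxia_mm**2

    @property
    def lambda_upt_H(self) -> float:
        return self.lambda_upt_H_rel * self.lambda_upt_V

    @property
    def lambda_N(self) -> float:
        """Dimensional necrosis rate, day^-1."""
        return self.lambda_N_nd * self.lambda_M

    @property
    def lambda_N_H(self) -> float:
        return self.lambda_N_H_nd * self.lambda_M

    @property
    def nu(self) -> float:
        """Vessel substrate delivery rate, day^-1."""
        return self.nu_nd * self.lambda_upt_V

    @property
    def A_ratio(self) -> float:
        return self.lambda_A / self.lambda_M

    def supply_level(self, t_day: float) -> float:
        """Intravascular supply level n_sup(t).

        Starts at ``n_init`` when the node is seeded and relaxes to the full
        intravascular level 1 with time constant ``tau_vasc_day`` as the
        vasculature matures.  With ``n_init=1`` (the baseline, the maximum
        possible value of initial nutrient) the supply is identically 1.
        """
        dt = max(t_day - self.t_seed_day, 0.0)
        return 1.0 - (1.0 - self.n_init) * math.exp(-dt / self.tau_vasc_day)

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in _POSITIVE and not v > 0:
                raise ValueError(f"parameter {f.name} must be > 0, got {v!r}")
            if f.name in _NONNEG and v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")
            if f.name in _UNIT_INTERVAL_OPEN and not (0.0 < v < 1.0):
                raise ValueError(f"parameter {f.name} must lie in (0, 1), got {v!r}")
            if f.name in _UNIT_INTERVAL_HALFOPEN and not (0.0 < v <= 1.0):
                raise ValueError(f"parameter {f.name} must lie in (0, 1], got {v!r}")
        if self.D_nV >= self.D_n:
            raise ValueError("VEGF diffusivity D_nV must be smaller than D_n")
        if self.dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.dim}")
        if self.t_end_day <= self.t_seed_day:
            raise ValueError("t_end_day must exceed t_seed_day")
        if not 0.0 < self.vascular_support < 1.0:
            raise ValueError("vascular_support must lie in (0, 1)")

    def replace(self, **kw) -> "ModelParameters":
        p = dataclasses.replace(self, **kw)
        p.validate()
        return p

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        """Resolved-parameter export for provenance, including derived rates."""
        d = self.to_dict()
        d["derived"] = {
            "lambda_upt_V_per_day": self.lambda_upt_V,
            "lambda_upt_H_per_day": self.lambda_upt_H,
            "lambda_N_per_day": self.lambda_N,
            "nu_per_day": self.nu,
            "A_ratio": self.A_ratio,
            "D_n_mm2_day": self.D_n_mm2_day,
            "D_nV_mm2_day": self.D_nV_mm2_day,
        }
        return json.dumps(d, indent=2, sort_keys=True)


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(ModelParameters)}


def _coerce(key: str, raw: str):
    t = _FIELD_TYPES[key]
    raw = raw.strip()
    if t == "bool":
        if raw.lower() in ("1", "true", "yes", "on"):
            return True
        if raw.lower() in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"cannot parse boolean for {key}: {raw!r}")
    if t == "int":
        return int(raw)
    try:
        return float(raw)
    except ValueError as e:
        raise ValueError(f"cannot parse value for {key}: {raw!r}") from e


def parse_config(text: str) -> ModelParameters:
    """Parse a flat ``key=value`` configuration (``#`` starts a comment).

    Unknown keys are rejected; unspecified keys keep their documented
    baselines.  Out-of-range values raise ``ValueError`` naming the key.
    """
    overrides: dict = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {ln}: expected key=value, got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in _FIELD_TYPES:
            raise ValueError(f"line {ln}: unknown configuration key {key!r}")
        overrides[key] = _coerce(key, raw)
    p = ModelParameters(**overrides)
    p.validate()
    return p


def load_config(path) -> ModelParameters:
    with open(path) as fh:
        return parse_config(fh.read())


def write_config(p: ModelParameters, path) -> None:
    """Write every documented key so the round trip is bit-identical."""
    lines = ["# lymphsim run configuration (flat key=value)"]
    for f in dataclasses.fields(ModelParameters):
        lines.append(f"{f.name}={getattr(p, f.name)!r}".replace("'", ""))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass(frozen=True)
class NondimParameters:
    """Non-dimensional view of :class:`ModelParameters`.

    Length is scaled by the substrate diffusion length ``sqrt(D_n/lambda_upt_V)``
    (numerically equal to the hypoxia-distance anchor) and time by the mitosis
    time ``1/lambda_M``; the conventional "non-dimensional units" for rates
    (e.g. the necrosis rate 5–7) live on this scale.
    """

    length_scale_mm: float
    time_scale_day: float
    dimensional: ModelParameters
    rates_nd: Mapping[str, float] = field(default_factory=dict)

    def redimensionalize(self) -> ModelParameters:
        return self.dimensional


def nondimensionalize(p: ModelParameters) -> NondimParameters:
    if p.lambda_M <= 0:
        raise ValueError("nondimensionalisation requires lambda_M > 0")
    if p.lambda_upt_V <= 0:
        raise ValueError("nondimensionalisation requires lambda_upt_V > 0")
    ls = math.sqrt(p.D_n_mm2_day / p.lambda_upt_V)
    ts = 1.0 / p.lambda_M
    rates = {
        "lambda_A": p.lambda_A * ts,
        "lambda_N": p.lambda_N * ts,
        "lambda_D": p.lambda_D * ts,
        "lambda_upt_V": p.lambda_upt_V * ts,
        "lambda_upt_H": p.lambda_upt_H * ts,
        "nu": p.nu * ts,
        "seed_radius": p.seed_radius_mm / ls,
        "node_radius": p.node_radius_mm / ls,
    }
    return NondimParameters(length_scale_mm=ls, time_scale_day=ts,
                            dimensional=p, rates_nd=rates)
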