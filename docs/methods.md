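# Methods

This document describes the model implemented by `lymphsim`, the parameter
defaults and their rationale, the numerical methods, what the synthetic
data emulate, and the package's limitations.

## 1. Model

### 1.1 Mixture kinematics

Tissue is a saturated mixture of viable tumor (ρ_V), dead tumor (ρ_D) and
host lymphoid tissue (ρ_H); the remainder 1 − Σρ_i is water/ECM. Each
species obeys a conservation law

∂ρ_i/∂t + ∇·(u_i ρ_i) = S_i,

with a generalized Darcy velocity

u_i = −k_i (∇p + γ ∇µ) + χ_n ∇n + χ_h ∇f,

where p is the oncotic (solid) pressure, µ the adhesion chemical potential,
and χ_n, χ_h optional chemotaxis/haptotaxis coefficients (0 by default —
bulk motion is pressure-driven). The pressure solves the quasi-static
compatibility condition ∇·(k∇p) = −S_total under zero-flux boundaries. A
pure-Neumann Poisson problem is only solvable for a zero-mean source, so
the source is projected to zero mean (uniform water efflux through the
far-field lymphatics) and p is gauged to zero mean.

Cell–cell adhesion derives from a Cahn–Hilliard energy on the tumor
fraction ρ_T = ρ_V + ρ_D,

E = γ ∫ [ W(ρ_T) + (ε²/2)|∇ρ_T|² ],  W(r) = r²(1−r)²/4,

whose gradient flow compacts the tumor–host interface to a width of a few
voxels (ε defaults to one grid spacing).

### 1.2 Substrate and VEGF

The substrate (oxygen/nutrient) field is quasi-steady — its diffusive
relaxation time over 100 µm is seconds, versus days for growth:

0 = D_n ∇²n + ν δ_vessel (n_sup − n) − (λ_upt ρ_V + λ_upt,H ρ_H) n.

The uptake rate is anchored by the measured hypoxia penetration length:
λ_upt = D_n / L² with L = 80 µm, i.e. tissue 80 µm from a vessel sits at
the hypoxia threshold. The VEGF-like factor n_V obeys the same quasi-steady
balance with secretion λ_sec ρ_V H(n_N − n)(1 − n_V) by hypoxic viable
tissue and uptake at vessels; both fields live in [0, 1].

### 1.3 Cell kinetics

S_V = λ_M n H(n − n_N) ρ_V − λ_A ρ_V − λ_N H(n_N − n) ρ_V
S_D = λ_A ρ_V + λ_N H(n_N − n) ρ_V (+ host terms) − λ_D ρ_D
S_H = −λ_A,H ρ_H − λ_N,H H(n_N − n) ρ_H

Mitosis is additionally gated by a small density floor (see §3.4). The
ratio A = λ_A/λ_M controls the terminal size: growth stalls where the
substrate the vasculature can maintain no longer exceeds the level at
which net proliferation balances apoptosis.

### 1.4 Angiogenesis

Vessels live on the grid lattice as a parent-linked forest rooted in a
pre-existing central vascular ball plus three radial stems. Perfused
segments exposed to VEGF above a threshold launch tips; tips execute a
no-backtrack random walk with step weights ∝ exp(β Δn_V), branch at a
VEGF-proportional rate, and anastomose (retire, marking their path
perfused) when they meet an existing segment. Only perfused voxels deliver
substrate when perfusion gating is enabled; by default all vessel voxels
deliver.

### 1.5 Calibration from IHC

Stained fractions f of cell-count tables convert to rates:

- λ_M ⟨n⟩ = (f_Ki67 / 20 h) · 24 — Ki-67 marks cells in a ~20 h cycle;
- λ_A = (f_Casp3 / 5 h) · 24 — cleaved Caspase-3 is visible ~5 h;
- vascular support fraction B = (1 − f_CD31)^{3/2};
- hypoxic cell fraction = f_HIF1a^{3/2}

(the 3/2 powers convert an area fraction on a section to a volume
fraction). λ_M needs the tumor mean substrate ⟨n⟩, which depends on the
simulation; `fit_with_simulation` iterates rate → simulate → ⟨n⟩ → rate to
a fixed point (converges in 2–3 iterations at 1% tolerance).

### 1.6 Reduced spherical model

Assuming radial symmetry and uniform density inside radius R:

dR/dt = (1/R²) ∫₀ᴿ [ λ_M n H(n − n_N) − λ_A − λ_N H(n_N − n) ] r² dr,

with n from a 1D quasi-steady radial solve. Two supply modes: `core`
(delivery only in a central vascular ball — the configuration used for
oracle comparisons against the 3D simulator) and `distributed` (volumetric
delivery at the fraction B of demand the vasculature supports — the
terminal-size theory). With the normoxic closure (n = n_sup at the tumor
boundary) the stationary condition is analytic:

B + (1 − B)·3(x coth x − 1)/x² = A,  x = R/L,

giving a terminal diameter of ~6.5 mm at A = 0.4, B = 0.354, L = 80 µm;
the numerical model reproduces this.

## 2. Parameters

| name | default | unit | rationale |
|---|---|---|---|
| `D_n` | 1e-5 | cm²/s | oxygen diffusivity in tissue |
| `D_nV` | 1e-7 | cm²/s | VEGF diffusivity (much slower than O₂) |
| `L_hypoxia_um` | 80 | µm | measured hypoxia penetration length; sets λ_upt = D_n/L² |
| `lambda_M` | 1.5 | /day | fixed point of λ_M⟨n⟩ = (f_Ki67/20 h)·24 at the simulated ⟨n⟩ ≈ 0.76 |
| `lambda_A` | 0.6 | /day | makes A = λ_A/λ_M = 0.4, the calibrated apoptosis-to-proliferation ratio |
| `lambda_N_nd` | 6 | — (×λ_M) | mid-range of the necrosis rates the sweep accepts |
| `lambda_D` | 12 | /day | ~2 h apoptotic-body clearance (rapid phagocytosis) |
| `lambda_A_H`, `lambda_N_H_nd` | 0 | | passive homeostatic host: with no host proliferation, tumor-scale death rates would dissolve the host compartment within days and necrose all avascular host tissue; 0 keeps the host inert unless configured otherwise |
| `n_N` | 0.3 | — | hypoxia/quiescence threshold; must sit below the vascular support level B ≈ 0.354 so supported tissue does not necrose |
| `n_init`, `tau_vasc_day` | 1.0, 3 | —, day | initial intravascular supply level, relaxing to 1 as the co-opted vasculature matures; a quasi-steady field has no memory, so "initial nutrient" must enter through the supply boundary term to affect the growth phase |
| `nu_nd` | 10 | ×λ_upt | vessel-adjacent tissue equilibrates near the intravascular level |
| `lambda_sec_V`, `vessel_uptake_V_nd`, `theta_sprout` | 50/day, 1, 0.01 | | set once so the angiogenic loop is functional (hypoxic rims produce VEGF levels above the sprouting threshold) |
| `beta_chemotaxis`, `tip_speed_mm_day`, `branch_per_day` | 50, 0.3, 1 | | strong up-gradient bias; endothelial tip speed ~0.3 mm/day |
| `gamma`, `eps_int_vox` | 0.1, 1 | | adhesion strength and interface width (voxels) |
| `rho_prolif_floor` | 0.01 | — | no mitosis in advection-smeared trace fractions (§3.4) |
| `seed_radius_mm`, `t_seed_day`, `t_end_day` | 0.5, 9, 21 | | incipient nodal seed at Day 9 (bioluminescence-detected arrival), excision at Day 21 |
| `extent_mm`, `spacing_um` | 6.4, 100 | | 6.4 mm box at 100 µm spacing |
| `node_radius_mm`, `mobility_reduction` | 1.5, 10 | | lymph-node capsule as a 10× Darcy-mobility reduction outside 1.5 mm |
| `host_density` | 0.8 | — | dense lymphoid parenchyma |

All defaults are plain `key=value` entries in config files; unknown keys
are rejected.

## 3. Numerics

### 3.1 Elliptic solves

The screened Poisson (substrate, VEGF) and variable-coefficient pressure
equations are solved matrix-free with preconditioned conjugate gradients;
the preconditioner inverts the constant-coefficient operator exactly in
DCT space (zero-flux boundaries make the Neumann Laplacian diagonal under
DCT-II). The pure-Neumann pressure system is projected to the zero-mean
subspace.

### 3.2 Advection

Species advect with conservative first-order upwind fluxes on cell faces
(harmonic-mean face mobilities for the pressure, donor-cell values for
transport), CFL-substepped inside each kinetics step with frozen sources
and velocities. The per-step discrete mass identity (mass change = source
integral − boundary flux) is tracked and held below 1e-8.

### 3.3 Adhesion substep

The fourth-order Cahn–Hilliard term is operator-split and Eyre-stabilised:
the biharmonic part implicit (diagonal in DCT space), the double-well part
explicit with a linear stabilisation shift. The substep conserves tumor
mass; enforcement of 0 ≤ ρ_T ≤ 1 − ρ_H is conservative (clipped mass is
restored into remaining capacity inside the tumor body).

### 3.4 Regularisations

First-order upwinding leaks small tumor fractions ahead of the front;
letting those trace fractions proliferate at host-side substrate levels
creates an artificial "pulled" front. Mitosis is therefore gated by
ρ_V > 0.01. The 1D radial solver uses a finite-volume tridiagonal solve
with a smooth fractional rim-coverage weight so dR/dt is continuous in R.

### 3.5 Determinism

A single seed fans out to named substreams (IHC fixture sampling,
angiogenesis, sweep streams) via `numpy` seed sequences; reruns with the
same seed are bit-identical, and toggling one stochastic component does
not perturb the others.

## 4. Synthetic data

`synth_ihc` emulates stain-count tables from five sections (S1–S5) × two
regions (core/periphery) × five markers (Ki-67, Casp3, CD31, HIF-1α,
H&E viability), drawing stained counts binomially around preset target
fractions. Presets represent phenotypes: `baseline` (f_Ki67 = 0.95,
f_Casp3 = 0.125, f_CD31 = 0.5, f_HIF = 0.25, H&E ≈ 0.9), `sensitive`
(higher apoptosis), `resistant` (higher central endothelial density, 4×
core CD31 enrichment). They stand in for real IHC panels — counting noise
included — but encode no real measurements beyond the anchor rates above.

## 5. Limitations

- The simulator is desk-scale: 2D 64² or 3D 32³ grids; full-resolution 3D
  runs are possible but slow on one CPU.
- First-order upwinding is diffusive; interface positions carry O(h)
  error, and the equivalent diameter is quantised at the voxel scale.
- The angiogenesis mechanism is a minimal lattice reconstruction; its free
  parameters (secretion, thresholds, tip kinetics) are plausible values,
  not fits to vascular data.
- Host tissue is passive (no proliferation or death by default); lymphatic
  drainage is represented only by the uniform pressure-source projection.
- The reduced model's `distributed` mode assumes a uniform supported
  supply and a normoxic boundary; it is a theory closure, not a coupled
  simulation, and intentionally ignores the host screening layer.
- Because `n_init` enters as the initial intravascular supply level with a
  3-day maturation time, initial supply at or below the hypoxia threshold
  (`n_init <= n_N`) exposes the whole seed to necrosis for days and can
  annihilate it; the growth-phase sensitivity to `n_init` is therefore
  strong near that threshold.
- Calibration assumes stain fractions map to rates through fixed
  detectability windows (20 h, 5 h); absolute rates inherit any error in
  those windows.
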