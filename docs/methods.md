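# Methods

## Model

Two related continuum models of glioblastoma at MRI scale are implemented
on a homogeneous, rectangular 2D brain domain with no-flux (skull)
boundaries.

**Single-cell model.**  One glioma phenotype `G` that simultaneously
moves and divides, live brain `B`, necrotic debris `N`; total
concentration `C = G + B + N` (always recomputed from the components,
never integrated separately).  Transport of `G` combines passive
Fickian diffusion (rate `δ`, mm²/hr, diffusivity map `D ≡ 1` on the
homogeneous brain) and hypoxia-driven active transport `−η ∇·(G∇B)`:
cells drift up the live-brain gradient with velocity `v = η∇B`, i.e. in
bulk away from necrosis into healthy tissue.  Reactions are gated by
smooth tanh switches of steepness `k = 100` around the necrotic
threshold `C_ltm = σ log(1+G) + Ω` (natural log): mitosis at rate
`τ (1+tanh k(C_ltm−C))/2` and necrosis at rate
`γ (1+G)/(B+0.01) (1−tanh k(C_ltm−C))/2` applied identically to `G` and
`B`, with all necrosed mass transferred to `N`.  Angiogenesis is the
logarithmic lift of `C_ltm` with tumor burden (rate `σ`); anti-angiogenic
therapy is `σ = 0`.

**Go-or-Grow (GoG) baseline.**  Proliferative `P` (divides, immobile) and
invasive `I` (moves, does not divide) phenotypes interconvert at rates
`αH` (P→I under hypoxia) and `β(1−H)` (I→P under normoxia), where the
hypoxia measure `H` and the mitosis gate are complementary switches at
the hypoxic threshold `C_hyp = σ log(1+P) + Ω`, and the necrotic
threshold sits a fixed gap above it, `C_ltm = C_hyp + Φ`.

Reference kinetic constants (single-cell / GoG): τ = 0.25 / 0.35 hr⁻¹,
γ = 0.1 / 0.085 hr⁻¹, σ = 0.8 / 1.5, Ω = 1.1, α = 1.01 hr⁻¹,
β = 1.0 hr⁻¹, Φ = 0.1.  Published sources are inconsistent about the
single-cell σ (0.8 in the parameter table vs 1.0 in an equation
footnote); the parameter-table value 0.8 is the default and the value is
configurable.  Motility ranges: δ ∈ [0, 1e−3] mm²/hr,
η ∈ [1.4e−4, 1.4e−3] mm/hr.

## Numerics

Method of lines with operator splitting, fully explicit:

* **Diffusion** — conservative 5-point flux-form central differences;
  grid sum is zero to machine precision under no-flux boundaries.
* **Active transport** — finite-volume fluxes with first-order upwinding
  in the face velocity `η ∇B`; conservative and positivity-friendly under
  the CFL bound.  Negative undershoot is clipped at zero with the clipped
  mass accounted; a run aborts if cumulative clipping exceeds 1e−6 of the
  total mass (it never approaches this in default runs).
* **Reaction** — pointwise semi-analytic update.  Each substep freezes
  the nonlinear rates at a midpoint predictor (second-order accurate) and
  then integrates exactly: `B` decays as `exp(−γF h)`, `G` as
  `exp((M−γF)h)`, and the necrotic transfer into `N` uses the closed-form
  integral of the decaying fields, so `ΔG+ΔB+ΔN = M∫G dt` holds to
  machine precision and total mass is conserved exactly when `τ = 0`.
  The GoG conversion exchange is applied as exact half-steps around the
  growth/decay update (Strang splitting) and conserves `P+I` exactly.
  This construction tolerates the stiffness of the `k = 100` switches and
  of the necrosis rate as `B → 0` (a numerical-safety cap at 50/hr exists
  but never binds with default parameters).
* **Time step** — `0.5 · min(h²/4δ, h/max|v|, c_react/(τ+γ[+α+β]))`,
  capped at 6 hr; with default parameters the reaction-accuracy bound
  (c_react = 0.25) governs, giving dt ≈ 0.36 hr.
* Verified properties: agreement with an adaptive ODE oracle to 1e−4
  relative at `δ = η = 0`; exact preservation of 8-fold dihedral symmetry
  for centered seeds; pointwise monotonicity of `B` (down) and `N` (up);
  first-enhancement timing stable to <10% under grid refinement.

## Domain, initial condition, readouts

Defaults: 120×120 cells, h = √3 mm (one cell = one ≈3 mm² MRI pixel,
domain ≈ 208×208 mm), B ≡ 1, N ≡ 0, and a centered Gaussian glioma seed
of amplitude 0.1 and width 2h, truncated to exact zero beyond 3 widths.
The truncation matters: an analytic Gaussian carries tails across the
whole domain, and because growth is exponential those tails — not cell
transport — would set the apparent invasion speed.  All geometry and the
seed are configurable (YAML).

Virtual MRI masks use strict thresholds: FLAIR `C > 1.003`, enhancement
(vascular proliferation) `C > 1.12`, radiological necrosis `B < 0.30`,
pathological necrosis `B < 0.9995`.  Area fractions are percentages of
the whole rectangular domain, which is counted as brain under the
homogeneity assumption.  Enhancement is a concentration-threshold proxy
for blood–brain-barrier disruption, not an MRI-physics simulation.

## Trial engine

Diagnosis and death are threshold crossings of the area-fraction time
series, sampled every 12 hr and linearly interpolated between snapshots.
Treated patients restart from the stored state at the first snapshot past
diagnosis with σ = 0, instantaneously and permanently.  Patients sharing
a motility preset share the pre-diagnosis trajectory: one base run per
preset, with treated branches forked per diagnosis titration, and each
branch serving all five death titrations.  Survival is reported in months
(730 hr/month).  Runs exceeding 24 simulated months are censored;
Kaplan–Meier and log-rank handle censoring throughout (deaths tied at one
time use the hypergeometric variance; a censoring tied with a death
counts the death first; the median is the smallest t with S(t) ≤ 0.5).

The hypoxia-driven arm's two-readout diagnosis rule pairs the i-th
enhancement titration with the i-th necrosis titration as an OR-set
(first to fire).

Progression patterns of treated branches are classified at death:
PP1 (Expanding FLAIR) if the FLAIR burden reaches ≥30% of the brain —
death through low-density invasion; otherwise PP2 (Expanding FLAIR +
Necrosis) if the FLAIR margin leads the necrotic rim by more than 2.5 mm
in equivalent-disk radius, else PP3 (Expanding Necrosis).  The margins
are desk-scale operationalizations (see below).

## Motility presets and calibration

The published parameter ranges leave the per-phenotype motility values
free.  The `calibrate` subcommand sweeps (δ, η) strictly within the
ranges, runs each candidate's treated arm and untreated control, and
minimizes squared log-ratios to the reference arm medians (14.5 / 5.5 /
6.6 / 3.2 months) with penalties for broken median ordering or
progression classification.  The frozen defaults are the sweep's
optimum on the default grid:

| phenotype | δ (mm²/hr) | η (mm/hr) |
|---|---|---|
| high (highly dispersive) | 1e−4 | 1.4e−4 |
| moderate | 1e−5 | 1.4e−4 |
| low (hypoxia-driven) | 1e−8 | 1.4e−4 |

## Desk-scale limits

On an MRI-resolution grid the invasion front advances by colonizing one
pixel at a time: transport seeds a neighboring pixel with a small tumor
amplitude, exponential growth at τ fills it, necrosis follows.  The
cycle takes `~(1/τ)·ln(…) + B-death time` ≈ 20–60 hr/pixel for every
(δ, η) in the published ranges — active transport across the
under-resolved necrotic rim (true continuum width ≪ h) sets a hard floor
of ≈0.03 mm/hr even as δ → 0.  Resolving the continuum front instead
would require grids of order 5000², since the domain-crossing time at
the Fisher front speed is `n_x/(2τ)` independent of δ.

Consequences, measured and reproduced by the test suite:

* The absolute survival scale of the default trial is compressed to
  ~0.2–1.7 months against reference medians of 3.2–14.5 months; the
  acceptance-tier tests asserting the reference medians and the full
  median ordering fail under the default conditions and are retained as
  faithful statements of the reference behavior.
* A treated necrosis-criterion patient can never outlive the fastest
  untreated enhancement-criterion control (≈7 vs ≈19 pixels of front
  travel), so the reference ordering PP2 > untreated is structurally
  out of reach at this resolution.
* The low-density FLAIR halo ahead of the necrotic rim spans
  `front speed × ~36 hr` ≈ 1–2 pixels, so the PP2-vs-PP3 morphological
  distinction ("FLAIR well beyond the rim" vs "FLAIR at the rim") is
  sub-pixel; the moderately dispersive arm classifies as PP3 under the
  2.5 mm margin, and the corresponding signature test fails.
* Group separation itself is robust: all pairwise log-rank p-values in
  the default trial are below 1e−9.

## Other fixed conventions

* Without angiogenesis the model caps total concentration near
  Ω = 1.1; the reaction dynamics overshoot the threshold by ≈1.7 pp
  (converged under time-step refinement) because mitosis still runs at
  τ/2 at the threshold while necrosis winds up.  The overshoot stays
  inside the tanh switch width (2/k = 2 pp) and strictly below the
  enhancement threshold 1.12, so "no enhancement without angiogenesis"
  holds exactly.
* Events interpolate linearly between 12-hr snapshots; the treated
  branch forks at the first snapshot past diagnosis (timing error
  bounded by the snapshot interval, ≈0.02 months).
* hours_per_month = 730 at the reporting layer; all internal times are
  hours.
* The synthetic-data fixtures (healthy brain, Gaussian seed, necrotic
  annulus, linear-B ramp) are constructed states with countable ground
  truth; they emulate field configurations, not patient data — passing
  tests demonstrate internal consistency of the solver and readouts, not
  fidelity to any clinical cohort.

## Known limitations

2D homogeneous domain (no anatomy, no 3D); first-order upwinding adds
numerical diffusion near the necrotic rim, which *overestimates* the
active-transport wave speed at this resolution; no pharmacokinetics —
treatment is an instantaneous, permanent σ = 0; no resection, radiation
or chemotherapy; the classifier margins are resolution-specific.
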