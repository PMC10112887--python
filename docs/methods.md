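# Methods

`extrudesim` simulates a confluent monolayer of N deformable cells on a
rigid substrate with a three-dimensional multi-phase-field model, and
analyses the simulated trajectories for the mechanics and topology of
cell extrusion: nematic ±1/2 defects in the cell orientation field,
fivefold/sevenfold disclinations in the neighbour arrangement,
coarse-grained 3D stress fields, and a Poisson-null hypothesis test for
the extrusion–defect correlation.

## Model

Each cell i carries a phase field φᵢ(x) ∈ [0, 1] on a cuboidal grid
(spacing a₀ = 1, periodic in x and y, bounded in z) with a diffuse
interface of width λ; the φᵢ = 0.5 level set is the cell boundary.  A
static, z-only field φ_w represents the substrate,
φ_w(z) = ½(1 − tanh(2(z − z_s)/λ)), with the surface plane z_s placed a
few grid points above the box floor so cell fields never touch the
boundary.

The free energy has six terms per cell:

    F = Σᵢ γ/λ ∫ [4 φᵢ²(1−φᵢ)² + λ²|∇φᵢ|²]          (Cahn–Hilliard)
      + Σᵢ µ (1 − (1/V₀)∫ φᵢ²)²                       (soft volume constraint)
      + Σᵢ Σ_{j≠i} κ_cc/λ ∫ φᵢ² φⱼ²                   (cell–cell repulsion)
      + Σᵢ Σ_{j≠i} ω_cc λ² ∫ ∇φᵢ·∇φⱼ                  (cell–cell adhesion)
      + Σᵢ κ_cw/λ ∫ φᵢ² φ_w²                          (cell–wall repulsion)
      + Σᵢ ω_cw λ² ∫ ∇φᵢ·∇φ_w                         (cell–wall adhesion)

with target volume V₀ = (4/3)πR₀³.  The adhesion terms are implemented
exactly as written: at an overlap of two diffuse interfaces the gradients
are anti-parallel, the integrand is negative, and increasing ω lowers the
energy — attraction.  This is verified behaviourally (a two-droplet
fixture stays in contact when ω_cc > 0 and separates when repulsion
dominates) rather than assumed.

Dynamics couple a per-cell rigid velocity to relaxation:

    ∂φᵢ/∂t + v⃗ᵢ·∇φᵢ = −δF/δφᵢ
    ξ v⃗ᵢ = t⃗ᵢ + α p⃗ᵢ,   t⃗ᵢ = ∫ φᵢ ∇·Π_int dx,  Π_int = (Σⱼ −δF/δφⱼ) 𝟙
    dθᵢ = −J |t⃗ᵢ| Δθᵢ dt + √(2 D_r dt) 𝒩(0,1)

where p⃗ᵢ = (cos θᵢ, sin θᵢ, 0) is the in-plane polarity, ξ the substrate
friction, α the self-propulsion strength, and Δθᵢ the signed angle from
the in-plane projection of t⃗ᵢ to p⃗ᵢ, so the drift rotates the polarity
toward the net interaction force (contact inhibition of locomotion).  An
exact anti-parallel tie (Δθ = ±π) is broken toward +π.  The polarity is
strictly in-plane, but tractions — and hence velocities — acquire z
components as cells deform, which is what pushes extruding cells out of
the plane.  Times are reported in units of τ₀ = ξR₀/α.

An extrusion event is recorded the first time a cell's vertical
center-of-mass displacement exceeds R₀/2 relative to the *median* z-COM
of the still-attached cells (the median is robust to the extruding cell
itself); extruded cells are excluded from the reference median
thereafter.  By default extruded cells keep evolving and detach
naturally; a switch removes them from the dynamics at detection.

## Discretisation

* Gradient terms in the energy use forward differences.  The exact
  variation of the discrete energy `Σ (φ_{k+1}−φ_k)²` is the standard
  7-point Laplacian, so the analytic functional derivative equals a
  numerical variation of the energy to round-off.  This identity is the
  central oracle test of the package.
* z boundaries are zero-flux (the z-bond sum omits boundary-crossing
  bonds, equivalently edge replication in the Laplacian).
* Advection is first-order upwind per velocity component; the traction
  field ∇Π uses second-order central differences.
* Time integration is explicit Euler for both the fields and the
  polarity angles (Itô convention, increment √(2 D_r dt)·𝒩(0,1)).  The
  default dt = 0.25 keeps the stiffest local term (cell–cell repulsion at
  full overlap, rate ≈ 4κ_cc/λ) well inside the stability region.
  Production runs additionally subdivide any step whose advection CFL
  number v·dt/a₀ would exceed 0.4 (`adaptive`); the plain integrator
  raises a stability error at CFL ≥ 1 instead.
* Each cell's field is stored on a moving x/y patch (full z extent) that
  recenters on the cell and grows when the φ > 0.25 support nears its
  edge.  The patch is required because the literal adhesion variations
  contain φ-independent sources (−ω_cw λ²∇²φ_w near the wall and
  −2ω_cc λ² Σ∇²φⱼ at neighbour interfaces) that would otherwise wet the
  entire plane with a thin halo (amplitude ~ωλ²|∇²φ_w|·λ/(8γ), well below
  the 0.5 level set).  Clipping that halo at the patch boundary is the
  standard device in moving-patch phase-field codes; its energetic effect
  is negligible except bookkeeping-level jumps when a patch shifts.
* Compressed (confluent) initial conditions seed droplets at the largest
  non-overlapping radius and let the volume constraint inflate them to
  V₀, avoiding violently overlapping initial fields.

## Parameters

Defaults, in lattice units (a₀ = 1):

| symbol | meaning | default | provenance |
|---|---|---|---|
| γ | interface stiffness | 0.01 | chosen; phase-field regime of this model family |
| λ | interface width | 2 | chosen; ≥ 2a₀ for resolvability |
| µ | volume stiffness | 40 | chosen; holds volumes within ~3 % of V₀ |
| κ_cc, κ_cw | repulsions | 0.25, 0.15 | chosen; strong enough to prevent interpenetration, soft enough for dt = 0.25 |
| ω_cw | wall adhesion | 0.0025 | reference sweep value {0.0015, 0.002, 0.0025} |
| Ω = ω_cc/ω_cw | relative cell–cell adhesion | 0.4 | reference sweep value {0.2, 0.4, 0.6} |
| ξ | substrate friction | 1 | sets the unit of force |
| α | polarity force | 0.05 | chosen; isolated-cell speed α/ξ = 0.05 a₀/time |
| J | CIL alignment rate | 0.005 | chosen; alignment time ≈ (J·|t|)⁻¹ of order τ₀ |
| D_r | rotational diffusivity | 10⁻⁴ | chosen; persistence time ≫ single-step |
| R₀ | initial cell radius | 8 (reference), 6 in desk-scale scenarios | reference geometry |

The reference geometry is a 320×320×64 box with 400 cells and 29,000
steps.  Desk-scale scenarios (used by the tests and the acceptance
script) keep all couplings and the adhesion ratios but shrink the box,
N and the step count: `passive_hex_relax` (12 passive cells,
hexagon-commensurate box), `two_cell_adhesion`, and
`small_active_monolayer` (25 active cells seeded at tangency spacing
2R₀ — the reference areal density — on 60×60×28).  These
sizes are the package's own choice of the smallest systems in which the
studied phenomenology (hexagonal packing, defect pairs, extrusions) is
observable.

## Analysis stack

* **Basal footprints** — each φᵢ sliced on the first lattice plane above
  the substrate surface; a slice that never reaches 0.5 marks a detached
  (extruded) cell.
* **Orientation** — principal axis of the footprint's second-moment
  tensor; anisotropy = normalised eigenvalue difference; footprints with
  anisotropy < 0.05 carry no reliable orientation and are excluded from
  director averaging.
* **Director field** — Gaussian-weighted average (length ℓ_dir = R₀) of
  per-cell nematic tensors Q = 2n⊗n − 𝟙 on a regular grid; defects are
  plaquettes with nematic winding ±π (orientation differences re-wrapped
  to (−π/2, π/2]); the +1/2 comet axis is the direction of ∇·Q at the
  core.  Defect tracking is greedy nearest-neighbour linking, same charge
  only, gated at R₀ per frame.
* **Coordination** — edge (i, j) iff ∫φᵢ²φⱼ² dx exceeds a small
  threshold (default 10⁻²; the hexagonal fixture's coordination is
  insensitive to it over two decades); z = degree; z = 5/7 are
  fivefold/sevenfold disclinations.  Lewis's linear ((z−2)/4) and
  quadratic ((z/6)²) laws are tabulated against the empirical normalised
  mean basal areas.
* **Stress** — traction density T(x) = Σφᵢ ∇Π; coarse-grained tensor per
  voxel of side ℓ_stress = R₀/4, σᵢⱼ = 1/(2V_cg) Σ_m sym(T(x_m)⊗ê^n)
  with ê^n the unit vector from the lattice point toward the voxel
  centre (the singular centre point, which only exists for odd voxel
  sizes, is excluded).  σ_iso is the 3D trace/3 (an in-plane trace/2
  variant is available); compression is negative.  Defect-frame maps
  sample basal σ_iso on a square window of side L ≈ 1.5R₀ rotated so the
  comet axis points +x (bilinear interpolation, periodic wrap), average
  over all +1/2 track frames and normalise by the maximum magnitude.
* **Statistics** — d̃_min^±1/2 is the windowed minimum in-plane distance
  (t̃ − t̃_e ∈ [−5.625, 0.625]) between the extruding cell's COM and any
  same-sign defect, over R₀; z̄ averages the extruding cell's
  coordination over t̃ − t̃_e ∈ [−2.5, 0.3125].  The null model is a
  homogeneous Poisson point process at the observed extrusion intensity
  with uniform integer times; five realizations are pooled into one
  sample for the two-sample KS test (per-realization tests are reported
  alongside).  D = sup|ECDF_a − ECDF_b|; the p-value uses the asymptotic
  Kolmogorov distribution at the effective size √(nm/(n+m)), validated
  against an independent reference implementation and calibrated
  (type-I error ≈ 5 % at n = 500).

## What the desk-scale scenarios do and do not show

The synthetic scenarios reproduce the *mechanisms*: passive relaxation
is a strict gradient flow; passive monolayers settle into sixfold
packing; active monolayers nucleate ±1/2 defect pairs with zero total
charge and eject cells that cross the R₀/2 criterion.  With tens of
cells and thousands of steps the *statistics* (d̃_min distributions, z̄
histograms, defect-frame stress asymmetry) carry large sampling error
compared to the reference 36-run, 400-cell ensemble; the acceptance
script therefore reports those statistics at desk scale without claiming
ensemble-level precision.  Real epithelial features outside the model's
scope: proliferation, apoptotic signalling, deformable substrates,
active nematic (dipolar) stresses, and biochemical coupling.

## Numerical conventions and edge cases

* Empty cell fields raise a degenerate-cell error in COM computations;
  detached cells produce masked footprints, and statistics windows with
  no same-sign defects yield missing values (NaN), never zero.
* Normalised stress maps of an all-zero field are zero by convention.
* The extrusion detector emits at most one event per cell.
* All randomness flows from numpy `SeedSequence`/PCG64 streams; a master
  seed spawns per-run and per-module streams (`sweep_seed`) so analysis
  reshuffles never perturb simulation randomness.  Runs are bit-for-bit
  reproducible from their seed.
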