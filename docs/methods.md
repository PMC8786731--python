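# Methods

`trusscage` replaces a patient-specific continuum finite-element model of the
operated lumbar spine with a deliberately small, fully testable surrogate
chain: lumped spinal segments deliver boundary conditions to a beam-FE model
of a trussed interbody cage. This note records the model, its parameters and
units, the calibration choices, the numerics, and what the synthetic setup
can and cannot say about real patients.

Units are fixed package-wide: mm, N, MPa, Nm for moments, degrees at module
interfaces (radians internally), µε (10⁻⁶ strain) for reported strains.
Sign convention: positive sagittal rotations and moments are flexion,
negative extension. Geometry: +x anterior, y medio-lateral (midsagittal
plane y = 0), +z cranial.

## Virtual cohort

`sample_cohort` draws patients independently and uniformly per parameter:
weight 60–74 kg, height 164–172 cm, lumbar lordosis 29–40°, per-disc
Pfirrmann grades II–IV, bone quality 0.6–1.0. The bounds reproduce the
narrow spread of a fusion-eligible subgroup selected for a single cage size;
no joint distribution between parameters is imposed because none is
established for such a subgroup. Bone quality is a dimensionless stand-in
for trabecular density: it rescales the cage–endplate interface modulus
linearly between 0.7× and 1.3× of its nominal value. Lordosis weakly
modulates the extension/flexion stiffness asymmetry (+1 %/° around 34.5°),
encoding that a more lordotic spine resists extension slightly more.

What the generator does **not** emulate: correlated demographics (weight ↔
disc degeneration), vertebral geometry variation (all patients share one
cage and one disc-area scaling), comorbidities, and any longitudinal change.
Consequently patient-to-patient variability downstream is smaller than in
imaging-based cohorts; the package's cohort claims are therefore about the
*ordering* of variability sources (condition ≫ patient), not its magnitude.

## Parametric cage lattice

The as-manufactured cage geometry is proprietary; the stand-in is a regular
trussed box whose claims-relevant features are preserved: slender circular
struts joined at rigid nodes, vertical members and crossing diagonals
spanning caudal→cranial, in-plane chords on both contact faces, and a
posterior screw-insertion block that carries a disproportionate load share.
Defaults: footprint 25 × 10 mm (anterior–posterior × medio-lateral), height
11 mm, pitch 5 mm, strut diameter 0.6 mm, block = posterior 25 % of the
length with struts at 2.5× effective diameter. The outer dimensions are a
documented assumption (typical PLIF envelope); they are config-overridable.
The block is a sub-lattice with enlarged diameter rather than a solid,
keeping everything within the beam formulation. The node grid is symmetric
about y = 0, so the lattice is bilaterally mirror-symmetric by construction;
seeded jitter (default off) is available to break symmetry in robustness
studies. Strut diameter and the block factor are the two defaults that were
calibrated (see Calibration).

## Spine surrogate

Each FSU's moment–rotation map is M(θ) = k₀ · a(θ) · b · sinh(θ/b) with
k₀ = 2.5 Nm/° (healthy flexion stiffness at the origin), shape b = 3°
(stiffening beyond ~3°), and asymmetry a = 0.40 for θ < 0 (extension more
compliant). b = 0 degenerates to the linear map, which the tests exploit.
Pfirrmann grade rescales k₀ by {I: 0.85, II: 1.0, III: 1.2, IV: 1.45,
V: 1.7} — degenerated discs are stiffer — and the swelling pressure by
{I: 1.1, II: 1.0, III: 0.7, IV: 0.45, V: 0.3} — degenerated nuclei
pressurise less.

A prescribed total deflection (±20° by default) is shared by series
equilibrium: one chain moment M such that Σθᵢ(M) equals the target,
solved by bracketing + bisection to |Σθ − target| < 1e-10° (≤ 200
iterations). The instrumented level inverts M = M_FSU(θ) + k_instr·θ, where
k_instr is the rod-construct rotational stiffness: two Ti-6Al-4V rods
(5 mm diameter, free length 28 mm) in the fixed-guided deflection mode,
k = 12EI/L³ each, acting at a 40 mm posterior lever arm (≈ 109 Nm/° total).
The fixed-guided idealisation absorbs screw bending and screw–bone
compliance into one number; it is the single most influential
instrumentation parameter and is exposed in the config. With the defaults
the operated level retains a ~0.1–0.4° rotation share, and chain reaction
moments land at 20–25 Nm in flexion and −8…−10 Nm in extension —
physiological for an instrumented spine that is stiff in flexion.

Follower loads come from a built-in bilinear table over (weight, height),
one table per condition, linear in both variables. The table was calibrated
once so the default cohort hull maps into the physiological ranges
368–454 N (neutral), 748–888 N (extension), 976–1148 N (flexion); queries
outside the hull clamp with a logged warning. No per-level attenuation is
applied: the operated segment receives the condition-level magnitude.

Intradiscal pressure is the undrained short-time superposition
IDP = π_swell·f(grade) + c_u·F/A + c_m·|M|·g(condition), with π_swell =
0.45 MPa, c_u = 0.6, c_m = 0.06 MPa/Nm, g(flexion) = 1, g(extension) =
0.25, and disc area 1700 mm² at 168 cm stature scaled by (height/168)².
The long pre-swelling equilibration of a poroelastic disc is collapsed into
the constant π_swell term because the 5-s load steps are fast against disc
drainage. The coefficients were set once so that a grade-II disc reads
0.45 MPa unloaded and 0.55–0.65 MPa under the neutral follower load (both
inside the physiological 0.4–0.8 MPa band), ~2 MPa in flexion and
~0.9 MPa in extension, and so that IDP in flexion always exceeds extension.

## Cage finite-element model

Two-node 3D Timoshenko beams with circular sections (A = πd²/4,
I = πd⁴/64, J = πd⁴/32, shear factor κ_s = 0.9); shear flexibility via
Φ = 12EI/(κ_s G A L²). Element frames are built from the global z axis
(global x for near-vertical struts). Assembly is sparse; before constraints
the global matrix is symmetric positive semi-definite with exactly six
rigid-body modes (asserted in the tests).

Boundary conditions: the caudal plate is fixed ground; the cranial plate is
a rigid body with one retained degree of freedom (axial translation,
carrying the applied follower-load share) and a prescribed sagittal
rotation; all off-axis plate motions are fixed. Each contact-surface node
couples to its plate through a foundation spring representing the 2-mm
interface layer: k_n = E_layer·A_trib/t normal, k_t = k_n/(2(1+ν_layer))
tangential, with the tributary area A_trib = footprint area / number of
face nodes (conservation-exact). "Hard" two-body contact is thus replaced
by a layer-derived penalty foundation; a bonded mode is provided for
interface-stiffness side studies.

Unilateral contact is an active-set iteration: springs whose normal force
goes tensile are released (normal and tangential together); released
springs are re-admitted on strict penetration. Friction caps the tangential
force at μN (μ = 0.20) by secant scaling of k_t. Because each configuration
is linear, the iteration terminates as soon as the configuration stops
changing; beyond half the 100-iteration budget re-admission is disabled so
the active set shrinks monotonically, which provably breaks
release/re-admit limit cycles at the cost of a slightly conservative
contact area in pathological configurations. Loads ramp linearly and
simultaneously (rotation with force); since the formulation is holonomic
(the final state depends only on the final loads), the default is a single
step and path independence is tested.

The rod construct appears in the cage model as a vertical spring between
the cranial plate (at the posterior lever arm) and ground, with the same
fixed-guided stiffness as in the surrogate — one rod per half-model. Under
flexion the stretched rods pull the plate caudally at the posterior offset,
which both shields the posterior struts and amplifies anterior contact:
this single mechanism produces the anterior strain shift in flexion and the
posterior shift in extension.

Left and right cages are solved as independent mirror-image half-models,
each with half the segment axial force, the full rotation share, and one
rod; under the sagittally symmetric loading this is equivalent to one model
with two cages, and the tests assert left/right coincidence.

Strain recovery: per strut, the axial strain and twist rate come from the
local end displacements, curvatures from the linear internal bending-moment
distribution (κ = M/EI; shear adds deflection, not curvature). Surface
samples at n_axial = 3 stations × n_circ = 8 angles read
ε(s,θ) = ε_m + (d/2)(κ_y sinθ + κ_z cosθ) and γ = (d/2)φ′; the reported
quantity is the absolute maximum principal strain |ε|/2 + √((ε/2)² + (γ/2)²)
with the sign of ε attached. Each sample weighs πdL/(n_axial·n_circ) of
lateral surface, so weights sum exactly to the lattice's lateral area and
thick block struts count proportionally to their surface — by default block
surface is included (config switch to exclude it). Von Mises stress per
sample is √((Eε)² + 3(Gγ)²).

## Metrics

The threshold fraction is the area-weighted percentage of samples with
|strain| strictly above 200 µε ("exceeds": boundary samples do not count).
Histograms use half-open bins on |strain| with default edges
{0, 100, 200, 500} µε and an open final bin; percentages sum to 100 exactly.
Mean caudal contact pressure divides total normal force by the **active**
contact area (matching the contact-pressure semantics of a two-body
formulation; normalisation by nominal area is available in the config).
Cohort variability: CV = sd/mean·100 with the n−1 denominator, computed
across patients within condition and across conditions within patient,
after averaging left/right cages within each patient; a zero mean yields a
logged missing value. The package emits descriptive mean ± 95 % t-intervals
and makes no inferential claims.

## Calibration

Free parameters were fixed once, in this order, and not revisited:
(1) follower-load table and IDP coefficients against the physiological
ranges above; (2) FSU stiffness (k₀, b, a) against instrumented-spine
reaction-moment magnitudes at 20°; (3) strut diameter (0.6 mm) and block
diameter factor (2.5×) so that the default cohort's flexion threshold
fraction lands near the ~30 % headline that motivates trussed-cage designs,
with the rod free length (28 mm) set to a plausible L4-5 posterior height.
With these defaults the cohort run yields a flexion threshold fraction of
≈ 28 %, worst-case mean caudal pressures of ≈ 5 MPa, and peak von Mises
stresses ≈ 225 MPa — far below the ~900 MPa yield of printed Ti-6Al-4V.

## Numerical choices and degenerate inputs

Bisection tolerances: chain moment to 1e-10°, contact settling by exact
configuration repetition, equilibrium asserted to 1e-8 of the applied load.
Zero total rotation short-circuits to M = 0. A linear FSU (b = 0) and a
rigid or absent rod construct are legal limiting cases used by the tests.
Zero-length struts, disconnected lattices, empty or overlapping surface
sets, inverted sampling bounds and non-monotone histogram edges raise
errors; a fully separated caudal face raises a model error rather than
returning a singular solve.

## Known limitations

- Beam kinematics cannot represent sub-millimetre surface features, nodal
  fillets or strut porosity; reported strains are smooth-fiber values.
- The lumped FSU chain has no facet contact, no individual ligaments and no
  fluid flow; its validity is limited to sagittal-plane rotation sharing
  and order-of-magnitude IDP.
- Geometric linearity: no subsidence, no endplate plasticity, no
  screw–bone interface failure, monotonic proportional loading only.
- Cohort variability is bounded below by construction (shared cage and
  geometry scaling), so across-patient CVs are smaller than imaging-based
  cohorts would show; the condition-dominance ordering is the robust claim.
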