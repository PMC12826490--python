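# Methods

## The model

The perivitelline space (PVS) — the thin gap (H = 0.5 µm) between the
oocyte/nurse-cell surface and the overlying follicle cells (FCs) — is
treated as a curved two-dimensional surface, a prolate spheroid with
semi-axes `L_AP(t) = L_E(t)/2` (anterior–posterior, along z) and
`L_DV(t) = W_E(t)/2`. Seven surface-density fields evolve on it:

| species | meaning | lives on |
|---|---|---|
| L | free Gurken (GRK) ligand in the PVS | whole surface |
| R | free EGFR | FC-covered cap |
| C | surface ligand–receptor complexes | FC cap |
| Ci | internalized complexes | FC cap |
| S | dpERK signal | FC cap |
| STY | Sprouty inhibitor | FC cap |
| KEK1 | Kekkon1 inhibitor | FC cap |

The ligand obeys a diffusion equation with the (time-varying)
Laplace–Beltrami operator of the growing surface, a moving secretion source
V(t, x), growth transport, and the binding reactions; the six cell-bound
species obey local kinetics plus growth transport and the tangential
FC-shift advection. Binding is reduced by KEK1 and signal production by STY:

    k̄_on = k_on / (1 + γ_KEK1 · KEK1 / K),
    k̄_s  = k_s  / (1 + γ_STY  · STY  / K′).

The receptor equation implements ligand binding as a *loss* of free
receptor (mass-consistent with the complex equation); the alternative sign
convention is available through `receptor_binding_sign` for comparison.

### Geometry and kinematics

Six staged measurements (3 h = S7 through 19.5 h = S10A) of egg-chamber
length/width, oocyte length/width and columnar-FC extent are interpolated
piecewise-linearly — the minimal assumption for six time points. Because
these are straight (axial-projection) image measurements, the oocyte and FC
domains are *axial caps*, `{z ≥ L_AP − L_O}` and `{z ≥ L_AP − L_FC}`; this
reading is forced by S7, where `L_FC = L_E` while the meridian half-arc is
longer than `L_E`, and the epithelium demonstrably covers the whole chamber.
Meridian arc-length is used for along-surface kinematics and metrics.

Growth is the coordinate-preserving map: a point keeps its angular
coordinates (η, θ) while the semi-axes change. Its velocity field v is what
the transport term ∇·(vP) advects by; discretely the map is realized by
rebuilding the mesh on the new semi-axes (logical node identities preserved)
and multiplying every field by the per-node area-element ratio
(old/new). That dilution factor is the exact conservative form: total mass
is invariant under growth to machine precision.

The nucleus sits at the posterior pole through S7, migrates along the
dorsal meridian (θ = 0) between 7.5 h and the anchoring time (10.5 h, late
S8), and thereafter stays anchored at the dorsal-anterior cortex of the
oocyte, i.e. at the oocyte's anterior boundary as it grows. The migration
ramp is linear in target arc-length; the exact path between S7 and late S8
is not constrained by data, and only its endpoints matter for the signal
because the dorsal stripe of the source trails the nucleus anyway.

The FC shift w is meridional and posterior-directed while the cuboidal→
columnar transition compacts the epithelium: its magnitude is zero at the
posterior pole, linear in meridian arc up to the FC anterior edge, constant
beyond, and scaled so the edge tracks the measured `L_FC(t)` after the
growth map's own drift is subtracted. When `L_FC` covers the whole chamber
(S7–S8) the shift vanishes identically.

### The secretion source

GRK is secreted over a T-shaped support travelling with the nucleus: a
dorsal stripe running posterior from the nucleus (meridian extent =
`ratio_dorsal_length` × oocyte curved length) and a transverse band at the
nucleus (azimuthal extent = `ratio_anterior_width` × half-perimeter; the
stripe's azimuthal width uses `ratio_posterior_width`). The flux profile is
uniform over the support (the measurements delineate a region, not a graded
profile). The stage-resolved ratio values come from source-geometry
measurements that are not reproduced here; the packaged defaults are 0.5
placeholders and should be overridden for production use.

Total secretion is proportional to the oocyte surface area:
`Φ(t) = V0 · A_support(t_ref) · A_oocyte(t) / A_oocyte(t_ref)` with
t_ref = 19.5 h, so `V0` is the per-area flux at the reference stage. Under
a growth stop the oocyte area freezes and the total flux stays constant and
below the unperturbed value. Before the first measured oocyte stage the
oocyte cap is back-extrapolated linearly and floored at 5 µm. Secretion
starts at full amplitude at 3 h (no ramp; the early support is a small
posterior cap, so the early totals are small regardless).

## Discretization

### Mesh

The spheroid is meshed by the cubed-sphere construction: regular grids on
the faces of the inscribed cube (half-side `L_AP/√3`) are projected
radially onto the sphere of radius `L_AP`, then onto the spheroid
orthogonally to the z-axis. This avoids the polar degeneracy of prolate
spheroidal coordinates. The problem is mirror-symmetric about the
dorsal-ventral (y = 0) plane, so only the half-spheroid `y ≥ 0` is
represented — 8 logically rectangular n×n zones (posterior cap, dorsal,
lateral, ventral; anterior mirrors), with interface nodes stored once in a
global node table. Integrals over the half mesh are doubled.

Default resolution n = 32 (≈ 7.8k nodes); recovery experiments run at
n = 16 and the refinement check compares n = 16 against n = 32.

### Operators

The Laplace–Beltrami operator is assembled as a linear (cotangent) finite
element stiffness matrix on the triangulated surface with a lumped mass
matrix. This choice, rather than per-zone metric finite differences, is
deliberate: the stiffness matrix is symmetric with zero row and column
sums, so constants are exactly in the kernel and explicit diffusion
conserves the discrete surface integral to round-off — including across
zone interfaces and at the cube-corner nodes, which need no special
stencil. The y = 0 rim needs no boundary handling: the natural boundary
condition of the element formulation *is* the reflection (Neumann)
condition. Eigenvalue accuracy is second order (measured order ≈ 2.1 on
spherical harmonics between n = 16 and n = 32).

Surface advection (the FC shift) uses a vertex-centered finite-volume
scheme on the median dual mesh with first-order upwinding; fluxes are
antisymmetric per dual face, so transport conserves mass identically. The
scheme's numerical diffusion slightly smooths advected patterns (it biases
the no-shift-versus-wild-type maximum comparison by ~2% at n = 32).
Vector fields handed to the transport operators must be tangent
(`|u·n|/|u| < 1e-8`, enforced).

### Time stepping

Operator splitting with forward Euler, four sub-steps per cycle: ligand
diffusion, growth, FC shift, reactions+source. Geometry (mesh, operators,
masks, source support, shift field) is frozen over an outer geometry step
(default 0.05 h) — the chamber doubles in linear size only over ~16 h, so
this cadence resolves the growth smoothly. Within it, reactions advance at
dt = 5·10⁻⁴ h (safely under the fastest local rate, the initial binding
rate k_on R0 / H ≈ 8·10² hr⁻¹), and diffusion is sub-cycled at the
explicit stability limit dt ≤ 0.9·2/(D·λ_max), with λ_max of the lumped
operator estimated by a warm-started power iteration each geometry step.
Negative values produced by explicit stepping are floored at zero and
counted in the diagnostics (typically a few thousand node-updates per run,
all in the early sharp-source transient). The solver is deterministic;
identical configurations give bit-identical output.

Everything is computed in the measurement units (µm, hr, mol) in double
precision; the nondimensionalization utility (concentrations by R0, lengths
by L_AP(19.5 h)) is provided for working with order-1 variables and
round-trips exactly, but rescaling is not needed for accuracy in float64.

## Parameters

Published point values are used as-is (k_ec = k_off = 6 hr⁻¹, R0 =
6.7·10⁻²² mol µm⁻², k_rec = k_deg = k_d = 2.3 hr⁻¹, V0 = 2·10⁻²¹,
Q_r = 4·10⁻²², k_s = 1 hr⁻¹, H = 0.5 µm). Where the literature gives
ranges, one value is fixed and config-overridable:

- **D = 3,600 µm²/hr** (1 µm²/s): the geometric midpoint of the published
  36–360,000 range and a standard extracellular-morphogen diffusivity.
- **k_on = 6·10²³ mol⁻¹ µm³ hr⁻¹** (decade above the range floor).
- **k_er = 0.6 hr⁻¹**: forced by consistency of the resting receptor level,
  R0 = Q_r/k_er.
- **α_rec = 0.7, α_deg = 0.3** (fractions sum to one; sums ≠ 1 are accepted
  with a warning).
- Inhibitor kinetics k_STY = k_KEK1 = 1 hr⁻¹, k_dSTY = k_dKEK1 = 2.3 hr⁻¹
  (degradation matched to the model's other first-order decay rates).

The inhibitor strengths default to the calibrated values γ_STY = 500·10²
and γ_KEK1 = 10·10². Their normalizations K, K′ are the steady-state
inhibitor scales of the wild-type working point, derived in closed form:
the secreted flux must be disposed by complex degradation, so
Ci_ref = V0/(α_deg·k_deg); the STY feedback then fixes the self-consistent
signal scale S_ref = k_s·Ci_ref/(k_d·(1+γ_STY)); and
K = (k_KEK1/k_dKEK1)·S_ref, K′ = (k_STY/k_dSTY)·S_ref. With this choice γ
is the fold-reduction of the corresponding rate at the working point —
uptake is cut ~(1+γ_KEK1)-fold where the signal is at its typical level,
giving a ligand decay length √(D·(1+γ_KEK1)·H·2(k_ec+k_off)/(k_on·R0·k_ec))
of order 10² µm, the scale of the observed patterns. These normalizations
were fixed from this dimensional argument, not fitted.

## Quantification

- **AP profile**: 100 points along the dorsal midline, anterior →
  posterior; over the full chamber through S8 (cuboidal epithelium), over
  the columnar-FC meridian arc from S9 on.
- **DV profile**: 50 points along the transverse ring 5 µm posterior of the
  nucleus, restricted to the central 30% of the half-ring arc centered on
  the dorsal midline (matching the protocol that discards the artifact-prone
  edges of micrographs).
- **Maximum signal**: the nodal maximum of S over the surface.
- **Elongation**: arc-length of the closed AP meridian ring (dorsal and
  ventral branches through both poles) where S, normalized by the wild-type
  maximum at the same stage, exceeds a threshold (0.6 for the perturbation
  metrics; the threshold is always an explicit argument). The closed-ring
  convention is what makes reported extensions comparable against the full
  meridian circumference; a single dorsal branch is shorter than the
  reported wild-type extension, so the metric cannot live on one branch.
- **Model–data error**: L1 relative error, ∫|sim − ref| / ∫ref by
  trapezoid sums after resampling to the reference positions. Simulated
  curves are put on the data scale by one global factor anchored where the
  wild-type AP S10A curves sit at 20% of the profile length.
- **Calibration**: grid search over (γ_STY, γ_KEK1), scoring each grid
  point by the summed L1 error over three grk dosages (½, 1, 2 × V0), the
  five stages from S8E on, and both axes. Depletion scans compare
  25/50/75% reductions of k_STY (sty) or of R0 and Q_r jointly (egfr)
  against S10A curves.

## Synthetic references

No experimental intensity data ships with the package. The
`synth_reference_curves` generator runs the simulator at nominal "true"
parameters, extracts all profiles, and adds seeded Gaussian noise with
standard deviation expressed as a fraction of each curve's maximum — a
stand-in for stage-averaged immunostaining profiles. It reproduces the
sampling geometry and noise level of such data but none of its systematic
features (border-cell contamination at the dorsal-anterior tip, edge
autofluorescence, fixation losses of unbound ligand); recovery tests
therefore demonstrate identifiability of the feedback strengths under the
model's own assumptions, not robustness to those artifacts.

## Problem sizes and checks

The packaged experiments run the full 3–19.5 h window at n = 32
(perturbation predictions, elongation figures) and n = 16 (calibration and
depletion recovery, 3×3 γ-grid with decade spacing, 20 noise replicates at
5% of curve max). The refinement check compares wild-type elongation
between n = 16 and n = 32 (within 10%). Conservation checks: growth-only
transport and pure diffusion drift below 10⁻⁶ relative per simulated hour
(both are conservative by construction, so the observed drift is
round-off). The local kinetics are validated against an adaptive stiff
integration of the same ODEs to better than 10⁻⁴ over the full window.

## Known limitations

- The source-shape ratios and feedback normalizations are placeholders /
  derived scales, not the unpublished measured values; quantities that
  depend on them (absolute elongations, intensity scale) carry that
  uncertainty, and the simulated wild-type S10A gradient is somewhat
  flatter than the reported one (the 0.6-threshold band nearly fills the
  FC cap).
- First-order upwinding makes the FC-shift sub-step diffusive; patterns
  advected over many hours smear by a few mesh cells.
- The stretched-cell region is simply receptor-free; partial receptor
  density there is untested biology.
- Border cells are outside the model's scope, as is the microtubule
  dependence of grk mRNA localization (the nucleus-stop perturbation
  assumes localized translation persists at the posterior).
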