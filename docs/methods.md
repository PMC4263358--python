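# Methods

## Model

**CG-DNA.** Each base pair is one pseudo-residue: a pseudo-backbone bead PB
on the helix axis and a pseudo-phosphate bead PP at the B-DNA phosphate
radius 8.973 Å, carrying the −2e of the two nucleotides it represents.
Consecutive PB beads are 3.38 Å apart; the PP azimuth advances 36° per
residue (33.8 Å pitch, right-handed).  Bonded terms are harmonic in the
½·k·Δ² convention: bonds PP–PB (k = 100 k_BT/r₀², r₀ = 8.973 Å) and PB–PB
(k = 100 k_BT/r₀², r₀ = 3.38 Å); angles PP(α)–PB(α)–PB(α+1) and
PB(α)–PB(α+1)–PP(α+1) (k = 100 kcal/mol, θ₀ = 90°); backbone bending
PB(α−1)–PB(α)–PB(α+1) (k = 87.7 kcal/mol); torsion
PP(α)–PB(α)–PB(α+1)–PP(α+1) (k = 131.6 kcal/mol, φ₀ = +36°).

The backbone equilibrium angle uses the straight-chain convention
θ₀ = 180°, under which the ideal helical build is the exact energy minimum
(total bonded energy 0) and the bending stiffness maps onto the worm-like
chain as Lp = k·b/k_BT = 87.7·3.38/0.59248 ≈ 500 Å, the B-DNA value.  A
printed parameter source gives 32.7° for this angle; that value is
incompatible with a straight ground state and with the 50 nm persistence
length, so we treat it as an erratum.  It remains available through
`build_dna(..., backbone_theta0_deg=32.7)` for exact-replication runs.

Note a genuine subtlety: the *full* bonded chain (with phosphates) is
measurably stiffer than the backbone term alone.  Bending in the plane of
the local phosphate forces the two 90° phosphate angles off their minima by
±δ/2, adding ≈ 2·½·100·(δ/2)² = 25δ² to the ½·87.7·δ² backbone cost; with
the helical rotation of the anisotropy axis this yields Lp ≈ 610 Å
(anisotropic-WLC estimate), and pivot-MC sampling of the full chain indeed
measures ≈ 600 Å.  The quoted 500 Å is the property of the named backbone
stiffness; the persistence-length acceptance measurement therefore samples
the PB backbone chain, and a separate test asserts the full-model
stiffening.

**CG-protein.** Three beads: a body bead PBP (excluded-volume radius
27.6 Å, Stokes radius 30/40/50 Å, neutral) and two DNA-binding beads DBP
(radius 6 Å, Stokes radius 8 Å, charge q(DBP), the binding-affinity knob).
The DBP pair is spaced exactly one pitch (33.8 Å) so both beads share one
helix phase; the PBP sits at sqrt(41.59² − 16.9²) ≈ 38 Å from the DBP line,
closing both 41.59 Å bonds exactly and placing the docked PBP ≈ 47 Å off
the DNA axis.  All three protein bonds have k = 1 kcal/mol/Å².

**Nonbonded terms.** Excluded volume is half-harmonic,
½·k_ex·(σ_i+σ_j−r)² below contact with k_ex = 1 kcal/mol/Å².
Electrostatics is a screened Yukawa form

V(r) = (C/ε)·q_i q_j·f_ij·e^{−κr}/r,  C = 332.06 kcal·Å/mol, ε = 78.5,
κ⁻¹ = 7.8 Å (0.15 M 1:1 salt),

truncated at 40 Å (plain truncation; the discontinuity at the cutoff is
≤ ~1e-3 kcal/mol for the largest charge products used).  Pairs within the
same molecule separated by ≤ 4 pseudo-residues are excluded — exactly the
exclusion that makes the ideal helix strain-free (the nearest included
intra-DNA PP pair, |Δα| = 5, sits just outside its 20.8 Å contact).
Intermolecular pairs always interact.

The finite-ion-size factor f_ij is selectable: bare screening (f = 1), the
per-sphere DLVO product [e^{κa_i}/(1+κa_i)][e^{κa_j}/(1+κa_j)], or a single
DLVO factor at the pair effective radius ā = sqrt((a_i²+a_j²)/2) (the same
ā used in the hydrodynamic tensor).  The default is the ā form: calibrating
against the model's reference binding-affinity scale (ΔG ≈ 5.7 kcal/mol at
q(DBP) = 8 and ≈ 30 kcal/mol at q(DBP) = 20 on restrained DNA), the
per-sphere product is uniformly ~1.4× too strong and bare screening far too
weak, while the ā form tracks the scale across the whole charge range.
Units throughout: Å, kcal/mol, e; k_BT = 0.59248 kcal/mol at 298 K.

## Hydrodynamics

The grand diffusion matrix uses the Rotne–Prager–Yamakawa tensor
(divergence-free, positive definite).  For overlapping pairs of unequal
radii the equal-sphere overlap form is evaluated at ā = sqrt((a_i²+a_j²)/2);
the branch switches at r = a_i + a_j.  η = 0.89 cP and T = 298 K give
k_BT/6πη ≈ 245.4 Å³/ns, so a 20 Å bead diffuses at 12.3 Å²/ns.  Three
modes: `full_hi`, `intra_hi` (inter-molecule blocks zeroed — isolates the
effect of protein–DNA hydrodynamic coupling) and `free_draining`.

## Brownian dynamics

Predictor–corrector (second-order Runge–Kutta) overdamped integration with
Δt = 0.25 ps: the predictor displaces by (Δt/k_BT)·D·F(x) + S with
S ~ N(0, 2DΔt); the corrector replaces the drift with the average of the
predictor and corrected forces, reusing the same S and the same D.  D and
its Cholesky factor refresh every 200 steps.  ∇·D is not required (RPY is
divergence-free).  Boundaries are open (no container).  DNA treatments:
`restrained` (every DNA bead anchored, k_r = 1 kcal/mol/Å²) and `flexible`
(only the two terminal residues at each end anchored, k_r = 0.01).  A
per-step displacement sanity bound (default 5 Å) aborts diverging runs with
the trajectory retained.  Identical seeds give bit-identical trajectories.

## Umbrella sampling and WHAM

Reaction coordinate: 3D distance between the PBP and the PB bead nearest
the DNA centre, with the PBP confined to that bead's Z-plane (k = 1
kcal/mol/Å²); windows r₀ = 90…31 Å in 1 Å steps, k_umb = 5 kcal/mol/Å²,
DNA fully restrained.  Windows may be sampled by BD or by a Metropolis
sampler on the identical potential — equilibrium averages do not depend on
the mobility matrix, so the MC route is the fast path for free energies.
The MC move set combines single-bead displacements, rigid protein
translations, rigid rotations about the PBP, and rigid rotations about the
DNA axis; the latter two are essential, otherwise window continuation
under-samples the bound-state orientation/registry and biases the well.
Contact windows (r₀ ≤ 48 Å) are re-seeded from the docked build geometry.

WHAM iterates the standard self-consistent equations to a window-offset
tolerance of 1e-6 kcal/mol on 0.5 Å bins (both configurable); bins with
fewer than 5 counts are masked.  The binding free energy is the mean PMF
over the 80–90 Å plateau minus the PMF minimum, with no standard-state
volume correction (the number is the well depth of this confined geometry;
a Boltzmann-integrated well-depth estimator is provided for comparison and
runs ~1–2 kcal/mol deeper due to well-width entropy).  Errors come from
independent repeats.

## Rigid-particle theory

The bead friction matrix (inverse grand RPY mobility) is summed into the
6×6 rigid-body resistance and inverted; the centre of diffusion is the
point where the rotation–translation coupling is symmetric (equivalently,
minimal translational trace), located in closed form from the rotational
and coupling blocks.  D_T is the orientation average trace(D_tt)/3 there,
converted to a_T = k_BT/(6πη·D_T); D_R likewise with a_R³ = k_BT/(8πη·D_R).
The beads are translational point mobilities: rotational friction of the
assembly arises purely from constrained bead translation, with no per-bead
spin term.  This convention reproduces the reference rotational radii
(a_R ≈ 20.4–20.7 Å for all body sizes); the classical volume correction
(8πη·a³ per bead, needed for the single-sphere limit a_R = a and for
collinear assemblies) is available as `include_bead_rotation=True`.
R_OC is the distance of the docked centre of diffusion from the DNA axis:
the phosphate radius plus the body-frame offset.

## Scales used in stochastic measurements

The persistence-length measurement samples a 200-residue backbone chain by
pivot + local-move Metropolis MC (~600 decorrelated conformations) and fits
tangent correlations over lags 1–30 excluding 5 residues at each end.  The
binding-free-energy measurement uses a 60-bp DNA segment (the 40 Å cutoff
makes longer DNA irrelevant to both the bound well and the 80–90 Å
plateau), 60 windows with (1500–2000 equilibration + 7000–10000 production)
sweeps, and a frozen-DNA equilibrium sampler; restrained-DNA fluctuations
shift ΔG by ≲ 0.4 kcal/mol (measured), within the repeat spread.

HI-effect comparisons need care at reduced scale: at q(DBP) = 20 sliding is
activated hopping between helix-registry sites with ~100 ns waiting times,
so equilibrium D₁D only converges over tens of microseconds (short
trajectories show intra-well rattle, whose short-lag apparent D is an
order of magnitude above the sliding diffusivity, and saturated long-lag
MSDs).  The desk-scale comparison therefore measures the sliding *mobility*
instead: drift velocity of the protein (relative to the DNA centre) under
a weak constant axial force (0.25 kcal/mol/Å per protein bead) on a 40-bp
system over 75 ns, matched seeds across conditions.  Full-HI and intra-HI
runs share identical energetics and differ only in the mobility matrix, so
their velocity ratio equals the diffusivity ratio (Einstein relation); the
DNA-flexibility comparison keeps its usual interpretation.  Orderings and
the inter-HI reduction fraction are asserted on these drift velocities —
full-scale (25 µs, 10-replica) coefficients are outside desk scale by
design.

## What the synthetic conditions do and do not show

All inputs are the model's own parameter tables; there is no external data.
Sequence dependence (all PP identical), protein internal flexibility,
near-field hydrodynamics (lubrication), and crowding are outside the model,
so passing tests validate the implementation of this idealised model and
its agreement with helical-sliding hydrodynamic theory — not predictions
for any specific protein.  The Yukawa charge q(DBP) is an effective
parameter calibrated through the binding free energy, not a structural
charge.

## Numerical choices

Angle forces use a guarded small-sine branch (the straight-backbone
equilibrium has vanishing prefactor there); dihedral gradients are the
standard analytic form validated against central differences to < 1e-5
kcal/mol/Å.  The Cholesky factorisation failure of a non-PD matrix raises
with the minimum eigenvalue reported.  WHAM bins, tolerance and the MC step
sizes (0.45 Å displacements, 0.08–0.10 rad rotations, ~60% acceptance) are
configurable defaults.  All RNG flows from explicit integer seeds; one
stream per replica, seeded as base·k + replica index.
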