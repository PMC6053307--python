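# Methods

`mtshell` simulates the mechanical response of two biological filaments held
between optically trapped beads — the microtubule, modeled as a discrete
orthotropic cylindrical shell, and the straight bacterial flagellum, modeled
as a 1D elastic chain — and provides the measurement-chain emulation and
fitting machinery needed to extract elastic moduli from force–strain curves.

## Models

### 1D chain (flagellum)

N point masses along the filament axis, spacing l0 = L/(N−1), connected by
harmonic springs V = ½k(l−l0)² and by angle springs V = ½κ(φ−π)² on every
interior triplet.  κ maps to the flexural rigidity as κ = B·N/L, so the
continuum limit of the chain is an Euler–Bernoulli rod of rigidity B.  The
stretch constant k is a numerical inextensibility constraint, set to 10³ ×
κ/l0² (the bending-derived stiffness scale); its strain energy is audited in
the tests to stay below 1 % of the bending energy.  N is a convergence
parameter: the post-buckling force of a pinned, centerline-loaded chain
approaches π²B/L² from above as N grows (within 10 % by N ≈ 24 at L = 4.1 µm,
within ~3 % by N = 64).

### 3D spring-network shell (microtubule)

A planar spring network wrapped into a cylinder: Nr = round(L/d)+1 rings of
Np = 10 particles (one per protofilament) at radius R = 12 nm, axial spacing
d (8 nm at production fidelity — the tubulin dimer repeat — 16–32 nm for
coarse runs), circumferential spacing p = 2R sin(π/Np).  Typed harmonic
interactions: axial and circumferential stretch springs (ka, kc), axial bend
triplets (κa, rest angle π), circumferential bend triplets (κc, rest angle =
the regular-decagon interior angle 144°), and shear triplets (κs, rest angle
π/2) — one for every (axial arm, circumferential arm) pair at each particle,
i.e. four per interior particle.  Energies are reported per channel, which
the observables rely on (see "modified force").

The map from the macroscopic orthotropic-shell moduli (Ea, Ec, G; wall
stretching thickness h = 2.7 nm, wall bending thickness h0 = 1.6 nm, with
Poisson terms neglected) to the spring constants is the thin-shell relation

    ka = Ea·h·p/d     κa = Ea·h0³·p/(6d)
    kc = Ec·h·d/p     κc = Ec·h0³·d/(6p)
    κs = 2·G·h·p·d

times a per-channel dimensionless correction factor.  The corrections are
needed because the prefactors of those formulas are not exact for a coarse
10-particle ring, and are determined by energy matching: impose a canonical
homogeneous deformation (uniform axial strain, uniform inflation, a
circular-arc centerline, the inextensional n = 2 ovalization mode, a uniform
twist) on a short test lattice and set the factor so the discrete channel
energy equals the continuum orthotropic-shell energy of the same deformation
(membrane density E·h/2·ε², wall bending density E·h0³/12·Δκ², shear density
G·h/2·γ²).  Comparing each channel over the axial extent its interactions
actually tile makes the factors intensive — independent of lattice length
and of the moduli, exactly.  For the decagon they evaluate to ≈1.0166
(stretch channels; the perimeter ratio 2πR/(Np·p)), ≈0.5083 (axial bend),
≈0.641 (circumferential bend), ≈0.1405 (shear; absorbs both the κs prefactor
convention and the 4-triplet multiplicity).  The choice of the κs prefactor
convention (we read it as 2·G·h·p·d) is therefore immaterial.

Two deliberate consequences of this discretization are worth stating.
First, under beam bending the shear triplets acquire first-order angle
changes (of order d·c/2 per ring), so the shear channel contributes an
unphysical, d²-dependent extra bending stiffness when G is large.  This is
why the critical-moment observable uses the *modified force* — the
derivative of all energies except shear — mirroring the way the shear
channel is excluded from the continuum Brazier comparison.  Second, the
orthotropic shell has no energy penalty for in-plane shearing of the
cross-section; the resulting marginal out-of-plane mode is suppressed by a
stiff harmonic penalty on each ring-centroid z-coordinate (stiffness
10²·ka), which fixes the buckling plane to x–y while leaving within-ring z
motion (ovalization, kinking) entirely free.  The penalty energy remains at
round-off level in symmetric runs and is excluded from physical observables.

### Beads

Each optical bead is one particle tethered to a single surface particle
(azimuth 0, same protofilament at both ends) by a stiff spring of rest
length b = 500 nm plus a stiff angle constraint keeping the tether normal to
the local filament axis.  Both constraint constants are 10³ × the stiffest
physical constant of their kind.  Because the trap holds the bead's position
but not its orientation, the filament–bead assembly retains a soft
pendulum-like compliance: small compressions are first absorbed by tether
pivoting plus gentle filament bending, which is why measured force–strain
curves rise smoothly from zero rather than exhibiting a sharp Euler
threshold.  The single-particle tether also imprints a local, non-Brazier
ring distortion on the few rings next to each attachment (the reaction
couple F·b is carried by two particles d apart); observables that look for
kinks therefore exclude a 5 % arclength margin at either end.

## Quasistatic protocol

The anchor bead (detection trap) is fixed; the drive bead (manipulation
trap) moves along the trap axis in small increments, and the network is
relaxed to mechanical equilibrium after every move.  The convergence
contract is a force balance: max residual force per free particle ≤ 10⁻³ pN
(two orders below the pN-scale measured forces); halving the tolerance
changes reported forces by less than the noise floor.  The measured force is
the axial component of the constraint force on the anchor bead, positive in
compression.  Quasistatic adequacy is certified by the forward/backward
hysteresis gap being < 2 % of peak force before any kink; after a kink,
hysteresis is expected and physical.  Optional seeded Langevin kicks
(`thermal` flag) let the low-strain persistence of post-kink hysteresis be
annealed away; they are off by default.

Relaxation is a damped Newton minimizer with the exact sparse Hessian
(pair-spring blocks analytic; angle-triplet blocks by central finite
differences of the per-triplet analytic gradient; Levenberg-style diagonal
shift with strict energy decrease so the solver can never settle on a
saddle).  This replaces explicit overdamped integration — whose friction
constant only sets the relaxation clock τ ∼ γL⁴/B, not the equilibria — and
is validated by the same no-hysteresis criterion.  Continuation across a
protocol uses a secant predictor (the previous relaxed displacement,
rescaled to the upcoming step) except across collapse events, where
extrapolating a several-hundred-nm kink displacement would wreck the
geometry; steps whose displacement exceeds 150 nm start from the plain warm
start.  For centerline-loaded (pinned) configurations, which cross a true
bifurcation, an optional stability check computes the lowest Hessian
eigenmode after convergence and kicks along it until a genuine minimum is
reached.

The compression driver adapts its step to the solver effort: it ramps in at
5 nm (the early pivot/bow branch is strongly nonlinear), grows geometrically
to 40 nm while continuation is cheap, and refines to 8 nm once the interior
flatness exceeds a third of the kink threshold (e ≈ 0.1).  The early
refinement matters: the pre-kink branch develops curvature localization,
and coarse continuation through that window can hop onto a prematurely
localized branch whose onset curvature disagrees with the smooth
beam-amplitude estimate.  All steps are within the 2–20 nm experimental
range except the mid-branch coarse steps, which the no-hysteresis and
step-halving checks justify.  A kink is declared at a step-to-step force
drop > 1 % combined with an interior flatness spike: a local maximum of e
exceeding max(0.3, 3× the median e), outside 5 % end margins.

## Observables

Strain ε = (db − L)/L on bead separation.  Flatness e = (R − a)/R per ring,
with the semi-minor axis a estimated by projecting the ring onto the plane
normal to the local centerline tangent and taking the minor half-axis of the
second-moment (equal-area) ellipse, a = √(2·λ_min) — exact for points
uniformly spaced in angle, robust for 10 points.  A collapsed (collinear)
ring reports e = 1 with a degeneracy flag.  Centerline curvature is the
turning angle at each ring centroid divided by the mean adjacent segment
length.

The critical bending moment observed in simulation is MB = F_mod × w, where
F_mod is the shear-agnostic modified force and w the filament's maximum
deflection: the largest perpendicular distance of a ring centroid from the
chord joining the end centroids, i.e. the displacement the centerline has
acquired relative to its rest shape.  (The alternative reading — distance
from the bead-bead line — adds the constant R + b ≈ 0.5 µm offset to the
lever arm and systematically inflates MB; the deflection reading is both
the literal meaning of a displacement and the one whose values match the
experimental MB range.)  Both are
evaluated at the *onset* of the first kink — the last relaxed state before
the force drop — with a backward difference for F_mod, so no post-collapse
energies enter; after the drop the profile is dominated by the localized
spike and the smooth-state moment is no longer defined.  The same onset
state provides the simulated critical curvature; its analytic counterpart is
MB/B.  The thin-shell prediction is MB = h²R√(Ea·Ec) (times 2√2π/9 ≈ 0.987
in the isotropic limit).  The plateau onset is the compressive strain at
which the local slope dF/d|ε| first stays below 10 % of the initial linear
slope for two consecutive grid points.

## Synthetic experiments

No public raw data exists for this experiment class, so the generator
emulates the measurement chain: trap steps of 5 nm (experimental range
2–20 nm) every 0.75 s, QPD sampling at 100 kHz averaged ×1000 to an
effective 100 Hz (75 samples per dwell), force = trap stiffness × bead
displacement with ko = 0.05 pN/nm per trap (typical for ~1 µm silica beads
at moderate power), white Gaussian force noise of 0.1 pN per 100 Hz sample
with an equal-amplitude zero-mean perpendicular component, and ≥ 2
forward/backward cycles.  Bead separation follows trap separation
self-consistently through db = dt + F·(1/ko_d + 1/ko_m).  What the generator
does *not* emulate: colored QPD noise spectra, trap anharmonicity,
bead-attachment compliance or failure, drift, and filament heterogeneity —
so passing recovery tests demonstrates correctness of the pipeline, not
robustness to every instrumental artifact.  All randomness flows from one
mandatory seed; bundled fixtures regenerate byte-identically.

## Fitting

Preprocessing follows the experimental procedure exactly: project samples
onto the trap axis, bin by trap separation, pool over time and runs, convert
to bead separation, locate the equilibrium length at the |F| minimum
(parabolic refinement; a boundary minimum is flagged).  The objective is
Σ[(F_sim − F_mean)/max(std, 0.02 pN)]² on the measured strain grid, with
simulated curves interpolated by monotone cubic (PCHIP).  The 1D fit is a
log-grid scan plus bounded golden-section over B with a 1σ interval from the
local χ² curvature; the 3D fit is Nelder–Mead over log(Ea, Ec, G) within
bounds (Ea ∈ [0.1, 5] GPa, Ec ∈ [0.5, 100] MPa, G ∈ [0.1, 20] GPa) from a
coarse grid start, with per-point curve caching and calibration factors
computed once per geometry.  A curve that never leaves the linear regime
triggers an Ec identifiability warning, since the plateau position is what
pins Ec down.

## Problem sizes and numerical defaults

Headline shell runs use d = 16 nm (so an 8.3 µm filament is 520 rings, 5202
particles) — coarse enough for minute-scale runs, fine enough that the kink
physics is resolved; d = 8 nm reproduces the same phenomenology at higher
cost.  Fit simulations and recovery tests use shorter filaments (1–2 µm) and
d = 24–32 nm with the calibration re-run per d.  Tolerances: relaxation
10⁻³ pN; kink force-drop 1 %; flatness threshold 0.2–0.3 with a 3× median
rule for spikes; fit objective floor 0.02 pN.

## Known limitations

* The shear channel's spurious d²-bending stiffness means measured (total)
  forces at coarse d overestimate the d = 8 nm model when G is large; the
  shear-agnostic modified force and the calibration keep the headline
  observables meaningful, but fitted G at coarse d partially absorbs the
  artifact.
* Kinking is a subcritical collapse; the exact kink strain depends weakly on
  the continuation step near the transition (the post-collapse state does
  not).  Forward/backward hysteresis after kinks is physical in this model
  class, and the low-strain persistence seen without thermal kicks is a
  lattice-trapping artifact, reproduced here as in the original simulations.
* No bond breaking, no thermal sampling, no 13-protofilament or mixed
  lattices, no α/β-tubulin distinction, no polymorphic flagellar states.
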