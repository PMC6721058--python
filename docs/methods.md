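# Methods

## Model

The joint is a planar elastostatic multibody system.  A fixed basis (the
tibia–fibula segment, TFS) and a moving body (the talus–calcaneus segment,
TCS) interact through six tension-only exponential cables (the ligaments
ATT, TC, PTT, ATF, CF, PTF) and Hertzian sphere–sphere cartilage contact.
The configuration variables are the rotation θ (radians, counter-clockwise
positive) and the moving-frame origin **p** (mm, basis frame).  Statics
only: no inertia, damping, muscle forces, friction or ligament wrapping.

Units are mm / N / N·mm internally.  At the I/O boundary external moments
are N·m (×1000 on entry) and angles are degrees.  All internal moments are
taken about the basis-frame origin; since the force balance holds at
equilibrium, the choice of moment reference does not move the solution set.

### Ligament force laws

Two variants of the exponential cable law ship behind
`force_model`:

* `exp_shifted` (default): F = A·exp(B·ε − 1) for ε > 0, else 0.  This is
  the law exactly as usually typeset.  It is **discontinuous at
  activation**: the tension jumps from 0 to A/e as ε crosses 0⁺.
* `exp_minus_one`: F = A·(exp(B·ε) − 1), the classical continuous
  exponential ligament law.

The package deliberately implements both and defaults to the shifted form
rather than silently "fixing" it.  The discontinuity has real mechanical
consequences (below); we believe the shifted form is a typographical
artefact of the classical law, and the package's own behaviour furnishes
the evidence: under the shifted law isolated intervals of external moment
provably admit no equilibrium at all, something no physical joint exhibits.

Both laws are conservative.  Closed-form elastic potentials
(A·l_s/B·(e^{Bε−1} − e^{−1}) and A·l_s·((e^{Bε}−1)/B − ε) above slack,
zero below) power the energy diagnostics.  Exponents are capped at 500
so absurd solver trial states produce huge finite forces instead of inf.

### Contact

Conforming (internal) sphere–sphere contact: female radius r_a (concave
tibial plafond, center fixed in the basis), male radius r_b < r_a (talar
dome, center fixed in the moving body), both radii stored positive;
femaleness is structural, not a sign convention.  Penetration
δ = |O_b − O_a| + r_b − r_a is positive when the male surface passes beyond
the female surface — for internal contact the centers *separate* as the
joint loads.  Generalized stiffness K = 2E/(3(1−ν²))·√(r_a r_b/(r_a−r_b))
(N/mm^1.5), force K·δ^{3/2}, applied at O_b + n̂(r_b + δ/2) ("half the
penetration"; for extreme δ this point can leave the overlap zone — the
moment is unaffected because the point slides along the line of action).
The two anatomical pairs sit symmetrically in the frontal plane and project
onto the same sagittal location, so one record with `multiplicity=2`
represents both; listing two identical records is exactly equivalent
(tested to 1e-10 on solved equilibria).  Contact potential
(2/5)K·δ^{5/2} per pair.

### Equilibrium solver

The residual stacks (ΣFx [N], ΣFy [N], ΣM [N·m]).  A solution is accepted
when the **sum of absolute components** falls below 1e-10 (configurable;
an l2 convention is also available and is recorded in the config and
output metadata).  The mixed N / N·m scaling makes the tolerance
meaningful at both scales for a newton-and-millimetre-sized joint.

Levenberg–Marquardt (scipy `least_squares`, finite-difference Jacobian,
tolerances 1e-15) with up to 8 deterministic jittered restarts (seeded;
the seed lives in the solver settings).  Non-convergence is reported as a
flagged result, never silently.  Because the residual is 2π-periodic in θ,
a solved angle is wrapped back into (−π, π).

Moment sweeps proceed outward from zero load with warm starting
(continuation).  Two guards handle the shifted law's kinks:

* the first step of each branch is nudged 0.01 rad in the direction the
  moment will rotate the body.  At the all-slack neutral pose every cable
  sits exactly at its activation kink, where a finite-difference Jacobian
  measures the jump, not a slope, and LM can fly to a spurious distant
  equilibrium (statics is not unique: a hyper-rotated configuration with
  re-tightened cables also balances).
* a converged step more than 0.35 rad from its warm start is treated as a
  basin jump; the segment is re-walked with bisection load substeps and,
  near kinks, jittered restarts that prefer the *nearest* converged
  equilibrium.  If no equilibrium exists in the basin the step is honestly
  flagged and the branch aborts (partial table).

Warm- and cold-started sweeps agree to ~1e-13 on the default fixture; the
package reports the equilibrium reached by continuation and documents that
other equilibria can exist.

### No-equilibrium gaps under the shifted law

Each activation jump of a cable removes an interval of statically
attainable external moment.  On the default fixture: near neutral the
plantar side has no equilibrium below ≈0.006 N·m and the dorsal side below
≈0.010 N·m; the re-crossings of the near-isometric cables (CF, ATF, PTF)
carve further gaps of ~0.003–0.007 N·m width in mid-branch.  Consequences:

* the ±0.20 N·m, 51-step protocol (`sim1`) has its smallest steps
  (±0.008 N·m) inside the neutral gap: under the default law the sweep is
  honestly partial.  Under `exp_minus_one` it converges at all 51 points
  (dorsiflexion 7.5°, plantarflexion 10.6°).
* the ±5 N·m protocols (51 and 101 steps) converge at every grid point
  under both laws; the default geometry was checked against a fine
  moment–angle scan so that no gap contains a protocol grid point.
* the PTT sensitivity variant (`sim3`, +1 mm on the PTT basis attachment,
  slack deliberately not recomputed) has *no unloaded equilibrium* under
  the shifted law — its rest pose pins ATF inside the activation jump —
  so the M=0 row is flagged and both load branches complete.  Under the
  continuous law sim3 converges everywhere.

## The synthetic fixture

The published anatomical geometry exists only as figures, so
`default_ankle_fixture()` generates a deterministic stand-in with the same
topology and the same material defaults (cartilage E = 10.00 MPa,
ν = 0.46).  Frame conventions: basis origin at the female sphere center,
moving origin at the male center at neutral, anterior = −x (a right ankle
viewed medially) so that positive external moment = plantarflexion = +θ.
Radii 22/20 mm; slack lengths computed at neutral; zero contact penetration
at neutral by default, so the unloaded neutral pose is an exact
equilibrium.  A `contact_preload` option instead starts the joint mildly
compressed, covering the alternative reading in which the cartilage is
active at rest (the rest pose then shifts slightly off neutral).

Attachments and coefficients were chosen once, by design, so the fixture
exhibits the physiology the model is meant to show: TC and CF run almost
through the joint center (near-isometric, mean |strain| ≈ 4% over the ±5
N·m sweep vs ≈ 18% for ATT/PTT); ATT restrains plantarflexion and PTT
dorsiflexion with ~12–15 mm moment arms; ATF/PTF are short, nearly
horizontal and contribute little; A = 0.5–2.2 N with B = 15–55 give peak
ligament and contact forces of ~530–620 N at 5 N·m, ranges of 37.8°
(plantar) / 31.0° (dorsal), and an 8–9.5× secant-stiffness ramp between
0.2 and 5 N·m.  Keeping A small also keeps the shifted law's activation
jumps (A/e) small, which is what keeps the protocol grids clear of the
no-equilibrium gaps.

What the fixture does **not** emulate: real attachment scatter, curved
ligament paths, fiber bundles, cartilage layers of varying thickness, or
the authors' atlas-derived coordinates.  Passing tests therefore validate
the mechanics, the solver and the fitting machinery — not anatomical
accuracy of any particular ankle.

## Ligament fine-tuning

`synthetic_ligament3d` builds straight 3-D cables whose axis makes a
prescribed angle with the sagittal plane (0° = in-plane; an ATF-like,
nearly frontal cable is 90° − 2.19° off the plane).  `project_to_sagittal`
drops z from both attachments and recomputes the slack length in-plane at
neutral.  The displacement protocol translates the moving segment ±4 mm
along y and along x (four cases, no rotation), applied identically to the
3-D cable and its projection.  One residual per displacement:

    res_j(A, B) = F_2D(A, B, ε_2D,j) − F_3D/sag,j

where F_2D includes the slack branch (zero force at ε ≤ 0; the residual
system as commonly written omits this, which would let slack displacements
contribute negative "forces").  `fit_material_params` minimizes the sum of
squares with trust-region least squares bounded to A ≥ 0, B > 0, starting
from the 3-D coefficients; it is deterministic given the initial guess.
Problems in which no displacement activates the planar cable are flagged
unfittable rather than fitted.

Identifiability drives the test generator's choices: in-plane angles are
drawn from 55–80° so the ±x and ±y displacements yield two well-separated
active strains (at exactly 45° the two active residuals coincide and (A, B)
degenerate to a curve).  Moderately oblique cables activate only two of the
four planar strains, so the 2-parameter fit is *exactly* solvable (residual
≈ 1e-16); strongly oblique, near-frontal cables activate all four and leave
a genuinely irreducible residual.  For this reason the grid-search oracle
is asserted one-sided — the fit must come within 1% of (or beat) the grid
minimum — since no finite grid can match an exact zero to relative
precision.  Refitting with ±2 mm instead of ±4 mm changes the fitted
coefficients for oblique cables (documented by test, not asserted to any
value): smaller displacements leave near-frontal cables barely active.

## Numerical choices

* Solver tolerances at 1e-15 (just above machine epsilon); the residual
  noise floor on the default fixture is ~1e-13 in the summed norm.
* Finite-difference energy oracle: central differences with h = 1e-6 along
  the three rigid-body motions (rotation about the basis origin — the
  motion conjugate to the moment-about-origin convention — and the two
  translations); worst relative error ~1e-7 over 1000 random states.
* Degenerate inputs: coincident attachments raise a geometry error;
  r_a ≤ r_b is rejected at construction and at config load; strain exactly
  0 is inactive; concentric contact centers are simply inactive.
* Ties/non-uniqueness: sweeps report the continuation branch; the
  continuity limit (0.35 rad) defines "same branch".

## Known limitations

* Under the default (shifted) force law, external moments inside an
  activation gap have no equilibrium; the solver reports this honestly but
  cannot conjure a solution.  Use `exp_minus_one` for sweeps into the
  millinewton-metre regime.
* The fitting protocol is the fixed four-translation scheme; per-ligament
  protocols and richer force laws are out of scope.
* Sweeps assume pure moment loads; combined force-moment sweeps work
  through `solve_equilibrium` but the energy-minimum diagnostic
  Pi = U − F·p − M·θ is stationary at equilibria only for pure moments
  (with a force the moment-about-origin convention contributes an extra
  p × F term).
* 2-D statics only: no out-of-plane motion, no dynamics.
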