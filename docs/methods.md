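# Methods

`planarsts` predicts sit-to-stand (STS) movements by optimizing open-loop
muscle excitations on a planar musculoskeletal model, and diagnoses
strength-related STS failure by tracking reference motions with reserve
actuators. This note documents the model, the numerical choices, the
defaults and their rationale, and what the synthetic test conditions do and
do not show about real movement data.

## The skeletal model

The body is a sagittal-plane chain of three rigid segments — shank, thigh,
and a head-arms-trunk (HAT) segment — standing on a foot welded to the
ground. The three degrees of freedom are ankle, knee and hip rotations,
flexion-positive, zero in the upright posture. Everything above the pelvis
(trunk, head, both arms) plus the contralateral leg is lumped into the HAT
segment so that the segment masses plus the welded foot add up to the full
75 kg body mass of a 1.70 m adult male; lengths, COM offsets and inertias
follow standard segment-inertia fractions scaled to that stature. A locked
lumbar angle of −10° is carried as metadata only.

In absolute segment angles `phi = W q` the chain is the classic n-link
pendulum, so the equations of motion have an exact closed form: each
segment's COM is a fixed linear combination of unit vectors
`u(phi_j + δ_ij)` (the phase offsets δ carry anterior COM components),
giving

    M_abs[j,k] = Σ_i m_i a_ij a_ik cos(ψ_ij − ψ_ik) + δ_jk I_j
    h_abs[j]   = Σ_{i,k} m_i a_ij a_ik sin(ψ_ij − ψ_ik) φ̇_k²
    ∂V/∂phi_j  = −g Σ_i m_i a_ij sin(ψ_ij)

with `ψ_ij = phi_j + δ_ij` and constant coefficients `a` from the segment
geometry. Joint-space quantities follow by congruence with the constant
map `W`. The closed form is verified in the test suite against an
independently derived symbolic Lagrangian and against compound-pendulum
limits.

**Chair contact.** The chair is a two-dimensional point constraint pinning
the femur head (hip centre) to a seat anchor, enforced with Lagrange
multipliers plus light Baumgarte stabilization (β = 20 s⁻¹). The
multiplier pair is the seat reaction; the constraint is removed — for the
rest of the roll-out — at the first integration step where the reaction
turns non-compressive (`F_y ≤ 0`) or leaves the friction cone
(`|F_x| > μ F_y`, default μ = 0.8 for chair and ground; μ has no
authoritative value and is therefore a required, visible config field).

**Passive joint structures.** Ligament limit springs produce zero torque
strictly inside the physiological ranges (hip −30°…120°, knee 0°…140°,
ankle −40°…30°) and an exponentially stiffening restoring torque outside
(scale 5 N·m, rate 30 rad⁻¹, both configurable; the exponent is capped so
blown-up candidates stay finite and rankable). The stops are deliberately
stiff and carry a damper active only outside the range (15 N·m·s/rad):
the knee's extension stop then behaves like the bony lock real standing
rests on — arriving joints are caught inelastically with millimetre-scale
penetration instead of bouncing, and quiet standing "on the skeleton" is
nearly free of ligament torque. Joints also carry linear viscous damping
(default 3 N·m·s/rad): lumped passive tissue dissipation, without which
the undamped torso oscillates indefinitely on the seat constraint.

**Anterior trunk mass.** The HAT centre of mass sits 3 cm anterior to
the segment axis (a perpendicular COM component, handled exactly as a
phase offset in the segment's COM direction). This reproduces a load-
bearing feature of upright anatomy: at standing, trunk gravity produces a
small hip-flexion moment balanced by extensor tone, instead of an
unresisted extension runaway through the hyperextension gap that would
make every arrival at upright topple backward.

**Initial posture.** Sitting is ankle 15° dorsiflexion, knee 85° flexion,
hip 78° flexion, with the seat anchor placed exactly at the femur-head
position this posture implies. Two properties motivated the choice, both
checked in code: (i) with the default 0.05 activation the seated model is
near passive equilibrium — the torso settles forward by a few tens of
degrees and the chair keeps carrying it through the whole horizon;
(ii) at maximal seated trunk flexion the whole-body COM can enter the
foot support polygon, so standing does not require an extreme momentum
strategy. Without lumbar actuation a slightly forward, fairly
upright-trunk start is the standard compensation.

## Musculotendon model

Eight lumped Hill-type units actuate the chain: ILPSO, GMAX, RF, HAMS,
VAS, GAS, SOL, TA, with RF/HAMS biarticular across hip and knee and GAS
across knee and ankle. Maximum isometric forces are the published values
for these groups (e.g. VAS 9594 N); a strength deficit scales all of them
uniformly (`strength_scale` 0.4 = 60 % deficit).

Activation follows first-order dynamics toward the excitation with
τ_act = 10 ms and τ_deact = 40 ms (standard Hill practice; only the
assistance time constant of 100 ms has an authoritative value). The
contractile element multiplies a Gaussian active force-length curve
(width 0.45), a hyperbolic force-velocity curve (curvature 0.25,
eccentric plateau 1.4, v_max 10 fiber lengths/s) and the maximum force;
an exponential passive curve (shape 4, strain 0.6) adds fiber-stretch
force. The tendon is rigid by default, so fiber kinematics follow the
musculotendon path; an elastic-tendon equilibration (linear tendon,
bisection root) is available for initialization studies.

Moment arms are constants per muscle and joint by default (cubic
polynomials in the joint angle are supported), with signs chosen so each
group torques its anatomical direction; path length is the exact integral
of the arms, which keeps every path/arm consistency check analytic. The
default arm magnitudes (e.g. VAS 5.0 cm at the knee, GMAX 9.0 cm and
HAMS 8.0 cm at the hip, HAMS 2.5 cm at the knee) were chosen, within
physiological ranges, so the model reproduces the capability boundary the
deficit study turns on — verified by a quasi-static feasibility scan over
seated-to-upright postures: a standing path exists down to 40 % strength,
none exists at 20 % strength unassisted (the knee and hip extensors both
fall short), and the path reappears at 20 % strength once the two 200 N
assistance forces are available.
Because the groups are lumped, the *effective* optimal fiber lengths are
deliberately long (0.10–0.26 m): they absorb the moment-arm variation a
detailed model would distribute over wrapping geometry, and keep each
group's normalized fiber excursion over the full sit-to-stand sweep to
roughly ±0.2 so no group collapses on its force-length curve at either
end of the motion. Each muscle's path is anchored so its fiber is at
optimal length at a configurable reference fraction of the seated posture
(default 0.6 of the way from standing to sitting for every group); the
resulting seated stretch of the hip extensors supplies the passive
extension moment that brakes trunk slump the way posterior hip structures
do.

## Forward simulation

Fixed-step RK4 (default 1 ms) integrates skeletal and activation states
together; activations are clamped to [0, 1] each step. The seat-release
test runs every step on the current multiplier; release applies at the
step boundary and is permanent. Roll-outs whose joint speeds exceed
50 rad/s, or whose state turns non-finite, are truncated and flagged
`failed` but keep their partial series so the cost function can still
rank them. Every step records joint kinematics and accelerations, muscle
forces (active/passive split), limit torques, seat and ground reaction
wrenches, COM kinematics and the zero-moment point, so inverse-dynamics
round trips close to machine-level precision without re-differentiation.

The ZMP convention: the stored feet moment is taken about the ground
point below the ankle, positive when the reaction tips the body toe-ward,
so `zmp_x = ankle_x − moment / F_y`; it is NaN wherever the vertical
ground force is not positive.

## The objective

One roll-out is scored by ten weighted penalties (weights 800, 1.2, 175,
70, 5, 10, 0.1, 1000, 6, 0.3; chair time constant τ = t_max/8): remaining
COM distance to the upright goal (normalized by the starting distance);
chair force weighted by a normalized rising exponential (integrates to
one over the movement, penalizing late contact); mean squared activation
and activation rate; assistance usage; limit-spring torques; foot slip
margin; peak ZMP excursion from the foot midpoint (a time-integral
variant is available behind `phi8_integral`); terminal joint speed; and
the deviation of the vertical ground force from body weight after
seat-off. The progress scalar α (0 = still at the start COM, 1 =
standing) gates the last four terms and complements the chair term, so
exploration of unstable candidates is not crushed early. Activation
rates use central differences on the stored activation series;
quadrature is the trapezoid rule on the integration grid. For roll-outs
that never release the seat, α is simply small and the post-seat-off
window degenerates to the final sample, keeping failed candidates
smoothly rankable.

## Optimization

The decision vector holds one excitation node per actuator per 0.1 s up
to t_max = 1.6 s plus the duration t_f — 129 unknowns unassisted, 161
with the two assistance forces. Excitations interpolate linearly from
the fixed defaults at t = 0 (muscles 0.05, assistance 0). The search is
a restarted aCMA-ES (active covariance update) written in-package:
initial mean at the "sitting in the chair" guess, restart on a 4000
generation budget or when the best cost improves by less than 1.0 over
250 generations, mean re-centred on the best-ever candidate at each
restart, four restarts by default. Node genes are clamped to [0, 1] at
decode time with a quadratic out-of-bounds penalty keeping the sampler
informed; the duration gene lives on [0, 1] and maps affinely onto
[0.8, 1.6] s. The 0.8 s floor is a package choice: durations far below
the human STS envelope act as a loophole in which the candidate releases
the chair and terminates the simulation before the ensuing fall is ever
penalized, and desk-scale searches reliably fall into it. Population
(default 24 for the STS problem), initial step size (0.15) and the
restart step size (0.05 — finer, so restarts refine around the best-seen
candidate rather than leaping away from it) are config-exposed; fixed
seeds give bitwise-reproducible runs.

At desk-scale budgets (tens of thousands of roll-outs rather than the
hundreds of thousands of a fully converged protocol) the searches in
this package reliably discover seat-off and carry the transfer to
80–90 % completion, but usually truncate at the apex of the rise rather
than finishing and stabilizing upright: the final stand requires a
precisely timed hip-flexor/dorsiflexor braking burst whose cost valley
is narrow, and deploying assistance must overcome the usage penalty
before its benefit materializes. Fully converged runs are supported by
simply raising the budgets.

## Tracking-based failure diagnosis

To ask which muscle's weakness breaks STS, a weakened model tracks a
reference trajectory: desired accelerations come from a PD law with a
10 ms lookahead (k_p = 100 s⁻², k_v = 20 s⁻¹, a critically-damped
pairing), and a static optimization distributes the required generalized
forces over the muscles — bounded by their instantaneous force
capability at the current length and velocity — plus one idealized
reserve actuator per joint. The stage minimizes the sum of squared
controls subject to the acceleration equalities (the convex "fast
target"); it is solved by an exact active-set method for this QP and
cross-checked against an independent solver in the tests. Reserve
"prices" (torque per unit control) make a reserve cheap or expensive;
comparing two pricings — hip-favoured versus knee-favoured — identifies
the joint whose reserve persists in both as the seat of weakness.
Seat-constraint forces recorded during forward simulation are supplied
to the tracked model as external forces, since the tracked model carries
no event-based constraint. Reference derivatives come from a cubic
spline of the supplied trajectory; controls are frozen over each 10 ms
step while the skeleton integrates with RK4 substeps.

## Synthetic data

No experimental recordings are consumed. The fixtures module generates:
deficit-sweep model configs (strength scales 1.0 … 0.2 in steps of 0.2);
synthetic surface-EMG (20–250 Hz band-shaped noise under smooth bursts
with known MVC peaks) matching the *structure* of STS recordings —
channels, sampling, normalization — but none of their physiology;
smooth minimum-jerk seated-to-upright reference trajectories with an
early trunk-flexion peak for tracking tests; and hip-angle ramps with
known onsets for event detection. Consequently, passing tests
demonstrate internal consistency, correct mechanics and the qualitative
phenomena (seat-off, phase structure, reserve dominance, assist-as-needed
timing) — they do not validate the model against human kinematics,
EMG timing or contact-force magnitudes.

## Problem sizes for routine runs

Full-protocol optimizations (4000 generations, four restarts) reproduce
the published study design but are hours-long; the packaged workflows and
the acceptance script run a reduced protocol chosen as the package's
standard desk-scale configuration: population 24, a few hundred
generations with one restart, early stop once α exceeds 0.92, and a 4 ms
roll-out integration step during the search (the 1 ms default remains for
analysis-quality roll-outs; at STS speeds the coarser step changes costs
by well under 1 %). The deficit sweep at these sizes reproduces the
qualitative pattern — successful transfers at mild deficits, failure
unassisted at 80 % deficit, success at 80 % deficit with bounded
assistance — not the published peak torques or forces, which require the
original geometry and fully converged searches.

## Numerical choices and edge cases

- RK4 at 1 ms is exact enough that passive-chain energy drifts by less
  than 1e-4 of the total over 1.6 s for motions up to ~5 rad/s; the
  energy stress test releases the chain near upright, which whips the
  light shank to ~50 rad/s, and therefore runs at 0.5 ms for a
  commensurate error level.
- The seat KKT system is solved directly (5×5); rank loss is impossible
  while the two constrained joints are away from chain singularities,
  and a failure raises a NumericalError with the offending state.
- Limit-spring and passive-force exponents are capped (30 and 40) and the
  limit-spring magnitude saturates at 500 N·m, so divergent candidates
  produce huge finite torques that remain integrable rather than NaNs;
  roll-outs that still hit the 50 rad/s divergence cap are truncated and
  their cost carries a fixed failure penalty so they can never outrank an
  honest attempt.
- α is undefined when the start COM coincides with the goal COM; this is
  raised explicitly rather than returned as a default.
- Ties in the failure diagnosis (equal persistent reserves) name no
  joint.

## Known limitations

Planar symmetry; no lumbar actuation; the foot is welded (no heel-rise
or toe-tipping mechanics — the ZMP term penalizes, but cannot produce,
tipping); chair contact is a single point without friction-consistent
tangential compliance; constant default moment arms; rigid tendon;
uniform strength scaling as the only deficit model. Quantitative joint
torques and contact forces depend on the documented default
anthropometry and muscle geometry and should be interpreted relative to
this model, not as subject-level predictions.
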