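# planarsts

Predictive simulation of sit-to-stand (STS) movement on a planar
musculoskeletal model, for biomechanists and assistive-device designers who
want to study how muscle strength deficits reshape the transfer — and what
external assistance profile complements them.

## What it does

The model is a sagittal three-link chain (shank, thigh, head-arms-trunk)
on a foot welded to the ground, actuated by eight lumped Hill-type muscle
groups (ILPSO, GMAX, RF, HAMS, VAS, GAS, SOL, TA — RF/HAMS biarticular at
hip+knee, GAS at knee+ankle). The chair is a point constraint on the femur
head, released permanently when its reaction turns non-compressive or
slips (|F_x| > μ F_y). Strength deficits scale all maximum isometric
forces uniformly; optional assistance is two first-order-filtered point
forces (vertical + horizontal, 0–200 N each) at the trunk centre of mass.

Open-loop muscle excitations are parameterized as piecewise-linear nodes
every 0.1 s plus the movement duration t_f ≤ 1.6 s (129 decision
variables unassisted, 161 assisted), and optimized by a restarted aCMA-ES
against a ten-term cost

    phi_total = Σ_i w_i phi_i ,    i = 1..10,

combining the remaining COM distance to upright, exponentially
late-weighted chair contact, activation effort and rate, assistance use,
ligament-limit torques, foot slip, zero-moment-point excursion, terminal
joint speed, and vertical ground-force deviation from body weight — the
last four gated by the STS-progress scalar

    alpha = 1 − min(d(C_f, C_goal), d(C_0, C_goal)) / d(C_0, C_goal).

A computed-muscle-control style tracking tool (PD desired accelerations +
a fast-target static optimization with per-joint reserve actuators)
diagnoses *which* joint's muscles cause a failed transfer, and analysis
utilities provide inverse-dynamics torques, per-muscle contributions,
three-phase segmentation, surface-EMG envelopes and STS event detection.

## Worked example

```python
import planarsts as ps

# a 40 % strength deficit model (scale 0.6), desk-scale search budget
model, opt, sim = ps.optimize_sts(strength_scale=0.6, seed=1,
                                  max_generations=500, n_restarts=1)
bd = opt.best_breakdown
print(f"progress alpha = {bd.alpha:.3f}")
print(f"seat-off at t = {sim.t_seat_release:.2f} s, duration {sim.t_f:.2f} s")

from planarsts.analysis import segment_phases
seg = segment_phases(sim)
print(f"phases end at {seg.t_phase1_end:.2f} / {seg.t_phase2_end:.2f} "
      f"/ {seg.t_phase3_end:.2f} s")
```

Output at this seed and budget:

```
progress alpha = 0.869
seat-off at t = 0.71 s, duration 1.40 s
phases end at 0.71 / 0.81 / 1.40 s
```

`alpha` is the fraction of the seated-to-upright COM distance completed
(1.0 = standing; desk-scale budgets typically reach the high 0.8s —
carrying the transfer to the top of the rise — while fully converged
multi-hour searches are needed to also stabilize quiet upright stance,
see `docs/methods.md`); seat-off is the event where the chair constraint
released; the three phase boundaries are seat-off, peak hip flexion, and
movement end.

The same workflows are scriptable from the shell:

```bash
planarsts optimize --scale 0.6 --generations 500 --restarts 1 --seed 1 \
         --dt 0.004 --out run_060
planarsts analyze --simulation run_060/best_simulation.csv --out run_060
planarsts fixture deficit_sweep --out configs/
```

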