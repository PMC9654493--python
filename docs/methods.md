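# Methods

## Scope and model

`stairgait` simulates a muscle-driven human walker ascending stairs and a
ramp and trains a binary muscle-excitation policy against a reference gait.
The default model is a **planar sagittal biped**: seven rigid segments (a
lumped pelvis+trunk+head body, and thigh/shank/foot per leg), six pin joints
(hips, knees, ankles) plus a free planar root — 9 degrees of freedom —
actuated by 14 Hill-type muscles (7 per leg: iliopsoas, gluteus maximus,
vasti, biceps femoris short head, hamstrings, soleus, tibialis anterior).
The full 3D topology (14 DOF, 18 muscles including rectus femoris and
gastrocnemius) is available as a configuration preset for description and
serialization; forward dynamics is implemented for the planar variant, and
hip ab/adduction plays no part in any quantitative check.

Two task presets fix the study conditions: **stairs** (trunk fixed at
−15°, all maximum isometric forces increased by 80%) and **ramp** (trunk
−5°, nominal forces). The terrain geometry matches the task: stairs 2 m
wide with 3 steps of 0.2 m rise × 0.25 m going (total rise 0.6 m); ramp
2 m wide, 3.25 m run, 0.45 m rise (gradient 7.883°, incline length 3.28 m).

### Muscle model

Rigid-tendon Hill muscles: fiber force
`F = f_max [a·fL(l̃)·fV(ṽ) + fP(l̃)] cos α` with a Gaussian active
force–length curve (width 0.45), a hyperbolic Hill shortening branch
vanishing at the maximum shortening velocity with a C¹-matched saturating
lengthening branch (plateau 1.5), and an exponential passive curve that is
zero at and below the optimal length. Excitation→activation is first-order
with τ_act = 10 ms, τ_deact = 40 ms (configurable); the update is the exact
exponential solution of the linear ODE, hence unconditionally stable and
bound-preserving. The rigid-tendon approximation (fiber length = path
length − tendon slack length) removes the inner tendon-equilibrium solve;
it slightly stiffens short-tendon muscles but is adequate at this scale.

Muscle paths are straight origin→insertion lines with optional via points
(the vasti wrap a patella point); moment arms follow from the path-length
Jacobian and are centimetre-scale with physiological signs at standing.
Per-muscle maximum isometric forces, optimal fiber lengths and pennation
angles are approximate values typical of published lower-limb models — the
source model family does not print them — and tendon slack lengths are
calibrated so every muscle sits at its optimal fiber length in the
reference standing pose. They are configuration, not claims.

### Dynamics formulation

The engine integrates **maximal planar coordinates** (x, y, θ per body)
with the six pin joints enforced by constraint impulses solved exactly each
step (12×12 system), rather than minimal joint coordinates. The reason is
bookkeeping-free momentum correctness: joint impulses, muscle tension pairs
and joint-limit torque pairs all cancel pairwise by construction, so the
chain's linear momentum is conserved to machine precision without any
Coriolis terms to get wrong. Generalized joint coordinates are derived
views used by the observation builder, the reward and the reference
generator. Joint drift is removed by velocity-level Baumgarte stabilization
(β = 0.2 per step).

Integration is semi-implicit (symplectic) Euler. The default physics step
is **1 ms**: the elastic-foundation stiffness acting on the light foot
segments makes 5 ms unstable and 2 ms marginal; at 1 ms drop tests show a
per-step mechanical-energy increase below the documented bound of 0.01 J
within the operating envelope (feet-first contact, before a fall).
Episodes terminate on a fall (pelvis below 60% of initial height), on
leaving the terrain footprint in x (±0.5 m margin), on numerical
divergence (flagged, never silently propagated), or when the reference
ends. Joint limits are soft spring–dampers (300 N·m/rad, 2 N·m·s/rad)
plus a small passive viscous term (0.1 N·m·s/rad).

### Contact

Elastic-foundation contact is discretized at the vertices of the foot
spheres (heel ∅50 mm at (30, 20, 0) mm in the hindfoot frame; two toe
spheres ∅25 mm at (20, −5, ∓26) mm in the forefoot frame; 107 vertices and
210 faces per sphere as a 15-segment × 8-ring UV triangulation). Pressure
is `p = k·x·(1 + c·ẋ)` clamped at zero — stiffness k = 50 MPa/m read as
pressure per metre of penetration, dissipation c = 5 s/m applied
multiplicatively (Hunt–Crossley style; an additive form would change
restitution only marginally at these depths). Per-vertex force is pressure
× tributary area (sphere area / vertex count). Friction opposes tangential
slip with a Stribeck-style blend rising through the static coefficient at
the transition velocity (0.1 m/s) and decaying to the dynamic value, plus
a viscous term; all three coefficients default to 0.9.

Two numerical guards make the explicit integration of these stiff damping
terms robust: the dissipative part of the normal force and the friction
force are each clamped so they can at most cancel, within one step, the
relative motion they oppose (using the per-point effective mass
`1/(1/m + r²/I)` shared across the body's contacts). Without the clamps
the default coefficients destabilize any practical step size.

The simulation loop queries analytic stair/ramp fields (exact 2D distance
to the step-profile polyline / incline segment, identical to the generic
mesh query on the walking surfaces, verified in tests); arbitrary OBJ
terrain goes through the generic watertight-mesh query (vertical-ray
parity for inside tests, exact closest-point-on-triangle for depth).

### Reference motion

External motion-capture data are replaced by a **synthetic gait
generator**: per cycle the pelvis advances one step depth and rises one
step height (stairs) or advances a fixed stride along the incline (ramp),
with smoothstep within-cycle progression; joint angles follow two-harmonic
templates with the right leg half a cycle out of phase and the left leg
swinging first; a 0.3 s quiet-standing lead-in fades the pattern in.
Defaults: cycle duration 1.4 s, 3 cycles, 10 ms sampling, no noise; seeded
Gaussian angle noise is available. Template amplitudes/phases give the
qualitative structure of stair/ramp ascent (knee flexion peaking in swing,
plantarflexion at push-off); they are configuration, not measurements, so
what passing tests show is that the pipeline tracks *a* plausible
reference — not that it reproduces human kinematics. Velocities use the
backward-difference rule `v(t) = (p(t) − p(t−1))/Δt` with `v(0) = v(1)`;
dividing by the sampling interval (not absolute time) is the only
dimensionally consistent reading. Trajectory files round-trip through
plain CSV (SI units) and a TRC-like tab-separated dialect (mm/degrees,
rate-checked header).

### Reward

Per control step, `J = 0.1·J_goal + 0.9·J_imitation` with
`J_goal = exp(−8·p_vel_pelvis)` and
`J_imitation = 0.9·exp(−4·p_pos) + 0.1·exp(−0.1·p_vel)`, where the
penalties are squared-error sums over the tracked coordinates (all nine
planar DOFs by default — pelvis translation and rotation included, which
is the inclusive reading of "pelvis, hip, knee and ankle"; configurable).
The sums inside the exponents are over DOFs within one step — a cumulative
sum over time would drive every reward to zero. The goal penalty uses the
pelvis translational velocity only. Rewards therefore lie in (0, 1] and
equal 1 exactly on perfect tracking, which the idealized kinematic replay
realises (the 100%-reward-fraction anchor).

### Policy and PPO

The policy is an MLP with tanh hidden layers whose final linear layer
parameterises independent Bernoulli excitation probabilities per muscle
(a sigmoid head: a tanh output cannot represent probabilities). Actions
are sampled during training and thresholded at 0.5 for evaluation. The
full-model reference architecture is 214→312→312→18; the planar default
observation is 114-dimensional (segment kinematics, generalized joint
kinematics, muscle forces, limit torques, ground reactions) with fixed
diagonal scaling and clipping at ±5 to keep contact transients from
saturating the tanh layers.

PPO maximises the clipped surrogate with generalized advantage estimation
from a value network of the same trunk sizes; gradients are hand-written
closed forms (the networks are small), optimised with Adam, all randomness
from one seeded generator (bit-reproducible runs). Defaults: clip 0.2,
γ = 0.99, λ = 0.95, 4 epochs × 256 minibatch per update, rollout 2048
steps, advantage normalization on. The policy head bias can be initialised
negative (default 0; the training experiments use −1, i.e. initial
excitation probability ≈ 0.27) — sparse initial firing is both
physiologically sensible and reduces the violent initial thrashing of a
fair-coin policy. Metrics are flushed every 5 iterations; checkpoints are
saved on improvement; a NaN loss aborts with the last checkpoint retained.

### Problem sizes used in the checked experiments

The learning experiment in the test suite runs the planar stair task with
the synthetic reference at the default settings (1 ms physics substeps,
10 ms control interval), a 64×64 policy/value trunk, 2048-step rollouts,
learning rate 6e-3 decayed linearly to 15%, entropy bonus 0.003, policy
head bias initialised to −1, 30 iterations, seed 1 (about six minutes on
one CPU). Success is measured as: best iteration-mean per-step reward at
least 3× the mean per-step reward of a Bernoulli(0.5) random policy, and
Spearman rank correlation ≥ 0.8 between iteration index and mean reward
over the first half of training. The bandit sanity check (single state, one action
bit, reward for firing) must drive the rewarded action's probability above
0.9 within 200 updates.

## Known limitations

- Planar dynamics: no mediolateral balance, no hip ab/adduction; the full
  3D preset is descriptive only.
- Rigid tendons and straight-line paths with a single via point; no
  wrapping surfaces.
- The synthetic reference is kinematically plausible but not
  dynamically consistent (it is not the output of a physical simulation),
  so perfect tracking by the dynamics is not attainable — by design the
  reward measures closeness, not feasibility.
- Muscle parameters are approximate defaults of the model family, not
  subject-specific values.
- Desk-scale training: the checked experiments demonstrate learning
  progress and a margin over random behaviour, not a full ascent of the
  staircase at mocap fidelity; reproducing multi-day training outcomes is
  out of scope.
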