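# Methods

This note records the model, the estimator, the numerical choices and the
limits of what the synthetic experiments can show. Units throughout:
metres, seconds, newtons, newton-metres, radians; x is the anterior
horizontal axis, y vertical, ground at y = 0.

## Body model

The body is a planar (sagittal) floating-base tree of rigid segments.
Generalised coordinates are `[base_x, base_y, base_theta, q_1..q_n]`: a
3-DoF planar pelvis base plus n actuated joints (default n = 9: lumbar,
shoulder, elbow, and hip/knee/ankle per leg). Left and right arms move
symmetrically in the sagittal plane and are collapsed into one upper-arm /
forearm pair with doubled mass; the forearm link spans forearm *plus hand*
(0.46 m), so a hand-held object contacts the FA link at ~0.31 m from the
elbow. Legs are kept as separate left/right chains.

Default anthropometrics (70 kg, 1.75 m) use Dempster-style segment mass
fractions and segment lengths, shipped as an editable YAML file
(`src/ergoload/data/body_default.yaml`). They are a documented stand-in: no
attempt is made to reproduce any specific subject or simulation model.
Per-joint torque capacities for the traffic-light bands are likewise a
rough, editable table (adult static strength orders of magnitude).

Forward kinematics places each segment from its parent; point Jacobians
are the planar `[I₂ | ⟂(p − x₀) | ⟂(p − joint_k) …]` construction, with
the base-translation block always the identity and zero columns for joints
off the chain to the point. `Jᵀf` gives generalised forces; the last n
rows are joint torques (the actuation selector).

## SESC CoP model

For any branched chain the whole-body CoM is exactly linear in the link
rotations, `CoM = x₀ + Σ A_i φ_i`, where the constant blocks φ_i combine
each link's own first moment with the mass it carries distally. In the
planar reduction each block has 2 components and only the x-row of each
rotation enters the ground-projected (CoP) regression, giving per pose one
row `W` with `W·Φ = CoP_x − x₀_x`. Identification is ordinary least
squares over p static poses.

Numerical choices:

- **Rank guard.** Identification refuses to return parameters when the
  regressor is rank-deficient or its condition number exceeds 1e8 —
  repeated or insufficiently varied poses must fail loudly rather than
  return garbage.
- **Calibration poses break symmetry.** Under a strictly left/right
  symmetric protocol the two legs' rotation columns are identical and the
  regressor is structurally rank-deficient; the calibration-pose sampler
  therefore draws each leg independently and varies the pelvis tilt
  (±15°). Detection-phase streams may remain symmetric.
- Measured CoP per pose is the mean over the pose's dwell window (rows
  sharing a `pose_id` in the calibration CSV are averaged).
- The analytic parameter vector computed from the model's true masses
  serves as the simulator's ground truth and the identification oracle.

With 25 noiseless poses the held-out CoP error is at numerical precision;
with 2 mm CoP noise and 200 poses the held-out RMSE is ~0.9 mm.

## Contact-point detection

The torque balance about a ground pivot gives the load line's x-coordinate
from `(CP_wt f_wt − CP_wo f_wo)/(f_wt − f_wo)`. The unloaded reference
force f_wo is the mean vGRF over a leading baseline window (default 100
samples) unless supplied; a gate |f_wt − f_wo| ≥ 5 N avoids the
singular division when no load is present.

**Noise amplification and filtering.** The balance multiplies CoP error by
f_wt/(f_wt − f_wo) — about 18× for 4 kg on a 70 kg body — so raw 5 mm
plate noise becomes ±10 cm per sample, wider than most body links. The
detector therefore averages the plate channels *and the model CoP* over a
causal window (default 25 samples, 0.5 s at 50 Hz) before applying the
balance; filtering both sides through the same window cancels the body-sway
component exactly. Windows do not overlap (decimation), keeping the
accumulated samples independent for the normality test, and the windowed
value is intersected with the *mid-window* posture so motion introduces no
geometric lag. A window of 1 disables the front-end entirely; noiseless
behaviour is unchanged.

Two sample-quality guards follow from the method's own assumptions:

- **Quasi-static gate.** The balance only holds quasi-statically; windows
  during which the model CoP drifts more than 2 cm are discarded.
- **Inclination guard.** A vertical line crossing a link maps ground error
  into link-frame error scaled by 1/inclination; crossings of links whose
  horizontal extent is below 0.25 of their length are discarded, since
  such samples are wildly heteroscedastic and break the homoscedastic
  Gaussian sample model behind the A² test (near-vertical links carry
  almost no localisation information in x anyway).

Per accepted sample, the vertical line at x_ah is intersected with every
candidate link (several can be crossed at once); link-frame coordinates
accumulate per link. Once a link holds more than n_min = 50 samples its A²
statistic (standardised by the sample mean and sd with ddof = 1, normal
CDF clamped to [1e-15, 1−1e-15] before the logs, zero-variance sets
defined as A² = 0 and flagged degenerate) is compared with the critical
value 0.735 (5% level). Candidates are tested in descending sample count,
ties broken by the configured distal-to-proximal order, and the first
acceptor is **latched for the rest of the episode**. After latching, the
episode stops when `z*·σ̂/√n ≤ 1 cm` (z* = 1.96); the sample mean, clipped
to the link's [0, L], is the contact position. Samples whose vertical line
misses every candidate are counted and dropped; if the load disappears for
a dwell (default 50 samples) the episode state clears.

## Overloading torques

With the contact point known, the extra static torque per joint is the
loaded-minus-unloaded Jacobian-transpose balance; gravity/inertia terms are
identical in both states and cancel, so only three contact terms remain
(load-point term, unloaded-CoP term weighted by the distribution gains,
and a CoP-displacement term). The per-foot ground points are the measured
CoP (loaded) and the model CoP (unloaded) on the ground line, treated as
frame points of each foot. The vGRF distribution gains are a linear
interpolation of the measured CoP between the two ankle ground positions,
clipped to [0, 1] (coincident ankles split evenly; single support takes
ζ = 1) — a deliberately simple stand-in for posture-based force-share
models. Equality with brute-force loaded-minus-unloaded statics is exact
by construction and verified to 1e-9 N m; Δτ is linear in the load.
Levels act on |Δτ|: GREEN ≤ 0.3 τ_max < ORANGE ≤ 0.6 τ_max < RED, with
magnitudes beyond τ_max clamped to RED and flagged.

## Synthetic data

The simulator generates statically balanced sagittal postures by rejection
sampling over configured physiological joint ranges (ground-projected CoM
within the foot support interval plus an 8 cm heel margin; the lowest foot
point pinned to the ground). Episode streams interpolate slowly (cosine
ease, default 20 s per transition) between balanced keyposes with a small
residual sway — a person moving freely but quasi-statically — then rest a
point load on a chosen link: the unloaded CoP is the exact mass-weighted
CoM projection, vGRF is (m_body + m_load)·g, and the loaded CoP is the
force-weighted convex combination of body CoP and load line. I.i.d.
Gaussian noise (defaults σ_CoP = 5 mm, σ_F = 5 N, deliberately coarse
plate-grade values) is added to the measurement channels; noiseless truth
is carried alongside. Everything is seeded and byte-reproducible.

The validation scenario mirrors the hardware protocol: a standing subject
(no deep squats — `standing_model` narrows hip/knee ranges), 4 kg shared
across both limbs at the hands (FA @ 0.31 m), mid-forearms (FA @ 0.14 m)
or mid-upper arms (UA @ 0.22 m), 4 s unloaded baseline then 60 s loaded.
The factorial evaluation grid (default 17 poses × 7 links × 3 locations =
357 conditions) runs the noiseless round trip per condition and reports
signed errors and intersection failures.

What the simulator does **not** emulate: soft-tissue and marker artefacts,
IMU orientation drift, asymmetric 3-D motion, distributed (non-point)
contacts, dynamic transients at load pickup, and real anthropometric
variation. Passing tests therefore demonstrate the estimator's correctness
and its noise behaviour under the stated sensor model — not performance on
any particular human dataset.

## Problem sizes and expected numbers

The shipped tests and `scripts/acceptance.py` use: the full 357-condition
noiseless grid (errors < 1e-6 m, zero intersection failures at interior
placements), 50 random draws for the torque oracle (agreement < 1e-9 N m),
25/200-pose SESC calibrations over 20 seeds (held-out RMSE ≤ 3 mm at 2 mm
noise), 10 000 standard-normal replicates of n = 100 for the A² null
(rejection ≈ 5–6% at 0.735), and 100 noisy validation episodes
(correct-link rate ≈ 90%, median detection ≈ 28 s, hands-condition
position error ≈ 2–3%).

## Known limitations

- Links that overlap in the sagittal x-coordinate (torso vs thighs; left
  vs right leg in a symmetric stance) are intrinsically ambiguous to a
  CoP-only method: the same vertical line crosses both and both
  accumulate plausible Gaussian samples. The candidate order then decides,
  so loads on the trunk or legs are localised far less reliably than arm
  loads; mirrored left/right legs are strictly indistinguishable.
- Near-vertical carrying links (an arm hanging at the side) produce few
  usable crossings; detection waits until the limb inclines.
- Localisation accuracy degrades near link endpoints, where part of the
  sample distribution falls off the link and the mean is pulled inward.
- The method assumes a single point contact, vertical load, flat floor,
  and negligible tangential GRF; none of these are checked at run time.
- A 4 kg load against 5 mm CoP noise sits near the method's working limit
  (±10 cm per raw sample); heavier loads or quieter plates improve every
  figure roughly linearly in f_wt/(f_wt − f_wo)·σ_CoP.
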