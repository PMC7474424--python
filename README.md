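# ergoload

Online detection and localisation of an external load on the human body —
and assessment of the joint overloading it causes — from nothing but a
force plate (ground CoP and vertical GRF) and whole-body posture tracking.

The intended user is a researcher or ergonomist instrumenting quasi-static
industrial tasks (lifting, carrying, sagittal pick-and-place): the package
answers *where* on the body a carried weight rests and *how much extra
torque* each joint bears, without force sensors on the body or a known,
pre-declared grasp point.

## Method

In quasi-static stance on a flat floor, the moment balance about a ground
pivot in the sagittal plane relates the measured loaded plate readings
(CP_wt, f_wt), the *unloaded* reference (CP_wo, f_wo), and the load's line
of action:

    x_ah = (CP_wt · f_wt − CP_wo · f_wo) / (f_wt − f_wo)

The unloaded CoP for the current posture is predicted by a **statically
equivalent serial chain** (SESC) model: the whole-body CoM is exactly
linear in the link rotation matrices, `CoM = x0 + Σ A_i φ_i`, so the
parameter vector Φ is identified once, offline, by ordinary least squares
from ~25 held static poses paired with measured CoP (`Φ̂ = W⁺Ω`).

Online, each filtered sample of `x_ah` is intersected with the body's
candidate links (forearm FA, upper arm UA, torso T, thighs LT/RT, shanks
LS/RS); link-frame coordinates accumulate per link. The link actually
carrying the load yields approximately i.i.d. Gaussian samples, so it is
selected as the first candidate whose sample passes a one-sided
**Anderson–Darling** normality test (A² < 0.735 at the 5% level, once
n > 50) and is then never revised. The episode stops when the confidence
half-width of the sample mean, `z*·σ̂/√n` (z* = 1.96), drops below 1 cm;
the sample mean is the reported contact position.

Given the contact point, the **overloading joint torques** are the three
Jacobian-transpose terms of the loaded-minus-unloaded static balance (the
body-dynamics terms cancel):

    Δτ = Sᵀ[ −J_ahᵀ f_h + Σ_i ( ζ_i J_wo,iᵀ f_h − (J_wt,i − J_wo,i)ᵀ ζ_i f_wt ) ]

with ζ_i the per-foot vGRF distribution gains (Σζ_i = 1). Each joint's
|Δτ| is classified GREEN (≤ 0.3 τ_max), ORANGE (≤ 0.6 τ_max) or RED
against configurable per-joint capacities.

A synthetic statics simulator (balanced sagittal postures, exact CoP/vGRF
with and without a placed point load, Gaussian sensor noise) stands in for
the motion-capture suit and force plate, so the whole pipeline runs and is
tested without hardware. See `docs/methods.md` for model details,
assumptions and limitations.

## Worked example

Run the full pipeline — calibrate the CoP model from 100 synthetic static
poses, simulate a subject carrying a 5 kg box at the hands (0.31 m along
the forearm link) while moving freely, detect the contact point, then
compute the overloading torques:

```
$ ergoload --seed 3 run --out-dir demo --link FA --fraction 0.674 --n-calibration 100
wrote 100 calibration poses to demo/calibration.csv
identified 20 parameters from 100 poses (residual RMS 3.72 mm, cond 72.0) -> demo/sesc.yaml
contact point: link FA at 0.330 m (n=51, 27.5 s) -> demo/estimate.json
wrote overloading torques for 3200 samples -> demo/overload.csv
```

The detector latched the forearm link and placed the contact at 0.330 m
from the elbow — 2 cm (6.4%) from the true 0.31 m — after 27.5 s of
loaded data, using 51 accepted samples. `demo/overload.csv` then holds one
row per sample and joint; mid-episode, for example:

```
    t    joint    delta_tau_Nm level
40.02    torso      12.81      GREEN
40.02    shoulder   10.39      GREEN
40.02    elbow      -3.75      GREEN
```

i.e. the box adds ~10 N m to the shoulder and ~13 N m to the lumbar joint
in that posture — well inside the GREEN band of the default capacities.
Torques are zero before the load appears and during non-quasi-static
windows.

The individual stages are also available as `ergoload simulate`,
`calibrate`, `detect` and `overload`; see `--help` on each for the file
formats (CSV streams, YAML models/parameters, JSON estimates).

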