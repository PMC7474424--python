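# Default sagittal body model: 70 kg adult, Dempster-style segment masses
# and lengths.  Units: metres, kilograms, degrees (rest/mount angles and
# joint ranges).  The world x axis points anteriorly, y up, ground at y=0.
#
# Segments extend along their local +x axis from the proximal attachment;
# rest_deg is the fixed mounting offset so that all-zero joint angles give
# an upright stance (pelvis up, legs down, feet forward, arms hanging).
# The two arms move symmetrically in the sagittal plane and are collapsed
# into a single upper-arm/forearm pair of doubled mass; the FA link spans
# forearm plus hand so hand-held loads lie on it.
name: adult-70kg
joints: [torso, shoulder, elbow, l_hip, l_knee, l_ankle, r_hip, r_knee, r_ankle]
candidate_links: [FA, UA, T, LT, LS, RT, RS]
foot_links: [LF, RF]
segments:
  - {name: PV, parent: null, joint: null, attach: distal, length_m: 0.10, mass_kg: 10.55, com_offset_m: 0.05, rest_deg: 90}
  - {name: T,  parent: PV, joint: torso,    attach: distal,   length_m: 0.60, mass_kg: 30.00, com_offset_m: 0.30, rest_deg: 0}
  - {name: UA, parent: T,  joint: shoulder, attach: distal,   length_m: 0.30, mass_kg: 3.90,  com_offset_m: 0.13, rest_deg: 180}
  - {name: FA, parent: UA, joint: elbow,    attach: distal,   length_m: 0.46, mass_kg: 3.05,  com_offset_m: 0.18, rest_deg: 0}
  - {name: LT, parent: PV, joint: l_hip,    attach: proximal, length_m: 0.42, mass_kg: 7.00,  com_offset_m: 0.18, rest_deg: 180}
  - {name: LS, parent: LT, joint: l_knee,   attach: distal,   length_m: 0.43, mass_kg: 3.25,  com_offset_m: 0.19, rest_deg: 0}
  - {name: LF, parent: LS, joint: l_ankle,  attach: distal,   length_m: 0.26, mass_kg: 1.00,  com_offset_m: 0.12, rest_deg: 90}
  - {name: RT, parent: PV, joint: r_hip,    attach: proximal, length_m: 0.42, mass_kg: 7.00,  com_offset_m: 0.18, rest_deg: 180}
  - {name: RS, parent: RT, joint: r_knee,   attach: distal,   length_m: 0.43, mass_kg: 3.25,  com_offset_m: 0.19, rest_deg: 0}
  - {name: RF, parent: RS, joint: r_ankle,  attach: distal,   length_m: 0.26, mass_kg: 1.00,  com_offset_m: 0.12, rest_deg: 90}
# physiological sampling ranges for the synthetic posture generator
joint_ranges_deg:
  torso:    [-50, 10]
  shoulder: [-10, 100]
  elbow:    [0, 130]
  l_hip:    [-20, 90]
  l_knee:   [-120, 0]
  l_ankle:  [-25, 25]
  r_hip:    [-20, 90]
  r_knee:   [-120, 0]
  r_ankle:  [-25, 25]
# per-joint torque capacities (editable) for the overloading levels
torque_limits_Nm:
  torso: 180.0
  shoulder: 90.0
  elbow: 60.0
  l_hip: 200.0
  l_knee: 180.0
  l_ankle: 120.0
  r_hip: 200.0
  r_knee: 180.0
  r_ankle: 120.0
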