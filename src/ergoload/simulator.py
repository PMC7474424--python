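"""Synthetic quasi-static sagittal data: postures, statics-consistent
CoP/vGRF with and without a placed point load, and sensor noise.

This module stands in for the motion-capture suit, the force plate and the
multibody simulation: it generates statically balanced sagittal postures,
computes the exact ground CoP (mass-weighted CoM projection) and vGRF with
and without a point load resting on a chosen link, and adds i.i.d. Gaussian
noise to the CoP and force channels.  It is the ground-truth oracle for the
detection, identification and overloading modules, and the source of the
factorial (pose x link x location) evaluation grid.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .body_model import BodyModel, Posture, forward_kinematics, point_on_link
from .overload import ExternalLoad
from .detection import contact_x, link_intersections

__all__ = [
    "GRAVITY",
    "ScenarioSpec",
    "StaticsResult",
    "InfeasibleRangesError",
    "VALIDATION_PLACEMENTS",
    "STANDING_RANGES_DEG",
    "standing_model",
    "com_ground_x",
    "sample_posture",
    "sample_calibration_poses",
    "simulate_statics",
    "make_stream",
    "factorial_grid",
]

GRAVITY = 9.81  # m s^-2

#: Margin behind the rearmost foot point accepted as support (the heel
#: extends behind the ankle, which the foot segment does not model).
HEEL_MARGIN = 0.08


class InfeasibleRangesError(RuntimeError):
    """Rejection sampling could not find a balanced posture."""


#: Load placements of the validation protocol: a 4 kg weight held at the
#: hands, strapped to the mid-forearms, and strapped to the mid-upper arms
#: (link, link-frame position in metres).
VALIDATION_PLACEMENTS: tuple[tuple[str, float], ...] = (
    ("FA", 0.31), ("FA", 0.14), ("UA", 0.22))

#: Joint ranges (degrees) for a subject standing on a force plate and
#: moving freely but staying upright — no deep squats, knees and hips near
#: neutral; arms free.
STANDING_RANGES_DEG: dict[str, tuple[float, float]] = {
    "torso": (-40, 10), "shoulder": (-10, 100), "elbow": (0, 130),
    "l_hip": (-20, 40), "l_knee": (-60, 0), "l_ankle": (-20, 20),
    "r_hip": (-20, 40), "r_knee": (-60, 0), "r_ankle": (-20, 20),
}


def standing_model(model: BodyModel) -> BodyModel:
    """Copy of ``model`` whose posture-sampling ranges describe upright
    standing (the stance of a subject on a force plate); joints absent from
    the standing table keep their configured ranges."""
    ranges = dict(model.joint_ranges)
    for joint, (lo, hi) in STANDING_RANGES_DEG.items():
        if joint in ranges:
            ranges[joint] = (math.radians(lo), math.radians(hi))
    return dataclasses.replace(model, joint_ranges=ranges)


@dataclass(frozen=True)
class ScenarioSpec:
    """One synthetic evaluation scenario.

    Defaults follow the validation conditions: a 4 kg load (2 kg per limb
    folded into the symmetric sagittal model), three locations per link at
    10/50/90% of its length, and plate-grade sensor noise of 5 mm on the
    CoP and 5 N on the vGRF.  ``symmetric`` mirrors the left/right leg
    joints (the symmetric-movement protocol); an asymmetric stance makes
    the left and right leg links geometrically distinct, which is required
    for them to be distinguishable candidates.
    """

    n_poses: int = 17
    links: tuple[str, ...] = ("FA", "UA", "T", "LT", "LS", "RT", "RS")
    locations: tuple[float, ...] = (0.1, 0.5, 0.9)
    load_mass: float = 4.0
    noise_cop: float = 0.005
    noise_force: float = 5.0
    seed: int = 0
    rate_hz: float = 50.0
    baseline_s: float = 4.0
    loaded_s: float = 60.0
    sway_amplitude: float = 0.05  # rad, residual joint sway on top of the path
    keypose_s: float = 20.0  # seconds between free-movement keyposes
    symmetric: bool = True

    def __post_init__(self) -> None:
        if not all(0.0 <= f <= 1.0 for f in self.locations):
            raise ValueError("locations must be fractions in [0, 1]")
        if self.load_mass < 0 or self.noise_cop < 0 or self.noise_force < 0:
            raise ValueError("masses and noise levels must be >= 0")


@dataclass(frozen=True)
class StaticsResult:
    """Exact quasi-static plate readings for one posture and load."""

    cop_unloaded: float
    cop_loaded: float
    vgrf_unloaded: float
    vgrf_loaded: float
    load_x: float | None  # world x of the load line, None when unloaded


def com_ground_x(model: BodyModel, posture: Posture) -> float:
    """Ground projection (x) of the whole-body CoM: the exact unloaded CoP."""
    segs = forward_kinematics(model, posture)
    by_name = {s.link: s for s in segs}
    num = 0.0
    for spec in model.segments:
        seg = by_name[spec.name]
        com = point_on_link(seg, spec.com_offset)
        num += spec.mass * com[0]
    return num / model.total_mass


def _support_interval(model: BodyModel, posture: Posture) -> tuple[float, float]:
    segs = {s.link: s for s in forward_kinematics(model, posture)}
    xs: list[float] = []
    for f in model.foot_links:
        xs.extend([segs[f].proximal[0], segs[f].distal[0]])
    if not xs:
        raise ValueError("model defines no foot links")
    return min(xs) - HEEL_MARGIN, max(xs)


def _ground_base_y(model: BodyModel, posture: Posture) -> float:
    """Base height that puts the lowest foot point on the ground line."""
    segs = {s.link: s for s in forward_kinematics(
        model, replace_base(posture, y=0.0))}
    lowest = min(min(segs[f].proximal[1], segs[f].distal[1])
                 for f in model.foot_links)
    return -lowest


def replace_base(posture: Posture, x: float | None = None,
                 y: float | None = None) -> Posture:
    bx = posture.base_position[0] if x is None else x
    by = posture.base_position[1] if y is None else y
    return Posture(np.array([bx, by]), posture.base_orientation,
                   posture.joint_angles.copy())


def _mirror_pairs(model: BodyModel) -> list[tuple[int, int]]:
    """(left, right) joint index pairs, by the l_/r_ naming convention."""
    pairs = []
    for j in model.joints:
        if j.startswith("l_") and ("r_" + j[2:]) in model.joints:
            pairs.append((model.joint_index(j), model.joint_index("r_" + j[2:])))
    return pairs


def sample_posture(
    model: BodyModel,
    rng: np.random.Generator,
    symmetric: bool = True,
    base_tilt_range: tuple[float, float] = (-0.17, 0.17),
    max_attempts: int = 1000,
) -> Posture:
    """Rejection-sample a statically balanced sagittal posture.

    Joint angles are drawn uniformly from the model's configured ranges
    (with left/right limbs mirrored when ``symmetric``), the pelvis tilt
    from ``base_tilt_range``, and the base is placed so the lowest foot
    point touches the ground.  Candidate postures whose ground-projected
    CoM falls outside the foot support interval are rejected.
    """
    missing = [j for j in model.joints if j not in model.joint_ranges]
    if missing:
        raise InfeasibleRangesError(f"no joint range configured for {missing}")
    pairs = _mirror_pairs(model)
    for _ in range(max_attempts):
        q = np.array([rng.uniform(*model.joint_ranges[j]) for j in model.joints])
        if symmetric:
            for li, ri in pairs:
                q[ri] = q[li]
        theta0 = rng.uniform(*base_tilt_range)
        posture = Posture(np.zeros(2), theta0, q)
        posture = replace_base(posture, y=_ground_base_y(model, posture))
        lo, hi = _support_interval(model, posture)
        if lo <= com_ground_x(model, posture) <= hi:
            return posture
    raise InfeasibleRangesError(
        f"no balanced posture found in {max_attempts} attempts; "
        "check the joint ranges"
    )


def sample_calibration_poses(
    model: BodyModel, n: int, rng: np.random.Generator
) -> list[Posture]:
    """Diverse static calibration poses (asymmetric limbs, wider tilt) for
    SESC identification — calibration deliberately breaks the left/right
    symmetry so the per-side parameters separate."""
    return [sample_posture(model, rng, symmetric=False,
                           base_tilt_range=(-0.26, 0.26)) for _ in range(n)]


def place_load(model: BodyModel, posture: Posture, link: str,
               fraction: float, mass: float) -> ExternalLoad:
    """Point load of ``mass`` kg at ``fraction`` of ``link``'s length."""
    length = model.segment(link).length
    return ExternalLoad.from_mass(mass, link, fraction * length)


def load_world_x(model: BodyModel, posture: Posture, load: ExternalLoad) -> float:
    segs = {s.link: s for s in forward_kinematics(model, posture)}
    return float(point_on_link(segs[load.link], load.position)[0])


def simulate_statics(
    model: BodyModel, posture: Posture, load: ExternalLoad | None = None,
) -> StaticsResult:
    """Exact quasi-static force-plate readings.

    The unloaded CoP is the mass-weighted CoM ground projection and the
    unloaded vGRF the body weight; a point load shifts the CoP to the
    force-weighted average of body CoP and load line and adds its weight to
    the vGRF, so the loaded CoP is always a convex combination of the two.
    """
    cop_wo = com_ground_x(model, posture)
    f_wo = model.total_mass * GRAVITY
    if load is None:
        return StaticsResult(cop_wo, cop_wo, f_wo, f_wo, None)
    spec = model.segment(load.link)
    if not 0.0 <= load.position <= spec.length:
        raise ValueError(f"load position outside link {load.link}")
    f_load = float(-load.force_vec[1])  # downward weight, positive magnitude
    x_load = load_world_x(model, posture, load)
    f_wt = f_wo + f_load
    cop_wt = (cop_wo * f_wo + x_load * f_load) / f_wt
    return StaticsResult(cop_wo, cop_wt, f_wo, f_wt, x_load)


def _free_motion_postures(
    model: BodyModel, base: Posture, times: np.ndarray,
    scenario: "ScenarioSpec", rng: np.random.Generator,
) -> list[Posture]:
    """Slow free movement through the posture space: cosine interpolation
    between balanced keyposes every ``keypose_s`` seconds (starting from
    ``base``), with a small residual sinusoidal sway superimposed —
    emulating a person moving freely but quasi-statically in the sagittal
    plane."""
    n = model.n_joints
    duration = float(times[-1]) if len(times) else 0.0
    n_key = max(2, int(math.ceil(duration / scenario.keypose_s)) + 1)
    keys = [base] + [sample_posture(model, rng, symmetric=scenario.symmetric)
                     for _ in range(n_key - 1)]
    key_q = np.array([k.joint_angles for k in keys])
    key_theta = np.array([k.base_orientation for k in keys])
    freqs = rng.uniform(0.05, 0.2, size=n)
    phases = rng.uniform(0.0, 2 * math.pi, size=n)
    pairs = _mirror_pairs(model) if scenario.symmetric else []
    out = []
    for t in times:
        s = min(t / scenario.keypose_s, n_key - 1 - 1e-9)
        k = int(s)
        w = 0.5 - 0.5 * math.cos(math.pi * (s - k))  # smooth ease in/out
        q = (1 - w) * key_q[k] + w * key_q[k + 1]
        theta = (1 - w) * key_theta[k] + w * key_theta[k + 1]
        dq = scenario.sway_amplitude * np.sin(2 * math.pi * freqs * t + phases)
        for li, ri in pairs:
            dq[ri] = dq[li]
        p = Posture(base.base_position.copy(), theta, q + dq)
        p = replace_base(p, y=_ground_base_y(model, p))
        out.append(p)
    return out


def stream_frame(
    model: BodyModel,
    scenario: ScenarioSpec,
    link: str | None = None,
    fraction: float = 0.5,
    base_posture: Posture | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build one detection episode as a merged posture + plate DataFrame.

    The episode holds an unloaded baseline of ``baseline_s`` seconds, then
    rests the scenario load on ``link`` at ``fraction`` of its length for
    ``loaded_s`` seconds, the posture swaying quasi-statically throughout.
    Noiseless ground-truth columns (suffix ``_true``, plus the load's world
    x) are carried alongside the noisy measurement columns.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    if base_posture is None:
        base_posture = sample_posture(model, rng, symmetric=scenario.symmetric)
    n_base = int(round(scenario.baseline_s * scenario.rate_hz))
    n_load = int(round(scenario.loaded_s * scenario.rate_hz))
    times = np.arange(n_base + n_load) / scenario.rate_hz
    postures = _free_motion_postures(model, base_posture, times, scenario, rng)
    rows = []
    for k, (t, posture) in enumerate(zip(times, postures)):
        loaded = link is not None and k >= n_base
        load = (place_load(model, posture, link, fraction, scenario.load_mass)
                if loaded else None)
        st = simulate_statics(model, posture, load)
        cop_true = st.cop_loaded if loaded else st.cop_unloaded
        f_true = st.vgrf_loaded if loaded else st.vgrf_unloaded
        row = {
            "t": t,
            "base_x": posture.base_position[0],
            "base_y": posture.base_position[1],
            "base_theta": posture.base_orientation,
        }
        for i in range(model.n_joints):
            row[f"q{i + 1}"] = posture.joint_angles[i]
        row["cop_x"] = cop_true + rng.normal(0.0, scenario.noise_cop)
        row["vgrf"] = f_true + rng.normal(0.0, scenario.noise_force)
        row["cop_x_true"] = cop_true
        row["vgrf_true"] = f_true
        row["cop_x_unloaded_true"] = st.cop_unloaded
        row["load_x_true"] = st.load_x if loaded else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def make_stream(
    model: BodyModel,
    scenario: ScenarioSpec,
    out_path: str,
    truth_path: str | None = None,
    link: str | None = None,
    fraction: float = 0.5,
) -> pd.DataFrame:
    """Write a measurement-stream CSV (and optional ground-truth CSV).

    The measurement file carries the documented stream schema
    ``t,base_x,base_y,base_theta,q1..qn,cop_x,vgrf``; the truth file the
    noiseless channels.  Identical scenarios (same seed) produce
    byte-identical files.
    """
    df = stream_frame(model, scenario, link=link, fraction=fraction)
    meas_cols = (["t", "base_x", "base_y", "base_theta"]
                 + [f"q{i + 1}" for i in range(model.n_joints)]
                 + ["cop_x", "vgrf"])
    df[meas_cols].to_csv(out_path, index=False, float_format="%.12g")
    if truth_path is not None:
        truth_cols = ["t", "cop_x_true", "vgrf_true",
                      "cop_x_unloaded_true", "load_x_true"]
        df[truth_cols].to_csv(truth_path, index=False, float_format="%.12g")
    return df


@dataclass
class GridCondition:
    """One factorial condition with its noiseless recovery outcome."""

    pose_index: int
    link: str
    fraction: float
    true_position: float
    estimated_position: float | None
    error: float | None
    intersected: bool


def factorial_grid(
    model: BodyModel,
    scenario: ScenarioSpec | None = None,
    rng: np.random.Generator | None = None,
) -> list[GridCondition]:
    """Enumerate the full pose x link x location design and run the
    noiseless torque-balance localisation on each condition.

    For every condition the exact plate readings are inverted through the
    contact-point formula and intersected with the true link; the signed
    link-frame error and an intersection-failure flag are reported.
    """
    scenario = scenario or ScenarioSpec()
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    poses = [sample_posture(model, rng) for _ in range(scenario.n_poses)]
    out: list[GridCondition] = []
    for pi, posture in enumerate(poses):
        segments = forward_kinematics(model, posture)
        for link in scenario.links:
            length = model.segment(link).length
            for frac in scenario.locations:
                load = place_load(model, posture, link, frac, scenario.load_mass)
                st = simulate_statics(model, posture, load)
                x = contact_x(st.cop_loaded, st.vgrf_loaded,
                              st.cop_unloaded, st.vgrf_unloaded)
                hits = dict(link_intersections(segments, x, list(scenario.links)))
                true_pos = frac * length
                if link in hits:
                    est = hits[link]
                    out.append(GridCondition(pi, link, frac, true_pos,
                                             est, est - true_pos, True))
                else:
                    out.append(GridCondition(pi, link, frac, true_pos,
                                             None, None, False))
    return out
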