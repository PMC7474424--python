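"""Overloading joint torques induced by a detected external load.

In quasi-static conditions the extra torque an external load puts on each
actuated joint is the difference between the loaded and unloaded static
joint torques.  Because the gravity/inertia terms of the full dynamics are
identical in both states they cancel, leaving only Jacobian-transpose
contact terms:

    dtau = S^T [ -J_ah^T f_h
                 + sum_i ( zeta_i J_wo,i^T f_h - (J_wt,i - J_wo,i)^T zeta_i f_wt ) ]

where J_ah is the contact Jacobian at the load application point, J_wo,i /
J_wt,i are the Jacobians of the per-foot ground points at the estimated
(unloaded) and measured (loaded) CoP, f_h the load's weight vector, f_wt the
measured vGRF vector, and zeta_i the per-foot vGRF distribution gains
(summing to one).  S^T selects the actuated rows: the floating-base rows are
never joint torques.

Each joint's magnitude is classified against a per-joint torque capacity
tau_max on a stepwise traffic-light scheme: GREEN up to 0.3 tau_max, ORANGE
up to 0.6 tau_max, RED above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body_model import (
    BodyModel,
    Posture,
    forward_kinematics,
    frame_point_jacobian,
    point_jacobian,
)

__all__ = [
    "ExternalLoad",
    "DistributionGains",
    "OverloadResult",
    "distribution_gains",
    "overloading_torques",
    "classify_level",
    "assess_overload",
    "GREEN",
    "ORANGE",
    "RED",
]

GREEN, ORANGE, RED = "GREEN", "ORANGE", "RED"
#: Level boundaries as fractions of the per-joint torque capacity.
LEVEL_GREEN_MAX = 0.3
LEVEL_ORANGE_MAX = 0.6


@dataclass(frozen=True)
class ExternalLoad:
    """A point load: sagittal force vector (N), carrying link, and
    link-frame position (m from the proximal end)."""

    force: tuple[float, float]
    link: str
    position: float

    @property
    def force_vec(self) -> np.ndarray:
        return np.asarray(self.force, dtype=float)

    @staticmethod
    def from_mass(mass_kg: float, link: str, position: float,
                  g: float = 9.81) -> "ExternalLoad":
        """Purely vertical (downward) weight of a carried mass."""
        return ExternalLoad((0.0, -mass_kg * g), link, position)


@dataclass
class DistributionGains:
    """Per-foot vGRF fractions, in the model's foot order; sum to one."""

    zeta: np.ndarray
    feet: list[str]

    def __post_init__(self) -> None:
        self.zeta = np.asarray(self.zeta, dtype=float)
        if np.any(self.zeta < -1e-12) or np.any(self.zeta > 1 + 1e-12):
            raise ValueError("distribution gains must lie in [0, 1]")
        if abs(float(np.sum(self.zeta)) - 1.0) > 1e-12:
            raise ValueError("distribution gains must sum to 1")


@dataclass
class OverloadResult:
    """Per-joint overloading torques with traffic-light levels."""

    joints: list[str]
    delta_tau: np.ndarray
    tau_max: np.ndarray
    levels: list[str]
    over_limit: np.ndarray  # bool per joint: |dtau| exceeded tau_max


def distribution_gains(
    model: BodyModel, posture: Posture, cop_x: float
) -> DistributionGains:
    """vGRF distribution gains from the body configuration.

    Linear interpolation of the measured CoP between the two ankle ground
    positions (the feet's proximal points), clipped to [0, 1]; a CoP at one
    ankle loads that foot fully.  Coincident ankles (sagittally symmetric
    stance) split the load evenly; a single support foot takes zeta = 1.
    """
    feet = model.foot_links
    if not feet:
        raise ValueError("model defines no foot links")
    segs = {s.link: s for s in forward_kinematics(model, posture)}
    xs = np.array([segs[f].proximal[0] for f in feet])
    if len(feet) == 1:
        return DistributionGains(np.array([1.0]), list(feet))
    if len(feet) != 2:
        raise ValueError("distribution gains support at most two feet")
    span = xs[1] - xs[0]
    if abs(span) < 1e-9:
        z0 = 0.5
    else:
        z0 = float(np.clip((xs[1] - cop_x) / span, 0.0, 1.0))
    return DistributionGains(np.array([z0, 1.0 - z0]), list(feet))


def overloading_torques(
    model: BodyModel,
    posture: Posture,
    load: ExternalLoad,
    cop_measured: float,
    cop_estimated: float,
    vgrf_measured: float,
    gains: DistributionGains,
) -> np.ndarray:
    """Per-joint overloading torques (N m), in model joint order.

    Implements the three Jacobian-transpose terms of the loaded-minus-
    unloaded static balance with the body-dynamics terms cancelled; the
    per-foot ground points sit at the measured CoP (loaded state) and at the
    model-estimated CoP (unloaded state), both on the ground line y = 0.
    """
    spec = model.segment(load.link)
    if not 0.0 <= load.position <= spec.length:
        raise ValueError(
            f"load position {load.position} outside [0, {spec.length}] "
            f"on link {load.link}"
        )
    segments = forward_kinematics(model, posture)
    fh = load.force_vec
    fwt = np.array([0.0, vgrf_measured])

    J_ah = point_jacobian(model, posture, load.link, load.position, segments)
    tau = -J_ah.matrix.T @ fh
    for zeta_i, foot in zip(gains.zeta, gains.feet):
        J_wo = frame_point_jacobian(
            model, posture, foot, np.array([cop_estimated, 0.0]), segments)
        J_wt = frame_point_jacobian(
            model, posture, foot, np.array([cop_measured, 0.0]), segments)
        tau += zeta_i * (J_wo.matrix.T @ fh)
        tau -= (J_wt.matrix - J_wo.matrix).T @ (zeta_i * fwt)
    return tau[3:]  # actuated rows only


def classify_level(delta_tau: float, tau_max: float) -> tuple[str, bool]:
    """Traffic-light level for one joint: ``(level, over_limit)``.

    Levels act on the torque magnitude; the GREEN/ORANGE and ORANGE/RED
    boundaries are inclusive on the lower band.  Magnitudes beyond tau_max
    clamp to RED with the over-limit flag raised.
    """
    if tau_max <= 0:
        raise ValueError("tau_max must be > 0")
    a = abs(delta_tau)
    if a > tau_max:
        return RED, True
    if a <= LEVEL_GREEN_MAX * tau_max:
        return GREEN, False
    if a <= LEVEL_ORANGE_MAX * tau_max:
        return ORANGE, False
    return RED, False


def assess_overload(
    model: BodyModel,
    posture: Posture,
    load: ExternalLoad,
    cop_measured: float,
    cop_estimated: float,
    vgrf_measured: float,
    tau_max: dict[str, float] | None = None,
) -> OverloadResult:
    """Full per-joint assessment: torques, capacities and levels."""
    gains = distribution_gains(model, posture, cop_measured)
    dtau = overloading_torques(
        model, posture, load, cop_measured, cop_estimated, vgrf_measured, gains)
    limits = tau_max if tau_max is not None else model.torque_limits
    missing = [j for j in model.joints if j not in limits]
    if missing:
        raise ValueError(f"no torque limit configured for joints: {missing}")
    tmax = np.array([limits[j] for j in model.joints])
    levels, over = [], []
    for d, tm in zip(dtau, tmax):
        lvl, o = classify_level(float(d), float(tm))
        levels.append(lvl)
        over.append(o)
    return OverloadResult(
        joints=list(model.joints),
        delta_tau=dtau,
        tau_max=tmax,
        levels=levels,
        over_limit=np.array(over, dtype=bool),
    )
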