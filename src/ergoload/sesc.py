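"""Statically equivalent serial chain (SESC) centre-of-mass model.

Whatever the true mass distribution, the whole-body CoM of a branched chain
is an exactly linear function of the segment rotation matrices:

    CoM = x0 + sum_i  A_i(q) . phi_i

where A_i are the world rotations of the base frame and of every link, and
phi_i are constant "mass distribution" vectors (metre-weighted mass
fractions).  In quasi-static stance the ground CoP equals the ground
projection of the CoM, so stacking the x-row of the rotations over a set of
calibration poses gives a linear regressor W with  W . Phi = CoP_x - x0_x,
and Phi is identified by ordinary least squares (Moore-Penrose pseudo-
inverse).  The identified model then predicts the *unloaded* CoP for any
posture, which is what the contact-point torque balance needs online.

In this planar reduction each block phi_i has 2 components (x, y in the link
frame); only the x-row of each 2x2 rotation enters the CoP regression.  The
block order is the model's segment order, the base-fixed pelvis segment
playing the role of the base block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body_model import BodyModel, Posture, forward_kinematics

__all__ = [
    "SESCParameters",
    "CalibrationSet",
    "IllConditionedCalibrationError",
    "build_regressor",
    "identify_parameters",
    "estimate_cop",
    "true_parameters",
]

#: Refuse identification above this regressor condition number: the
#: calibration poses were not diverse enough to separate the parameters.
DEFAULT_COND_MAX = 1e8


class IllConditionedCalibrationError(RuntimeError):
    """Calibration poses do not excite the parameters (rank-deficient or
    numerically ill-conditioned regressor)."""

    def __init__(self, message: str, cond: float, rank: int, n_params: int):
        super().__init__(message)
        self.cond = cond
        self.rank = rank
        self.n_params = n_params


@dataclass
class SESCParameters:
    """Identified (or analytic) SESC parameter vector.

    ``phi`` has length ``2 * (n_links + 1)``: one (x, y) block per segment,
    base block first.  ``residual_rms``/``rank``/``cond`` are identification
    diagnostics (None for analytic parameters).
    """

    phi: np.ndarray
    segment_names: list[str]
    residual_rms: float | None = None
    rank: int | None = None
    cond: float | None = None
    model_hash: str | None = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phi must be finite")
        if self.phi.shape != (2 * len(self.segment_names),):
            raise ValueError("phi length must be 2 * number of blocks")

    @property
    def n_blocks(self) -> int:
        return len(self.segment_names)

    def block(self, name: str) -> np.ndarray:
        i = self.segment_names.index(name)
        return self.phi[2 * i: 2 * i + 2]


@dataclass
class CalibrationSet:
    """Static calibration poses paired with their measured ground CoP x.

    ``measured_cop`` is one value per pose; when a pose was held for a dwell
    window the caller averages the force-plate samples first (see
    :func:`ergoload.io.read_calibration`).
    """

    model: BodyModel
    poses: list[Posture]
    measured_cop: np.ndarray
    _regressor: np.ndarray | None = field(default=None, repr=False)
    _base_x: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.measured_cop = np.asarray(self.measured_cop, dtype=float)
        if len(self.poses) < 1:
            raise ValueError("calibration needs at least one pose")
        if self.measured_cop.shape != (len(self.poses),):
            raise ValueError("one measured CoP value per pose is required")

    @property
    def regressor(self) -> np.ndarray:
        if self._regressor is None:
            self._regressor, self._base_x = build_regressor(self.model, self.poses)
        return self._regressor

    @property
    def base_x(self) -> np.ndarray:
        _ = self.regressor
        return self._base_x


def _rotation_row(model: BodyModel, posture: Posture) -> np.ndarray:
    """x-row of the stacked link rotations for one posture: per block
    [cos(theta_i), -sin(theta_i)]."""
    segs = forward_kinematics(model, posture)
    row = np.empty(2 * len(segs))
    for i, seg in enumerate(segs):
        row[2 * i] = seg.rotation[0, 0]
        row[2 * i + 1] = seg.rotation[0, 1]
    return row


def build_regressor(
    model: BodyModel, poses: list[Posture]
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-projected, base-relative CoP regressor.

    Returns ``(W, base_x)`` with ``W`` of shape ``(p, 2*(n_links+1))`` and
    ``base_x`` the per-pose base ground projection, so that
    ``W @ phi + base_x`` predicts the CoP x-coordinate.
    """
    if not poses:
        raise ValueError("poses must be non-empty")
    W = np.vstack([_rotation_row(model, p) for p in poses])
    base_x = np.array([p.base_position[0] for p in poses])
    return W, base_x


def identify_parameters(
    calib: CalibrationSet, cond_max: float = DEFAULT_COND_MAX
) -> SESCParameters:
    """Least-squares identification of the SESC parameter vector.

    Solves ``W phi = cop_x - base_x`` by the Moore-Penrose pseudo-inverse
    and reports the residual RMS and regressor rank.  Raises
    :class:`IllConditionedCalibrationError` when the poses are not diverse
    enough (condition number above ``cond_max``), e.g. repeated identical
    poses.
    """
    W = calib.regressor
    omega = calib.measured_cop - calib.base_x
    n_params = W.shape[1]
    svals = np.linalg.svd(W, compute_uv=False)
    rank = int(np.sum(svals > svals[0] * max(W.shape) * np.finfo(float).eps))
    cond = float(svals[0] / svals[-1]) if svals[-1] > 0 else float("inf")
    if rank < n_params or cond > cond_max:
        raise IllConditionedCalibrationError(
            f"calibration regressor is ill-conditioned "
            f"(rank {rank}/{n_params}, condition number {cond:.3g}); "
            f"hold more poses with more varied segment orientations",
            cond=cond, rank=rank, n_params=n_params,
        )
    phi, *_ = np.linalg.lstsq(W, omega, rcond=None)
    residual = W @ phi - omega
    return SESCParameters(
        phi=phi,
        segment_names=[s.name for s in calib.model.segments],
        residual_rms=float(np.sqrt(np.mean(residual**2))),
        rank=rank,
        cond=cond,
    )


def estimate_cop(
    model: BodyModel, params: SESCParameters, posture: Posture
) -> float:
    """Model-predicted unloaded ground CoP x for one posture."""
    row = _rotation_row(model, posture)
    if row.shape != params.phi.shape:
        raise ValueError("parameter vector does not match the model")
    return float(posture.base_position[0] + row @ params.phi)


def true_parameters(model: BodyModel) -> SESCParameters:
    """Analytic SESC parameters from the model's segment masses.

    Each block is ``phi_i = (m_i c_i + L_i D_i) / M`` where ``c_i`` is the
    link-frame CoM offset, ``L_i`` the link-frame length vector and ``D_i``
    the total mass carried distally through link *i* (all segments whose
    attachment path traverses *i*'s length).  Used by the statics simulator
    and as the noiseless oracle for identification.
    """
    M = model.total_mass
    if M <= 0:
        raise ValueError("model must have positive total mass")
    order = [s.name for s in model.segments]
    carried = {name: 0.0 for name in order}
    by_name = {s.name: s for s in model.segments}
    for s in model.segments:
        # walk up: each distal attachment hop carries this mass across the
        # parent's length
        child = s
        while child.parent is not None:
            if child.attach == "distal":
                carried[child.parent] += s.mass
            child = by_name[child.parent]
    phi = np.zeros(2 * len(order))
    for i, s in enumerate(model.segments):
        phi[2 * i] = (s.mass * s.com_offset + s.length * carried[s.name]) / M
        phi[2 * i + 1] = 0.0  # link-frame CoM lies on the segment axis
    return SESCParameters(phi=phi, segment_names=order)
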