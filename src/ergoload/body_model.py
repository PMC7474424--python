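"""Planar (sagittal) floating-base kinematic chain of the human body.

The body is modelled as a tree of rigid segments rooted in a floating pelvis
frame.  Generalised coordinates are ``[base_x, base_y, base_theta, q_1..q_n]``
(n actuated joints), i.e. a 3-DoF planar base followed by the joint vector.
All lengths are metres, angles radians; the world frame has x pointing in the
anterior (walking) direction, y vertically up, and the ground at y = 0.

Every segment extends along its local +x axis from its proximal attachment
point.  A segment's world angle is::

    theta_seg = theta_parent + rest_angle + q_joint

where ``rest_angle`` is a fixed mounting offset chosen so that the zero
posture is a natural upright stance, and ``q_joint`` is the actuated angle
(zero for segments rigidly attached to the base, e.g. the pelvis itself).
Children may attach at the parent's distal end (the usual serial case) or at
its proximal end (branching at the pelvis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentSpec",
    "BodyModel",
    "Posture",
    "LinkSegment2D",
    "PointJacobian",
    "DimensionMismatchError",
    "UnknownLinkError",
    "GeometryError",
    "forward_kinematics",
    "point_jacobian",
    "frame_point_jacobian",
    "to_link_frame",
    "point_on_link",
]


class DimensionMismatchError(ValueError):
    """Posture dimension does not match the model joint count."""


class UnknownLinkError(KeyError):
    """A link name not present in the model was requested."""


class GeometryError(ValueError):
    """A point does not satisfy the geometric precondition (e.g. off-axis)."""


@dataclass(frozen=True)
class SegmentSpec:
    """Geometry and inertia of one body segment.

    ``parent`` is the name of the parent segment (``None`` for a segment
    rigidly carried by the floating base, such as the pelvis), ``joint`` the
    name of the actuated joint connecting it to the parent (``None`` for
    base-fixed segments), ``attach`` either ``"distal"`` or ``"proximal"``
    (point on the parent where this segment's proximal end sits) and
    ``rest_angle`` the fixed mounting offset in radians.
    """

    name: str
    length: float
    mass: float
    com_offset: float
    parent: str | None = None
    joint: str | None = None
    attach: str = "distal"
    rest_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0")
        if self.mass < 0:
            raise ValueError(f"segment {self.name}: mass must be >= 0")
        if not 0.0 <= self.com_offset <= self.length:
            raise ValueError(
                f"segment {self.name}: com_offset must lie in [0, length]"
            )
        if self.attach not in ("distal", "proximal"):
            raise ValueError(f"segment {self.name}: attach must be distal|proximal")


@dataclass
class BodyModel:
    """Tree of :class:`SegmentSpec` plus the actuated-joint ordering.

    ``joints`` fixes the order of the joint block of the generalised
    coordinate vector; ``candidate_links`` lists the links on which an
    external load may be detected; ``foot_links`` the segments that touch the
    ground (used for vGRF distribution gains).
    """

    segments: list[SegmentSpec]
    joints: list[str]
    candidate_links: list[str] = field(default_factory=list)
    foot_links: list[str] = field(default_factory=list)
    joint_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    torque_limits: dict[str, float] = field(default_factory=dict)
    name: str = "body"

    def __post_init__(self) -> None:
        by_name = {s.name: s for s in self.segments}
        if len(by_name) != len(self.segments):
            raise ValueError("duplicate segment names")
        declared = {s.joint for s in self.segments if s.joint is not None}
        if declared != set(self.joints):
            raise ValueError(
                "joints list must match the joints declared by the segments"
            )
        for s in self.segments:
            if s.parent is not None and s.parent not in by_name:
                raise ValueError(f"segment {s.name}: unknown parent {s.parent}")
            if s.parent is None and s.joint is not None:
                raise ValueError(f"segment {s.name}: base segments carry no joint")
        self._by_name = by_name
        self._joint_index = {j: i for i, j in enumerate(self.joints)}

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    @property
    def n_coords(self) -> int:
        """Generalised-coordinate dimension: 2 base translations + base
        rotation + joints."""
        return 3 + self.n_joints

    @property
    def n_links(self) -> int:
        """Number of non-base segments (the base segment is counted
        separately wherever a per-link block structure is needed)."""
        return len(self.segments) - sum(1 for s in self.segments if s.parent is None)

    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments))

    def segment(self, name: str) -> SegmentSpec:
        try:
            return self._by_name[name]
        except KeyError as exc:
            raise UnknownLinkError(name) from exc

    def joint_index(self, joint: str) -> int:
        return self._joint_index[joint]

    def chain_to(self, link: str) -> list[SegmentSpec]:
        """Segments from the base down to (and including) ``link``."""
        chain: list[SegmentSpec] = []
        seg: SegmentSpec | None = self.segment(link)
        while seg is not None:
            chain.append(seg)
            seg = self._by_name[seg.parent] if seg.parent is not None else None
        return list(reversed(chain))


@dataclass
class Posture:
    """One whole-body configuration sample."""

    base_position: np.ndarray
    base_orientation: float
    joint_angles: np.ndarray

    def __post_init__(self) -> None:
        self.base_position = np.asarray(self.base_position, dtype=float)
        self.joint_angles = np.atleast_1d(np.asarray(self.joint_angles, dtype=float))
        if self.base_position.shape != (2,):
            raise DimensionMismatchError("base_position must be a 2-vector")
        if not np.all(np.isfinite(self.base_position)):
            raise DimensionMismatchError("base_position must be finite")
        if not np.isfinite(self.base_orientation):
            raise DimensionMismatchError("base_orientation must be finite")
        if not np.all(np.isfinite(self.joint_angles)):
            raise DimensionMismatchError("joint_angles must be finite")

    def translated(self, dx: float, dy: float) -> "Posture":
        return Posture(self.base_position + np.array([dx, dy]),
                       self.base_orientation, self.joint_angles.copy())


@dataclass
class LinkSegment2D:
    """World-frame placement of one segment: endpoints plus rotation."""

    link: str
    proximal: np.ndarray
    distal: np.ndarray
    rotation: np.ndarray  # 2x2, world_from_link

    @property
    def angle(self) -> float:
        return math.atan2(self.rotation[1, 0], self.rotation[0, 0])

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.distal - self.proximal))

    @property
    def axis(self) -> np.ndarray:
        return self.rotation[:, 0]


@dataclass
class PointJacobian:
    """Planar point Jacobian: maps generalised velocities to the point's
    world velocity.  ``matrix`` is (2, n+3); columns are [base_x, base_y,
    base_theta, q_1..q_n].  ``matrix.T @ f`` gives generalised forces; the
    last n rows are the actuated joint torques (the S-selection)."""

    matrix: np.ndarray
    link: str
    point: np.ndarray

    def generalized_forces(self, force: np.ndarray) -> np.ndarray:
        return self.matrix.T @ np.asarray(force, dtype=float)

    def joint_torques(self, force: np.ndarray) -> np.ndarray:
        return self.generalized_forces(force)[3:]


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _check_dims(model: BodyModel, posture: Posture) -> None:
    if posture.joint_angles.shape != (model.n_joints,):
        raise DimensionMismatchError(
            f"posture has {posture.joint_angles.shape[0]} joint angles, "
            f"model has {model.n_joints} joints"
        )


def forward_kinematics(model: BodyModel, posture: Posture) -> list[LinkSegment2D]:
    """Place every segment in the world frame.

    Returns one :class:`LinkSegment2D` per segment, in model order.  The
    distal point of a parent coincides with the proximal point of any
    distal-attached child.
    """
    _check_dims(model, posture)
    placed: dict[str, LinkSegment2D] = {}
    angles: dict[str, float] = {}
    # segments are stored parents-first is not guaranteed; iterate until done
    pending = list(model.segments)
    while pending:
        progressed = False
        for seg in list(pending):
            if seg.parent is None:
                parent_angle = posture.base_orientation
                origin = posture.base_position
            elif seg.parent in placed:
                parent_angle = angles[seg.parent]
                parent_placed = placed[seg.parent]
                origin = (parent_placed.distal if seg.attach == "distal"
                          else parent_placed.proximal)
            else:
                continue
            q = posture.joint_angles[model.joint_index(seg.joint)] if seg.joint else 0.0
            theta = parent_angle + seg.rest_angle + q
            R = _rot(theta)
            proximal = np.asarray(origin, dtype=float)
            distal = proximal + R @ np.array([seg.length, 0.0])
            placed[seg.name] = LinkSegment2D(seg.name, proximal, distal, R)
            angles[seg.name] = theta
            pending.remove(seg)
            progressed = True
        if not progressed:
            raise ValueError("segment tree contains a cycle or unknown parent")
    return [placed[s.name] for s in model.segments]


def _joint_positions(model: BodyModel, segments: list[LinkSegment2D]) -> dict[str, np.ndarray]:
    """World position of every actuated joint (the proximal point of the
    segment it drives)."""
    by_name = {s.link: s for s in segments}
    out: dict[str, np.ndarray] = {}
    for spec in model.segments:
        if spec.joint is not None:
            out[spec.joint] = by_name[spec.name].proximal
    return out


def _perp(v: np.ndarray) -> np.ndarray:
    """90-degree CCW rotation: the planar 'omega cross r' operator."""
    return np.array([-v[1], v[0]])


def frame_point_jacobian(
    model: BodyModel,
    posture: Posture,
    link: str,
    world_point: np.ndarray,
    segments: list[LinkSegment2D] | None = None,
) -> PointJacobian:
    """Jacobian of an arbitrary world point rigidly attached to ``link``.

    The point need not lie on the segment axis (a ground CoP under a foot is
    a typical off-axis frame point).
    """
    _check_dims(model, posture)
    if segments is None:
        segments = forward_kinematics(model, posture)
    model.segment(link)  # raises UnknownLinkError
    p = np.asarray(world_point, dtype=float)
    joint_pos = _joint_positions(model, segments)
    J = np.zeros((2, model.n_coords))
    J[:, 0] = (1.0, 0.0)
    J[:, 1] = (0.0, 1.0)
    J[:, 2] = _perp(p - posture.base_position)
    for spec in model.chain_to(link):
        if spec.joint is not None:
            J[:, 3 + model.joint_index(spec.joint)] = _perp(p - joint_pos[spec.joint])
    return PointJacobian(J, link, p)


def point_jacobian(
    model: BodyModel,
    posture: Posture,
    link: str,
    local_point: float,
    segments: list[LinkSegment2D] | None = None,
) -> PointJacobian:
    """Jacobian of the material point ``local_point`` metres from the
    proximal end along the axis of ``link``."""
    spec = model.segment(link)
    if not 0.0 <= local_point <= spec.length:
        raise ValueError(
            f"local_point {local_point} outside [0, {spec.length}] on {link}"
        )
    if segments is None:
        segments = forward_kinematics(model, posture)
    seg = next(s for s in segments if s.link == link)
    world = point_on_link(seg, local_point)
    return frame_point_jacobian(model, posture, link, world, segments)


def point_on_link(segment: LinkSegment2D, local_point: float) -> np.ndarray:
    """World position of the point ``local_point`` metres along the link
    axis from the proximal end (inverse of :func:`to_link_frame`)."""
    return segment.proximal + segment.axis * local_point


def to_link_frame(
    segment: LinkSegment2D, world_point: np.ndarray, tol: float = 1e-6
) -> float:
    """Scalar link-frame coordinate of a world point on the link axis.

    Raises :class:`GeometryError` when the point lies further than ``tol``
    from the segment's supporting line.
    """
    p = np.asarray(world_point, dtype=float)
    d = p - segment.proximal
    s = float(d @ segment.axis)
    off = d - s * segment.axis
    if float(np.linalg.norm(off)) > tol:
        raise GeometryError(
            f"point {p} is {np.linalg.norm(off):.3e} m off the {segment.link} axis"
        )
    return s
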