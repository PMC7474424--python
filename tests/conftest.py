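"""Shared fixtures: the packaged body model and small hand-built chains."""

from __future__ import annotations

import numpy as np
import pytest

from ergoload import BodyModel, Posture, SegmentSpec, default_body_model


@pytest.fixture(scope="session")
def model() -> BodyModel:
    return default_body_model()


def make_arm(l1: float = 0.3, l2: float = 0.25,
             m1: float = 2.0, m2: float = 1.5) -> BodyModel:
    """Planar two-link arm on a short base-fixed root: joints shoulder,
    elbow; zero posture lies along +x."""
    segs = [
        SegmentSpec("root", 0.05, 0.0, 0.0, None, None),
        SegmentSpec("upper", l1, m1, l1 / 2, "root", "shoulder", "proximal"),
        SegmentSpec("lower", l2, m2, l2 / 2, "upper", "elbow"),
    ]
    return BodyModel(segs, ["shoulder", "elbow"],
                     candidate_links=["lower", "upper"], foot_links=["root"])


@pytest.fixture()
def arm() -> BodyModel:
    return make_arm()


def arm_posture(q1: float, q2: float, base=(0.0, 0.0), theta: float = 0.0) -> Posture:
    return Posture(np.asarray(base, dtype=float), theta, np.array([q1, q2]))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_posture(model: BodyModel, rng: np.random.Generator) -> Posture:
    """Unconstrained random configuration (no balance filter) for kinematic
    property tests."""
    return Posture(
        rng.uniform(-0.5, 0.5, size=2),
        rng.uniform(-0.5, 0.5),
        rng.uniform(-1.0, 1.0, size=model.n_joints),
    )
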