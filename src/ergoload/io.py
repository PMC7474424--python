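"""File formats and stream readers/writers.

Units everywhere: seconds, metres, newtons, newton-metres, radians (files
that state degrees are converted on load).  The merged measurement stream
is a CSV with header ``t,base_x,base_y,base_theta,q1..qn,cop_x,vgrf``, one
row per sample.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .body_model import BodyModel, Posture, SegmentSpec
from .detection import ContactEstimate, DetectionConfig, ForcePlateSample
from .sesc import CalibrationSet, SESCParameters

__all__ = [
    "SchemaError",
    "StreamParseError",
    "load_body_model",
    "default_body_model",
    "model_hash",
    "save_sesc",
    "load_sesc",
    "read_stream",
    "write_stream",
    "postures_from_stream",
    "plates_from_stream",
    "read_calibration",
    "write_calibration",
    "save_estimate",
    "load_estimate",
    "load_detection_config",
]

logger = logging.getLogger("ergoload")


class SchemaError(ValueError):
    """A file does not match its documented schema."""


class StreamParseError(ValueError):
    """A stream file could not be parsed."""


# ---------------------------------------------------------------- body model

def _model_from_dict(doc: dict) -> BodyModel:
    try:
        segments = [
            SegmentSpec(
                name=s["name"],
                length=float(s["length_m"]),
                mass=float(s["mass_kg"]),
                com_offset=float(s["com_offset_m"]),
                parent=s.get("parent"),
                joint=s.get("joint"),
                attach=s.get("attach", "distal"),
                rest_angle=math.radians(float(s.get("rest_deg", 0.0))),
            )
            for s in doc["segments"]
        ]
        ranges = {
            j: (math.radians(lo), math.radians(hi))
            for j, (lo, hi) in doc.get("joint_ranges_deg", {}).items()
        }
        return BodyModel(
            segments=segments,
            joints=list(doc["joints"]),
            candidate_links=list(doc.get("candidate_links", [])),
            foot_links=list(doc.get("foot_links", [])),
            joint_ranges=ranges,
            torque_limits={k: float(v)
                           for k, v in doc.get("torque_limits_Nm", {}).items()},
            name=doc.get("name", "body"),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"invalid body-model file: {exc}") from exc


def load_body_model(path: str | Path) -> BodyModel:
    """Load a body model from its YAML definition file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"body-model file {path} is not a mapping")
    return _model_from_dict(doc)


def default_body_model() -> BodyModel:
    """The packaged 70 kg Dempster-style default model."""
    ref = resources.files("ergoload.data").joinpath("body_default.yaml")
    return _model_from_dict(yaml.safe_load(ref.read_text()))


def model_hash(model: BodyModel) -> str:
    """Stable digest of the model's kinematic/inertial content, stored with
    identified parameters as provenance."""
    doc = {
        "name": model.name,
        "joints": model.joints,
        "segments": [
            [s.name, s.length, s.mass, s.com_offset, s.parent, s.joint,
             s.attach, round(s.rest_angle, 12)]
            for s in model.segments
        ],
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


# ------------------------------------------------------------ SESC parameters

def save_sesc(params: SESCParameters, model: BodyModel, path: str | Path) -> None:
    doc = {
        "model_hash": model_hash(model),
        "segment_names": params.segment_names,
        "phi": [float(v) for v in params.phi],
        "residual_rms_m": params.residual_rms,
        "regressor_rank": params.rank,
        "regressor_cond": params.cond,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_sesc(path: str | Path, model: BodyModel | None = None) -> SESCParameters:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        params = SESCParameters(
            phi=np.asarray(doc["phi"], dtype=float),
            segment_names=list(doc["segment_names"]),
            residual_rms=doc.get("residual_rms_m"),
            rank=doc.get("regressor_rank"),
            cond=doc.get("regressor_cond"),
            model_hash=doc.get("model_hash"),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"invalid SESC parameter file: {exc}") from exc
    if model is not None and params.model_hash is not None:
        if params.model_hash != model_hash(model):
            logger.warning(
                "SESC parameters in %s were identified on a different body "
                "model (hash %s != %s)", path, params.model_hash,
                model_hash(model))
    return params


# ------------------------------------------------------------------- streams

def _stream_columns(model: BodyModel) -> list[str]:
    return (["t", "base_x", "base_y", "base_theta"]
            + [f"q{i + 1}" for i in range(model.n_joints)]
            + ["cop_x", "vgrf"])


def read_stream(path: str | Path, model: BodyModel) -> pd.DataFrame:
    """Read and validate a merged posture + force-plate stream CSV.

    Missing columns (including a joint-count mismatch) raise
    :class:`SchemaError`; an empty or unreadable file raises
    :class:`StreamParseError`; non-monotonic timestamps are kept but logged.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise StreamParseError(f"cannot parse stream file {path}: {exc}") from exc
    expected = _stream_columns(model)
    missing = [c for c in expected if c not in df.columns]
    extra_q = [c for c in df.columns
               if c.startswith("q") and c[1:].isdigit() and c not in expected]
    if missing or extra_q:
        raise SchemaError(
            f"stream {path} does not match the model "
            f"({model.n_joints} joints): missing columns {missing}, "
            f"unexpected joint columns {extra_q}")
    if len(df) == 0:
        raise StreamParseError(f"stream file {path} contains no samples")
    bad = df[expected].isna().any(axis=1)
    if bad.any():
        raise StreamParseError(
            f"stream file {path}: malformed row at line "
            f"{int(bad.idxmax()) + 2}")
    t = df["t"].to_numpy()
    if np.any(np.diff(t) < 0):
        logger.warning("stream %s has non-monotonic timestamps; rows kept", path)
    return df


def write_stream(df: pd.DataFrame, path: str | Path, model: BodyModel) -> None:
    df[_stream_columns(model)].to_csv(path, index=False, float_format="%.12g")


def postures_from_stream(df: pd.DataFrame, model: BodyModel) -> list[Posture]:
    qcols = [f"q{i + 1}" for i in range(model.n_joints)]
    base = df[["base_x", "base_y"]].to_numpy()
    theta = df["base_theta"].to_numpy()
    q = df[qcols].to_numpy()
    return [Posture(base[i], float(theta[i]), q[i]) for i in range(len(df))]


def plates_from_stream(df: pd.DataFrame) -> list[ForcePlateSample]:
    return [ForcePlateSample(float(r.t), float(r.cop_x), float(r.vgrf))
            for r in df.itertuples()]


# --------------------------------------------------------------- calibration

def write_calibration(model: BodyModel, poses: list[Posture],
                      cop_x: np.ndarray, vgrf: np.ndarray,
                      path: str | Path) -> None:
    """Write a calibration CSV: one (or more) posture rows per static pose
    with the measured ``cop_x`` and ``vgrf``."""
    rows = []
    for i, p in enumerate(poses):
        row = {"pose_id": i, "base_x": p.base_position[0],
               "base_y": p.base_position[1], "base_theta": p.base_orientation}
        for k in range(model.n_joints):
            row[f"q{k + 1}"] = p.joint_angles[k]
        row["cop_x"] = float(cop_x[i])
        row["vgrf"] = float(vgrf[i])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_calibration(path: str | Path, model: BodyModel) -> CalibrationSet:
    """Read a calibration CSV into a :class:`CalibrationSet`.

    When a ``pose_id`` column is present, the rows of each dwell window are
    averaged (posture and CoP alike) into a single static pose; otherwise
    every row is one pose.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise StreamParseError(f"cannot parse calibration file {path}: {exc}") from exc
    qcols = [f"q{i + 1}" for i in range(model.n_joints)]
    needed = ["base_x", "base_y", "base_theta", *qcols, "cop_x"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"calibration {path}: missing columns {missing}")
    if len(df) == 0:
        raise StreamParseError(f"calibration file {path} contains no rows")
    if "pose_id" in df.columns:
        df = df.groupby("pose_id", as_index=False).mean(numeric_only=True)
    poses = [
        Posture(np.array([r["base_x"], r["base_y"]]), float(r["base_theta"]),
                r[qcols].to_numpy(dtype=float))
        for _, r in df.iterrows()
    ]
    return CalibrationSet(model, poses, df["cop_x"].to_numpy(dtype=float))


# ------------------------------------------------------- estimates & configs

def save_estimate(estimate: ContactEstimate, path: str | Path) -> None:
    doc = {"link": estimate.link, "position_m": estimate.position,
           "world_x_m": estimate.world_x, "n_used": estimate.n_used,
           "elapsed_s": estimate.elapsed}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_estimate(path: str | Path) -> ContactEstimate:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        return ContactEstimate(link=doc["link"], position=float(doc["position_m"]),
                               world_x=float(doc["world_x_m"]),
                               n_used=int(doc["n_used"]),
                               elapsed=float(doc["elapsed_s"]))
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"invalid estimate file {path}: {exc}") from exc


def load_detection_config(path: str | Path | None) -> DetectionConfig:
    if path is None:
        return DetectionConfig()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise SchemaError(f"detection config {path} is not a mapping")
    known = set(DetectionConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise SchemaError(f"detection config {path}: unknown keys {sorted(unknown)}")
    return DetectionConfig(**doc)
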