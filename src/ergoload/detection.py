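"""Online detection and localisation of an external load's contact point.

When a point load of weight ``f_h`` rests on the body, the measured ground
CoP shifts away from the model-predicted unloaded CoP.  Taking moments about
a ground pivot in the sagittal plane, the x-coordinate of the load's line of
action is

    x_ah = (CP_wt * f_wt - CP_wo * f_wo) / (f_wt - f_wo)

with (CP_wt, f_wt) the measured loaded CoP/vGRF and (CP_wo, f_wo) the
unloaded reference.  Each sample of x_ah is intersected with the body's
candidate links; the local (link-frame) coordinates accumulate per link.
Sensor noise makes the per-link samples approximately Gaussian on the link
actually carrying the load, and systematically non-Gaussian (truncated,
multi-modal) on links crossed only incidentally — so the carrying link is
selected as the first candidate whose sample passes a one-sided
Anderson-Darling normality test (A-squared below a critical value, default
0.735 at the 5% level).  Once a link is latched it is never revised within
the episode.  The estimate is emitted when the confidence half-width of the
sample mean, z* . sd / sqrt(n), drops below a threshold (default 1 cm); the
sample mean is the reported contact position.

The raw torque balance amplifies CoP sensor noise by roughly
``f_wt / (f_wt - f_wo)`` — an order of magnitude for loads of a few
kilograms — so the detector low-pass filters the plate channels first: each
accumulated sample is the mean of a causal window of ``filter_window``
consecutive loaded readings, and windows do not overlap (decimation), which
keeps the accumulated samples independent for the normality test.  A window
of one disables filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .body_model import (
    BodyModel,
    LinkSegment2D,
    Posture,
    forward_kinematics,
    point_on_link,
)
from .sesc import SESCParameters, estimate_cop

__all__ = [
    "ForcePlateSample",
    "DetectionConfig",
    "LinkSampleSet",
    "DetectionState",
    "ContactEstimate",
    "NotCalibratedError",
    "contact_x",
    "link_intersections",
    "ad_statistic",
    "confidence_halfwidth",
    "detect_step",
    "run_detection",
]

#: Clamp for the normal CDF before taking logs in the A-squared sum.
_CDF_EPS = 1e-15
#: Below this sample standard deviation (metres) a sample set is treated as
#: perfectly concentrated: A-squared = 0 by convention (accept, degenerate).
_SD_EPS = 1e-12


class NotCalibratedError(RuntimeError):
    """Detection was started without identified SESC parameters."""


@dataclass(frozen=True)
class ForcePlateSample:
    """One force-plate reading: ground CoP x (m) and total vGRF (N)."""

    t: float
    cop_x: float
    vgrf: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t) and math.isfinite(self.cop_x)
                and math.isfinite(self.vgrf)):
            raise ValueError("force-plate sample must be finite")
        if self.vgrf <= 0:
            raise ValueError("vGRF must be positive")


@dataclass
class DetectionConfig:
    """Tunables of the online detector.

    Defaults follow a 5% significance level: Anderson-Darling critical value
    0.735, z* = 1.96, stopping threshold 1 cm on the confidence half-width,
    and a minimum of 50 samples per link before testing.  ``min_load`` gates
    the torque-balance division against a near-zero force difference.
    ``f_wo`` fixes the unloaded reference vGRF; when None it is estimated as
    the mean vGRF over the first ``baseline_n`` samples (assumed unloaded).
    ``reset_dwell_n`` consecutive unloaded samples after a load was seen
    clear the episode state.  ``filter_window`` is the length (in samples)
    of the causal moving-average prefilter on the plate channels; one
    accumulated sample is produced per full non-overlapping window of
    consecutive gate-passing readings (window 1 = no filtering).
    ``qs_max_drift`` rejects windows during which the model CoP drifted
    more than this distance — the torque balance only holds quasi-
    statically, so samples taken during fast motion are discarded.
    ``min_inclination`` discards crossings of links whose horizontal extent
    is below this fraction of their length: the link-frame coordinate error
    scales with the reciprocal of the inclination, so near-vertical
    crossings produce wildly heteroscedastic samples that violate the
    homoscedastic Gaussian sample model behind the normality test.
    """

    significance: float = 0.05
    ad_critical: float = 0.735
    z_star: float = 1.96
    ci_threshold: float = 0.01
    n_min: int = 50
    min_load: float = 5.0
    link_order: list[str] | None = None
    f_wo: float | None = None
    baseline_n: int = 100
    reset_dwell_n: int = 50
    filter_window: int = 25
    qs_max_drift: float = 0.02
    min_inclination: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.significance < 1.0:
            raise ValueError("significance must be in (0, 1)")
        if self.ci_threshold <= 0:
            raise ValueError("ci_threshold must be > 0")
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if self.min_load <= 0:
            raise ValueError("min_load must be > 0")
        if self.filter_window < 1:
            raise ValueError("filter_window must be >= 1")


@dataclass
class LinkSampleSet:
    """Accumulated link-frame contact-point samples for one candidate."""

    link: str
    samples: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples)) if self.samples else float("nan")

    @property
    def sd(self) -> float:
        if len(self.samples) < 2:
            return 0.0
        return float(np.std(self.samples, ddof=1))


@dataclass
class ContactEstimate:
    """Final localisation: link, link-frame position (m), world x (m)."""

    link: str
    position: float
    world_x: float
    n_used: int
    elapsed: float


@dataclass
class DetectionState:
    """Mutable state of one detection episode."""

    per_link: dict[str, LinkSampleSet] = field(default_factory=dict)
    latched_link: str | None = None
    ad_values: dict[str, float] = field(default_factory=dict)
    ci_halfwidth: float = float("inf")
    result: ContactEstimate | None = None
    baseline_vgrf: list[float] = field(default_factory=list)
    f_wo: float | None = None
    first_load_t: float | None = None
    unloaded_streak: int = 0
    gate_streak: int = 0
    window_cop: list[float] = field(default_factory=list)
    window_vgrf: list[float] = field(default_factory=list)
    window_cop_wo: list[float] = field(default_factory=list)
    window_postures: list[Posture] = field(default_factory=list)
    dropped: int = 0
    degenerate: bool = False

    def reset_episode(self) -> None:
        """Clear per-episode accumulation; the unloaded baseline is kept."""
        self.per_link.clear()
        self.latched_link = None
        self.ad_values.clear()
        self.ci_halfwidth = float("inf")
        self.result = None
        self.first_load_t = None
        self.unloaded_streak = 0
        self.gate_streak = 0
        self.window_cop.clear()
        self.window_vgrf.clear()
        self.window_cop_wo.clear()
        self.window_postures.clear()
        self.dropped = 0
        self.degenerate = False


def contact_x(
    cop_loaded: float, vgrf_loaded: float,
    cop_unloaded: float, vgrf_unloaded: float,
) -> float:
    """Ground x-coordinate of the load's line of action from the sagittal
    moment balance.  The caller must gate on a sufficient force difference;
    the formula is symmetric under swapping the loaded/unloaded pairs."""
    return (cop_loaded * vgrf_loaded - cop_unloaded * vgrf_unloaded) / (
        vgrf_loaded - vgrf_unloaded
    )


def link_intersections(
    segments: list[LinkSegment2D], x: float, candidates: list[str],
) -> list[tuple[str, float]]:
    """Candidates crossed by the vertical line at ``x``, with link-frame
    coordinates, in candidate order.  A vertical line can cross several
    links; an empty list means the sample misses the body."""
    by_name = {s.link: s for s in segments}
    hits: list[tuple[str, float]] = []
    for name in candidates:
        seg = by_name.get(name)
        if seg is None:
            continue
        x0, x1 = seg.proximal[0], seg.distal[0]
        dx = x1 - x0
        if abs(dx) < 1e-12:
            continue  # exactly vertical link: no unique crossing coordinate
        t = (x - x0) / dx
        if 0.0 <= t <= 1.0:
            hits.append((name, t * seg.length))
    return hits


def ad_statistic(samples: np.ndarray | list[float]) -> float:
    """Anderson-Darling A-squared for normality with estimated mean/sd.

    Samples are sorted and standardised by the sample mean and standard
    deviation (ddof = 1); the statistic is the classical weighted log-CDF
    sum with the standard normal CDF, its values clamped away from 0 and 1
    before the logs.  A zero-variance sample is perfectly concentrated and
    returns 0 (accepted, flagged degenerate by the caller)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("Anderson-Darling test needs at least 3 samples")
    sd = np.std(x, ddof=1)
    if sd < _SD_EPS:
        return 0.0
    s = (x - np.mean(x)) / sd
    F = np.clip(ndtr(s), _CDF_EPS, 1.0 - _CDF_EPS)
    i = np.arange(1, n + 1)
    return float(-n - np.sum((2 * i - 1) / n * (np.log(F) + np.log(1.0 - F[::-1]))))


def confidence_halfwidth(sd: float, n: int, z_star: float = 1.96) -> float:
    """Half-width of the normal confidence interval of the sample mean."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return z_star * sd / math.sqrt(n)


def _test_order(state: DetectionState, config: DetectionConfig,
                candidates: list[str]) -> list[str]:
    """Candidate testing order: descending sample count, ties broken by the
    configured (distal-to-proximal) candidate order."""
    order = {name: k for k, name in enumerate(candidates)}
    with_samples = [name for name in candidates if name in state.per_link]
    return sorted(with_samples, key=lambda nm: (-state.per_link[nm].n, order[nm]))


def detect_step(
    state: DetectionState,
    posture: Posture,
    plate: ForcePlateSample,
    sesc: SESCParameters,
    model: BodyModel,
    config: DetectionConfig,
) -> DetectionState:
    """One online update of the contact-point detector.

    Estimates the unloaded CoP from the SESC model, gates on the vGRF
    difference, accumulates link-frame samples on every candidate link the
    vertical load line crosses, latches the first candidate accepted by the
    Anderson-Darling test (once ``n > n_min``), and emits the estimate when
    the confidence half-width falls below the stopping threshold.  The state
    is updated in place and returned.
    """
    if sesc is None:
        raise NotCalibratedError("identified SESC parameters are required")
    if state.result is not None:
        return state

    f_wo = config.f_wo if config.f_wo is not None else state.f_wo
    if f_wo is None:
        # unloaded baseline: average the first baseline_n samples
        state.baseline_vgrf.append(plate.vgrf)
        if len(state.baseline_vgrf) >= config.baseline_n:
            state.f_wo = float(np.mean(state.baseline_vgrf))
        return state

    candidates = config.link_order or model.candidate_links
    if abs(plate.vgrf - f_wo) < config.min_load:
        # no load present on this raw reading
        state.gate_streak = 0
        state.window_cop.clear()
        state.window_vgrf.clear()
        state.window_cop_wo.clear()
        state.window_postures.clear()
        if state.first_load_t is not None:
            state.unloaded_streak += 1
            if state.unloaded_streak >= config.reset_dwell_n:
                state.reset_episode()
        return state
    state.unloaded_streak = 0
    if state.first_load_t is None:
        state.first_load_t = plate.t

    # causal moving-average prefilter with decimation: one accumulated
    # sample per full non-overlapping window of gate-passing readings.
    # The model-estimated unloaded CoP is filtered through the identical
    # window so the body-sway component cancels from the torque balance.
    state.gate_streak += 1
    state.window_cop.append(plate.cop_x)
    state.window_vgrf.append(plate.vgrf)
    state.window_cop_wo.append(estimate_cop(model, sesc, posture))
    state.window_postures.append(posture)
    if len(state.window_cop) < config.filter_window:
        return state
    cop_wt = float(np.mean(state.window_cop))
    vgrf_wt = float(np.mean(state.window_vgrf))
    cop_wo = float(np.mean(state.window_cop_wo))
    drift = float(np.ptp(state.window_cop_wo))
    # the windowed value is centred on the window middle, so intersect with
    # the mid-window posture to avoid a geometric lag during motion
    posture_mid = state.window_postures[len(state.window_postures) // 2]
    state.window_cop.clear()
    state.window_vgrf.clear()
    state.window_cop_wo.clear()
    state.window_postures.clear()
    if drift > config.qs_max_drift:
        # not quasi-static within this window; the balance does not hold
        state.dropped += 1
        return state

    x = contact_x(cop_wt, vgrf_wt, cop_wo, f_wo)
    segments = forward_kinematics(model, posture_mid)
    by_name = {s.link: s for s in segments}
    hits = [
        (name, local)
        for name, local in link_intersections(segments, x, candidates)
        if (abs(by_name[name].distal[0] - by_name[name].proximal[0])
            / by_name[name].length) >= config.min_inclination
    ]
    if not hits:
        state.dropped += 1
    for name, local in hits:
        state.per_link.setdefault(name, LinkSampleSet(name)).samples.append(local)

    if state.latched_link is None:
        for name in _test_order(state, config, candidates):
            ss = state.per_link[name]
            if ss.n <= config.n_min:
                continue
            if ss.sd < _SD_EPS:
                a2 = 0.0
                state.degenerate = True
            else:
                a2 = ad_statistic(ss.samples)
            state.ad_values[name] = a2
            if a2 < config.ad_critical:
                state.latched_link = name
                break

    if state.latched_link is not None:
        ss = state.per_link[state.latched_link]
        state.ci_halfwidth = confidence_halfwidth(ss.sd, ss.n, config.z_star)
        if ss.n > config.n_min and state.ci_halfwidth <= config.ci_threshold:
            seg = next(s for s in segments if s.link == state.latched_link)
            length = model.segment(state.latched_link).length
            position = float(np.clip(ss.mean, 0.0, length))
            world = point_on_link(seg, position)
            state.result = ContactEstimate(
                link=state.latched_link,
                position=position,
                world_x=float(world[0]),
                n_used=ss.n,
                elapsed=plate.t - (state.first_load_t
                                   if state.first_load_t is not None else plate.t),
            )
    return state


def run_detection(
    model: BodyModel,
    sesc: SESCParameters,
    postures: list[Posture],
    plates: list[ForcePlateSample],
    config: DetectionConfig | None = None,
    collect_diagnostics: bool = False,
):
    """Feed a whole (posture, force-plate) stream through the detector.

    Returns ``(estimate_or_None, state, diagnostics)``; diagnostics is a
    list of per-step dicts (t, per-link counts, latest A-squared values,
    half-width, latched link) when requested, else an empty list.
    """
    if len(postures) != len(plates):
        raise ValueError("posture and force-plate streams must align")
    config = config or DetectionConfig()
    state = DetectionState()
    diagnostics: list[dict] = []
    for posture, plate in zip(postures, plates):
        detect_step(state, posture, plate, sesc, model, config)
        if collect_diagnostics:
            row = {"t": plate.t, "latched": state.latched_link or "",
                   "ci_halfwidth": state.ci_halfwidth
                   if math.isfinite(state.ci_halfwidth) else "",
                   "dropped": state.dropped}
            for name, ss in state.per_link.items():
                row[f"n_{name}"] = ss.n
            for name, a2 in state.ad_values.items():
                row[f"A2_{name}"] = a2
            diagnostics.append(row)
        if state.result is not None:
            break
    return state.result, state, diagnostics
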