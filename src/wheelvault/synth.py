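"""Synthetic vault performances with known ground-truth events and scores.

The simulator scripts a stick-figure gymnast through the mounting-phase
choreography -- an approach run, a jump to the pike apex, a descent onto a
static wheel, a ride of configurable duration, a squat-then-extension
thrust, and a short flight -- and renders, per frame, a binary wheel/gymnast
mask pair, a dense flow field, and a nine-joint keypoint set.  Every frame
index of the four key events is known exactly, as is the deduction implied
by the regulation time-on-wheel table and the pike-mount knee angle, so
every downstream stage can be tested without any recorded video.

Geometry is fixed to a 160x120 canvas (left-travelling gymnast, wheel on
the left); the flow field assigns each gymnast pixel the inter-frame
displacement of the keypoint centroid, plus optional Gaussian noise, which
keeps the field exactly consistent with the rendered trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import disk, line

from .errors import ConfigError, InputError
from .events import EventSet
from .ioformats import JOINT_NAMES, FlowField, Keypoint, KeypointSet, MaskPair

__all__ = [
    "VideoMeta",
    "SynthConfig",
    "GroundTruth",
    "FrameSeries",
    "SimulatedPerformance",
    "STRAIGHT_LEG_THRESHOLD_DEG",
    "regulation_time_deduction",
    "simulate_performance",
    "generate_dataset",
]

#: Knee angle below which legs count as bent in the planted deduction rule.
STRAIGHT_LEG_THRESHOLD_DEG = 162.5


@dataclass(frozen=True)
class VideoMeta:
    """Recording metadata: frame rate, canvas size, travel direction."""

    fps: float = 60.0
    width: int = 160
    height: int = 120
    n_frames: int = 1
    motion_direction: str = "leftward"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")
        if self.width < 1 or self.height < 1 or self.n_frames < 1:
            raise ConfigError("width, height and n_frames must all be >= 1")
        if self.motion_direction not in ("leftward", "rightward"):
            raise ConfigError(
                f"motion_direction must be leftward/rightward, got "
                f"{self.motion_direction!r}"
            )


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic corpus generator."""

    seed: int = 0
    n_days: int = 8
    performances_per_day: int = 13
    ride_time_range: tuple[float, float] = (3.5, 6.5)
    knee_angle_range: tuple[float, float] = (140.0, 180.0)
    knee_penalty_rate: float = 0.01
    judge_noise_sd: float = 0.05
    flow_noise_sd: float = 0.15
    straight_leg_threshold_deg: float = STRAIGHT_LEG_THRESHOLD_DEG
    meta: VideoMeta = field(default_factory=VideoMeta)

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.performances_per_day < 1:
            raise ConfigError("n_days and performances_per_day must be >= 1")
        for name in ("ride_time_range", "knee_angle_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} must have low <= high, got ({lo}, {hi})")
        if self.judge_noise_sd < 0 or self.flow_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.knee_penalty_rate < 0:
            raise ConfigError("knee_penalty_rate must be >= 0")
        if self.meta.width < _CANVAS_W or self.meta.height < _CANVAS_H:
            raise ConfigError(
                f"canvas must be at least {_CANVAS_W}x{_CANVAS_H} for the "
                "scripted choreography"
            )
        if round(self.ride_time_range[0] * self.meta.fps) < _MIN_RIDE_FRAMES:
            raise ConfigError(
                "ride_time_range too short for the scripted squat/extension "
                f"phases (need >= {_MIN_RIDE_FRAMES} frames)"
            )


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator knows about one performance."""

    event_frames: EventSet
    true_time_on_wheel: float
    true_knee_angle_pikemount: float
    true_deduction: float
    judge_scores: tuple[float, float]

    def __post_init__(self) -> None:
        if self.true_deduction < 0:
            raise InputError("true_deduction must be >= 0")
        for s in self.judge_scores:
            if not 0.0 <= s <= 6.0:
                raise InputError(f"judge score {s} outside [0, 6]")


def regulation_time_deduction(t: float) -> float:
    """Deduction mandated by the time-on-wheel regulation table.

    Zero below 3 s; linear 0.1 -> 0.2 over [3, 4]; linear 0.2 -> 0.3 over
    the unprinted (4, 5) band (gap interpolation for continuity); linear
    0.3 -> 0.4 over [5, 6]; 0.5 beyond 6 s.
    """
    if t < 0:
        raise InputError(f"time on wheel must be >= 0, got {t}")
    if t < 3.0:
        return 0.0
    if t <= 4.0:
        return 0.1 + 0.1 * (t - 3.0)
    if t < 5.0:
        return 0.2 + 0.1 * (t - 4.0)
    if t <= 6.0:
        return 0.3 + 0.1 * (t - 5.0)
    return 0.5


# ---------------------------------------------------------------------------
# Scripted choreography (fixed 160x120 geometry, leftward travel)
# ---------------------------------------------------------------------------

_CANVAS_W, _CANVAS_H = 160, 120
_WHEEL_CENTER = (42.0, 30.0)  # analysis coords (x, y-up)
_WHEEL_R_OUT = 22.0
_WHEEL_R_IN = 16.0
_TOE_ANCHOR = (42.0, 52.5)  # where the soles sit on the rim while riding

# frame-count layout of the fixed phases
_N_APPROACH = 40      # positions 0..39, downward drift (run + crouch)
_N_ASCENT = 34        # positions 40..73, sustained upward flow
_N_DESCENT1 = 8       # positions 74..81, drop from the apex
_N_DESCENT2 = 8       # positions 82..89, level approach to the wheel
_CONTACT_FRAME = _N_APPROACH + _N_ASCENT + _N_DESCENT1 + _N_DESCENT2  # 90
_TAKEOFF_FRAME = _N_APPROACH - 2   # 38: last downward flow step
_PIKEMOUNT_FRAME = _N_APPROACH + _N_ASCENT - 1  # 73: apex position
_N_RISE = 24          # crouch -> stand after contact (sub-threshold motion)
_N_SQUAT = 13         # descending steps of the pre-thrust squat
_N_FLIGHT = 15        # frames rendered after the thrust
_MIN_RIDE_FRAMES = _N_RISE + _N_SQUAT + 4

# centroid waypoints of the free-flight phases (x, y-up)
_P_START = np.array([146.0, 27.0])
_P_PREJUMP = np.array([98.0, 16.0])
_P_APEX = np.array([70.0, 78.0])
_P_DROP = np.array([55.0, 71.0])
_P_HOVER = np.array([41.3, 72.5])
_LAUNCH_STEP = np.array([-0.2, 2.6])  # per-frame climb after the thrust

# joint order matches ioformats.JOINT_NAMES
_POSE_RUN = {
    "nose": (-5, 19), "neck": (-2, 16), "shoulder": (-2, 13), "elbow": (-4, 6),
    "wrist": (-6, 0), "hip": (0, 0), "knee": (2, -10), "ankle": (3, -19),
    "toes": (-1, -20),
}
_POSE_CROUCH = {
    "nose": (-7, 14), "neck": (-4, 11), "shoulder": (-4, 9), "elbow": (-7, 3),
    "wrist": (-9, -3), "hip": (0, 0), "knee": (5, -7), "ankle": (3, -15),
    "toes": (-1, -16),
}
_POSE_STAND = {
    "nose": (-3, 20), "neck": (-1, 17), "shoulder": (-1, 14), "elbow": (1, 19),
    "wrist": (2, 23), "hip": (0, 0), "knee": (1, -10), "ankle": (1, -19),
    "toes": (-2, -20),
}
_POSE_SQUAT = {
    "nose": (-6, 9), "neck": (-3, 6), "shoulder": (-3, 4), "elbow": (0, 2),
    "wrist": (1, -2), "hip": (0, -6), "knee": (6, -11), "ankle": (2, -19),
    "toes": (-2, -20),
}

_SKELETON = (
    ("nose", "neck"), ("neck", "shoulder"), ("shoulder", "elbow"),
    ("elbow", "wrist"), ("neck", "hip"), ("hip", "knee"),
    ("knee", "ankle"), ("ankle", "toes"),
)


def _pose_array(pose: dict[str, tuple[float, float]]) -> np.ndarray:
    return np.array([pose[n] for n in JOINT_NAMES], dtype=float)


def _pike_pose(knee_angle_deg: float, arm_drop: float = 0.0) -> np.ndarray:
    """Folded pike pose with the hip-knee-ankle angle set exactly.

    ``arm_drop`` shifts the gripping arm vertically (performance-to-
    performance variation), which decorrelates the hand-level features from
    the knee angle.
    """
    hip = np.array([0.0, 0.0])
    thigh_dir = math.radians(200.0)
    knee = hip + 13.0 * np.array([math.cos(thigh_dir), math.sin(thigh_dir)])
    shank_dir = math.radians(20.0 + knee_angle_deg)
    ankle = knee + 12.0 * np.array([math.cos(shank_dir), math.sin(shank_dir)])
    foot_dir = math.radians(20.0 + knee_angle_deg - 25.0)
    toes = ankle + 4.0 * np.array([math.cos(foot_dir), math.sin(foot_dir)])
    pose = {
        "nose": (-11, -13), "neck": (-8, -11), "shoulder": (-7, -10),
        "elbow": (-9, -17 + 0.5 * arm_drop), "wrist": (-10, -23 + arm_drop),
        "hip": tuple(hip), "knee": tuple(knee), "ankle": tuple(ankle),
        "toes": tuple(toes),
    }
    return _pose_array(pose)


def _centered(pose: np.ndarray) -> np.ndarray:
    return pose - pose.mean(axis=0)


def _anchored_at_toes(pose: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    toes_idx = JOINT_NAMES.index("toes")
    return pose - pose[toes_idx] + anchor


def _build_trajectory(
    ride_frames: int, knee_angle_deg: float, arm_drop: float = 0.0
) -> np.ndarray:
    """Keypoint positions (n_frames, 9, 2) in y-up analysis coordinates."""
    run = _pose_array(_POSE_RUN)
    crouch = _pose_array(_POSE_CROUCH)
    pike = _pike_pose(knee_angle_deg, arm_drop)
    stand = _pose_array(_POSE_STAND)
    squat = _pose_array(_POSE_SQUAT)
    anchor = np.array(_TOE_ANCHOR)

    frames: list[np.ndarray] = []

    # approach: run -> crouch, drifting down-left
    for i in range(_N_APPROACH):
        c = _P_START + (i / (_N_APPROACH - 1)) * (_P_PREJUMP - _P_START)
        m = i / (_N_APPROACH - 1)
        frames.append(c + _centered((1 - m) * run + m * crouch))
    # ascent: crouch -> pike, sustained upward flow to the apex
    for i in range(1, _N_ASCENT + 1):
        c = _P_PREJUMP + (i / _N_ASCENT) * (_P_APEX - _P_PREJUMP)
        m = i / _N_ASCENT
        frames.append(c + _centered((1 - m) * crouch + m * pike))
    # descent toward the wheel: pike -> crouch, never touching the rim
    n_desc = _N_DESCENT1 + _N_DESCENT2
    for i in range(1, _N_DESCENT1 + 1):
        c = _P_APEX + (i / _N_DESCENT1) * (_P_DROP - _P_APEX)
        m = i / (n_desc + 1)
        frames.append(c + _centered((1 - m) * pike + m * crouch))
    for i in range(1, _N_DESCENT2 + 1):
        c = _P_DROP + (i / _N_DESCENT2) * (_P_HOVER - _P_DROP)
        m = (_N_DESCENT1 + i) / (n_desc + 1)
        frames.append(c + _centered((1 - m) * pike + m * crouch))

    # contact: soles pinned to the rim; crouch -> stand below the flow
    # threshold, then hold until the squat.  The ride spans ride_frames + 1
    # positions so the squat bottom sits exactly at contact + ride_frames
    # and the first upward flow step is the thrust frame itself.
    for i in range(_N_RISE):
        m = i / (_N_RISE - 1)
        frames.append(_anchored_at_toes((1 - m) * crouch + m * stand, anchor))
    for _ in range(ride_frames + 1 - _N_RISE - _N_SQUAT):
        frames.append(_anchored_at_toes(stand, anchor))
    # squat: the sustained downward run preceding the thrust
    for i in range(1, _N_SQUAT + 1):
        m = i / _N_SQUAT
        frames.append(_anchored_at_toes((1 - m) * stand + m * squat, anchor))

    # thrust and flight: extend and climb away from the wheel
    squat_anchor_centroid = _anchored_at_toes(squat, anchor).mean(axis=0)
    for i in range(1, _N_FLIGHT + 1):
        c = squat_anchor_centroid + i * _LAUNCH_STEP
        m = min(i / 6.0, 1.0)
        frames.append(c + _centered((1 - m) * squat + m * stand))

    return np.stack(frames)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _wheel_mask(meta: VideoMeta) -> np.ndarray:
    rows = np.arange(meta.height)[:, None]
    cols = np.arange(meta.width)[None, :]
    y_up = (meta.height - 1) - rows
    d = np.hypot(cols - _WHEEL_CENTER[0], y_up - _WHEEL_CENTER[1])
    return (d >= _WHEEL_R_IN) & (d <= _WHEEL_R_OUT)


_DILATE_3X3 = np.ones((3, 3), dtype=bool)


def _render_gymnast(kp: np.ndarray, meta: VideoMeta) -> np.ndarray:
    """Rasterize the stick figure (3-px strokes, small head disc)."""
    canvas = np.zeros((meta.height, meta.width), dtype=bool)
    rr_all = []
    cc_all = []
    pts = {name: kp[i] for i, name in enumerate(JOINT_NAMES)}
    for a, b in _SKELETON:
        r0 = int(round((meta.height - 1) - pts[a][1]))
        c0 = int(round(pts[a][0]))
        r1 = int(round((meta.height - 1) - pts[b][1]))
        c1 = int(round(pts[b][0]))
        rr, cc = line(r0, c0, r1, c1)
        rr_all.append(rr)
        cc_all.append(cc)
    nose = pts["nose"]
    rr, cc = disk(((meta.height - 1) - nose[1], nose[0]), 2.5)
    rr_all.append(rr)
    cc_all.append(cc)
    rr = np.concatenate(rr_all)
    cc = np.concatenate(cc_all)
    ok = (rr >= 0) & (rr < meta.height) & (cc >= 0) & (cc < meta.width)
    canvas[rr[ok], cc[ok]] = True
    return binary_dilation(canvas, structure=_DILATE_3X3)


class FrameSeries:
    """Per-performance time-indexed bundle of keypoints, masks, and flow.

    Masks and flow fields are rendered lazily per frame (and masks cached)
    so a full corpus of performances stays cheap to hold in memory.
    Identical construction parameters yield bit-identical frames: the flow
    noise stream is keyed by ``(noise_key, frame_index)``.
    """

    def __init__(
        self,
        keypoints: np.ndarray,
        meta: VideoMeta,
        flow_noise_sd: float = 0.0,
        noise_key: int = 0,
    ):
        if keypoints.ndim != 3 or keypoints.shape[1:] != (len(JOINT_NAMES), 2):
            raise InputError("keypoints must have shape (n_frames, 9, 2)")
        self.keypoints = keypoints
        self.meta = replace(meta, n_frames=len(keypoints))
        self.flow_noise_sd = float(flow_noise_sd)
        self.noise_key = int(noise_key)
        self._wheel = _wheel_mask(self.meta)
        self._mask_cache: dict[int, np.ndarray] = {}

    @property
    def n_frames(self) -> int:
        return len(self.keypoints)

    def keypoint_set(self, t: int, confidence: float = 1.0) -> KeypointSet:
        pts = {
            name: Keypoint(float(x), float(y), confidence)
            for name, (x, y) in zip(JOINT_NAMES, self.keypoints[t])
        }
        return KeypointSet(points=pts, side="left", y_up=True)

    def _gymnast_mask(self, t: int) -> np.ndarray:
        cached = self._mask_cache.get(t)
        if cached is None:
            cached = _render_gymnast(self.keypoints[t], self.meta)
            self._mask_cache[t] = cached
        return cached

    def masks(self, t: int) -> MaskPair:
        return MaskPair(
            wheel=self._wheel, gymnast=self._gymnast_mask(t), frame_index=t
        )

    def flow(self, t: int) -> FlowField:
        """Dense flow between frames ``t`` and ``t + 1`` (file coordinates)."""
        if not 0 <= t < self.n_frames - 1:
            raise InputError(f"flow index {t} out of range")
        d = self.keypoints[t + 1].mean(axis=0) - self.keypoints[t].mean(axis=0)
        sil = self._gymnast_mask(t)
        u = np.zeros(sil.shape, dtype=np.float32)
        v = np.zeros(sil.shape, dtype=np.float32)
        u[sil] = d[0]
        v[sil] = -d[1]  # file coords are y-down
        if self.flow_noise_sd > 0:
            rng = np.random.default_rng([self.noise_key, t])
            u += rng.normal(0.0, self.flow_noise_sd, sil.shape).astype(np.float32)
            v += rng.normal(0.0, self.flow_noise_sd, sil.shape).astype(np.float32)
        return FlowField(u=u, v=v)

    def clear_cache(self) -> None:
        self._mask_cache.clear()


@dataclass(frozen=True)
class SimulatedPerformance:
    """One synthetic performance plus its tags for record assembly."""

    series: FrameSeries
    truth: GroundTruth
    day: int
    gymnast_id: str = "g1"


def simulate_performance(
    config: SynthConfig, day: int, rng: np.random.Generator
) -> tuple[FrameSeries, GroundTruth]:
    """Simulate one performance; all randomness comes from ``rng``."""
    ride_time = float(rng.uniform(*config.ride_time_range))
    knee_angle = float(rng.uniform(*config.knee_angle_range))
    judge_noise = rng.normal(0.0, 1.0, size=2) * config.judge_noise_sd
    arm_drop = float(rng.uniform(-3.0, 3.0))
    noise_key = int(rng.integers(0, 2**62))

    fps = config.meta.fps
    ride_frames = int(round(ride_time * fps))
    if ride_frames < _MIN_RIDE_FRAMES:
        raise ConfigError(
            f"ride of {ride_frames} frames is shorter than the scripted "
            f"minimum of {_MIN_RIDE_FRAMES}"
        )
    keypoints = _build_trajectory(ride_frames, knee_angle, arm_drop)
    series = FrameSeries(
        keypoints,
        config.meta,
        flow_noise_sd=config.flow_noise_sd,
        noise_key=noise_key,
    )

    thrust = _CONTACT_FRAME + ride_frames
    events = EventSet(
        takeoff=_TAKEOFF_FRAME,
        pikemount=_PIKEMOUNT_FRAME,
        contact_start=_CONTACT_FRAME,
        thrust=thrust,
    )
    true_tow = ride_frames / fps
    deduction = regulation_time_deduction(true_tow) + config.knee_penalty_rate * max(
        0.0, config.straight_leg_threshold_deg - knee_angle
    )
    judges = tuple(float(np.clip(deduction + e, 0.0, 6.0)) for e in judge_noise)
    truth = GroundTruth(
        event_frames=events,
        true_time_on_wheel=true_tow,
        true_knee_angle_pikemount=knee_angle,
        true_deduction=deduction,
        judge_scores=judges,
    )
    return series, truth


def generate_dataset(config: SynthConfig) -> list[SimulatedPerformance]:
    """All ``n_days x performances_per_day`` performances of a corpus.

    Per-performance random substreams are spawned by counter from the one
    configured seed, so the corpus is deterministic and any performance can
    be regenerated independently.
    """
    n = config.n_days * config.performances_per_day
    children = np.random.SeedSequence(config.seed).spawn(n)
    out: list[SimulatedPerformance] = []
    for day in range(1, config.n_days + 1):
        for j in range(config.performances_per_day):
            idx = (day - 1) * config.performances_per_day + j
            rng = np.random.default_rng(children[idx])
            series, truth = simulate_performance(config, day, rng)
            out.append(SimulatedPerformance(series=series, truth=truth, day=day))
    return out


def iter_dataset(config: SynthConfig) -> Iterator[SimulatedPerformance]:
    """Memory-light generator variant of :func:`generate_dataset`."""
    children = np.random.SeedSequence(config.seed).spawn(
        config.n_days * config.performances_per_day
    )
    for day in range(1, config.n_days + 1):
        for j in range(config.performances_per_day):
            idx = (day - 1) * config.performances_per_day + j
            rng = np.random.default_rng(children[idx])
            series, truth = simulate_performance(config, day, rng)
            yield SimulatedPerformance(series=series, truth=truth, day=day)
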