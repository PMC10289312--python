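"""Rule-based detection of the four mounting-phase key frames.

Take-off and the final position before the thrust are found from per-frame
summaries of the dense optical flow (median direction and magnitude over
moving pixels); the starting point of time on the wheel and the pike-mount
position come from segmentation-mask geometry (lower-body/wheel contact and
the gymnast barycenter height).

Direction convention: flow files store v y-down, so the per-pixel direction
is ``atan2(-v, u)`` mapped to [0, 360).  Upward motion is the open band
(0, 180) and downward the open band (180, 360); motion at exactly 0, 90,
180, or 270 degrees lies on a band boundary only for 180/360 -- angles at
exactly 180 or 0/360 are neither upward nor downward and break runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.ndimage import binary_dilation

from .errors import (
    EmptyMaskError,
    EventExtractionError,
    InputError,
    NoContactError,
    NoTakeoffError,
    NoThrustError,
    OrderingError,
)

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .ioformats import FlowField, MaskPair
    from .synth import FrameSeries, VideoMeta

__all__ = [
    "FlowSummary",
    "EventSet",
    "EventParams",
    "summarize_flow",
    "detect_takeoff",
    "barycenter",
    "lower_body_mask",
    "detect_contact_start",
    "detect_pikemount",
    "detect_thrust",
    "extract_events",
]


@dataclass(frozen=True)
class FlowSummary:
    """Median flow direction/magnitude over the moving pixels of one frame.

    ``defined`` is False when no pixel moved faster than the threshold, in
    which case the statistics are meaningless and must not be used.
    """

    frame_index: int
    median_direction: float
    median_magnitude: float
    n_moving_pixels: int

    @property
    def defined(self) -> bool:
        return self.n_moving_pixels > 0

    @property
    def upward(self) -> bool:
        return self.defined and 0.0 < self.median_direction < 180.0

    @property
    def downward(self) -> bool:
        return self.defined and 180.0 < self.median_direction < 360.0


@dataclass(frozen=True)
class EventSet:
    """The four detected key-frame indices, strictly increasing."""

    takeoff: int
    pikemount: int
    contact_start: int
    thrust: int

    def __post_init__(self) -> None:
        if not self.takeoff < self.pikemount < self.contact_start < self.thrust:
            raise OrderingError(
                "event frames must satisfy takeoff < pikemount < "
                f"contact_start < thrust, got {self.as_tuple()}"
            )
        if self.takeoff < 0:
            raise OrderingError("event frames must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.takeoff, self.pikemount, self.contact_start, self.thrust)

    def as_dict(self) -> dict[str, int]:
        return {
            "takeoff": self.takeoff,
            "pikemount": self.pikemount,
            "contact_start": self.contact_start,
            "thrust": self.thrust,
        }


@dataclass(frozen=True)
class EventParams:
    """Tunable parameters of the four detectors.

    Defaults follow the reference rules for 60 fps footage (a 30-frame
    upward-persistence window, a 10-frame look-back, a thrust magnitude
    band of 5.5 to 15 px/frame).  Synthetic low-resolution data uses a
    rescaled magnitude band and moving-pixel threshold.
    """

    eps: float = 1.0
    window: int = 30
    min_contact_s: float = 0.5
    lookback: int = 10
    mag_lo: float = 5.5
    mag_hi: float = 15.0
    circular_median: bool = False

    def as_dict(self) -> dict:
        return {
            "eps": self.eps,
            "window": self.window,
            "min_contact_s": self.min_contact_s,
            "lookback": self.lookback,
            "mag_lo": self.mag_lo,
            "mag_hi": self.mag_hi,
            "circular_median": self.circular_median,
        }


def _circular_median(angles_deg: np.ndarray) -> float:
    """Angle among the data minimizing the summed circular arc distance."""
    a = np.deg2rad(angles_deg)
    diffs = np.abs(a[:, None] - a[None, :])
    diffs = np.minimum(diffs, 2 * np.pi - diffs)
    best = int(np.argmin(diffs.sum(axis=1)))
    return float(angles_deg[best])


def summarize_flow(
    field: "FlowField",
    eps: float = 1.0,
    frame_index: int = 0,
    circular_median: bool = False,
) -> FlowSummary:
    """Summarize a dense flow field over its moving pixels.

    Pixels with magnitude strictly greater than ``eps`` count as moving.
    The per-pixel direction is ``atan2(-v, u)`` in [0, 360) so that upward
    screen motion lands in (0, 180) despite y-down file storage.  The
    reported direction is the ordinary (non-circular) median of those
    angles unless ``circular_median`` is set.
    """
    if eps < 0:
        raise InputError(f"eps must be >= 0, got {eps}")
    mag = np.hypot(field.u, field.v)
    moving = mag > eps
    n = int(moving.sum())
    if n == 0:
        return FlowSummary(frame_index, float("nan"), float("nan"), 0)
    ang = np.degrees(np.arctan2(-field.v[moving], field.u[moving])) % 360.0
    if circular_median:
        direction = _circular_median(ang)
    else:
        direction = float(np.median(ang))
    return FlowSummary(frame_index, direction % 360.0, float(np.median(mag[moving])), n)


def detect_takeoff(summaries: Sequence[FlowSummary], window: int = 30) -> int:
    """Last downward frame preceding the first sustained upward run.

    Finds the first run of at least ``window`` consecutive upward frames
    (30 frames is 0.5 s at 60 fps) and returns the index of the nearest
    preceding frame whose median direction was downward.
    """
    if window < 1:
        raise InputError(f"window must be >= 1, got {window}")
    run = 0
    for i, s in enumerate(summaries):
        if s.upward:
            run += 1
            if run >= window:
                start = i - run + 1
                for j in range(start - 1, -1, -1):
                    if summaries[j].downward:
                        return j
                raise NoTakeoffError(
                    "upward run starts the sequence; no preceding downward frame",
                    stage="takeoff",
                )
        else:
            run = 0
    raise NoTakeoffError(
        f"no run of {window} consecutive upward frames", stage="takeoff"
    )


def barycenter(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic-mean foreground coordinate of a binary mask, y-up.

    The mask is an image array (row 0 at the top); the returned point is
    (x, y) in analysis coordinates with y increasing upward.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot take the barycenter of an empty mask")
    rows, cols = np.nonzero(mask)
    height = mask.shape[0]
    return float(cols.mean()), float((height - 1) - rows.mean())


def lower_body_mask(gymnast: np.ndarray, motion_direction: str) -> np.ndarray:
    """Pixels of the gymnast mask on the trailing side of its barycenter.

    For leftward travel the lower body trails to the right: keep pixels with
    x strictly greater than the barycenter x.  Rightward travel mirrors the
    split.  The result may be empty (the caller decides how to handle it).
    """
    gymnast = np.asarray(gymnast, dtype=bool)
    bx, _ = barycenter(gymnast)
    cols = np.arange(gymnast.shape[1])
    if motion_direction == "leftward":
        keep = cols > bx
    elif motion_direction == "rightward":
        keep = cols < bx
    else:
        raise InputError(f"unknown motion direction {motion_direction!r}")
    return gymnast & keep[None, :]


def _in_contact(pair: "MaskPair", motion_direction: str) -> bool:
    """Contact test: 1-px dilated lower body intersects the wheel mask."""
    if not pair.gymnast.any() or not pair.wheel.any():
        return False
    lower = lower_body_mask(pair.gymnast, motion_direction)
    if not lower.any():
        return False
    dilated = binary_dilation(lower, structure=np.ones((3, 3), dtype=bool))
    return bool((dilated & pair.wheel).any())


def detect_contact_start(
    masks: Sequence["MaskPair"],
    meta: "VideoMeta",
    min_contact_s: float = 0.5,
) -> int:
    """First frame of the first lower-body/wheel contact run longer than
    ``min_contact_s`` (strictly -- "more than 0.5 seconds of contact")."""
    if min_contact_s <= 0:
        raise InputError(f"min_contact_s must be > 0, got {min_contact_s}")
    threshold = min_contact_s * meta.fps
    contact = [_in_contact(p, meta.motion_direction) for p in masks]
    i = 0
    n = len(contact)
    while i < n:
        if contact[i]:
            j = i
            while j < n and contact[j]:
                j += 1
            if (j - i) > threshold:
                return i
            i = j
        else:
            i += 1
    raise NoContactError(
        f"no contact run longer than {min_contact_s} s", stage="contact_start"
    )


def detect_pikemount(
    masks: Sequence["MaskPair"], takeoff: int, contact_start: int
) -> int:
    """Frame with the highest gymnast barycenter strictly between take-off
    and contact start; ties resolve to the earliest frame."""
    if not takeoff < contact_start - 1:
        raise OrderingError(
            f"empty pike-mount search range ({takeoff}, {contact_start})"
        )
    best_frame = -1
    best_height = -np.inf
    for t in range(takeoff + 1, contact_start):
        _, y = barycenter(masks[t].gymnast)
        if y > best_height:
            best_height = y
            best_frame = t
    return best_frame


def detect_thrust(
    summaries: Sequence[FlowSummary],
    contact_start: int,
    lookback: int = 10,
    mag_lo: float = 5.5,
    mag_hi: float = 15.0,
) -> int:
    """First post-contact upward frame ending a sustained downward run.

    Scanning frames after ``contact_start``, returns the first frame whose
    median direction is upward while the ``lookback`` preceding frames were
    all downward and the maximum of their median magnitudes lies inside
    [``mag_lo``, ``mag_hi``].  The upper bound rejects the much faster
    landing-scale motion of the following unit.
    """
    if lookback < 1:
        raise InputError(f"lookback must be >= 1, got {lookback}")
    if not 0 <= mag_lo <= mag_hi:
        raise InputError(f"invalid magnitude band [{mag_lo}, {mag_hi}]")
    for t in range(max(contact_start + 1, lookback), len(summaries)):
        if not summaries[t].upward:
            continue
        window = summaries[t - lookback : t]
        if not all(s.downward for s in window):
            continue
        max_mag = max(s.median_magnitude for s in window)
        if mag_lo <= max_mag <= mag_hi:
            return t
    raise NoThrustError("no qualifying thrust frame found", stage="thrust")


def extract_events(series: "FrameSeries", params: EventParams = EventParams()) -> EventSet:
    """Run all four detectors on one performance and validate their order.

    Any detector failure (or an ordering violation) is re-raised as an
    :class:`EventExtractionError` whose ``stage`` names the failing step.
    """
    n = series.n_frames
    summaries = [
        summarize_flow(
            series.flow(t), params.eps, frame_index=t,
            circular_median=params.circular_median,
        )
        for t in range(n - 1)
    ]
    masks = [series.masks(t) for t in range(n)]

    stage = "takeoff"
    try:
        takeoff = detect_takeoff(summaries, window=params.window)
        stage = "contact_start"
        contact_start = detect_contact_start(
            masks, series.meta, min_contact_s=params.min_contact_s
        )
        stage = "pikemount"
        pikemount = detect_pikemount(masks, takeoff, contact_start)
        stage = "thrust"
        thrust = detect_thrust(
            summaries,
            contact_start,
            lookback=params.lookback,
            mag_lo=params.mag_lo,
            mag_hi=params.mag_hi,
        )
        stage = "ordering"
        return EventSet(
            takeoff=takeoff,
            pikemount=pikemount,
            contact_start=contact_start,
            thrust=thrust,
        )
    except (EventExtractionError,):
        raise
    except (NoTakeoffError, NoContactError, NoThrustError, OrderingError,
            EmptyMaskError) as exc:
        raise EventExtractionError(str(exc), stage=stage) from exc
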