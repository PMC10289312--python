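"""The 21 explanatory variables computed at the three scored key frames.

Eighteen joint angles (six joints at take-off, pike-mount, and the final
position before the thrust), two pike-mount level features in pixels, and
the time on the wheel in seconds.  All geometry is 2D, in y-up analysis
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .errors import DegenerateGeometryError, MissingKeypointError, OrderingError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .events import EventSet
    from .ioformats import KeypointSet

__all__ = [
    "ANGLE_NAMES",
    "ANGLE_TRIPLES",
    "FEATURE_NAMES",
    "FeatureVector",
    "joint_angle",
    "compute_angles",
    "level_features",
    "time_on_wheel",
    "build_feature_vector",
]

#: The six named joint angles, in canonical order.
ANGLE_NAMES = ("neck", "shoulder", "elbow", "hip", "knee", "ankle")

#: Adjacent-joint triples (a, vertex, c) defining each angle.  The shoulder
#: and hip triples follow the documented convention (elbow-shoulder-hip,
#: neck-hip-knee); the remaining triples continue the adjacent-joint chain.
ANGLE_TRIPLES: Mapping[str, tuple[str, str, str]] = {
    "neck": ("nose", "neck", "hip"),
    "shoulder": ("elbow", "shoulder", "hip"),
    "elbow": ("shoulder", "elbow", "wrist"),
    "hip": ("neck", "hip", "knee"),
    "knee": ("hip", "knee", "ankle"),
    "ankle": ("knee", "ankle", "toes"),
}

_FRAME_TAGS = ("takeoff", "pikemount", "before_thrust")

#: Canonical order of the 21 explanatory variables: the six angles at each
#: of the three scored frames, then the two pike-mount level features, then
#: the time on the wheel.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{angle}_{tag}" for tag in _FRAME_TAGS for angle in ANGLE_NAMES
) + ("hips_above_shoulders", "feet_above_hands", "time_on_wheel")

assert len(FEATURE_NAMES) == 21


@dataclass(frozen=True)
class FeatureVector:
    """The 21 named explanatory variables of one performance."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} features, got {len(self.values)}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[FEATURE_NAMES.index(name)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def joint_angle(a, b, c) -> float:
    """Angle in degrees at vertex ``b`` between limbs ``b->a`` and ``b->c``.

    Computed as the arc cosine of the normalized dot product; always in
    [0, 180].  A zero-length limb vector raises
    :class:`DegenerateGeometryError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    w = c - b
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        raise DegenerateGeometryError("zero-length limb vector at angle vertex")
    cosang = float(np.dot(u, w) / (nu * nw))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def compute_angles(kps: "KeypointSet") -> dict[str, float]:
    """The six joint angles of one keypoint set, keyed by angle name."""
    if not kps.complete:
        raise MissingKeypointError("incomplete keypoint set; performance discarded")
    return {
        name: joint_angle(kps.xy(a), kps.xy(b), kps.xy(c))
        for name, (a, b, c) in ANGLE_TRIPLES.items()
    }


def level_features(kps_pikemount: "KeypointSet") -> tuple[float, float]:
    """Pike-mount level features in pixels (positive = first part higher).

    ``hips_above_shoulders`` is the hip y minus the shoulder y;
    ``feet_above_hands`` is the toes y minus the wrist y.  Requires y-up
    coordinates.
    """
    kps = kps_pikemount
    if not kps.complete:
        raise MissingKeypointError("incomplete keypoint set; performance discarded")
    hips_above = float(kps.xy("hip")[1] - kps.xy("shoulder")[1])
    feet_above = float(kps.xy("toes")[1] - kps.xy("wrist")[1])
    return hips_above, feet_above


def time_on_wheel(contact_start: int, thrust: int, fps: float) -> float:
    """Seconds between the first sole-on-wheel frame and the thrust frame."""
    if fps <= 0:
        raise OrderingError(f"fps must be positive, got {fps}")
    if thrust < contact_start:
        raise OrderingError(
            f"thrust frame {thrust} precedes contact start {contact_start}"
        )
    return (thrust - contact_start) / fps


def build_feature_vector(
    events: "EventSet",
    kp_by_frame: Mapping[int, "KeypointSet"],
    fps: float,
) -> FeatureVector:
    """Assemble the 21 canonical features for one performance.

    ``kp_by_frame`` must provide complete keypoint sets at the take-off,
    pike-mount, and thrust frames; anything missing raises
    :class:`MissingKeypointError` (the performance is discarded, never
    imputed).
    """
    scored = {
        "takeoff": events.takeoff,
        "pikemount": events.pikemount,
        "before_thrust": events.thrust,
    }
    values: dict[str, float] = {}
    for tag, frame in scored.items():
        if frame not in kp_by_frame:
            raise MissingKeypointError(f"no keypoints at {tag} frame {frame}")
        angles = compute_angles(kp_by_frame[frame])
        for angle_name in ANGLE_NAMES:
            values[f"{angle_name}_{tag}"] = angles[angle_name]
    hips_above, feet_above = level_features(kp_by_frame[events.pikemount])
    values["hips_above_shoulders"] = hips_above
    values["feet_above_hands"] = feet_above
    values["time_on_wheel"] = time_on_wheel(events.contact_start, events.thrust, fps)
    return FeatureVector(values=tuple(values[name] for name in FEATURE_NAMES))
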