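"""Readers and writers for the standard file formats the pipeline touches.

Supported formats:

* BODY_25 pose JSON as emitted by common 25-keypoint pose estimators
  (``{"people": [{"pose_keypoints_2d": [x0, y0, c0, ...]}]}``).
* Middlebury ``.flo`` dense optical flow (float magic tag, little-endian).
* Mask PNGs using a two-bit label convention (bit 1 = wheel, bit 2 = gymnast),
  so overlapping masks during contact are representable in a single image.
* Feature/score tables as RFC-4180 CSV with a canonical column order.

Coordinate conventions: image files are y-down with the origin at the top
left.  Analysis code works y-up.  The conversion happens exactly once, at
read (or write) time, and the convention in force is recorded on the
``KeypointSet`` itself via ``y_up``.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .features import FEATURE_NAMES

__all__ = [
    "JOINT_NAMES",
    "BODY25_LEFT_INDICES",
    "BODY25_RIGHT_INDICES",
    "Keypoint",
    "KeypointSet",
    "FlowField",
    "MaskPair",
    "read_body25_json",
    "write_body25_json",
    "read_flo",
    "write_flo",
    "read_mask_dir",
    "write_mask_pair",
    "TABLE_COLUMNS",
    "write_feature_table",
    "read_feature_table",
]

#: The nine named body joints used throughout the package, proximal to distal.
JOINT_NAMES = (
    "nose",
    "neck",
    "shoulder",
    "elbow",
    "wrist",
    "hip",
    "knee",
    "ankle",
    "toes",
)

#: Fixed index map into the 25-keypoint layout.  "Toes" is the big-toe
#: keypoint, the most distal stable foot point of that layout.
BODY25_LEFT_INDICES: Mapping[str, int] = {
    "nose": 0,
    "neck": 1,
    "shoulder": 5,
    "elbow": 6,
    "wrist": 7,
    "hip": 12,
    "knee": 13,
    "ankle": 14,
    "toes": 19,
}

BODY25_RIGHT_INDICES: Mapping[str, int] = {
    "nose": 0,
    "neck": 1,
    "shoulder": 2,
    "elbow": 3,
    "wrist": 4,
    "hip": 9,
    "knee": 10,
    "ankle": 11,
    "toes": 22,
}

_FLO_TAG = 202021.25  # Middlebury sanity-check magic number


@dataclass(frozen=True)
class Keypoint:
    """A single 2D keypoint with a detector confidence in [0, 1]."""

    x: float
    y: float
    confidence: float = 1.0


@dataclass
class KeypointSet:
    """Nine named 2D joints for one side of the body at one frame.

    ``complete`` is False whenever a joint is absent or has zero
    confidence; incomplete sets cause the performance to be discarded
    downstream rather than silently imputed.
    """

    points: dict[str, Keypoint]
    side: str = "left"
    y_up: bool = True

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise InputError(f"side must be 'left' or 'right', got {self.side!r}")
        for name, kp in self.points.items():
            if name not in JOINT_NAMES:
                raise InputError(f"unknown joint name {name!r}")
            if not (np.isfinite(kp.x) and np.isfinite(kp.y)):
                raise InputError(f"non-finite coordinates for joint {name!r}")
            if not 0.0 <= kp.confidence <= 1.0:
                raise InputError(f"confidence out of [0, 1] for joint {name!r}")

    @property
    def complete(self) -> bool:
        return all(
            name in self.points and self.points[name].confidence > 0.0
            for name in JOINT_NAMES
        )

    def xy(self, name: str) -> np.ndarray:
        kp = self.points[name]
        return np.array([kp.x, kp.y], dtype=float)

    def flipped_y(self, height: int) -> "KeypointSet":
        """Return a copy with the y axis mirrored about an image of ``height``."""
        pts = {
            n: Keypoint(k.x, (height - 1) - k.y, k.confidence)
            for n, k in self.points.items()
        }
        return replace(self, points=pts, y_up=not self.y_up)


@dataclass
class FlowField:
    """Dense per-pixel displacement between two consecutive frames.

    ``u`` is horizontal (rightward positive); ``v`` is vertical in file
    coordinates (downward positive), matching the ``.flo`` convention.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float32)
        self.v = np.asarray(self.v, dtype=np.float32)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise InputError("u and v must be 2D arrays of identical shape")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise InputError("flow field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


@dataclass
class MaskPair:
    """Binary wheel and gymnast masks for one frame (image row order)."""

    wheel: np.ndarray
    gymnast: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.wheel = np.asarray(self.wheel, dtype=bool)
        self.gymnast = np.asarray(self.gymnast, dtype=bool)
        if self.wheel.shape != self.gymnast.shape or self.wheel.ndim != 2:
            raise InputError("wheel and gymnast masks must share one 2D shape")


# ---------------------------------------------------------------------------
# BODY_25 pose JSON
# ---------------------------------------------------------------------------

def read_body25_json(
    path: str | Path,
    side: str = "left",
    image_height: int | None = None,
    index_map: Mapping[str, int] | None = None,
) -> KeypointSet:
    """Read one frame of 25-keypoint pose JSON and extract one body side.

    When several people are present, the pose with the largest mean
    confidence is chosen.  If ``image_height`` is given, y coordinates are
    converted from image (y-down) to analysis (y-up) coordinates.

    Raises :class:`FormatError` for malformed JSON or a keypoint array whose
    length is not 25*3.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse pose JSON {path}: {exc}") from exc

    people = payload.get("people")
    if not isinstance(people, list) or not people:
        raise FormatError(f"{path}: no 'people' array in pose JSON")

    best: np.ndarray | None = None
    best_conf = -1.0
    for person in people:
        raw = person.get("pose_keypoints_2d")
        if raw is None:
            raise FormatError(f"{path}: person without 'pose_keypoints_2d'")
        arr = np.asarray(raw, dtype=float)
        if arr.size != 75:
            raise FormatError(
                f"{path}: expected 25 keypoints (75 floats), got {arr.size} floats"
            )
        arr = arr.reshape(25, 3)
        mean_conf = float(arr[:, 2].mean())
        if mean_conf > best_conf:
            best_conf = mean_conf
            best = arr

    assert best is not None
    if index_map is None:
        index_map = BODY25_LEFT_INDICES if side == "left" else BODY25_RIGHT_INDICES
    points = {}
    for name, idx in index_map.items():
        x, y, c = best[idx]
        points[name] = Keypoint(float(x), float(y), float(np.clip(c, 0.0, 1.0)))
    kps = KeypointSet(points=points, side=side, y_up=False)
    if image_height is not None:
        kps = kps.flipped_y(image_height)
    return kps


def write_body25_json(
    kps: KeypointSet,
    path: str | Path,
    image_height: int | None = None,
    index_map: Mapping[str, int] | None = None,
) -> None:
    """Write a keypoint set back out as a single-person 25-keypoint JSON.

    If the set is in analysis (y-up) coordinates, ``image_height`` is
    required to convert back to image coordinates; unmapped keypoint slots
    are written as zeros (absent).
    """
    out = kps
    if kps.y_up:
        if image_height is None:
            raise InputError("image_height required to write a y-up keypoint set")
        out = kps.flipped_y(image_height)
    if index_map is None:
        index_map = BODY25_LEFT_INDICES if kps.side == "left" else BODY25_RIGHT_INDICES
    flat = np.zeros((25, 3), dtype=float)
    for name, idx in index_map.items():
        if name in out.points:
            kp = out.points[name]
            flat[idx] = (kp.x, kp.y, kp.confidence)
    payload = {"version": 1.3, "people": [{"pose_keypoints_2d": flat.ravel().tolist()}]}
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Middlebury .flo
# ---------------------------------------------------------------------------

def read_flo(path: str | Path) -> FlowField:
    """Read a Middlebury ``.flo`` file (magic tag, width, height, u/v interleaved)."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 12:
        raise FormatError(f"{path}: truncated .flo header")
    (tag,) = struct.unpack("<f", data[:4])
    if tag != np.float32(_FLO_TAG):
        raise FormatError(f"{path}: bad .flo magic tag {tag!r}")
    width, height = struct.unpack("<ii", data[4:12])
    if width <= 0 or height <= 0:
        raise FormatError(f"{path}: invalid .flo dimensions {width}x{height}")
    expected = width * height * 2
    payload = np.frombuffer(data, dtype="<f4", offset=12)
    if payload.size != expected:
        raise FormatError(
            f"{path}: payload has {payload.size} floats, expected {expected}"
        )
    uv = payload.reshape(height, width, 2)
    return FlowField(u=uv[:, :, 0].copy(), v=uv[:, :, 1].copy())


def write_flo(field: FlowField, path: str | Path) -> None:
    height, width = field.shape
    with open(path, "wb") as fh:
        fh.write(struct.pack("<f", _FLO_TAG))
        fh.write(struct.pack("<ii", width, height))
        uv = np.stack([field.u, field.v], axis=-1).astype("<f4")
        fh.write(uv.tobytes())


# ---------------------------------------------------------------------------
# Mask images
# ---------------------------------------------------------------------------

def write_mask_pair(pair: MaskPair, path: str | Path) -> None:
    """Write one mask pair as an 8-bit label PNG (bit 1 wheel, bit 2 gymnast)."""
    label = pair.wheel.astype(np.uint8) | (pair.gymnast.astype(np.uint8) << 1)
    iio.imwrite(Path(path), label)


def read_mask_dir(directory: str | Path, pattern: str = "*.png") -> list[MaskPair]:
    """Read every mask PNG in ``directory`` (sorted by name) into mask pairs.

    Images must share a single resolution and contain only the label values
    {0, 1, 2, 3}; anything else raises :class:`FormatError`.
    """
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    pairs: list[MaskPair] = []
    shape: tuple[int, int] | None = None
    for i, f in enumerate(files):
        img = np.asarray(iio.imread(f))
        if img.ndim != 2:
            raise FormatError(f"{f}: mask image must be single-channel")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise FormatError(
                f"{f}: resolution {img.shape} differs from {shape}"
            )
        bad = set(np.unique(img)) - {0, 1, 2, 3}
        if bad:
            raise FormatError(f"{f}: unknown label values {sorted(bad)}")
        pairs.append(
            MaskPair(wheel=(img & 1) > 0, gymnast=(img & 2) > 0, frame_index=i)
        )
    return pairs


# ---------------------------------------------------------------------------
# Feature/score tables
# ---------------------------------------------------------------------------

#: Canonical column order of the on-disk feature table.  The 21 feature
#: columns come from :data:`wheelvault.features.FEATURE_NAMES` -- defined in
#: exactly one place and shared by writer, reader, and model.
TABLE_COLUMNS: tuple[str, ...] = (
    "gymnast",
    "day",
    *FEATURE_NAMES,
    "judge1",
    "judge2",
    "mean_deduction",
)


def write_feature_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a per-performance feature table as canonical CSV."""
    missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"feature table is missing columns: {missing}")
    frame.loc[:, list(TABLE_COLUMNS)].to_csv(
        path, index=False, lineterminator="\r\n", float_format="%.17g"
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table CSV, validating the canonical header."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if tuple(frame.columns) != TABLE_COLUMNS:
        raise FormatError(
            "feature table header does not match the canonical column list"
        )
    return frame
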