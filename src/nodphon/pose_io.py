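"""Readers and writers for pose keypoint streams and tiered annotations.

Pose input follows the OpenPose JSON layout: per frame, a ``people`` list whose
entries carry flat ``pose_keypoints_2d`` (25 body points x (x, y, confidence))
and ``face_keypoints_2d`` (70 face points) arrays.  Both the per-frame-file
layout (one JSON per video frame, frame index taken from the file name) and a
consolidated single-file layout (a JSON array of frame objects) are supported.

Annotations are ELAN EAF documents (XML): a ``TIME_ORDER`` of time slots in
milliseconds plus tiers of ``ALIGNABLE_ANNOTATION`` spans.  Unaligned time
slots are resolved by linear interpolation between the nearest anchored slots,
mirroring how ELAN displays them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lxml import etree

N_BODY = 25
N_FACE = 70

#: index of the collarbone/neck keypoint in the 25-point body model
BODY_NECK = 1
#: index of the mid-hip keypoint in the 25-point body model
BODY_MIDHIP = 8
#: index of the nose tip in the 70-point face model
FACE_NOSE_TIP = 30


class PoseParseError(ValueError):
    """Raised when a keypoint file cannot be interpreted."""


class AnnotationError(ValueError):
    """Raised for malformed or invalid annotation documents."""


@dataclass(frozen=True)
class Keypoint:
    """A single 2D image keypoint. ``confidence == 0`` means missing."""

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class PoseFrame:
    """One video frame: 25 body and 70 face keypoints as (n, 3) arrays.

    Columns are x, y, confidence.  An all-zero row is a missing keypoint.
    An empty face array (shape (0, 3)) marks a frame without face detection.
    """

    frame_index: int
    body: np.ndarray
    face: np.ndarray

    def __post_init__(self) -> None:
        self.body = np.asarray(self.body, dtype=float)
        self.face = np.asarray(self.face, dtype=float)
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.body.shape != (N_BODY, 3):
            raise ValueError(f"body must be ({N_BODY}, 3), got {self.body.shape}")
        if self.face.shape not in ((N_FACE, 3), (0, 3)):
            raise ValueError(f"face must be ({N_FACE}, 3) or empty, got {self.face.shape}")

    @property
    def has_person(self) -> bool:
        return bool(np.any(self.body[:, 2] > 0))

    @classmethod
    def missing(cls, frame_index: int) -> "PoseFrame":
        return cls(frame_index, np.zeros((N_BODY, 3)), np.zeros((N_FACE, 3)))


@dataclass
class PoseSequence:
    """An ordered keypoint stream for one participant.

    ``frame_index`` is strictly increasing but may have gaps (dropped frames);
    gaps are preserved, never silently filled, and reported by :meth:`gaps`.
    """

    frames: list[PoseFrame]
    fps: float
    participant_id: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([f.frame_index for f in self.frames], dtype=int)

    def gaps(self) -> list[int]:
        """Frame indices absent between the first and last recorded frame."""
        if not self.frames:
            return []
        present = set(self.frame_indices.tolist())
        lo, hi = self.frames[0].frame_index, self.frames[-1].frame_index
        return [i for i in range(lo, hi + 1) if i not in present]

    def body_array(self) -> np.ndarray:
        """Stack body keypoints as (n_frames, 25, 3)."""
        return np.stack([f.body for f in self.frames]) if self.frames else np.zeros((0, N_BODY, 3))

    def face_array(self) -> np.ndarray:
        """Stack face keypoints as (n_frames, 70, 3); empty faces become zeros."""
        out = np.zeros((len(self.frames), N_FACE, 3))
        for i, f in enumerate(self.frames):
            if f.face.shape[0] == N_FACE:
                out[i] = f.face
        return out


@dataclass(frozen=True)
class AnnotationSpan:
    """A time-aligned tag: [start, end) in milliseconds."""

    start: float
    end: float
    value: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid span ({self.start}, {self.end}, {self.value!r}): need 0 <= start < end"
            )

    @property
    def duration_ms(self) -> float:
        return self.end - self.start

    def intersects(self, other: "AnnotationSpan") -> bool:
        return min(self.end, other.end) > max(self.start, other.start)


@dataclass
class AnnotationDocument:
    """Named tiers of non-overlapping, start-sorted annotation spans."""

    tiers: dict[str, list[AnnotationSpan]]
    participant_id: str = ""

    def __post_init__(self) -> None:
        for name, spans in self.tiers.items():
            for a, b in zip(spans, spans[1:]):
                if b.start < a.start:
                    raise AnnotationError(f"tier {name!r}: spans not sorted by start")
                if b.start < a.end:
                    raise AnnotationError(
                        f"tier {name!r}: span ({b.start}, {b.end}) overlaps ({a.start}, {a.end})"
                    )

    def tier(self, name: str) -> list[AnnotationSpan]:
        if name not in self.tiers:
            raise AnnotationError(
                f"tier {name!r} not present; available: {sorted(self.tiers)}"
            )
        return self.tiers[name]


# ---------------------------------------------------------------------------
# OpenPose-style keypoint streams
# ---------------------------------------------------------------------------

def _person_to_frame(person: Mapping, frame_index: int) -> PoseFrame:
    def grab(key: str, n: int) -> np.ndarray:
        flat = person.get(key) or []
        if len(flat) == 0:
            return np.zeros((0, 3)) if key == "face_keypoints_2d" else np.zeros((n, 3))
        if len(flat) != 3 * n:
            raise PoseParseError(
                f"frame {frame_index}: {key} has {len(flat)} values, expected {3 * n}"
            )
        return np.asarray(flat, dtype=float).reshape(n, 3)

    return PoseFrame(frame_index, grab("pose_keypoints_2d", N_BODY), grab("face_keypoints_2d", N_FACE))


_FRAME_NUM_RE = re.compile(r"(\d+)\D*$")


def _frame_index_from_name(path: Path, fallback: int) -> int:
    m = _FRAME_NUM_RE.search(path.stem)
    return int(m.group(1)) if m else fallback


def read_pose_stream(
    source: str | Path,
    fps: float,
    participant_selector: int | Callable[[Sequence[Mapping]], Mapping] | None = None,
    participant_id: str = "",
) -> PoseSequence:
    """Read an OpenPose-style keypoint stream into a :class:`PoseSequence`.

    Parameters
    ----------
    source
        Either a directory of per-frame ``*.json`` files (frame index parsed
        from trailing digits in the file name) or a single JSON file holding a
        list of frame objects (optionally under a ``frames`` key), each with a
        ``people`` list and optional ``frame_index``.
    fps
        Frame rate of the source video in Hz.
    participant_selector
        Required when a frame contains more than one person: an integer index
        into the ``people`` list or a callable choosing one person dict.

    Frames with an empty ``people`` list are kept as all-missing frames so
    that timing is preserved; absent frame indices remain as gaps.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)

    records: list[tuple[int, Mapping]] = []
    if source.is_dir():
        files = sorted(source.glob("*.json"))
        if not files:
            raise PoseParseError(f"no .json keypoint files in {source}")
        for i, path in enumerate(files):
            try:
                payload = json.loads(path.read_text())
            except json.JSONDecodeError as exc:
                raise PoseParseError(f"malformed keypoint file {path.name}: {exc}") from exc
            records.append((_frame_index_from_name(path, i), payload))
    else:
        try:
            payload = json.loads(source.read_text())
        except json.JSONDecodeError as exc:
            raise PoseParseError(f"malformed keypoint file {source.name}: {exc}") from exc
        if isinstance(payload, Mapping):
            payload = payload.get("frames", [payload])
        for i, rec in enumerate(payload):
            records.append((int(rec.get("frame_index", i)), rec))

    frames: list[PoseFrame] = []
    for frame_index, rec in sorted(records, key=lambda r: r[0]):
        people = rec.get("people", [])
        if not people:
            frames.append(PoseFrame.missing(frame_index))
            continue
        if len(people) == 1:
            person = people[0]
        elif isinstance(participant_selector, int):
            person = people[participant_selector]
        elif callable(participant_selector):
            person = participant_selector(people)
        else:
            raise PoseParseError(
                f"frame {frame_index}: {len(people)} people present but no participant_selector"
            )
        frames.append(_person_to_frame(person, frame_index))

    return PoseSequence(frames=frames, fps=fps, participant_id=participant_id)


# ---------------------------------------------------------------------------
# ELAN EAF documents
# ---------------------------------------------------------------------------

def _resolve_time_slots(time_order: etree._Element) -> dict[str, float]:
    """Map time-slot ids to milliseconds, interpolating unanchored slots.

    ELAN permits slots without TIME_VALUE; their position in document order
    between anchored slots defines them.  Unanchored slots before the first /
    after the last anchor inherit that anchor's value.
    """
    slots = time_order.findall("TIME_SLOT")
    ids = [s.get("TIME_SLOT_ID") for s in slots]
    vals: list[float | None] = [
        float(s.get("TIME_VALUE")) if s.get("TIME_VALUE") is not None else None for s in slots
    ]
    anchored = [i for i, v in enumerate(vals) if v is not None]
    if not anchored and slots:
        raise AnnotationError("no anchored time slots in TIME_ORDER")
    for i, v in enumerate(vals):
        if v is not None:
            continue
        prev = max((a for a in anchored if a < i), default=None)
        nxt = min((a for a in anchored if a > i), default=None)
        if prev is None:
            vals[i] = vals[nxt]  # type: ignore[index]
        elif nxt is None:
            vals[i] = vals[prev]
        else:
            frac = (i - prev) / (nxt - prev)
            vals[i] = vals[prev] + frac * (vals[nxt] - vals[prev])  # type: ignore[operator]
    return {sid: float(v) for sid, v in zip(ids, vals)}  # type: ignore[arg-type]


def read_annotation_document(
    source: str | Path,
    tier_names: Iterable[str] | None = None,
    participant_id: str = "",
) -> AnnotationDocument:
    """Read the requested tiers of an EAF file with millisecond-resolved spans.

    Raises :class:`AnnotationError` if a requested tier is absent (the message
    lists the tiers that do exist) or if any span violates ``start < end``.
    """
    source = Path(source)
    root = etree.parse(str(source)).getroot()
    time_order = root.find("TIME_ORDER")
    ts = _resolve_time_slots(time_order) if time_order is not None else {}

    available: dict[str, etree._Element] = {
        t.get("TIER_ID"): t for t in root.findall("TIER")
    }
    wanted = list(tier_names) if tier_names is not None else list(available)
    missing = [n for n in wanted if n not in available]
    if missing:
        raise AnnotationError(
            f"tier(s) {missing} not found in {source.name}; available: {sorted(available)}"
        )

    tiers: dict[str, list[AnnotationSpan]] = {}
    for name in wanted:
        spans = []
        for ann in available[name].iter("ALIGNABLE_ANNOTATION"):
            start = ts[ann.get("TIME_SLOT_REF1")]
            end = ts[ann.get("TIME_SLOT_REF2")]
            value_el = ann.find("ANNOTATION_VALUE")
            value = value_el.text or "" if value_el is not None else ""
            if start >= end:
                raise AnnotationError(
                    f"tier {name!r}: span ({start}, {end}, {value!r}) has start >= end"
                )
            spans.append(AnnotationSpan(start, end, value))
        tiers[name] = sorted(spans, key=lambda s: s.start)
    return AnnotationDocument(tiers=tiers, participant_id=participant_id)


def write_annotation_document(doc: AnnotationDocument, destination: str | Path) -> None:
    """Write an :class:`AnnotationDocument` as a minimal valid EAF file."""
    root = etree.Element(
        "ANNOTATION_DOCUMENT",
        AUTHOR="nodphon",
        DATE="1970-01-01T00:00:00+00:00",
        FORMAT="3.0",
        VERSION="3.0",
    )
    header = etree.SubElement(root, "HEADER", MEDIA_FILE="", TIME_UNITS="milliseconds")
    etree.SubElement(header, "PROPERTY", NAME="participant").text = doc.participant_id
    time_order = etree.SubElement(root, "TIME_ORDER")

    slot_count = 0
    ann_count = 0
    tier_elems = []
    for name, spans in doc.tiers.items():
        tier = etree.Element(
            "TIER", LINGUISTIC_TYPE_REF="default-lt", TIER_ID=name,
            PARTICIPANT=doc.participant_id,
        )
        for span in spans:
            refs = []
            for t in (span.start, span.end):
                slot_count += 1
                sid = f"ts{slot_count}"
                val = str(int(round(t)))
                etree.SubElement(time_order, "TIME_SLOT", TIME_SLOT_ID=sid, TIME_VALUE=val)
                refs.append(sid)
            ann_count += 1
            ann = etree.SubElement(tier, "ANNOTATION")
            al = etree.SubElement(
                ann, "ALIGNABLE_ANNOTATION",
                ANNOTATION_ID=f"a{ann_count}", TIME_SLOT_REF1=refs[0], TIME_SLOT_REF2=refs[1],
            )
            etree.SubElement(al, "ANNOTATION_VALUE").text = span.value
        tier_elems.append(tier)
    for tier in tier_elems:
        root.append(tier)
    etree.SubElement(
        root, "LINGUISTIC_TYPE",
        GRAPHIC_REFERENCES="false", LINGUISTIC_TYPE_ID="default-lt", TIME_ALIGNABLE="true",
    )
    Path(destination).write_bytes(
        etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

FLOAT_FORMAT = "%.6f"


def write_measurements(
    rows: pd.DataFrame,
    destination: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write per-nod measurement rows as UTF-8 CSV with a header.

    Column order is preserved as given (deterministic for a fixed pipeline);
    floats are written at fixed precision.  Configuration metadata goes into
    ``#``-prefixed comment lines before the header so a table is traceable to
    the parameters that produced it.
    """
    destination = Path(destination)
    with open(destination, "w", encoding="utf-8", newline="") as fh:
        for key in sorted(metadata or {}):
            fh.write(f"# {key}={metadata[key]}\n")
        rows.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_measurements(source: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_measurements`."""
    return pd.read_csv(source, comment="#")
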