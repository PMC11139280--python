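"""From keypoint streams to normalized nose trajectories and per-nod measures.

Nodding is tracked as the vertical motion of the nose tip relative to the
collarbone center.  To make measures comparable across participants and camera
distances, pixel displacements are divided by the participant's hip-to-
collarbone distance; the resulting unit is the normalized pixel (npix).
The image y axis grows downward, so the sign is flipped once here: positive y
in a :class:`NormalizedTrajectory` means the nose moved up.

The trajectory is low-pass filtered with a zero-phase (forward-backward)
Butterworth filter to suppress pose-estimation jitter, and extrema are found
with a topographic-prominence and minimum-separation constraint so that noise
wiggles do not count as nod peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from nodphon.pose_io import (
    BODY_MIDHIP,
    BODY_NECK,
    FACE_NOSE_TIP,
    AnnotationSpan,
    PoseSequence,
)


@dataclass
class NormalizedTrajectory:
    """Uniformly sampled vertical nose position, up-positive, in npix.

    ``t`` runs at spacing 1/fps from the first recorded frame; dropped frames
    and low-confidence samples are linearly interpolated and their share is
    reported in ``interpolated_fraction``.
    """

    t: np.ndarray
    y: np.ndarray
    fps: float
    interpolated_fraction: float = 0.0
    scale_npix: float = float("nan")
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have the same shape")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fps, rtol=1e-6, atol=1e-9):
                raise ValueError("t must be uniformly spaced at 1/fps")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be finite everywhere after interpolation")

    def __len__(self) -> int:
        return len(self.t)

    def sample_slice(self, span: AnnotationSpan) -> slice:
        """Index slice of samples whose time falls inside a span (ms)."""
        lo = int(np.searchsorted(self.t, span.start / 1000.0, side="left"))
        hi = int(np.searchsorted(self.t, span.end / 1000.0, side="right"))
        return slice(lo, hi)


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass configuration."""

    order: int = 2
    cutoff_hz: float = 20.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass(frozen=True)
class PeakSpec:
    """Extrema constraints: topographic prominence (npix) and separation (frames)."""

    min_prominence: float = 0.1
    min_separation: int = 5

    def __post_init__(self) -> None:
        if self.min_prominence <= 0 or self.min_separation <= 0:
            raise ValueError("min_prominence and min_separation must be > 0")


@dataclass
class Extrema:
    """Detected maxima and minima of a trajectory (indices, times, values)."""

    max_indices: np.ndarray
    min_indices: np.ndarray
    t: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def max_times(self) -> np.ndarray:
        return self.t[self.max_indices]

    @property
    def min_times(self) -> np.ndarray:
        return self.t[self.min_indices]

    @property
    def max_values(self) -> np.ndarray:
        return self.y[self.max_indices]

    @property
    def min_values(self) -> np.ndarray:
        return self.y[self.min_indices]


@dataclass(frozen=True)
class NodMeasures:
    """Per-nod phonetic measures.

    duration
        Seconds between annotated onset and offset; taken from the annotation
        alone, independent of pose data.
    velocity
        Mean absolute vertical nose displacement between adjacent frames
        within the span, scaled by fps: npix/s.
    max_amplitude
        Highest detected peak minus lowest detected trough inside the span
        (npix).  When the prominence threshold leaves no peak or no trough,
        the span's raw max(y) - min(y) is reported and ``amplitude_fallback``
        is set.
    """

    duration: float
    velocity: float
    max_amplitude: float
    n_peaks: int
    n_troughs: int
    peak_rate: float
    amplitude_fallback: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.velocity < 0 or self.max_amplitude < 0:
            raise ValueError("velocity and max_amplitude must be >= 0")


def _interp_nan(y: np.ndarray) -> tuple[np.ndarray, float]:
    """Linearly interpolate NaNs from nearest valid neighbors (edges held)."""
    bad = ~np.isfinite(y)
    if not bad.any():
        return y, 0.0
    if bad.all():
        raise ValueError("no valid samples to interpolate from")
    idx = np.arange(len(y))
    out = y.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], y[~bad])
    return out, float(bad.mean())


def normalize_pose(seq: PoseSequence, scale: str = "median") -> NormalizedTrajectory:
    """Extract the up-positive, size-normalized vertical nose trajectory.

    The person-size scale is the hip-to-collarbone (body keypoints 8 and 1)
    Euclidean distance: by default the median over all frames where both
    keypoints are confident (robust to posture changes and jitter); with
    ``scale="per_frame"`` each frame uses its own distance, interpolated where
    invalid.  The trajectory is resampled onto the full frame-index grid, so
    dropped frames become interpolated samples and are counted in
    ``interpolated_fraction`` together with low-confidence nose samples.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 frames")
    body = seq.body_array()
    face = seq.face_array()
    idx = seq.frame_indices

    neck = body[:, BODY_NECK, :]
    hip = body[:, BODY_MIDHIP, :]
    nose = face[:, FACE_NOSE_TIP, :]

    scale_valid = (neck[:, 2] > 0) & (hip[:, 2] > 0)
    if not scale_valid.any():
        raise ValueError("no frames with valid collarbone and hip keypoints")
    dist = np.hypot(neck[:, 0] - hip[:, 0], neck[:, 1] - hip[:, 1])
    median_scale = float(np.median(dist[scale_valid]))
    if median_scale <= 0:
        raise ValueError("non-positive hip-collarbone scale")

    y_valid = (nose[:, 2] > 0) & (neck[:, 2] > 0)
    raw = np.full(len(seq), np.nan)
    if scale == "median":
        raw[y_valid] = -(nose[y_valid, 1] - neck[y_valid, 1]) / median_scale
    elif scale == "per_frame":
        ok = y_valid & scale_valid & (dist > 0)
        raw[ok] = -(nose[ok, 1] - neck[ok, 1]) / dist[ok]
    else:
        raise ValueError(f"unknown scale mode {scale!r}")

    # resample onto the dense frame-index grid so t is uniform at 1/fps
    full_idx = np.arange(idx[0], idx[-1] + 1)
    dense = np.full(len(full_idx), np.nan)
    dense[idx - idx[0]] = raw
    y, frac = _interp_nan(dense)
    t = full_idx / seq.fps
    return NormalizedTrajectory(
        t=t, y=y, fps=seq.fps, interpolated_fraction=frac,
        scale_npix=median_scale, participant_id=seq.participant_id,
    )


def smooth_trajectory(traj: NormalizedTrajectory, spec: FilterSpec = FilterSpec()) -> NormalizedTrajectory:
    """Zero-phase Butterworth low-pass filtering of the whole trajectory.

    Filtering is applied forward and backward (``filtfilt``), so the output
    has no phase lag; length is unchanged.  Filter once per recording, never
    per annotation span, to keep filter transients away from nod boundaries.
    """
    nyquist = traj.fps / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    b, a = signal.butter(spec.order, spec.cutoff_hz / nyquist, btype="low")
    padlen = 3 * max(len(a), len(b))
    if len(traj) <= padlen:
        raise ValueError(f"trajectory of {len(traj)} samples too short for order-{spec.order} filtering")
    y = signal.filtfilt(b, a, traj.y)
    return NormalizedTrajectory(
        t=traj.t, y=y, fps=traj.fps,
        interpolated_fraction=traj.interpolated_fraction,
        scale_npix=traj.scale_npix, participant_id=traj.participant_id,
    )


def detect_extrema(traj: NormalizedTrajectory, spec: PeakSpec = PeakSpec()) -> Extrema:
    """Find maxima and minima under prominence and separation constraints.

    Maxima are local maxima of y with topographic prominence at least
    ``min_prominence`` whose pairwise index distance is at least
    ``min_separation`` (lower peaks dropped first); minima are the same
    procedure applied to -y.  An empty result is valid.
    """
    max_idx, _ = signal.find_peaks(
        traj.y, prominence=spec.min_prominence, distance=spec.min_separation
    )
    min_idx, _ = signal.find_peaks(
        -traj.y, prominence=spec.min_prominence, distance=spec.min_separation
    )
    return Extrema(max_indices=max_idx, min_indices=min_idx, t=traj.t, y=traj.y)


def compute_nod_measures(
    traj: NormalizedTrajectory,
    span: AnnotationSpan,
    spec: PeakSpec = PeakSpec(),
    extrema: Extrema | None = None,
) -> NodMeasures:
    """Measure one annotated nod span on a smoothed trajectory.

    ``extrema`` may be passed in when it was already computed for the whole
    trajectory (the normal batch path); otherwise it is computed here.
    """
    sl = traj.sample_slice(span)
    n = sl.stop - sl.start
    if sl.start >= len(traj) or sl.stop <= 0 or span.start / 1000.0 < traj.t[0] - 1e-9 or span.end / 1000.0 > traj.t[-1] + 1.0 / traj.fps + 1e-9:
        raise ValueError(f"span ({span.start}, {span.end}) outside trajectory extent")
    if n < 2:
        raise ValueError(f"span ({span.start}, {span.end}) shorter than 2 frames")

    duration = (span.end - span.start) / 1000.0
    y_span = traj.y[sl]
    velocity = float(traj.fps * np.mean(np.abs(np.diff(y_span))))

    if extrema is None:
        extrema = detect_extrema(traj, spec)
    in_span_max = extrema.max_indices[(extrema.max_indices >= sl.start) & (extrema.max_indices < sl.stop)]
    in_span_min = extrema.min_indices[(extrema.min_indices >= sl.start) & (extrema.min_indices < sl.stop)]

    fallback = False
    if len(in_span_max) and len(in_span_min):
        amplitude = float(traj.y[in_span_max].max() - traj.y[in_span_min].min())
    else:
        amplitude = float(y_span.max() - y_span.min())
        fallback = True

    n_peaks = int(len(in_span_max))
    return NodMeasures(
        duration=duration,
        velocity=velocity,
        max_amplitude=amplitude,
        n_peaks=n_peaks,
        n_troughs=int(len(in_span_min)),
        peak_rate=n_peaks / duration,
        amplitude_fallback=fallback,
    )
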