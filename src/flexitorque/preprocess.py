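"""Turn raw trial recordings into rectified circumference and strain series.

The chain is: calibrate a connatural (passive) circumference profile, segment
the trial into flexion sweeps, rectify each sweep's measured circumference
into the calibrated frame to cancel sensor baseline drift, then convert to
voluntary circumferential strain.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import (
    CalibrationCoverageError,
    OutOfRangeError,
    ParameterError,
    ProtocolError,
    RectificationError,
    SegmentationError,
)
from .synthetic import TrialRecording


@dataclass
class ConnaturalProfile:
    """Calibrated passive circumference C0 as a function of elbow angle.

    Evaluation is linear interpolation between calibration nodes with linear
    extrapolation (edge-segment slope) out to the ROM limits.
    """

    angle: np.ndarray  # node angles (deg), strictly increasing
    c0: np.ndarray     # circumference at nodes (mm)
    rom: tuple

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        self.c0 = np.asarray(self.c0, dtype=float)
        if self.angle.size != self.c0.size:
            raise ParameterError("profile node arrays must have equal length")
        if self.angle.size < 2:
            raise ParameterError("profile needs at least two nodes")
        if np.any(np.diff(self.angle) <= 0):
            raise ParameterError("profile node angles must be strictly increasing")
        if np.any(self.c0 <= 0):
            raise ParameterError("connatural circumference must be > 0 everywhere")

    def __call__(self, theta):
        scalar = np.isscalar(theta)
        th = np.asarray(theta, dtype=float)
        lo, hi = self.rom
        if np.any(th < lo - 1e-6) or np.any(th > hi + 1e-6):
            raise OutOfRangeError(
                f"angle outside profile range [{lo}, {hi}]")
        out = np.interp(th, self.angle, self.c0)
        a, c = self.angle, self.c0
        left = th < a[0]
        if np.any(left):
            s0 = (c[1] - c[0]) / (a[1] - a[0])
            out = np.where(left, c[0] + s0 * (th - a[0]), out)
        right = th > a[-1]
        if np.any(right):
            s1 = (c[-1] - c[-2]) / (a[-1] - a[-2])
            out = np.where(right, c[-1] + s1 * (th - a[-1]), out)
        return float(out) if scalar else out


def calibrate_connatural(passive_trials, bin_width: float = 1.0) -> ConnaturalProfile:
    """Average passive-trial circumference into angle bins and interpolate.

    Nodes are placed at each bin's mean sample angle (not the bin center), so
    a linear underlying profile is recovered exactly regardless of how the
    sweep samples fall.  An empty interior bin means a coverage gap larger
    than ``bin_width`` and raises :class:`CalibrationCoverageError`.
    """
    if isinstance(passive_trials, TrialRecording):
        passive_trials = [passive_trials]
    trials = list(passive_trials)
    if not trials:
        raise ParameterError("at least one passive trial is required")
    for trial in trials:
        if trial.protocol.mode != "passive":
            raise ProtocolError(
                f"calibration requires passive trials, got {trial.protocol.mode!r}")
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    lo, hi = trials[0].protocol.rom
    angles = np.concatenate([t.angle for t in trials])
    circs = np.concatenate([t.circumference for t in trials])
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    idx = np.clip(((angles - lo) / bin_width).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        gap = int(np.argmax(counts == 0))
        raise CalibrationCoverageError(
            f"no passive samples in angle bin "
            f"[{lo + gap * bin_width:.1f}, {lo + (gap + 1) * bin_width:.1f}] deg")
    node_angle = np.bincount(idx, weights=angles, minlength=n_bins) / counts
    node_c0 = np.bincount(idx, weights=circs, minlength=n_bins) / counts
    return ConnaturalProfile(node_angle, node_c0, rom=(lo, hi))


@dataclass
class FlexionSegment:
    """One monotone rising sweep of the elbow angle within a trial."""

    trial: TrialRecording
    start: int          # inclusive sample index
    stop: int           # exclusive sample index
    cycle: int          # 1-based flexion number within the trial

    @property
    def indices(self) -> slice:
        return slice(self.start, self.stop)

    @property
    def time(self) -> np.ndarray:
        return self.trial.time[self.indices]

    @property
    def angle(self) -> np.ndarray:
        return self.trial.angle[self.indices]

    @property
    def torque(self) -> np.ndarray:
        return self.trial.torque[self.indices]

    @property
    def circumference(self) -> np.ndarray:
        return self.trial.circumference[self.indices]


def _refine_extremum(angle: np.ndarray, i: int, w: int, kind: int) -> int:
    lo = max(0, i - w)
    hi = min(angle.size, i + w + 1)
    window = angle[lo:hi]
    off = int(np.argmax(window)) if kind > 0 else int(np.argmin(window))
    return lo + off


def segment_flexions(trial: TrialRecording, smooth_window_s: float = 0.05,
                     hysteresis_deg: float = 2.0,
                     span_tol_deg: float = 5.0) -> list[FlexionSegment]:
    """Detect rising angle sweeps spanning the ROM, ordered by time.

    Turnarounds are found on a moving-average smoothed angle with a prominence
    hysteresis, then refined to the raw-signal extremum so that noiseless
    triangular waves segment exactly at their vertices.
    """
    a = trial.angle
    n = a.size
    if n < 3:
        raise SegmentationError("trial too short to segment")
    lo, hi = trial.protocol.rom
    mid = 0.5 * (lo + hi)
    fs = trial.sample_rate
    w = max(1, int(round(smooth_window_s * fs)))
    if w % 2 == 0:
        w += 1
    sm = uniform_filter1d(a, size=w, mode="nearest")
    peaks, _ = find_peaks(sm, prominence=hysteresis_deg)
    troughs, _ = find_peaks(-sm, prominence=hysteresis_deg)
    extrema = [(int(i), 1) for i in peaks] + [(int(i), -1) for i in troughs]
    extrema.append((0, -1 if sm[0] < mid else 1))
    extrema.append((n - 1, -1 if sm[-1] < mid else 1))
    extrema.sort()
    # merge consecutive extrema of the same kind, keeping the raw extreme
    merged: list[tuple[int, int]] = []
    for i, kind in extrema:
        if merged and merged[-1][1] == kind:
            j = merged[-1][0]
            better = (a[i] > a[j]) if kind > 0 else (a[i] < a[j])
            if better:
                merged[-1] = (i, kind)
        else:
            merged.append((i, kind))
    refined = [( _refine_extremum(a, i, w, kind), kind) for i, kind in merged]
    segments: list[FlexionSegment] = []
    cycle = 0
    for (i0, k0), (i1, k1) in zip(refined[:-1], refined[1:]):
        if k0 == -1 and k1 == 1:
            if a[i0] <= lo + span_tol_deg and a[i1] >= hi - span_tol_deg:
                cycle += 1
                segments.append(FlexionSegment(trial, i0, i1 + 1, cycle))
    if not segments:
        raise SegmentationError(
            "no complete flexion sweep of the ROM found in trial")
    return segments


def select_flexion(segments: list[FlexionSegment], index: int = 2) -> FlexionSegment:
    """Pick the ``index``-th (1-based) flexion; the 2nd by default.

    The 2nd flexion is past the fabric sensor's non-repeatable 1st cycle but
    has accumulated the least baseline drift of the remaining cycles.
    """
    if index < 1:
        raise ParameterError("flexion index is 1-based")
    if len(segments) < index:
        raise SegmentationError(
            f"trial has only {len(segments)} flexions; cannot select #{index}")
    return segments[index - 1]


def _start_circumference(segment: FlexionSegment, window_deg: float) -> float:
    """Measured circumference at the relaxed ROM start of a flexion.

    Averages the trough sample together with the tail of the preceding
    extension (samples within ``window_deg`` of the trough angle), where the
    flexors are guaranteed relaxed.  Samples after the trough may already
    carry voluntary contraction (the isometric effort build-up against an
    isotonic impedance happens at the ROM start), so the forward direction is
    not used.
    """
    trial = segment.trial
    a_min = segment.angle[0]
    values = [trial.circumference[segment.start]]
    k = segment.start - 1
    while k >= 0 and trial.angle[k] <= a_min + window_deg:
        values.append(trial.circumference[k])
        k -= 1
    return float(np.mean(values))


def _end_window(segment: FlexionSegment, window_deg: float) -> slice:
    a = segment.angle
    k = a.size - 2
    while k >= 0 and a[k] >= a[-1] - window_deg:
        k -= 1
    return slice(k + 1, a.size)


def flexion_end_circumference(segments: list[FlexionSegment],
                              window_deg: float = 1.0) -> float:
    """Average measured circumference at flexion-to-extension turnarounds.

    This is the upper frame constant of the rectification: all flexions end at
    the ROM top with the torque passing through zero, so their terminal
    circumferences estimate one common value.
    """
    if not segments:
        raise ParameterError("at least one flexion segment is required")
    ends = [float(seg.circumference[_end_window(seg, window_deg)].mean())
            for seg in segments]
    return float(np.mean(ends))


def rectify_circumference(segment: FlexionSegment, profile: ConnaturalProfile,
                          cbar120: float | None = None,
                          segments: list[FlexionSegment] | None = None,
                          window_deg: float = 1.0) -> np.ndarray:
    """Map a flexion's measured circumference into the calibrated frame.

    c_hat = (C - C_start) / (C_end - C_start) * (Cbar_end - C0_start) + C0_start

    where C_start/C_end are windowed means at the segment's angle extremes,
    C0_start is the calibrated connatural circumference at the ROM start, and
    Cbar_end is the trial-level average turnaround circumference (computed
    from ``segments`` if not supplied).  Additive offsets of the measured
    series cancel; the output hits C0_start and Cbar_end at the endpoints.
    """
    c = segment.circumference
    c_start = _start_circumference(segment, window_deg)
    c_end = float(c[_end_window(segment, window_deg)].mean())
    span = c_end - c_start
    if abs(span) < 1e-9:
        raise RectificationError(
            "circumference span across the flexion is degenerate (flat signal)")
    if cbar120 is None:
        if segments is None:
            segments = segment_flexions(segment.trial)
        cbar120 = flexion_end_circumference(segments, window_deg)
    c0_start = float(profile(profile.rom[0]))
    return (c - c_start) / span * (cbar120 - c0_start) + c0_start


@dataclass
class StrainSeries:
    """Voluntary circumferential strain of one flexion versus elbow angle."""

    angle: np.ndarray
    strain: np.ndarray
    circumference_rect: np.ndarray
    valid: np.ndarray
    time: np.ndarray | None = None
    torque: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        self.circumference_rect = np.asarray(self.circumference_rect, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.angle.size
        if not (self.strain.size == self.circumference_rect.size ==
                self.valid.size == n):
            raise ParameterError("strain series arrays must share one length")


def compute_strain(angle, rectified, profile: ConnaturalProfile) -> StrainSeries:
    """Pointwise voluntary strain s = (c_hat - C0(theta)) / C0(theta)."""
    theta = np.asarray(angle, dtype=float)
    chat = np.asarray(rectified, dtype=float)
    c0 = profile(theta)  # raises OutOfRangeError outside the profile range
    strain = (chat - c0) / c0
    valid = np.isfinite(strain) & np.isfinite(chat)
    return StrainSeries(theta, strain, chat, valid)


def normalize_strain(series: StrainSeries, s_max_profile) -> np.ndarray:
    """Normalized strain beta = s / s_max(theta), an activation-like quantity.

    ``s_max_profile`` may be a scalar, an array aligned with the series, or a
    callable of angle.  Provided for completeness; the trained torque model
    uses raw strain.
    """
    if callable(s_max_profile):
        smax = np.asarray(s_max_profile(series.angle), dtype=float)
    else:
        smax = np.broadcast_to(np.asarray(s_max_profile, dtype=float),
                               series.angle.shape).astype(float)
    if np.any(smax <= 0):
        raise ParameterError("s_max_profile must be > 0 over the segment")
    return series.strain / smax


def extract_strain(trial: TrialRecording, profile: ConnaturalProfile,
                   flexion_index: int = 2, window_deg: float = 1.0,
                   segments: list[FlexionSegment] | None = None) -> StrainSeries:
    """Full per-trial chain: segment, select flexion, rectify, compute strain.

    The returned series carries the segment's time and torque channels and
    trial metadata, ready for torque-per-strain analysis.
    """
    if segments is None:
        segments = segment_flexions(trial)
    seg = select_flexion(segments, flexion_index)
    rect = rectify_circumference(seg, profile, segments=segments,
                                 window_deg=window_deg)
    series = compute_strain(seg.angle, rect, profile)
    series.time = seg.time
    series.torque = seg.torque
    series.meta = {
        "subject_id": trial.subject_id,
        "mode": trial.protocol.mode,
        "velocity": trial.protocol.velocity,
        "impedance": trial.protocol.impedance,
        "flexion_index": flexion_index,
    }
    return series
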