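"""Saccade and fixation detection with adaptive MAD thresholds.

Saccade onsets/offsets come from track-velocity threshold crossings; the
thresholds are set adaptively to 3x the (unscaled) median absolute deviation
of the noise, estimated in two passes so that the saccades themselves do not
inflate the noise estimate.  An acceleration criterion (same 3xMAD idiom)
gates onsets, and every candidate must move the eye: the mean gaze position in
a 20 ms window before onset must differ from the mean in a 20 ms window after
offset by more than 3x the pooled within-window position MAD.

Fixations are the inter-saccadic intervals.  Fixations whose duration exceeds
median + 3xMAD of the recording's fixation durations (typically blink-adjacent
artifacts) are flagged as duration outliers: excluded from duration statistics
but still counted toward epoch time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import UniformGazeSignal

log = logging.getLogger(__name__)

__all__ = [
    "SaccadeEvent",
    "FixationEvent",
    "DetectionConfig",
    "estimate_noise_thresholds",
    "detect_saccades",
    "classify_axis",
    "parse_fixations",
    "detect_events",
]


@dataclass
class SaccadeEvent:
    onset: float  # s
    offset: float  # s
    dx: float  # deg
    dy: float  # deg
    peak_velocity: float  # deg/s
    backwards: bool = False  # set by epoch segmentation per reading direction

    @property
    def duration_ms(self) -> float:
        return (self.offset - self.onset) * 1000.0

    @property
    def amplitude(self) -> float:
        return math.hypot(self.dx, self.dy)

    @property
    def direction(self) -> float:
        """atan2(dy, dx) in degrees, in (-180, 180]."""
        d = math.degrees(math.atan2(self.dy, self.dx))
        return 180.0 if d == -180.0 else d

    @property
    def axis(self) -> str:
        return classify_axis(self)


@dataclass
class FixationEvent:
    start: float  # s
    end: float  # s
    cx: float  # centroid, deg
    cy: float
    row: int | None = None  # filled by epoch segmentation
    duration_outlier: bool = False
    truncated: bool = False  # abuts a signal-loss gap: true duration unknown

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0


@dataclass(frozen=True)
class DetectionConfig:
    mad_multiplier: float = 3.0
    window_ms: float = 20.0  # pre/post verification and acceleration look-back
    min_duration_ms: float = 6.0
    merge_gap_ms: float = 20.0
    boundary_peak_fraction: float = 0.05  # onset/offset at this fraction of peak v
    min_displacement_deg: float = 0.2  # instrument spatial resolution floor
    fixation_outlier_multiplier: float = 3.0
    velocity_floor: float = 10.0  # deg/s, guards against degenerate thresholds
    velocity_ceiling: float = 100.0
    min_noise_samples: int = 500
    max_invalid_fraction: float = 0.10  # recordings lossier than this are rejected


def _mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation from the median."""
    return float(np.median(np.abs(x - np.median(x)))) if len(x) else 0.0


def estimate_noise_thresholds(
    sig: UniformGazeSignal, config: DetectionConfig | None = None
) -> tuple[float, float]:
    """Adaptive velocity/acceleration thresholds: 3x MAD of the noise.

    Two passes: a provisional threshold from the full |v| (|a|) series, then a
    final 3xMAD over only the sub-threshold ("noise") samples, so real
    saccades do not inflate the estimate.  The velocity threshold is clamped
    to [velocity_floor, velocity_ceiling].
    """
    config = config or DetectionConfig()
    if sig.v is None or sig.a is None:
        raise ValueError("signal has no kinematics; run preprocess first")
    m = sig.valid
    if m.sum() < sig.fs:  # need >= 1 s of valid signal
        raise ValueError("need at least 1 s of valid signal")

    def two_pass(series: np.ndarray) -> float:
        series = np.abs(series[m])
        thr0 = config.mad_multiplier * _mad(series)
        noise = series[series < thr0] if thr0 > 0 else series
        if len(noise) < config.min_noise_samples:
            log.warning("too few noise samples; single-pass MAD estimate used")
            return thr0
        return config.mad_multiplier * _mad(noise)

    v_thr = float(np.clip(two_pass(sig.v), config.velocity_floor, config.velocity_ceiling))
    a_thr = two_pass(sig.a)
    return v_thr, a_thr


def classify_axis(saccade: SaccadeEvent) -> str:
    """'horizontal' iff the direction lies strictly within 45 deg of the horizontal
    meridian (either side); everything else, including exactly 45 deg, is vertical."""
    if saccade.dx == 0.0 and saccade.dy == 0.0:
        raise ValueError("zero-displacement saccade cannot be classified")
    d = abs(saccade.direction)
    return "horizontal" if min(d, abs(180.0 - d)) < 45.0 else "vertical"


def _window_stats(
    sig: UniformGazeSignal, a: int, b: int
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Window mean position plus per-axis absolute deviations from the median."""
    x = sig.x[a:b]
    y = sig.y[a:b]
    devx = np.abs(x - np.median(x))
    devy = np.abs(y - np.median(y))
    return float(x.mean()), float(y.mean()), devx, devy


def detect_saccades(
    sig: UniformGazeSignal,
    config: DetectionConfig | None = None,
    thresholds: tuple[float, float] | None = None,
) -> list[SaccadeEvent]:
    """Threshold-based saccade detection on each valid segment.

    A candidate opens where track velocity crosses the velocity threshold
    upward with track acceleration having exceeded its threshold within the
    preceding 20 ms, and closes where velocity falls back below threshold.
    Candidates closer together than ``merge_gap_ms`` are merged (replacing the
    original procedure's manual inspection with a deterministic rule); then
    candidates shorter than the minimum duration or failing the pre/post
    position-displacement verification are dropped.
    """
    config = config or DetectionConfig()
    if thresholds is None:
        thresholds = estimate_noise_thresholds(sig, config)
    v_thr, a_thr = thresholds
    w = max(1, int(round(config.window_ms / 1000.0 * sig.fs)))
    events: list[SaccadeEvent] = []
    for s, e in sig.segments:
        v = sig.v[s:e]
        a = np.abs(sig.a[s:e])
        above = v > v_thr
        if not above.any():
            continue
        d = np.diff(above.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        stops = list(np.flatnonzero(d == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            stops.append(len(v))
        cands = []
        for i0, i1 in zip(starts, stops):
            # acceleration gate: |a| must exceed threshold within 20 ms before onset
            lo = max(0, i0 - w)
            if a[lo : i0 + 1].max(initial=0.0) <= a_thr:
                continue
            cands.append([i0, i1])
        # merge candidates separated by < merge_gap_ms
        merged: list[list[int]] = []
        gap = config.merge_gap_ms / 1000.0 * sig.fs
        for c in cands:
            if merged and c[0] - merged[-1][1] < gap:
                merged[-1][1] = c[1]
            else:
                merged.append(c)
        for i0, i1 in merged:
            # refine boundaries: the detection threshold is low (noise-scaled),
            # so its crossings sit in the filter-spread tails of the velocity
            # profile; place onset/offset where velocity leaves a small
            # fraction of the event's peak instead, walking inward from the
            # candidate edges (preserves merged extents)
            bt = max(v_thr, config.boundary_peak_fraction * v[i0:i1].max())
            while i0 < i1 - 1 and v[i0] < bt:
                i0 += 1
            while i1 > i0 + 1 and v[i1 - 1] < bt:
                i1 -= 1
            if (i1 - i0) / sig.fs * 1000.0 < config.min_duration_ms:
                continue
            # verification: pre/post 20 ms window means must differ by > 3x pooled MAD
            pre_a, pre_b = max(s, s + i0 - w), s + i0
            post_a, post_b = s + i1, min(e, s + i1 + w)
            if pre_b - pre_a < 2 or post_b - post_a < 2:
                continue
            mx0, my0, dx0, dy0 = _window_stats(sig, pre_a, pre_b)
            mx1, my1, dx1, dy1 = _window_stats(sig, post_a, post_b)
            # pooled within-window position MAD across both windows and axes
            pooled = math.hypot(
                float(np.median(np.concatenate([dx0, dx1]))),
                float(np.median(np.concatenate([dy0, dy1]))),
            )
            disp = math.hypot(mx1 - mx0, my1 - my0)
            if disp <= max(config.mad_multiplier * pooled, config.min_displacement_deg):
                continue
            events.append(
                SaccadeEvent(
                    onset=sig.t0 + (s + i0) / sig.fs,
                    offset=sig.t0 + (s + i1) / sig.fs,
                    dx=mx1 - mx0,
                    dy=my1 - my0,
                    peak_velocity=float(v[i0:i1].max()),
                )
            )
    return events


def parse_fixations(
    saccades: list[SaccadeEvent],
    sig: UniformGazeSignal,
    config: DetectionConfig | None = None,
) -> list[FixationEvent]:
    """Fixations as the inter-saccadic intervals of each valid segment.

    Includes the leading interval before the first saccade and the trailing
    interval after the last.  Fixations longer than median + 3xMAD of all
    fixation durations (single pass) are flagged ``duration_outlier``: they
    are excluded from duration statistics but their time still counts toward
    epoch durations, so time conservation stays exact.
    """
    config = config or DetectionConfig()
    fixations: list[FixationEvent] = []
    first_start = sig.segments[0][0] if sig.segments else 0
    last_end = sig.segments[-1][1] if sig.segments else 0
    for s, e in sig.segments:
        t_start = sig.t0 + s / sig.fs
        t_end = sig.t0 + e / sig.fs
        inside = [sc for sc in saccades if sc.onset >= t_start - 1e-9 and sc.offset <= t_end + 1e-9]
        bounds = [t_start] + [t for sc in inside for t in (sc.onset, sc.offset)] + [t_end]
        for a, b in zip(bounds[0::2], bounds[1::2]):
            if b - a <= 1e-9:
                continue
            ia, ib = sig.index_of(a), max(sig.index_of(a) + 1, sig.index_of(b))
            # a fixation cut by a signal-loss gap (blink) is a fragment: its
            # time is real but its duration is not a fixation duration
            trunc = (a == t_start and s != first_start) or (b == t_end and e != last_end)
            fixations.append(
                FixationEvent(
                    start=a,
                    end=b,
                    cx=float(np.mean(sig.x[ia:ib])),
                    cy=float(np.mean(sig.y[ia:ib])),
                    truncated=trunc,
                )
            )
    durations = np.array([f.duration_ms for f in fixations if not f.truncated])
    if len(durations) >= 3:
        med = np.median(durations)
        cut = med + config.fixation_outlier_multiplier * _mad(durations)
        for f in fixations:
            if not f.truncated and f.duration_ms > cut:
                f.duration_outlier = True
    return fixations


@dataclass
class EventSet:
    saccades: list[SaccadeEvent]
    fixations: list[FixationEvent]
    velocity_threshold: float
    acceleration_threshold: float


def detect_events(sig: UniformGazeSignal, config: DetectionConfig | None = None) -> EventSet:
    """Convenience wrapper: thresholds -> saccades -> fixations."""
    config = config or DetectionConfig()
    thr = estimate_noise_thresholds(sig, config)
    sacc = detect_saccades(sig, config, thr)
    fix = parse_fixations(sacc, sig, config)
    return EventSet(saccades=sacc, fixations=fix, velocity_threshold=thr[0], acceleration_threshold=thr[1])
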