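"""Gaze-signal preprocessing: irregular raw stream -> uniform filtered kinematics.

The chain is fixed: 13-point running median on the irregular sample sequence,
linear-interpolation resampling to 500 Hz, zero-phase 5th-order 40 Hz low-pass
Butterworth per contiguous valid segment, then 9-point noise-robust
differentiation for velocity and (of track velocity) acceleration.

Gaps in the raw stream longer than ``max_bridgeable_gap_ms`` (default 75 ms --
shorter than a blink) are never interpolated across; they split the recording
into valid segments that every later stage processes independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

log = logging.getLogger(__name__)

__all__ = [
    "NoDataError",
    "RawGazeStream",
    "UniformGazeSignal",
    "PreprocessConfig",
    "select_best_eye",
    "median_prefilter",
    "resample_uniform",
    "lowpass_zero_phase",
    "differentiate_nr",
    "kinematics",
    "preprocess",
]


class NoDataError(ValueError):
    """Raised when a stream has too few valid samples to process."""


@dataclass
class RawGazeStream:
    """Irregularly sampled monocular gaze angles.

    t is in seconds (strictly increasing), x/y in degrees (screen-centered
    axes, x rightward, y upward), ``valid`` flags tracked samples.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    eye: str = "right"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if len(self) else 0.0


@dataclass
class UniformGazeSignal:
    """Uniformly resampled gaze with derived kinematic channels.

    ``segments`` lists (start, stop) index pairs of contiguous valid runs;
    stop is exclusive.  Velocity is in deg/s, acceleration in deg/s^2;
    ``v`` is the track velocity ``sqrt(vx^2 + vy^2)`` (always >= 0).
    """

    t0: float
    fs: float
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    v: np.ndarray | None = None
    a: np.ndarray | None = None
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.x)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.x)) / self.fs

    def index_of(self, t: float) -> int:
        return int(round((t - self.t0) * self.fs))


@dataclass(frozen=True)
class PreprocessConfig:
    median_filter_length: int = 13
    resample_rate: float = 500.0
    butterworth_order: int = 5
    butterworth_cutoff: float = 40.0
    differentiator_length: int = 9
    max_bridgeable_gap_ms: float = 75.0

    def __post_init__(self) -> None:
        if self.median_filter_length % 2 == 0 or self.differentiator_length % 2 == 0:
            raise ValueError("filter lengths must be odd")
        if self.butterworth_cutoff >= self.resample_rate / 2:
            raise ValueError("cutoff must be below Nyquist")


def select_best_eye(left: RawGazeStream | None, right: RawGazeStream | None) -> RawGazeStream:
    """Return the stream with the larger fraction of valid samples (ties: right)."""
    lf = left.valid_fraction if left is not None and len(left) else -1.0
    rf = right.valid_fraction if right is not None and len(right) else -1.0
    if lf < 0 and rf < 0:
        raise NoDataError("both eye streams are empty")
    return left if lf > rf else right  # ties fall through to right


def _running_median(vals: np.ndarray, length: int) -> np.ndarray:
    """Index-wise running median with shrinking windows at the edges."""
    n = len(vals)
    if n == 0:
        return vals.copy()
    half = length // 2
    out = np.empty(n)
    if n >= length:
        out[half : n - half] = np.median(sliding_window_view(vals, length), axis=1)
    lim = min(half, n)
    for i in range(lim):
        out[i] = np.median(vals[: i + half + 1][: n])
    for i in range(max(n - half, lim), n):
        out[i] = np.median(vals[i - half :])
    if n < length:  # all edges
        for i in range(n):
            out[i] = np.median(vals[max(0, i - half) : i + half + 1])
    return out


def median_prefilter(stream: RawGazeStream, config: PreprocessConfig | None = None) -> RawGazeStream:
    """Running 13-sample median over the valid samples of x and y.

    Operates index-wise on the irregular sequence (at ~500 Hz a 13-sample
    window spans ~26 ms); timestamps and validity are untouched.
    """
    config = config or PreprocessConfig()
    if not len(stream):
        raise NoDataError("empty stream")
    x = stream.x.copy()
    y = stream.y.copy()
    m = stream.valid
    x[m] = _running_median(stream.x[m], config.median_filter_length)
    y[m] = _running_median(stream.y[m], config.median_filter_length)
    return replace(stream, x=x, y=y)


def resample_uniform(stream: RawGazeStream, config: PreprocessConfig | None = None) -> UniformGazeSignal:
    """Linear-interpolation resampling of the valid samples onto a 500 Hz grid.

    The grid spans [first, last] valid timestamp.  Grid samples falling inside
    a raw-data gap longer than ``max_bridgeable_gap_ms`` are marked invalid
    rather than interpolated.
    """
    config = config or PreprocessConfig()
    m = stream.valid
    if m.sum() < 2:
        raise NoDataError("fewer than 2 valid samples")
    tv = stream.t[m]
    fs = config.resample_rate
    n = int(np.floor((tv[-1] - tv[0]) * fs)) + 1
    tg = tv[0] + np.arange(n) / fs
    x = np.interp(tg, tv, stream.x[m])
    y = np.interp(tg, tv, stream.y[m])
    # mark grid samples inside over-long raw gaps invalid
    gaps = np.diff(tv)
    valid = np.ones(n, dtype=bool)
    max_gap = config.max_bridgeable_gap_ms / 1000.0
    for j in np.nonzero(gaps > max_gap)[0]:
        valid[(tg > tv[j]) & (tg < tv[j + 1])] = False
    sig = UniformGazeSignal(t0=float(tv[0]), fs=fs, x=x, y=y, valid=valid)
    sig.segments = _contiguous_segments(valid)
    return sig


def _contiguous_segments(valid: np.ndarray) -> list[tuple[int, int]]:
    if not len(valid):
        return []
    edges = np.flatnonzero(np.diff(valid.astype(np.int8)))
    starts = [0] if valid[0] else []
    stops: list[int] = []
    for e in edges:
        if valid[e]:
            stops.append(e + 1)
        else:
            starts.append(e + 1)
    if valid[-1]:
        stops.append(len(valid))
    return list(zip(starts, stops))


def lowpass_zero_phase(sig: UniformGazeSignal, config: PreprocessConfig | None = None) -> UniformGazeSignal:
    """Forward-backward Butterworth low-pass on each valid segment (zero phase).

    Two passes square the magnitude response, so the cutoff sits at -6 dB
    (amplitude ~1/2).  Segments shorter than 3x the filter order are left
    unfiltered with a warning.
    """
    config = config or PreprocessConfig()
    sos = sps.butter(
        config.butterworth_order, config.butterworth_cutoff, fs=sig.fs, output="sos"
    )
    x = sig.x.copy()
    y = sig.y.copy()
    min_len = 3 * config.butterworth_order
    for a, b in sig.segments:
        if b - a < min_len:
            log.warning("segment [%d, %d) too short to filter; skipped", a, b)
            continue
        padlen = min(50, b - a - 1)
        x[a:b] = sps.sosfiltfilt(sos, sig.x[a:b], padlen=padlen)
        y[a:b] = sps.sosfiltfilt(sos, sig.y[a:b], padlen=padlen)
    return replace(sig, x=x, y=y)


# Smooth noise-robust differentiator, length 9 (antisymmetric taps, exact for
# polynomials through degree 3 on interior samples): f' ~ sum_k c_k (f_k - f_-k)
# with c = (14, 14, 6, 1)/128 h.
_NR9_C = np.array([14.0, 14.0, 6.0, 1.0]) / 128.0


def differentiate_nr(values: np.ndarray, fs: float, config: PreprocessConfig | None = None) -> np.ndarray:
    """9-point smooth noise-robust first derivative of a uniformly sampled channel.

    Interior samples use the antisymmetric 9-tap kernel; the 4 samples at each
    end fall back to one-sided/central 2-point differences (np.gradient).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return np.zeros(n)
    out = np.gradient(values) * fs
    if n < 9:
        log.warning("segment shorter than differentiator; edge rule used throughout")
        return out
    interior = np.zeros(n - 8)
    for k, c in enumerate(_NR9_C, start=1):
        interior += c * (values[4 + k : n - 4 + k] - values[4 - k : n - 4 - k])
    out[4 : n - 4] = interior * fs
    return out


def kinematics(sig: UniformGazeSignal, config: PreprocessConfig | None = None) -> UniformGazeSignal:
    """Fill vx, vy, track velocity and track acceleration per valid segment.

    Track velocity is the Euclidean norm of the horizontal and vertical
    velocities; acceleration is the time derivative of track velocity.
    """
    config = config or PreprocessConfig()
    n = len(sig)
    vx = np.zeros(n)
    vy = np.zeros(n)
    v = np.zeros(n)
    a = np.zeros(n)
    for s, e in sig.segments:
        vx[s:e] = differentiate_nr(sig.x[s:e], sig.fs, config)
        vy[s:e] = differentiate_nr(sig.y[s:e], sig.fs, config)
        v[s:e] = np.hypot(vx[s:e], vy[s:e])
        a[s:e] = differentiate_nr(v[s:e], sig.fs, config)
    return replace(sig, vx=vx, vy=vy, v=v, a=a)


def preprocess(stream: RawGazeStream, config: PreprocessConfig | None = None) -> UniformGazeSignal:
    """Full chain: median prefilter -> resample -> zero-phase low-pass -> kinematics."""
    config = config or PreprocessConfig()
    filtered = median_prefilter(stream, config)
    sig = resample_uniform(filtered, config)
    sig = lowpass_zero_phase(sig, config)
    return kinematics(sig, config)
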