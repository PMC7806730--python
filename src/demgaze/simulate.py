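"""Synthetic DEM gaze recordings and reaction-time tables with full ground truth.

The generator emulates the measurement situation of the digitized DEM in
children: a reader fixates each number in reading order, with fixation
durations governed by a latent per-subject processing speed ``s`` that
decreases with age; saccades follow the main sequence (duration = intercept +
slope x amplitude) with raised-cosine velocity profiles; return sweeps split
into 1-3 hops with intermittent fixations, more hops for slower readers; and
the measurement layer adds white sample noise (< 0.05 deg), a slow
sinusoidal accuracy drift (up to ~0.7 deg), blink dropouts, and merged
irregular sampling from two asynchronous ~250 Hz clocks averaging ~500 Hz.

Blinks are placed inside sufficiently long fixations: blinking is suppressed
during saccades, and the original analysis discards blink-corrupted events
anyway, so the generator does not model mid-saccade tracking loss.

Everything the pipeline later estimates is also emitted as ground truth, so
detection, segmentation and scoring can be validated event by event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import DEMLayout, build_layout
from .preprocess import RawGazeStream

__all__ = [
    "ReaderProfile",
    "NoiseModel",
    "GroundTruth",
    "GTSaccade",
    "GTFixation",
    "GTEpoch",
    "SubjectRecord",
    "CohortConfig",
    "simulate_trial",
    "simulate_cohort",
    "profile_for_age",
    "ERRORLESS_PROFILE",
]


@dataclass(frozen=True)
class ReaderProfile:
    """Behavioral parameters of one simulated reader."""

    age: float = 9.0
    s: float = 450.0  # latent processing speed: mean identification fixation, ms
    fixation_sigma: float = 0.2  # lognormal shape of fixation durations
    refixation_rate: float = 0.0  # expected extra fixations per number
    regression_prob: float = 0.0  # chance of a backwards glance per number
    sweep_hops_mean: float = 1.0  # mean of the 1-3 hop count distribution
    sweep_fixation_ms: float = 160.0  # median intermittent sweep fixation
    main_sequence_intercept_ms: float = 21.0
    main_sequence_slope_ms_per_deg: float = 2.2
    landing_noise_sd_deg: float = 0.15
    skip_rows: tuple[int, ...] = ()  # lines skipped entirely (omission errors)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement layer: sensor noise, drift, blinks, asynchronous clocks."""

    sample_noise_sd_deg: float = 0.03  # must stay < 0.05
    drift_amplitude_deg: float = 0.7  # peak radial slow drift (accuracy)
    drift_period_s: float = 35.0
    blink_rate_per_min: float = 4.0
    blink_duration_ms: tuple[float, float] = (100.0, 300.0)
    clock_rates_hz: tuple[float, float] = (250.0, 250.0)
    clock_jitter_ms: float = 0.3

    def __post_init__(self) -> None:
        if self.sample_noise_sd_deg >= 0.05:
            raise ValueError("sample-to-sample noise must be < 0.05 deg")


NOISELESS = NoiseModel(
    sample_noise_sd_deg=1e-9,
    drift_amplitude_deg=0.0,
    blink_rate_per_min=0.0,
)

# errorless reading: no refixations/regressions, single-hop sweeps
ERRORLESS_PROFILE = ReaderProfile()


@dataclass
class GTSaccade:
    onset: float
    offset: float
    x0: float
    y0: float
    x1: float
    y1: float
    kind: str = "forward"  # forward | sweep_hop | refixation | regression

    @property
    def amplitude(self) -> float:
        return math.hypot(self.x1 - self.x0, self.y1 - self.y0)


@dataclass
class GTFixation:
    start: float
    end: float
    x: float
    y: float
    target: int | None  # index into layout positions; None for sweep stops
    row: int | None


@dataclass
class GTEpoch:
    kind: str
    row: int
    start: float
    end: float


@dataclass
class GroundTruth:
    saccades: list[GTSaccade]
    fixations: list[GTFixation]
    epochs: list[GTEpoch]
    subtest: str
    subtest_time: float  # last fixation end - first fixation start, pre-noise
    latent_s: float


def _draw_hops(rng: np.random.Generator, mean_hops: float) -> int:
    """Hop count in {1, 2, 3}: 1 + Binomial(2, p) with p matching the mean."""
    p = float(np.clip((mean_hops - 1.0) / 2.0, 0.0, 1.0))
    return 1 + int(rng.binomial(2, p))


def _lognormal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """Lognormal draw parameterized by its mean (not by exp(mu))."""
    mu = math.log(mean) - 0.5 * sigma**2
    return float(rng.lognormal(mu, sigma))


def _scanpath(
    profile: ReaderProfile, layout: DEMLayout, rng: np.random.Generator
) -> tuple[list[tuple], GroundTruth]:
    """Build the ideal (noise-free) piecewise gaze trajectory.

    Returns a list of timeline pieces ('fix', t0, t1, x, y) and
    ('sacc', t0, t1, x0, y0, x1, y1), plus the ground truth.
    """
    pos = layout.positions_deg()
    n_rows = layout.n_rows
    row_of = np.empty(len(pos), dtype=int)
    for r in range(n_rows):
        row_of[layout.row_indices(r)] = r
    ms_i = profile.main_sequence_intercept_ms / 1000.0
    ms_s = profile.main_sequence_slope_ms_per_deg / 1000.0

    pieces: list[tuple] = []
    gts: list[GTSaccade] = []
    gtf: list[GTFixation] = []
    gte: list[GTEpoch] = []
    t = 0.0
    land = rng.normal(0.0, profile.landing_noise_sd_deg, size=(len(pos), 2))
    first = next(i for i in range(len(pos)) if row_of[i] not in profile.skip_rows)
    cur = pos[first] + land[first]

    def add_fix(dur_s: float, target: int | None, row: int | None) -> None:
        nonlocal t
        pieces.append(("fix", t, t + dur_s, cur[0], cur[1]))
        gtf.append(GTFixation(t, t + dur_s, cur[0], cur[1], target, row))
        t += dur_s

    def add_sacc(to_xy: np.ndarray, kind: str) -> None:
        nonlocal t, cur
        amp = float(np.hypot(*(to_xy - cur)))
        dur = ms_i + ms_s * amp
        pieces.append(("sacc", t, t + dur, cur[0], cur[1], to_xy[0], to_xy[1]))
        gts.append(GTSaccade(t, t + dur, cur[0], cur[1], to_xy[0], to_xy[1], kind))
        t += dur
        cur = to_xy.copy()

    ident_start = t
    order = [i for i in range(len(pos)) if row_of[i] not in profile.skip_rows]
    for j, k in enumerate(order):
        dur = _lognormal(rng, profile.s / 1000.0, profile.fixation_sigma)
        add_fix(dur, k, int(row_of[k]))
        # optional refixation on the same number
        if rng.random() < profile.refixation_rate:
            step = rng.normal(0.0, 0.4, size=2)
            add_sacc(cur + step, "refixation")
            add_fix(_lognormal(rng, profile.s / 1000.0, profile.fixation_sigma), k, int(row_of[k]))
        if j + 1 >= len(order):
            break
        nxt = order[j + 1]
        # optional regression to the previous number before moving on
        if j >= 1 and rng.random() < profile.regression_prob:
            prev = order[j - 1]
            add_sacc(pos[prev] + land[prev] + rng.normal(0, 0.1, 2), "regression")
            add_fix(_lognormal(rng, profile.s / 1000.0, profile.fixation_sigma), prev, int(row_of[prev]))
            add_sacc(pos[k] + land[k] + rng.normal(0, 0.1, 2), "forward")
            add_fix(_lognormal(rng, profile.s / 1000.0, profile.fixation_sigma), k, int(row_of[k]))
        if row_of[nxt] != row_of[k]:
            # return sweep, possibly in several hops
            gte.append(GTEpoch("identification", int(row_of[k]), ident_start, t))
            sweep_start = t
            hops = _draw_hops(rng, profile.sweep_hops_mean)
            target = pos[nxt] + land[nxt]
            start_xy = cur.copy()
            # return sweeps undershoot: one large initial saccade covering
            # most of the way, then small corrective hops
            fracs = np.ones(hops)
            if hops > 1:
                f1 = rng.uniform(0.65, 0.85)
                rest = np.sort(rng.uniform(f1, 1.0, size=hops - 2)) if hops > 2 else np.array([])
                fracs = np.concatenate([[f1], rest, [1.0]])
            for h, frac in enumerate(fracs, start=1):
                way = start_xy + frac * (target - start_xy)
                if h < hops:
                    way = way + rng.normal(0.0, 0.2, size=2)
                add_sacc(way, "sweep_hop")
                if h < hops:
                    add_fix(_lognormal(rng, profile.sweep_fixation_ms / 1000.0, 0.25), None, None)
            gte.append(GTEpoch("return_sweep", int(row_of[k]), sweep_start, t))
            ident_start = t
        else:
            add_sacc(pos[nxt] + land[nxt], "forward")
    gte.append(GTEpoch("identification", int(row_of[order[-1]]), ident_start, t))
    gt = GroundTruth(
        saccades=gts,
        fixations=gtf,
        epochs=gte,
        subtest=layout.subtest,
        subtest_time=gtf[-1].end - gtf[0].start,
        latent_s=profile.s,
    )
    return pieces, gt


def _sample_pieces(pieces: list[tuple], ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the piecewise trajectory at the (sorted) sample times."""
    starts = np.array([p[1] for p in pieces])
    bounds = np.searchsorted(ts, starts, side="left")
    bounds = np.append(bounds, len(ts))
    x = np.empty(len(ts))
    y = np.empty(len(ts))
    for i, p in enumerate(pieces):
        a, b = bounds[i], bounds[i + 1]
        if a >= b:
            continue
        if p[0] == "fix":
            x[a:b], y[a:b] = p[3], p[4]
        else:
            _, t0, t1, x0, y0, x1, y1 = p
            u = np.clip((ts[a:b] - t0) / (t1 - t0), 0.0, 1.0)
            # raised-cosine velocity: displacement fraction u - sin(2*pi*u)/(2*pi)
            f = u - np.sin(2 * np.pi * u) / (2 * np.pi)
            x[a:b] = x0 + f * (x1 - x0)
            y[a:b] = y0 + f * (y1 - y0)
    # samples before the first piece (none: pieces start at 0) and after the
    # last are clamped by the final piece's u-clip above
    return x, y


def _clock_times(t_end: float, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    times = []
    for rate in noise.clock_rates_hz:
        n = int(t_end * rate) + 2
        base = rng.uniform(0, 1.0 / rate) + np.arange(n) / rate
        base = base + rng.normal(0.0, noise.clock_jitter_ms / 1000.0, size=n)
        times.append(base)
    ts = np.sort(np.concatenate(times))
    ts = ts[(ts >= 0) & (ts <= t_end)]
    # enforce strict monotonicity (double samples from clock collisions)
    keep = np.concatenate([[True], np.diff(ts) > 1e-6])
    return ts[keep]


def _blink_windows(
    gt: GroundTruth, noise: NoiseModel, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Place blinks inside fixations long enough to contain them."""
    t_end = gt.fixations[-1].end
    n_blinks = rng.poisson(noise.blink_rate_per_min * t_end / 60.0)
    lo, hi = noise.blink_duration_ms
    windows: list[tuple[float, float]] = []
    if n_blinks == 0:
        return windows
    candidates = [f for f in gt.fixations if (f.end - f.start) * 1000.0 > hi + 40.0]
    if not candidates:
        return windows
    for f in rng.choice(len(candidates), size=min(n_blinks, len(candidates)), replace=False):
        fx = candidates[int(f)]
        dur = rng.uniform(lo, hi) / 1000.0
        start = rng.uniform(fx.start + 0.01, fx.end - dur - 0.01)
        windows.append((start, start + dur))
    return windows


def simulate_trial(
    profile: ReaderProfile,
    layout: DEMLayout,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[RawGazeStream, GroundTruth]:
    """Simulate one DEM subtest recording; identical seed -> identical output."""
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pieces, gt = _scanpath(profile, layout, rng)
    t_end = pieces[-1][2]
    ts = _clock_times(t_end, noise, rng)
    x, y = _sample_pieces(pieces, ts)
    # slow sinusoidal accuracy drift, independent phase per axis
    amp = noise.drift_amplitude_deg / math.sqrt(2.0)
    ph = rng.uniform(0, 2 * math.pi, size=2)
    w = 2 * math.pi / noise.drift_period_s
    x = x + amp * np.sin(w * ts + ph[0])
    y = y + amp * np.sin(w * ts + ph[1])
    x = x + rng.normal(0.0, noise.sample_noise_sd_deg, size=len(ts))
    y = y + rng.normal(0.0, noise.sample_noise_sd_deg, size=len(ts))
    valid = np.ones(len(ts), dtype=bool)
    for b0, b1 in _blink_windows(gt, noise, rng):
        m = (ts >= b0) & (ts <= b1)
        valid[m] = False
        x[m] = np.nan
        y[m] = np.nan
    return RawGazeStream(t=ts, x=x, y=y, valid=valid, eye="right"), gt


def profile_for_age(
    age: float,
    rng: np.random.Generator,
    s_at_9: float = 480.0,
    log_slope_per_year: float = -0.055,
    log_noise_sd: float = 0.12,
) -> ReaderProfile:
    """Draw a reader profile with the latent speed log-linearly linked to age.

    Slower readers (larger s) get more return-sweep hops, more refixations and
    more regressions, so oculomotor counts co-vary with completion time the
    way they do in developing readers.
    """
    s = s_at_9 * math.exp(log_slope_per_year * (age - 9.0) + rng.normal(0.0, log_noise_sd))
    skill = float(np.clip((s - 380.0) / 260.0, 0.0, 1.0))  # 0 fast .. 1 slow
    return ReaderProfile(
        age=age,
        s=s,
        refixation_rate=0.10 * skill,
        regression_prob=0.05 * skill,
        sweep_hops_mean=1.0 + 1.6 * skill,
    )


@dataclass
class SubjectRecord:
    subject: int
    age: float
    profile: ReaderProfile
    streams: dict[str, RawGazeStream]
    truths: dict[str, GroundTruth]
    rt_trials: "object"  # pandas DataFrame: subject, task, size, rt


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the simulated cohort.

    Defaults mirror the eye-tracked subsample: 36 children aged 6-12, with
    speed-acuity reaction time positively coupled to the latent processing
    speed (gamma, in s of RT per s of fixation duration) plus trial noise.
    """

    n_subjects: int = 36
    age_range: tuple[float, float] = (6.0, 12.0)
    gamma: float = 1.0  # RT coupling to latent s (dimensionless, s per s)
    rt_base_s: float = 0.25
    rt_subject_sd: float = 0.04
    rt_trial_sd: float = 0.08
    n_sa_trials: int = 10
    n_detection_trials: int = 20
    subtests: tuple[str, ...] = ("A", "B", "C")


def _rt_trials(
    subject: int, s_ms: float, cfg: CohortConfig, rng: np.random.Generator
) -> "object":
    import pandas as pd

    rows = []
    s_sec = s_ms / 1000.0
    base = {
        "speed-acuity": cfg.rt_base_s + cfg.gamma * s_sec,
        "visual detection": 0.18 + 0.35 * cfg.gamma * s_sec,
        "auditory detection": 0.16 + 0.35 * cfg.gamma * s_sec,
    }
    subj_shift = rng.normal(0.0, cfg.rt_subject_sd)
    for task, n in (
        ("speed-acuity", cfg.n_sa_trials),
        ("visual detection", cfg.n_detection_trials),
        ("auditory detection", cfg.n_detection_trials),
    ):
        for _ in range(n):
            u = rng.random()
            if u < 0.02:  # attentional lapse
                rt = rng.uniform(2.0, 4.0)
            elif u < 0.03:  # anticipation
                rt = rng.uniform(0.0, 0.09)
            else:
                rt = base[task] + subj_shift + rng.normal(0.0, cfg.rt_trial_sd)
                rt = max(rt, 0.11)
            rows.append(
                {"subject": subject, "task": task, "size": 0.68 if task == "speed-acuity" else None, "rt": rt}
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: CohortConfig | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Simulate a cohort: per subject, gaze per subtest plus RT trial tables."""
    config = config or CohortConfig()
    noise = noise or NoiseModel()
    root = np.random.default_rng(seed)
    layouts = {st: build_layout(st) for st in config.subtests}
    records: list[SubjectRecord] = []
    ages = np.sort(root.uniform(*config.age_range, size=config.n_subjects))
    for i, age in enumerate(ages):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        profile = profile_for_age(float(age), rng)
        streams: dict[str, RawGazeStream] = {}
        truths: dict[str, GroundTruth] = {}
        for st in config.subtests:
            stream, gt = simulate_trial(profile, layouts[st], noise, rng)
            streams[st] = stream
            truths[st] = gt
        rt = _rt_trials(i, profile.s, config, rng)
        records.append(SubjectRecord(i, float(age), profile, streams, truths, rt))
    return records
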