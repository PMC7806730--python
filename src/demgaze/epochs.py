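"""Epoch segmentation of a DEM recording: number identification vs. return sweeps.

During the horizontal subtest (C) the gaze reads 16 rows left to right; after
each row it sweeps back to the start of the next row, often in several hops
with intermittent fixations.  An identification epoch runs from the moment the
gaze arrives at the beginning of a line until it leaves the line's end; a
return-sweep epoch runs from the onset of the saccade that starts the sweep to
the start of the first fixation at the beginning of another line, intermittent
fixations included.  The vertical subtests (A/B) have one sweep each -- from
the bottom of column 1 to the top of column 2.

The verbal definitions are quantified by three configurable thresholds
(:class:`SegmentationConfig`); epochs are contiguous, non-overlapping and tile
the recording between the first and the last number fixation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import FixationEvent, SaccadeEvent
from .geometry import DEMLayout, mm_to_deg

log = logging.getLogger(__name__)

__all__ = [
    "Epoch",
    "SegmentationConfig",
    "SegmentationError",
    "assign_rows",
    "segment_epochs",
    "epoch_metrics",
]


class SegmentationError(ValueError):
    pass


@dataclass
class Epoch:
    kind: str  # "identification" | "return_sweep"
    subtest: str
    row: int  # origin row (sweeps) / row read (identification)
    start: float
    end: float
    degenerate: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentationConfig:
    # vertical distance within which a fixation is attributed to a row; default
    # half the inter-row spacing (in deg), resolved per layout when None
    row_tolerance_deg: float | None = None
    line_start_tolerance_deg: float = 2.0
    sweep_trigger_fraction: float = 0.5  # of the row extent


def _row_tolerance(layout: DEMLayout, config: SegmentationConfig) -> float:
    if config.row_tolerance_deg is not None:
        return config.row_tolerance_deg
    return mm_to_deg(14.6, layout.viewing_distance_mm) / 2.0


def assign_rows(
    fixations: list[FixationEvent], layout: DEMLayout, config: SegmentationConfig | None = None
) -> list[FixationEvent]:
    """Label each fixation with the nearest line (C row / A-B column) center.

    For subtest C the assignment is by vertical position against the 16 row
    centers; for A/B by horizontal position against the two column centers.
    Fixations farther than the tolerance from every center stay unlabeled.
    Mutates and returns the input fixations.
    """
    config = config or SegmentationConfig()
    d = layout.viewing_distance_mm
    if layout.subtest == "C":
        centers = layout.row_centers_y_deg()
        tol = _row_tolerance(layout, config)
        for f in fixations:
            dist = np.abs(centers - f.cy)
            k = int(np.argmin(dist))
            f.row = k if dist[k] <= tol else None
    else:
        col_x = np.degrees(
            np.arctan2(
                [layout.positions_mm[0, 0], layout.positions_mm[layout.row_indices(1)[0], 0]], d
            )
        )
        tol = mm_to_deg(layout.row_extent_mm, d) / 2.0
        for f in fixations:
            dist = np.abs(col_x - f.cx)
            k = int(np.argmin(dist))
            f.row = k if dist[k] <= tol else None
    return fixations


def _line_geometry(layout: DEMLayout) -> tuple[np.ndarray, np.ndarray, float]:
    """Per line: start coordinate, end coordinate (deg, along reading axis) and extent."""
    pos = layout.positions_deg()
    starts, ends = [], []
    for r in range(layout.n_rows):
        idx = layout.row_indices(r)
        if layout.subtest == "C":
            starts.append(pos[idx[0], 0])  # leftmost x
            ends.append(pos[idx[-1], 0])  # rightmost x
        else:
            starts.append(pos[idx[0], 1])  # top y
            ends.append(pos[idx[-1], 1])  # bottom y
    extent = mm_to_deg(layout.row_extent_mm, layout.viewing_distance_mm)
    return np.asarray(starts), np.asarray(ends), extent


def segment_epochs(
    saccades: list[SaccadeEvent],
    fixations: list[FixationEvent],
    layout: DEMLayout,
    config: SegmentationConfig | None = None,
) -> list[Epoch]:
    """Split a recording into identification and return-sweep epochs.

    A sweep starts at the onset of the first sufficiently large
    against-reading-direction saccade (|displacement along the reading axis|
    >= ``sweep_trigger_fraction`` x line extent for C; for A/B the trigger is
    the rightward column jump) occurring after the gaze has entered the final
    position region of its current line, and ends at the start of the first
    fixation within the line-start tolerance of a different line's beginning.
    Saccades straddling a boundary belong to the sweep.
    """
    config = config or SegmentationConfig()
    labeled = [f for f in fixations if f.row is not None]
    if not labeled:
        raise SegmentationError("no fixation could be assigned to a line")
    starts, ends, extent = _line_geometry(layout)
    tol = config.line_start_tolerance_deg
    trigger = config.sweep_trigger_fraction * extent
    horizontal = layout.subtest == "C"
    # every line starts (and ends) at the same coordinate along the reading
    # axis, so arrival/departure regions are shared across lines; the control
    # flow below therefore never depends on possibly drift-corrupted row
    # labels, which are used for bookkeeping only.
    start_coord = float(starts[0])
    end_coord = float(ends[0])
    end_region = max(tol, 0.35 * extent)

    def coord(f: FixationEvent) -> float:
        return f.cx if horizontal else f.cy

    def near_line_end(f: FixationEvent) -> bool:
        if horizontal:  # reading rightward: end region is the right edge
            return coord(f) >= end_coord - end_region
        return coord(f) <= end_coord + end_region  # reading downward

    def near_line_start(f: FixationEvent) -> bool:
        return abs(coord(f) - start_coord) <= tol

    def is_sweep_step(s: SaccadeEvent) -> bool:
        # a sweep moves against the reading direction: leftward for C,
        # rightward column jump for A/B (reading axis is vertical there)
        return (s.dx <= -trigger) if horizontal else (s.dx >= trigger)

    def row_of(f: FixationEvent) -> int:
        return f.row if f.row is not None else -1

    t_first = labeled[0].start
    t_last = labeled[-1].end
    current_row = labeled[0].row
    epochs: list[Epoch] = []
    ident_start = t_first
    fixs = sorted(fixations, key=lambda f: f.start)
    saccs = sorted(saccades, key=lambda s: s.onset)
    guard = 0
    while True:
        # first trigger saccade after the gaze has entered the end region of
        # the line it is currently reading
        sweep = None
        for s in saccs:
            if s.onset < ident_start or s.onset >= t_last:
                continue
            if not is_sweep_step(s):
                continue
            if any(
                near_line_end(f) and ident_start - 1e-9 <= f.start and f.end <= s.onset + 1e-9
                for f in fixs
            ):
                sweep = s
                break
        if sweep is None:
            break
        landing = next(
            (f for f in fixs if f.start >= sweep.onset - 1e-9 and near_line_start(f)), None
        )
        if landing is None:
            log.warning(
                "sweep from row %s never lands; remaining time kept as identification",
                current_row,
            )
            break
        epochs.append(Epoch("identification", layout.subtest, current_row, ident_start, sweep.onset))
        epochs.append(Epoch("return_sweep", layout.subtest, current_row, sweep.onset, landing.start))
        ident_start = landing.start
        current_row = row_of(landing)
        guard += 1
        if guard > 4 * layout.n_rows:
            raise SegmentationError("segmentation did not converge")
    if t_last > ident_start:
        epochs.append(Epoch("identification", layout.subtest, current_row, ident_start, t_last))
    return epochs


def _col_bottom_y(layout: DEMLayout) -> float:
    idx = layout.row_indices(0)
    return float(
        np.degrees(np.arctan2(layout.positions_mm[idx[-1], 1], layout.viewing_distance_mm))
    )


def _col_span(layout: DEMLayout) -> float:
    idx = layout.row_indices(0)
    span_mm = layout.positions_mm[idx[0], 1] - layout.positions_mm[idx[-1], 1]
    return mm_to_deg(float(span_mm), layout.viewing_distance_mm)


@dataclass
class EpochMetrics:
    """Per-epoch-kind oculomotor summary of one recording."""

    subtest: str
    total_time: dict[str, float] = field(default_factory=dict)
    fixation_time: dict[str, float] = field(default_factory=dict)
    saccade_time: dict[str, float] = field(default_factory=dict)
    saccade_count: dict[str, int] = field(default_factory=dict)
    fixation_count: dict[str, int] = field(default_factory=dict)
    median_saccade_amplitude: dict[str, float] = field(default_factory=dict)
    median_fixation_duration: dict[str, float] = field(default_factory=dict)
    backwards_count: int = 0
    orthogonal_count: int = 0


def epoch_metrics(
    epochs: list[Epoch],
    saccades: list[SaccadeEvent],
    fixations: list[FixationEvent],
) -> EpochMetrics:
    """Aggregate oculomotor metrics per epoch kind.

    Saccades straddling an epoch boundary are attributed to the sweep (the
    sweep is defined by its initiating saccade, so a saccade whose onset falls
    in the epoch belongs to it).  Backwards saccades are horizontal-class
    leftward saccades inside C identification epochs (vertical-class upward
    for A/B); orthogonal saccades are the perpendicular class inside
    identification epochs.
    """
    if not epochs:
        raise SegmentationError("no epochs to summarize")
    subtest = epochs[0].subtest
    m = EpochMetrics(subtest=subtest)
    horizontal = subtest == "C"
    for kind in ("identification", "return_sweep"):
        eps = [e for e in epochs if e.kind == kind]
        sacc = [s for e in eps for s in saccades if e.start - 1e-9 <= s.onset < e.end - 1e-9]
        fix = [f for e in eps for f in fixations if e.start - 1e-9 <= f.start < e.end - 1e-9]
        m.total_time[kind] = sum(e.duration for e in eps)
        m.saccade_time[kind] = sum(s.offset - s.onset for s in sacc)
        m.fixation_time[kind] = sum(f.end - f.start for f in fix)
        m.saccade_count[kind] = len(sacc)
        m.fixation_count[kind] = len(fix)
        amps = [s.amplitude for s in sacc]
        durs = [f.duration_ms for f in fix if not (f.duration_outlier or f.truncated)]
        m.median_saccade_amplitude[kind] = float(np.median(amps)) if amps else float("nan")
        m.median_fixation_duration[kind] = float(np.median(durs)) if durs else float("nan")
        if kind == "identification":
            for s in sacc:
                ax = s.axis
                if horizontal:
                    if ax == "horizontal" and s.dx < 0:
                        s.backwards = True
                        m.backwards_count += 1
                    elif ax == "vertical":
                        m.orthogonal_count += 1
                else:
                    if ax == "vertical" and s.dy > 0:
                        s.backwards = True
                        m.backwards_count += 1
                    elif ax == "horizontal":
                        m.orthogonal_count += 1
    return m
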