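"""Stimulus geometry of the digital Developmental Eye Movement (DEM) test.

The DEM consists of two vertical subtests (A and B: two columns of 20 numbers
each) and one horizontal subtest (C: 16 rows of 5 numbers).  This module
encodes the printed layout of the digitized test -- number positions in mm on
the screen, with the origin at screen center, x positive rightward and
y positive upward -- together with the photometric/angular conversions
(visual angle, logMAR, Michelson contrast) the analysis and the simulator
depend on.

All angular gaze coordinates elsewhere in the package use the same axes,
expressed in degrees of visual angle at the nominal viewing distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "LayoutValidationError",
    "DEMLayout",
    "LayoutConfig",
    "mm_to_deg",
    "logmar_of_optotype",
    "michelson_contrast",
    "build_layout",
    "layout_to_tsv",
    "layout_from_tsv",
]

# Printed layout constants (mm)
VERTICAL_SPACING_MM = 14.6
COLUMN_GAP_AB_MM = 162.5
ROW_EXTENT_C_MM = 191.8
WITHIN_ROW_SPACING_RANGE_MM = (19.2, 57.5)
SYMBOL_HEIGHT_MM = 4.9
DEFAULT_VIEWING_DISTANCE_MM = 650.0

N_ROWS_C = 16
N_COLS_C = 5
N_PER_COLUMN_AB = 20


class InvalidGeometryError(ValueError):
    """Raised for non-physical geometric inputs (e.g. distance <= 0)."""


class LayoutValidationError(ValueError):
    """Raised when a layout violates the printed spacing constraints."""


def mm_to_deg(extent_mm: float, distance_mm: float) -> float:
    """Visual angle in degrees subtended by ``extent_mm`` at ``distance_mm``.

    Uses the exact symmetric formula ``2*atan(extent / (2*distance))``; monotone
    increasing in the extent.
    """
    if distance_mm <= 0:
        raise InvalidGeometryError(f"viewing distance must be > 0, got {distance_mm}")
    if extent_mm < 0:
        raise InvalidGeometryError(f"extent must be >= 0, got {extent_mm}")
    return math.degrees(2.0 * math.atan2(extent_mm, 2.0 * distance_mm))


def logmar_of_optotype(height_mm: float, distance_mm: float) -> float:
    """logMAR of an optotype of total height ``height_mm`` viewed at ``distance_mm``.

    The minimum angle of resolution is taken, by optotype convention, as 1/5 of
    the symbol height expressed in arcminutes; logMAR is its base-10 log.
    A symbol whose height subtends exactly 5 arcmin therefore scores 0.0.
    """
    if height_mm <= 0 or distance_mm <= 0:
        raise InvalidGeometryError("optotype height and distance must be > 0")
    arcmin = mm_to_deg(height_mm, distance_mm) * 60.0
    return math.log10(arcmin / 5.0)


def michelson_contrast(lum_max: float, lum_min: float) -> float:
    """Michelson contrast ``(Lmax - Lmin)/(Lmax + Lmin)`` as a fraction in [0, 1]."""
    if lum_min > lum_max:
        raise ValueError(
            f"lum_max ({lum_max}) must be >= lum_min ({lum_min}); arguments swapped?"
        )
    if lum_min < 0 or lum_max <= 0:
        raise ValueError("luminances must be non-negative with lum_max > 0")
    return (lum_max - lum_min) / (lum_max + lum_min)


@dataclass(frozen=True)
class LayoutConfig:
    """Configuration for :func:`build_layout`.

    The within-row x positions of subtest C are not fully constrained by the
    printed spacings (only the per-gap range and the first-to-last extent are),
    so the default layout draws the four per-row gaps from a seeded generator
    and rescales them to the printed 191.8 mm extent.  Digit identities are
    placeholders: no computation depends on them.
    """

    viewing_distance_mm: float = DEFAULT_VIEWING_DISTANCE_MM
    symbol_height_mm: float = SYMBOL_HEIGHT_MM
    vertical_spacing_mm: float = VERTICAL_SPACING_MM
    column_gap_ab_mm: float = COLUMN_GAP_AB_MM
    row_extent_c_mm: float = ROW_EXTENT_C_MM
    within_row_spacing_range_mm: tuple[float, float] = WITHIN_ROW_SPACING_RANGE_MM
    gap_seed: int = 20140917  # fixed: the layout is deterministic by contract


@dataclass(frozen=True)
class DEMLayout:
    """Number positions for one DEM subtest, in reading order.

    ``positions_mm`` is an (n, 2) array of (x, y) screen positions in mm
    relative to screen center.  Reading order is left-to-right then next row
    for subtest C, and top-to-bottom of column 1 then column 2 for A/B.
    """

    subtest: str  # "A" | "B" | "C"
    viewing_distance_mm: float
    symbol_height_mm: float
    positions_mm: np.ndarray
    digits: tuple[int, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        if self.subtest not in ("A", "B", "C"):
            raise LayoutValidationError(f"unknown subtest {self.subtest!r}")
        pos = np.asarray(self.positions_mm, dtype=float)
        object.__setattr__(self, "positions_mm", pos)
        self._validate(pos)

    # -- structure ---------------------------------------------------------
    @property
    def n_positions(self) -> int:
        return len(self.positions_mm)

    @property
    def n_rows(self) -> int:
        """Number of gaze 'lines': 16 rows for C, 2 columns for A/B."""
        return N_ROWS_C if self.subtest == "C" else 2

    def row_indices(self, row: int) -> np.ndarray:
        """Indices (in reading order) of the positions forming line ``row``."""
        if self.subtest == "C":
            return np.arange(row * N_COLS_C, (row + 1) * N_COLS_C)
        return np.arange(row * N_PER_COLUMN_AB, (row + 1) * N_PER_COLUMN_AB)

    @property
    def row_extent_mm(self) -> float:
        """First-to-last spatial extent of a line (C: horizontal; A/B: the column gap)."""
        if self.subtest == "C":
            r0 = self.positions_mm[self.row_indices(0)]
            return float(r0[-1, 0] - r0[0, 0])
        return float(
            self.positions_mm[self.row_indices(1)][0, 0]
            - self.positions_mm[self.row_indices(0)][0, 0]
        )

    # -- angular view ------------------------------------------------------
    def positions_deg(self) -> np.ndarray:
        """Positions as gaze angles (deg) at the nominal viewing distance."""
        d = self.viewing_distance_mm
        return np.degrees(np.arctan2(self.positions_mm, d))

    def row_centers_y_deg(self) -> np.ndarray:
        """Vertical gaze angle of each line center (C rows) in degrees."""
        if self.subtest == "C":
            ys = [self.positions_mm[self.row_indices(r)][:, 1].mean() for r in range(self.n_rows)]
        else:  # per-position rows are not meaningful for columns; use each number
            ys = list(self.positions_mm[:, 1])
        return np.degrees(np.arctan2(np.asarray(ys), self.viewing_distance_mm))

    # -- validation --------------------------------------------------------
    def _validate(self, pos: np.ndarray) -> None:
        if self.subtest == "C":
            if pos.shape != (N_ROWS_C * N_COLS_C, 2):
                raise LayoutValidationError(
                    f"subtest C needs {N_ROWS_C * N_COLS_C} positions, got {pos.shape}"
                )
            lo, hi = WITHIN_ROW_SPACING_RANGE_MM
            for r in range(N_ROWS_C):
                row = pos[r * N_COLS_C : (r + 1) * N_COLS_C]
                gaps = np.diff(row[:, 0])
                if np.any(gaps < lo - 1e-9) or np.any(gaps > hi + 1e-9):
                    raise LayoutValidationError(
                        f"row {r}: gaps {gaps} outside [{lo}, {hi}] mm"
                    )
                if not np.allclose(row[-1, 0] - row[0, 0], ROW_EXTENT_C_MM, atol=1e-6):
                    raise LayoutValidationError(
                        f"row {r}: extent {row[-1, 0] - row[0, 0]:.3f} != {ROW_EXTENT_C_MM} mm"
                    )
                if not np.allclose(row[:, 1], row[0, 1]):
                    raise LayoutValidationError(f"row {r} is not horizontal")
        else:
            if pos.shape != (2 * N_PER_COLUMN_AB, 2):
                raise LayoutValidationError(
                    f"subtest {self.subtest} needs {2 * N_PER_COLUMN_AB} positions"
                )
            for c in range(2):
                col = pos[c * N_PER_COLUMN_AB : (c + 1) * N_PER_COLUMN_AB]
                dy = np.diff(col[:, 1])
                if not np.allclose(dy, -VERTICAL_SPACING_MM, atol=1e-6):
                    raise LayoutValidationError(
                        f"column {c}: vertical steps must all be {VERTICAL_SPACING_MM} mm"
                    )
                if not np.allclose(col[:, 0], col[0, 0]):
                    raise LayoutValidationError(f"column {c} is not vertical")
        # C rows must also be spaced by the printed vertical spacing
        if self.subtest == "C":
            row_y = pos[::N_COLS_C, 1]
            if not np.allclose(np.diff(row_y), -VERTICAL_SPACING_MM, atol=1e-6):
                raise LayoutValidationError("C rows must be spaced 14.6 mm vertically")


def _row_gaps(rng: np.random.Generator, config: LayoutConfig) -> np.ndarray:
    """Draw 4 within-row gaps in the printed range, rescaled to the printed extent."""
    lo, hi = config.within_row_spacing_range_mm
    target = config.row_extent_c_mm
    for _ in range(1000):
        gaps = rng.uniform(lo, hi, size=N_COLS_C - 1)
        gaps *= target / gaps.sum()
        if np.all(gaps >= lo) and np.all(gaps <= hi):
            return gaps
    raise LayoutValidationError("could not draw row gaps satisfying the constraints")


def build_layout(subtest: str, config: LayoutConfig | None = None) -> DEMLayout:
    """Construct the layout of one DEM subtest from the printed spacings.

    Deterministic for a given config (the per-row gap draws use the config's
    fixed seed).  Raises :class:`LayoutValidationError` if spacing overrides
    make the printed constraints unsatisfiable.
    """
    config = config or LayoutConfig()
    rng = np.random.default_rng(config.gap_seed)
    s = config.vertical_spacing_mm
    if subtest == "C":
        rows = []
        y_top = (N_ROWS_C - 1) * s / 2.0
        for r in range(N_ROWS_C):
            gaps = _row_gaps(rng, config)
            xs = np.concatenate([[0.0], np.cumsum(gaps)])
            xs -= config.row_extent_c_mm / 2.0  # center each row
            y = y_top - r * s
            rows.append(np.column_stack([xs, np.full(N_COLS_C, y)]))
        pos = np.vstack(rows)
    elif subtest in ("A", "B"):
        y_top = (N_PER_COLUMN_AB - 1) * s / 2.0
        ys = y_top - np.arange(N_PER_COLUMN_AB) * s
        x_left = -config.column_gap_ab_mm / 2.0
        col1 = np.column_stack([np.full(N_PER_COLUMN_AB, x_left), ys])
        col2 = np.column_stack([np.full(N_PER_COLUMN_AB, -x_left), ys])
        pos = np.vstack([col1, col2])
    else:
        raise LayoutValidationError(f"unknown subtest {subtest!r}")
    digits = tuple(int(d) for d in rng.integers(0, 10, size=len(pos)))
    return DEMLayout(
        subtest=subtest,
        viewing_distance_mm=config.viewing_distance_mm,
        symbol_height_mm=config.symbol_height_mm,
        positions_mm=pos,
        digits=digits,
    )


def layout_to_tsv(layout: DEMLayout, path: str) -> None:
    """Serialize a layout as key:value header lines plus a TSV position table."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subtest: {layout.subtest}\n")
        fh.write(f"# viewing_distance_mm: {layout.viewing_distance_mm}\n")
        fh.write(f"# symbol_height_mm: {layout.symbol_height_mm}\n")
        fh.write("index\tx_mm\ty_mm\tdigit\n")
        digits = layout.digits or tuple([0] * layout.n_positions)
        for i, ((x, y), d) in enumerate(zip(layout.positions_mm, digits)):
            fh.write(f"{i}\t{x:.4f}\t{y:.4f}\t{d}\n")


def layout_from_tsv(path: str) -> DEMLayout:
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    digits: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            elif not line.startswith("index"):
                _, x, y, d = line.split("\t")
                rows.append((float(x), float(y)))
                digits.append(int(d))
    return DEMLayout(
        subtest=meta["subtest"],
        viewing_distance_mm=float(meta["viewing_distance_mm"]),
        symbol_height_mm=float(meta["symbol_height_mm"]),
        positions_mm=np.asarray(rows),
        digits=tuple(digits),
    )
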