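"""DEM scoring and reaction-time cleaning.

Subtest times: vertical time = A + B (never error-adjusted; if only one of
A/B is usable its time is duplicated and the record flagged); horizontal
(C) time is adjusted for naming errors as

    adjusted C = raw C * 80 / (80 - omissions + additions)

with line-level conventions: repeating a whole line counts as five addition
errors, skipping a whole line as two omission errors.  The DEM ratio is
adjusted C over vertical, and "naming" is vertical as a percentage of
(adjusted) horizontal time.

Reaction-time cleaning for the speed-acuity and detection tasks: drop trials
< 0.1 s, then trials deviating more than 3x the (unscaled) MAD from the
subject's median for that task; subjects whose retained-trial mean deviates
more than 3 group SDs from the group mean are flagged excluded.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEMResult",
    "InvalidScoreError",
    "adjust_time_C",
    "count_errors",
    "vertical_time",
    "clean_reaction_times",
    "score_subject",
]

N_TARGETS_C = 80
LINE_LENGTH_C = 5


class InvalidScoreError(ValueError):
    pass


@dataclass
class DEMResult:
    """Complete DEM score sheet for one subject."""

    time_a: float | None
    time_b: float | None
    raw_time_c: float
    omissions: int
    additions: int
    vertical: float = 0.0
    duplication: str = "complete"  # "complete" | "A-only" | "B-only"

    def __post_init__(self) -> None:
        self.vertical, self.duplication = vertical_time(self.time_a, self.time_b)

    @property
    def errors(self) -> int:
        return self.omissions + self.additions

    @property
    def adjusted_time_c(self) -> float:
        return adjust_time_C(self.raw_time_c, self.omissions, self.additions)

    @property
    def ratio(self) -> float:
        return self.adjusted_time_c / self.vertical

    @property
    def naming_percent(self) -> float:
        """Vertical time as a percentage of (adjusted) horizontal time."""
        return self.vertical / self.adjusted_time_c * 100.0


def adjust_time_C(raw_time: float, omissions: int, additions: int) -> float:
    """Error-adjusted horizontal DEM time: raw * 80/(80 - omissions + additions).

    Monotone increasing in omissions and decreasing in additions.  Only the
    horizontal subtest is ever adjusted; A and B times are used raw.
    """
    if raw_time <= 0:
        raise InvalidScoreError("raw time must be positive")
    if not 0 <= omissions < N_TARGETS_C:
        raise InvalidScoreError(f"omissions must be in [0, {N_TARGETS_C}), got {omissions}")
    if additions < 0:
        raise InvalidScoreError("additions must be >= 0")
    if omissions == additions:  # factor is exactly 1: keep the identity exact
        return raw_time
    return raw_time * N_TARGETS_C / (N_TARGETS_C - omissions + additions)


def count_errors(
    response: list[str],
    target_lines: list[list[str]],
    skipped_line_omissions: int = 2,
) -> tuple[int, int]:
    """Count omissions and additions from a named-number transcript.

    Responses are aligned to the 80-number target sequence by a
    longest-common-subsequence match; unmatched targets are omissions and
    unmatched responses additions, except that a fully skipped line counts a
    fixed ``skipped_line_omissions`` (default 2, as scored in the test) rather
    than one per number.  A fully repeated line naturally contributes one
    addition per number (= 5).

    Substitutions (wrong number at a matched position) count as neither.
    """
    target = [tok for line in target_lines for tok in line]
    response = [str(tok) for tok in response]
    if not response:
        warnings.warn("empty response transcript: scoring every line as skipped")
        om = sum(
            skipped_line_omissions if len(line) == LINE_LENGTH_C else len(line)
            for line in target_lines
        )
        return om, 0
    sm = difflib.SequenceMatcher(a=target, b=[str(t) for t in response], autojunk=False)
    matched_t = np.zeros(len(target), dtype=bool)
    matched_r = np.zeros(len(response), dtype=bool)
    for blk in sm.get_matching_blocks():
        matched_t[blk.a : blk.a + blk.size] = True
        matched_r[blk.b : blk.b + blk.size] = True
    # substitutions: a one-for-one unmatched target/response pair between two
    # matched blocks is a wrong digit in place, not an omission+addition
    opcodes = sm.get_opcodes()
    for tag, a0, a1, b0, b1 in opcodes:
        if tag == "replace" and (a1 - a0) == (b1 - b0):
            matched_t[a0:a1] = True
            matched_r[b0:b1] = True
    additions = int((~matched_r).sum())
    omissions = 0
    pos = 0
    for line in target_lines:
        line_mask = matched_t[pos : pos + len(line)]
        if len(line) == LINE_LENGTH_C and not line_mask.any():
            omissions += skipped_line_omissions
        else:
            omissions += int((~line_mask).sum())
        pos += len(line)
    return omissions, additions


def vertical_time(time_a: float | None, time_b: float | None) -> tuple[float, str]:
    """Vertical DEM time = A + B; a missing half is duplicated and flagged."""
    if time_a is None and time_b is None:
        raise InvalidScoreError("both subtest times missing")
    if time_a is not None and time_b is not None:
        return time_a + time_b, "complete"
    if time_a is not None:
        return 2.0 * time_a, "A-only"
    return 2.0 * time_b, "B-only"


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x)))) if len(x) else 0.0


def clean_reaction_times(
    table: pd.DataFrame,
    rt_floor: float = 0.1,
    mad_multiplier: float = 3.0,
    group_sd_multiplier: float = 3.0,
) -> pd.DataFrame:
    """Flag reaction-time trials and subjects per the robust cleaning rules.

    ``table`` needs columns ``subject``, ``task``, ``rt`` (seconds); an
    optional ``size`` column subdivides the speed-acuity task by optotype
    size.  Returns a copy with boolean columns ``kept`` (trial level) and
    ``subject_excluded``, plus per-subject means in the ``subject_mean``
    column (NaN where no trials survive).  Idempotent: re-cleaning the kept
    subset drops nothing more, because the rule is a strict inequality.
    """
    req = {"subject", "task", "rt"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    out = table.copy()
    keys = ["subject", "task"] + (["size"] if "size" in out.columns else [])
    out["kept"] = out["rt"] >= rt_floor
    for _, idx in out.groupby(keys, dropna=False).groups.items():
        # iterate the MAD rule to a fixed point so that cleaning is
        # idempotent: no retained trial deviates > 3xMAD of the retained set
        while True:
            sub = out.loc[idx]
            rts = sub.loc[sub["kept"], "rt"].to_numpy()
            if not len(rts):
                break
            med = np.median(rts)
            cut = mad_multiplier * _mad(rts)
            drop = sub["kept"] & (np.abs(sub["rt"] - med) > cut)
            if not drop.any():
                break
            out.loc[idx[drop], "kept"] = False
    means = out[out["kept"]].groupby(keys, dropna=False)["rt"].mean()
    out = out.merge(means.rename("subject_mean"), how="left", on=keys)
    # group-level exclusion, within task (and size)
    out["subject_excluded"] = False
    gkeys = keys[1:]
    per_subj = out.drop_duplicates(subset=keys)
    for _, grp in per_subj.groupby(gkeys, dropna=False) if gkeys else [(None, per_subj)]:
        mu = grp["subject_mean"].mean()
        sd = grp["subject_mean"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        bad = grp.loc[np.abs(grp["subject_mean"] - mu) > group_sd_multiplier * sd, "subject"]
        sel = out["subject"].isin(bad)
        for k in gkeys:
            sel &= out[k] == grp[k].iloc[0]
        out.loc[sel, "subject_excluded"] = True
    return out


def score_subject(
    time_a: float | None,
    time_b: float | None,
    raw_time_c: float,
    response: list[str] | None = None,
    target_lines: list[list[str]] | None = None,
    omissions: int | None = None,
    additions: int | None = None,
) -> DEMResult:
    """Build a :class:`DEMResult` from times plus either a transcript or counts."""
    if omissions is None or additions is None:
        if response is None or target_lines is None:
            raise InvalidScoreError("need either error counts or a transcript")
        omissions, additions = count_errors(response, target_lines)
    return DEMResult(time_a, time_b, raw_time_c, omissions, additions)
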