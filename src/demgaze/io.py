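"""Plain-text readers and writers for the pipeline's data products.

All files are UTF-8, tab-delimited with a header line; floating point uses a
decimal point.  Output files carry a comment header with the package version,
the seed and a hash of the resolved configuration, so any result file can be
traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .epochs import Epoch
from .events import FixationEvent, SaccadeEvent
from .preprocess import RawGazeStream, UniformGazeSignal

__all__ = [
    "read_gaze",
    "write_gaze",
    "write_signal",
    "write_events",
    "read_events",
    "write_epochs",
    "config_hash",
]


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _header(seed: int | None, cfg_hash: str | None) -> str:
    return f"# demgaze {__version__} seed={seed} config={cfg_hash}\n"


def write_gaze(stream: RawGazeStream, path: str | Path, seed: int | None = None, cfg_hash: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("t_s\tx_deg\ty_deg\tvalid\teye\n")
        for t, x, y, v in zip(stream.t, stream.x, stream.y, stream.valid):
            fh.write(f"{t:.6f}\t{x:.5f}\t{y:.5f}\t{int(v)}\t{stream.eye}\n")


def read_gaze(path: str | Path) -> RawGazeStream:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"t_s", "x_deg", "y_deg", "valid", "eye"}
    if not required.issubset(df.columns):
        raise ValueError(f"gaze file needs columns {sorted(required)}")
    return RawGazeStream(
        t=df["t_s"].to_numpy(),
        x=df["x_deg"].to_numpy(),
        y=df["y_deg"].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
        eye=str(df["eye"].iloc[0]),
    )


def write_signal(sig: UniformGazeSignal, path: str | Path, seed: int | None = None, cfg_hash: str | None = None) -> None:
    t = sig.t
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write(f"# fs={sig.fs} t0={sig.t0} segments={sig.segments}\n")
        fh.write("t_s\tx_deg\ty_deg\tvx\tvy\tv_track\ta_track\tvalid\n")
        z = np.zeros(len(sig.x))
        vx = sig.vx if sig.vx is not None else z
        vy = sig.vy if sig.vy is not None else z
        v = sig.v if sig.v is not None else z
        a = sig.a if sig.a is not None else z
        for row in zip(t, sig.x, sig.y, vx, vy, v, a, sig.valid):
            fh.write("\t".join(f"{x:.5f}" if not isinstance(x, (bool, np.bool_)) else str(int(x)) for x in row) + "\n")


def write_events(
    saccades: list[SaccadeEvent],
    fixations: list[FixationEvent],
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("type\tonset_s\toffset_s\tdx_deg\tdy_deg\tamplitude_deg\tdirection_deg\tpeak_velocity\taxis\tflags\n")
        for s in saccades:
            flags = "backwards" if s.backwards else ""
            fh.write(
                f"saccade\t{s.onset:.4f}\t{s.offset:.4f}\t{s.dx:.4f}\t{s.dy:.4f}\t"
                f"{s.amplitude:.4f}\t{s.direction:.2f}\t{s.peak_velocity:.2f}\t{s.axis}\t{flags}\n"
            )
        for f in fixations:
            flags = "duration_outlier" if f.duration_outlier else ""
            fh.write(
                f"fixation\t{f.start:.4f}\t{f.end:.4f}\t{f.cx:.4f}\t{f.cy:.4f}\t\t\t\t\t{flags}\n"
            )


def read_events(path: str | Path) -> tuple[list[SaccadeEvent], list[FixationEvent]]:
    saccades: list[SaccadeEvent] = []
    fixations: list[FixationEvent] = []
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    for _, row in df.iterrows():
        if row["type"] == "saccade":
            saccades.append(
                SaccadeEvent(
                    onset=float(row["onset_s"]),
                    offset=float(row["offset_s"]),
                    dx=float(row["dx_deg"]),
                    dy=float(row["dy_deg"]),
                    peak_velocity=float(row["peak_velocity"]),
                    backwards=row["flags"] == "backwards",
                )
            )
        else:
            f = FixationEvent(
                start=float(row["onset_s"]),
                end=float(row["offset_s"]),
                cx=float(row["dx_deg"]),
                cy=float(row["dy_deg"]),
            )
            f.duration_outlier = row["flags"] == "duration_outlier"
            fixations.append(f)
    return saccades, fixations


def write_epochs(epochs: list[Epoch], path: str | Path, seed: int | None = None, cfg_hash: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("kind\tsubtest\trow\tstart_s\tend_s\tduration_s\n")
        for e in epochs:
            fh.write(f"{e.kind}\t{e.subtest}\t{e.row}\t{e.start:.4f}\t{e.end:.4f}\t{e.duration:.4f}\n")
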