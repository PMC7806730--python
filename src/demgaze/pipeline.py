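"""End-to-end pipeline: simulate -> preprocess -> detect -> segment -> score -> stats.

`run_pipeline` drives the full analysis for a simulated cohort and writes
every stage's products as plain-text files under an output directory.  Reruns
with the same configuration and seed reproduce identical outputs; every file
header records the seed and a hash of the resolved configuration.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .epochs import SegmentationConfig, assign_rows, epoch_metrics, segment_epochs
from .events import DetectionConfig, detect_events
from .geometry import build_layout
from .preprocess import PreprocessConfig, preprocess
from .scoring import DEMResult, clean_reaction_times
from .simulate import CohortConfig, NoiseModel, simulate_cohort
from .stats import bh_fdr, pearson, partial_corr

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "analyze_cohort"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "demgaze_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build a config from nested plain dicts, rejecting unknown keys."""
        sections = {
            "cohort": CohortConfig,
            "noise": NoiseModel,
            "preprocess": PreprocessConfig,
            "detection": DetectionConfig,
            "segmentation": SegmentationConfig,
        }
        kwargs: dict = {}
        for key, value in data.items():
            if key in sections:
                sub = sections[key]
                known = {f.name for f in fields(sub)}
                bad = set(value) - known
                if bad:
                    raise ValueError(f"unknown keys in '{key}' section: {sorted(bad)}")
                value = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                kwargs[key] = sub(**value)
            elif key in ("seed", "out_dir"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown configuration key: {key!r}")
        return cls(**kwargs)

    def resolved(self) -> dict:
        # out_dir is a run location, not an analysis parameter: identical
        # configurations must hash identically wherever they are written
        d = asdict(self)
        d.pop("out_dir", None)
        return d


def analyze_cohort(config: PipelineConfig) -> pd.DataFrame:
    """Run the full per-subject analysis and return the cohort summary table.

    One row per subject: age, DEM times (vertical raw; horizontal raw and
    error-free adjusted), per-epoch-kind oculomotor metrics for the
    horizontal subtest, and cleaned reaction-time means.
    """
    records = simulate_cohort(config.cohort, config.noise, config.seed)
    layouts = {st: build_layout(st) for st in config.cohort.subtests}
    rows = []
    rt_all = pd.concat([r.rt_trials for r in records], ignore_index=True)
    rt_clean = clean_reaction_times(rt_all)
    sa_means = (
        rt_clean[(rt_clean["task"] == "speed-acuity") & ~rt_clean["subject_excluded"]]
        .drop_duplicates("subject")
        .set_index("subject")["subject_mean"]
    )
    det_means = {
        task: rt_clean[(rt_clean["task"] == task) & ~rt_clean["subject_excluded"]]
        .drop_duplicates("subject")
        .set_index("subject")["subject_mean"]
        for task in ("visual detection", "auditory detection")
    }
    for rec in records:
        row: dict = {"subject": rec.subject, "age": rec.age, "latent_s": rec.profile.s}
        times: dict[str, float] = {}
        for st, stream in rec.streams.items():
            sig = preprocess(stream, config.preprocess)
            ev = detect_events(sig, config.detection)
            fix = assign_rows(ev.fixations, layouts[st], config.segmentation)
            eps = segment_epochs(ev.saccades, fix, layouts[st], config.segmentation)
            m = epoch_metrics(eps, ev.saccades, fix)
            times[st] = sum(e.duration for e in eps)
            if st == "C":
                row.update(
                    {
                        "c_time": times[st],
                        "c_ident_fixdur_ms": m.median_fixation_duration["identification"],
                        "c_sweep_fixdur_ms": m.median_fixation_duration.get("return_sweep", np.nan),
                        "c_ident_sacc_count": m.saccade_count["identification"],
                        "c_sweep_sacc_count": m.saccade_count.get("return_sweep", 0),
                        "c_ident_amp_deg": m.median_saccade_amplitude["identification"],
                        "c_backwards": m.backwards_count,
                        "c_orthogonal": m.orthogonal_count,
                        "c_n_sweeps": sum(1 for e in eps if e.kind == "return_sweep"),
                        "c_fixation_time": m.fixation_time["identification"],
                        "c_saccade_time": m.saccade_time["identification"],
                        "c_sweep_time": m.total_time.get("return_sweep", 0.0),
                    }
                )
        dem = DEMResult(
            time_a=times.get("A"),
            time_b=times.get("B"),
            raw_time_c=times.get("C", np.nan),
            omissions=0,
            additions=0,
        )
        row["vertical_time"] = dem.vertical
        row["adjusted_c_time"] = dem.adjusted_time_c
        row["dem_ratio"] = dem.ratio
        row["sa_rt"] = sa_means.get(rec.subject, np.nan)
        row["visual_rt"] = det_means["visual detection"].get(rec.subject, np.nan)
        row["auditory_rt"] = det_means["auditory detection"].get(rec.subject, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_statistics(table: pd.DataFrame) -> pd.DataFrame:
    """The study's correlation family on a cohort table, with FDR adjustment."""
    pairs = [
        ("age", "vertical_time"),
        ("age", "adjusted_c_time"),
        ("age", "dem_ratio"),
        ("sa_rt", "vertical_time"),
        ("sa_rt", "adjusted_c_time"),
        ("sa_rt", "dem_ratio"),
        ("sa_rt", "c_ident_fixdur_ms"),
        ("c_ident_fixdur_ms", "visual_rt"),
        ("c_ident_fixdur_ms", "auditory_rt"),
        ("c_ident_fixdur_ms", "c_time"),
        ("c_ident_sacc_count", "c_time"),
    ]
    out = []
    for a, b in pairs:
        cols = list(dict.fromkeys([a, b, "age"]))
        sub = table[cols].dropna()
        res = pearson(sub[a], sub[b])
        rec = {"x": a, "y": b, "r": res.r, "n": res.n, "p": res.p}
        if "age" not in (a, b) and len(sub) >= 4:
            pr = partial_corr(sub[a], sub[b], sub["age"])
            rec["partial_rho"] = pr.r
            rec["partial_p"] = pr.p
        out.append(rec)
    df = pd.DataFrame(out)
    df["p_fdr"], df["significant_fdr"] = bh_fdr(df["p"].to_numpy())
    return df


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the results directory; returns its path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = dio.config_hash(config.resolved())
    from . import __version__

    def write_table(df: pd.DataFrame, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# demgaze {__version__} seed={config.seed} config={cfg_hash}\n")
            df.to_csv(fh, sep="\t", index=False)

    stage = "simulate+analyze"
    try:
        table = analyze_cohort(config)
        write_table(table, out / "cohort_summary.tsv")
        stage = "stats"
        stats = cohort_statistics(table)
        write_table(stats, out / "cohort_statistics.tsv")
        with open(out / "run_info.txt", "w", encoding="utf-8") as fh:
            fh.write(f"demgaze run seed={config.seed} config={cfg_hash}\n")
            fh.write(repr(config.resolved()) + "\n")
    except Exception as exc:  # noqa: BLE001 - stage attribution for the CLI
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return out
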