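import numpy as np
import pytest

from demgaze.epochs import SegmentationConfig, assign_rows, segment_epochs
from demgaze.events import detect_events
from demgaze.geometry import build_layout
from demgaze.pipeline import PipelineConfig, analyze_cohort, cohort_statistics
from demgaze.preprocess import preprocess
from demgaze.simulate import ERRORLESS_PROFILE, NoiseModel, simulate_trial


@pytest.fixture(scope="session")
def layout_c():
    return build_layout("C")


@pytest.fixture(scope="session")
def layout_a():
    return build_layout("A")


@pytest.fixture(scope="session")
def errorless_trial(layout_c):
    """One errorless horizontal-DEM recording, fully processed, with ground truth."""
    stream, gt = simulate_trial(ERRORLESS_PROFILE, layout_c, NoiseModel(), seed=1)
    sig = preprocess(stream)
    ev = detect_events(sig)
    fix = assign_rows(ev.fixations, layout_c, SegmentationConfig())
    epochs = segment_epochs(ev.saccades, fix, layout_c)
    return {"stream": stream, "gt": gt, "sig": sig, "ev": ev, "fix": fix, "epochs": epochs}


@pytest.fixture(scope="session")
def cohort_table():
    """Default 36-child cohort pushed through the full pipeline (the heavy fixture)."""
    return analyze_cohort(PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_stats(cohort_table):
    return cohort_statistics(cohort_table)
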