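"""Segment a horizontal-DEM recording into identification and return-sweep
epochs and summarize the oculomotor metrics per epoch kind.

Reading the 16-row array errorlessly takes 16 number-identification epochs
separated by 15 return sweeps; most of the trial is fixation time during
identification, which is what makes completion time track processing speed.
"""

from demgaze import NoiseModel, build_layout
from demgaze.epochs import assign_rows, epoch_metrics, segment_epochs
from demgaze.events import detect_events
from demgaze.preprocess import preprocess
from demgaze.simulate import ERRORLESS_PROFILE, simulate_trial

layout = build_layout("C")
stream, _ = simulate_trial(ERRORLESS_PROFILE, layout, NoiseModel(), seed=1)
signal = preprocess(stream)
events = detect_events(signal)
fixations = assign_rows(events.fixations, layout)
epochs = segment_epochs(events.saccades, fixations, layout)

n_ident = sum(1 for e in epochs if e.kind == "identification")
n_sweep = sum(1 for e in epochs if e.kind == "return_sweep")
print(f"{n_ident} identification epochs, {n_sweep} return sweeps")

m = epoch_metrics(epochs, events.saccades, fixations)
for kind in ("identification", "return_sweep"):
    print(f"{kind}: total {m.total_time[kind]:.1f} s "
          f"(fixation {m.fixation_time[kind]:.1f} s, saccades {m.saccade_time[kind]:.1f} s), "
          f"{m.saccade_count[kind]} saccades, "
          f"median fixation {m.median_fixation_duration[kind]:.0f} ms, "
          f"median amplitude {m.median_saccade_amplitude[kind]:.1f} deg")
print(f"backwards saccades during identification: {m.backwards_count}")
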