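"""Simulate one horizontal-DEM recording and detect its eye movements.

Shows the adaptive MAD thresholds the detector settled on and compares the
detected event count with the generator's ground truth (an errorless reading
of the 16x5 array makes 64 within-row saccades plus 15 return sweeps = 79).
"""

from demgaze import NoiseModel, build_layout
from demgaze.events import detect_events
from demgaze.preprocess import preprocess
from demgaze.simulate import ERRORLESS_PROFILE, simulate_trial

layout = build_layout("C")
stream, truth = simulate_trial(ERRORLESS_PROFILE, layout, NoiseModel(), seed=1)
print(f"raw stream: {len(stream)} samples, {stream.t[-1] - stream.t[0]:.1f} s, "
      f"{100 * stream.valid_fraction:.1f}% valid")

signal = preprocess(stream)
events = detect_events(signal)
print(f"thresholds: velocity {events.velocity_threshold:.1f} deg/s, "
      f"acceleration {events.acceleration_threshold:.0f} deg/s^2")
print(f"detected {len(events.saccades)} saccades "
      f"(ground truth {len(truth.saccades)}), {len(events.fixations)} fixations")

amps = sorted(s.amplitude for s in events.saccades)
print(f"saccade amplitudes: {amps[0]:.1f} .. {amps[-1]:.1f} deg "
      f"(large ones are the return sweeps)")
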