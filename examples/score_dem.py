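"""Score a DEM test sheet: error-adjusted time, ratio, and RT cleaning.

A child who named the array in 60 s but skipped one full line (2 omission
errors) gets a longer adjusted horizontal time; the DEM ratio divides that by
the vertical time A + B.  The reaction-time cleaner then shows the robust
trial-exclusion rule on a small speed-acuity block.
"""

import pandas as pd

from demgaze import DEMResult, clean_reaction_times, count_errors

target_lines = [[str((3 * i + j) % 10) for j in range(5)] for i in range(16)]
response = [tok for i, line in enumerate(target_lines) if i != 7 for tok in line]
omissions, additions = count_errors(response, target_lines)
print(f"transcript errors: {omissions} omissions, {additions} additions "
      f"(one skipped line counts 2)")

result = DEMResult(time_a=25.0, time_b=27.0, raw_time_c=60.0,
                   omissions=omissions, additions=additions)
print(f"vertical time  : {result.vertical:.1f} s ({result.duplication})")
print(f"adjusted C time: {result.adjusted_time_c:.3f} s (raw 60.0)")
print(f"DEM ratio      : {result.ratio:.3f}")
print(f"naming         : {result.naming_percent:.0f}% "
      f"(vertical as % of horizontal)")

trials = pd.DataFrame({
    "subject": 0,
    "task": "speed-acuity",
    "rt": [0.05, 0.40, 0.41, 0.42, 0.43, 2.50],
})
cleaned = clean_reaction_times(trials)
kept = cleaned[cleaned["kept"]]["rt"].tolist()
print(f"RT cleaning: kept {kept} -> mean {cleaned['subject_mean'].iloc[1]:.3f} s "
      f"(floor drops 0.05, the 3xMAD rule drops 2.50)")
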