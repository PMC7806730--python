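"""Simulate a small cohort, run the full pipeline, and print the study's
correlation family.

Each simulated child has a latent processing speed that falls with age and
drives both fixation durations and speed-acuity reaction times, so the
analysis should find: negative age-DEM-time correlations, and a positive
fixation-duration / reaction-time correlation that survives adjusting for
age and the false-discovery-rate correction.
"""

from demgaze import CohortConfig, PipelineConfig, analyze_cohort, cohort_statistics

config = PipelineConfig(seed=1, cohort=CohortConfig(n_subjects=20))
table = analyze_cohort(config)
print(f"analyzed {len(table)} subjects, ages {table['age'].min():.1f}-{table['age'].max():.1f}")
print(f"horizontal DEM time {table['c_time'].mean():.1f} +/- {table['c_time'].std():.1f} s, "
      f"vertical {table['vertical_time'].mean():.1f} +/- {table['vertical_time'].std():.1f} s")

stats = cohort_statistics(table)
cols = ["x", "y", "r", "p", "partial_rho", "p_fdr", "significant_fdr"]
print(stats[cols].round(3).to_string(index=False))
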