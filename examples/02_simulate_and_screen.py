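"""Simulate a distance-reproduction cohort and apply the exclusion rules.

The default cohort has 24 participants (2 orientations x 12 directions x
6 distances each); 4 of them reproduce elapsed time instead of distance and
should be caught by the correlation screen. After screening, trials deviating
more than 2 SD from a participant's overall mean absolute error are removed.
"""

import distaniso as da

config = da.CohortConfig(seed=7)
table = da.simulate_cohort(config)
print(f"simulated {len(table)} trials from {table['participant_id'].nunique()} participants")

kept, report = da.screen_participants(table)
print(f"screen excluded {len(report.excluded)} participants:")
for entry in report.excluded:
    r = "undefined" if entry["r"] is None else f"{entry['r']:.3f}"
    print(f"  {entry['participant_id']}: r = {r} ({entry['reason']})")

cleaned, fraction = da.remove_outlier_trials(kept)
print(f"outlier rule removed {fraction:.1%} of the remaining trials")
print(f"cleaned table: {len(cleaned)} trials, mean |error| = {cleaned['abs_error'].mean():.3f} m")
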