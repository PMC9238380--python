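"""Generate a synthetic 16-athlete dietary-intervention cohort.

Builds the sample sheet (2 diet arms x 8 subjects x 3 time points), a
bacterial genus count table and the linked time-trial-to-exhaustion (TTE)
performance table, then prints the per-arm mean TTE change at the mid
time point. With the default settings the high-protein arm loses about
23% of its TTE at mid and the high-carbohydrate arm gains about 6.5%,
because those are the arm effects the generator encodes.
"""

from gutstab import (
    CohortConfig,
    make_cohort,
    percent_change_tte,
    simulate_feature_table,
    simulate_performance,
)

config = CohortConfig(seed=1)
metadata = make_cohort(config)
print(f"cohort: {len(metadata.subjects)} subjects, {len(metadata.sample_ids)} samples")

bacteria = simulate_feature_table(metadata, config, "bacterial")
print(f"bacterial table: {bacteria.shape[0]} genera x {bacteria.shape[1]} samples, "
      f"library size {int(bacteria.values().sum(axis=0)[0])}")

perf = simulate_performance(metadata, config)
_, per_group = percent_change_tte(perf)
for arm in per_group.index:
    print(f"{arm}: mean TTE change at mid = {per_group.loc[arm, 'mid']:+.1f}% "
          f"(recovers to {per_group.loc[arm, 'post']:+.1f}% at post)")
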