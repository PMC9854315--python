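"""Simulate a pool of synthetic participants and inspect its composition.

Each participant completes 70 trials (the last 10 under verbal-disruption
instructions) of 4 arithmetic verifications plus 4 letter-recognition
probes, i.e. 560 responses.  Participants are drawn from an archetype
mixture: compliant responders plus contamination archetypes.
"""

from collections import Counter

from wmquality import preset_scenario, simulate_pool

scenario = preset_scenario("mturk", n_participants=50, seed=7)
cohort = simulate_pool(scenario)

pattern = cohort.patterns[0]
print(f"pool: {scenario.pool}, participants: {len(cohort)}")
print(f"records per participant: {pattern.n_records} "
      f"({len(pattern.subset(trial_type='regular'))} on regular trials)")
print("ground-truth archetype counts:", dict(Counter(cohort.labels.values())))
print(pattern.records.head(8).to_string(index=False))
# The archetype counts are the planted contamination that screening and the
# benchmark filters should later recover from the data alone.
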