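"""Generate one experimental run schedule and summarise its structure.

The design interleaves 48 short experimental blocks (8 conditions x 6
blocks of 4-6 s) with 7 fixation blocks; a valid run always totals 280 s.
"""

import numdecode as nd

schedule = nd.generate_run_schedule(nd.ExperimentDesign(), seed=1)

print(f"experimental blocks: {len(schedule.experimental_blocks)}")
print(f"fixation blocks:     {len(schedule.fixation_blocks)}")
print(f"total duration:      {schedule.total_duration:.0f} s")
counts = schedule.condition_counts()
print(f"blocks per condition: {sorted(set(counts.values()))}")
print()
print("first six blocks:")
print(schedule.to_frame().head(6).to_string(index=False))
# Every condition appears in exactly 6 blocks summing to 30 s; the five
# interleaved fixations (after every 8th experimental block) sum to 24 s,
# closing the run at exactly 280 s.
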