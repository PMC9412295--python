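"""Gait measures for one instructed 20 s walk.

Simulates a phone-in-pocket walk at 2 steps/s, computes duration, step count,
distance, speed and stride period over the test window, and compares the step
count and stride period against the generator's ground truth.
"""

from motionval import WalkScenario, gait_measures, generate_walk

scenario = WalkScenario(
    schedule=(("rest", 10.0), ("walk", 20.0), ("rest", 10.0)),
    step_freq_hz=2.0,
    seed=7,
)
record, (truth,) = generate_walk(scenario)
gm = gait_measures(record, (truth.start_time, truth.end_time))

print(f"duration      {gm.duration_s:6.2f} s")
print(f"steps         {gm.steps:6d}   (truth {truth.steps})")
print(f"distance      {gm.distance_m:6.2f} m (truth {truth.distance_m:.2f})")
print(f"speed         {gm.speed_mps:6.3f} m/s")
print(f"stride period {gm.stride_period_s:6.3f} s (truth {2 / scenario.step_freq_hz:.3f})")
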