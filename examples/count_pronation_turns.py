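"""Count arm pronation/supination turns from simulated gyroscope data.

Simulates 14 full palm-up/palm-down turns in 20 s about a random device axis,
integrates the angular velocity to a rotation angle and counts the qualifying
maxima/minima pairs. The count should match the simulated truth exactly and
the rate should be turns divided by the task duration.
"""

from motionval import RotationScenario, generate_rotation, pronation_supination_measures

scenario = RotationScenario(n_turns=14, turn_amplitude_deg=170.0, duration_s=20.0, seed=2)
record, truth = generate_rotation(scenario)
tm = pronation_supination_measures(record)

print(f"turns counted  {tm.turns}   (truth {truth.n_turns})")
print(f"rotation rate  {tm.rotation_rate_tps:.3f} turns/s (truth {truth.rate_task_tps:.3f})")
print(f"first extrema at t = {[round(float(t), 2) for t in tm.extrema_times[:4]]} s")
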