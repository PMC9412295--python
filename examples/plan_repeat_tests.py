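"""Plan the number of repeat tests for a reliability study.

For 10 subjects and a range of anticipated ICC values, finds the smallest
repeat count whose large-sample 95% CI satisfies both precision criteria:
the upper bound (ICC + half-width) at most 1 and the lower bound at least
0.75. At an anticipated ICC of 0.9 this yields 4 repeats; at 0.85 the lower
criterion is unreachable for any practical repeat count.
"""

from motionval import required_repeats

print(f"{'anticipated ICC':>16s} {'repeats':>8s} {'half-width':>11s} {'feasible':>9s}")
for rho in (0.85, 0.88, 0.90, 0.92, 0.95):
    plan = required_repeats(rho, n_subjects=10)
    print(
        f"{rho:16.2f} {plan.k_repeats:8d} {plan.half_width:11.4f} "
        f"{str(plan.feasible):>9s}"
    )
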