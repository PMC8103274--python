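"""Score one hand's VR session: two slicing attempts and five mug carries.

Builds slicing event logs and tilt trajectories of increasing instability,
then prints the per-hand VR Time (seconds to slice three items, averaged
over attempts) and VR ADL Score (cylinders left of 10, averaged over five
attempts; liquid spills while the mug tilts beyond 30 degrees).
"""

import vrmotor as vm

slice_logs = [vm.simulate_slice_log(52.0, seed=1, attempt_index=1),
              vm.simulate_slice_log(48.0, seed=2, attempt_index=2)]

adl_attempts = []
for k in range(1, 6):
    t, tilt = vm.simulate_adl_trajectory(instability=0.35, duration=8, rate=90, seed=k)
    adl_attempts.append(
        vm.ADLAttempt(hand="right", attempt_index=k, mug_index=k, t=t, tilt_deg=tilt)
    )

summary = vm.make_hand_summary("right", slice_logs, adl_attempts)
print(f"VR Time (mean of 2 attempts): {summary.vr_time:.1f} s")
print(f"VR ADL Score (mean of 5):     {summary.vr_adl_score:.1f} / 10")
for a in adl_attempts:
    print(f"  attempt {a.attempt_index}: "
          f"{vm.score_adl_attempt(a.t, a.tilt_deg)} cylinders left")
print("-> longer slicing times indicate bradykinesia; lower ADL scores")
print("   indicate unstable mug control (more time beyond the tilt threshold).")
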