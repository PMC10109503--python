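"""Synaptic-cleft pH during a 1 Hz windup train.

Drives a single buffered cleft with one 1-ms proton pulse per second and
prints the pH reached after each of the first stimuli and at the end:
the buffer makes each pulse's recovery take seconds, so acidification
accumulates toward a quasi-steady level.
"""

from windup_asic.cleft import CleftParams, CleftState, on_presynaptic_event, step_cleft

p = CleftParams()
state = CleftState.resting(p)
dt, t = 0.025, 0.0
stim_times = [1000.0 * (k + 1) for k in range(15)]
next_stim = 0
while t < 16_000.0:
    if next_stim < len(stim_times) and t >= stim_times[next_stim]:
        state = on_presynaptic_event(state, t, p)
        next_stim += 1
    state = step_cleft(state, t, dt, p)
    t += dt
    if abs(t % 1000.0 - 999.0) < dt / 2 and t < 6000:
        print(f"t = {t/1000:.0f} s   cleft pH = {state.pH:.3f}")
print(f"t = 16 s  cleft pH = {state.pH:.3f}  (quasi-steady acid shift "
      f"{7.4 - state.pH:.2f} pH units)")
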