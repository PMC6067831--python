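"""Proposed two-stage challenge: DEX suppression plus a timed stressor.

Runs the DST and then switches on a psychological stressor (a step
I_ext = 0.5 in the synaptic drive, 60 min long) at the 9-h post-DEX draw,
from each basin.  Under bistability the suppressed diseased state responds
MORE than the normal state -- the opposite of what an enhanced-negative-
feedback account predicts, which is what makes the protocol discriminating.
"""
import hpaxis as hx

params = hx.REFERENCE
fps = hx.find_fixed_points(params)

print("basin      DST s (%)   o before stressor   peak o in stressor   rise")
results = {}
for basin in ("normal", "diseased"):
    r = hx.run_two_stage_test(params, basin, fixed_points=fps)
    results[basin] = r
    print(f"{basin:9s}  {r.dex.s:8.2f}   {r.pre_stress_o:17.4f}   "
          f"{r.peak_o_during_stress:18.4f}   {r.rise:.4f}")

rd, rn = results["diseased"], results["normal"]
print()
print(f"diseased peak exceeds normal peak: "
      f"{rd.peak_o_during_stress:.4f} > {rn.peak_o_during_stress:.4f} "
      f"= {rd.peak_o_during_stress > rn.peak_o_during_stress}")
print("The stressor shifts the c-nullcline enough that the diseased state")
print("falls off the lower branch and jumps toward the upper one, so the")
print("MORE-suppressed subject mounts the LARGER cortisol response.")
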