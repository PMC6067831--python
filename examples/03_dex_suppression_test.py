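"""In-silico dexamethasone suppression test (DST) from both basins.

Simulates the clinical protocol -- a 30-min DEX infusion (height 2 in
cortisol units), cortisol drawn 9 h later -- starting from each stable
state of the same parameter set, and reports the percentage suppression
s = 100*(pre - post)/pre plus the drop in the pituitary feedback factor fa.
"""
import hpaxis as hx
from hpaxis.challenge import dex_protocol

params = hx.REFERENCE
fps = hx.find_fixed_points(params)

print("basin      pre <o>   post o    s (%)   delta_fa   residual osc.")
for basin in ("normal", "diseased"):
    r = hx.run_dex_test(params, basin, fixed_points=fps)
    resid = r.post_oscillation_amplitude / r.pre_oscillation_amplitude
    print(f"{basin:9s}  {r.pre_o:7.4f}  {r.post_o:7.4f}  {r.s:6.2f}   "
          f"{r.delta_fa:7.4f}   {100 * resid:.3f}% of pre-DEX amplitude")

print()
print("Identical parameters, different basin: the low-cortisol (diseased)")
print("state is suppressed MORE -- the enhanced suppression seen clinically")
print("needs no enhanced feedback sensitivity, only bistability. The")
print("convex feedback fa makes an equal DEX increment bite harder at the")
print("lower operating point, and cortisol pulsatility ceases post-DEX.")

print("\npre-DEX measurement at the cortisol cycle peak instead of the cycle mean:")
for basin in ("normal", "diseased"):
    r = hx.run_dex_test(params, basin,
                        protocol=dex_protocol(measurement_mode="instantaneous"),
                        fixed_points=fps)
    print(f"  {basin:9s} s = {r.s:.2f}%")
print("The measured suppression depends on the oscillation phase at draw")
print("time, so DST timing should be phase-controlled in practice.")
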