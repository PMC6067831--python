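"""Cosyntropin (ACTH) stimulation test with adrenal hyporeactivity.

Compares a normal subject against one whose adrenal reactivity is reduced
by 10% (mapped onto the complex-coupling parameters p2, p4), dosing at
controlled phases of the intrinsic cortisol cycle.
"""
import numpy as np

import hpaxis as hx

params = hx.REFERENCE

sweeps = {lam: hx.phase_sweep_acth(params, lam, n_phases=8) for lam in (1.0, 0.9)}

for lam, results in sweeps.items():
    peaks = np.array([r.peak_o for r in results[:-1]])
    resp = np.array([r.peak_response for r in results[:-1]])
    label = "normal      " if lam == 1.0 else "hyporeactive"
    print(f"{label} (reactivity {lam}):")
    print(f"  baseline cycle mean <o>     {results[0].baseline_mean_o:.4f}")
    print(f"  peak o over dosing phases   min {peaks.min():.3f}  "
          f"max {peaks.max():.3f}  mean {peaks.mean():.3f}")
    print(f"  mean response over baseline {resp.mean():.4f}")

hypo_max = max(r.peak_o for r in sweeps[0.9][:-1])
norm_min = min(r.peak_o for r in sweeps[1.0][:-1])
print(f"\nbest-case hyporeactive peak {hypo_max:.3f} vs "
      f"worst-case normal peak {norm_min:.3f} "
      f"({100 * (hypo_max - norm_min) / norm_min:+.1f}%)")
print()
print("Hyporeactive adrenals RAISE baseline cortisol (the loop compensates)")
print("while the mean stimulated response is slightly lower. Because dosing")
print("phase moves the peak by more than the 10% reactivity deficit, an")
print("unmatched-phase comparison can invert the apparent group ordering --")
print("stimulation tests should phase-match the dose to the cortisol cycle.")
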