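"""Permeability ratio from reversal potentials in two external solutions.

Generates GHK-shaped I-V curves for a poorly selective channel
(p_Na/p_K = 0.59) in two K+/Na+ solutions, reads the reversal potential
off each curve, and recovers the permeability ratio with the
two-solution estimator -- the same workflow used on voltage-clamp ramps.
"""

import numpy as np

from girkperm import ephys, synthetic

r_true = 0.59
internal = (100.0, 10.0)  # [K]_i, [Na]_i (mM); cancels in the estimator
voltages = np.arange(-120.0, 50.5, 0.5)

v_revs = []
for k_o, na_o in ((8.0, 90.0), (72.0, 26.0)):
    iv = synthetic.generate_ghk_iv(r_true, k_o, na_o, *internal, voltages)
    v_rev = ephys.reversal_potential(iv)
    v_revs.append(v_rev)
    f_ir = ephys.rectification_index(iv, v_rev)
    print(f"{k_o:4.0f} mM K / {na_o:2.0f} mM Na : V_rev = {v_rev:7.2f} mV, F_ir = {f_ir:.2f}")

pair = ephys.SolutionPair(8.0, 90.0, 72.0, 26.0, v_revs[0], v_revs[1])
r = ephys.permeability_ratio_from_vrev(pair)
print(f"recovered p_Na/p_K = {r:.4f} (planted {r_true})")

# slope of V_rev against log10[K]_o: 58.17 mV/decade for a perfect K+
# electrode, strongly depressed when Na+ leaks through the filter
for label, rr in (("selective (r=0.0)", 0.0), (f"nonselective (r={r_true})", r_true)):
    pts = [(k, ephys.ghk_vrev(k, 98.0 - k, *internal, rr)) for k in (2.0, 8.0, 24.0, 72.0)]
    print(f"V_rev-log[K_o] slope, {label:24s}: {ephys.vrev_slope(pts):5.1f} mV/decade")
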