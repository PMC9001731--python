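"""Fit Hill dose-response curves for pore-blocker inhibition.

Generates noisy replicate dose-response tables for Ba2+-like block of a
basal (IC50 = 26 uM) and an activated (IC50 = 63 uM) channel and fits
each replicate; the shift in IC50 is the functional readout of altered
filter dynamics.
"""

import numpy as np

from girkperm import ephys, synthetic

doses = np.logspace(0, 3, 7)  # 1 .. 1000 uM
for label, h, ic50 in (("basal", 1.053, 26.0), ("activated", 0.98, 63.0)):
    reps = synthetic.generate_hill_dose_response(
        h, ic50, doses, noise_sd=2.0, n_replicates=25, seed=3
    )
    fits = [ephys.hill_fit(dr) for dr in reps]
    ic50s = np.array([f.ic50 for f in fits])
    hs = np.array([f.h for f in fits])
    print(
        f"{label:9s}: IC50 = {ic50s.mean():5.1f} +/- {ic50s.std():4.1f} uM "
        f"(true {ic50:4.1f}), h = {hs.mean():.3f} +/- {hs.std():.3f} (true {h})"
    )
# IC50 is the blocker concentration at half-maximal inhibition; the Hill
# slope h near 1 indicates non-cooperative single-site block.
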