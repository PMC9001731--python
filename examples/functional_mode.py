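"""Functional mode analysis on an ensemble with a planted coupled motion.

One collective displacement pattern is planted in a 10 000-frame
ensemble and linearly coupled (true correlation 0.73) to a scalar
functional quantity.  FMA regresses the functional series onto a
50-component PCA basis on the first 40% of frames and cross-validates on
the remaining 60%.
"""

import numpy as np

from girkperm import fma, synthetic
from girkperm.trajectory import select

spec = synthetic.CoupledEnsembleSpec(
    n_frames=10_000, n_atoms=100, target_correlation=0.73, seed=5
)
ens = synthetic.generate_coupled_ensemble(spec)
traj = ens.trajectory

basis = fma.pca_backbone(traj, select(traj, "all"), n_components=50)
mode = fma.fma_build(basis, traj, ens.functional, (0, 4000))
r_val, mi_val = fma.fma_cross_validate(mode, traj, ens.functional, (4000, 10_000))

print(f"R (build)        : {mode.r_build:.3f}")
print(f"R (validation)   : {r_val:.3f}   (planted correlation 0.73)")
print(f"MI (validation)  : {mi_val:.3f} nats")

# the ensemble-weighted MCM damps directions the ensemble barely explores,
# so it recovers the planted pattern much more cleanly than the raw MCM
cos_mcm = abs(mode.mcm_vector @ ens.mode_vector.ravel())
cos_ew = abs(mode.ewmcm_vector @ ens.mode_vector.ravel())
print(f"|cos(planted mode, MCM)|   = {cos_mcm:.3f}")
print(f"|cos(planted mode, ewMCM)| = {cos_ew:.3f}")

weights = fma.project_mode_on_structure(mode)
top = np.argsort(weights)[::-1][:3]
print(f"top ewMCM atoms  : {list(top)} with weights {np.round(weights[top], 3)}")
# A validated R well above the null shows the functional quantity is
# genuinely coupled to a collective motion; the per-atom weights locate
# the regions carrying that motion.
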