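# Methods

This note documents the models and procedures implemented in `girkperm`,
the defaults and conventions they use, the design choices that were
genuinely open, and what the synthetic-data validation does and does not
establish.

## Units and conventions

Lengths are Å, times ns (µs for pooled rates), voltages mV, currents nA
(negative = inward), concentrations mM, blocker doses µM.  The toy
trajectory format may declare nm; conversion happens at the I/O boundary
only.  Boxes are orthorhombic — the analyses only need the axial extent —
and triclinic inputs are rejected outright rather than silently
mis-handled.  +z is the extracellular (outward) direction; a flag on the
filter definition flips the convention.

## Selectivity-filter model and permeation events

The filter is represented by five carbonyl-oxygen planes, one per filter
residue, each plane being the mean z of that residue's backbone O over the
(typically four) chains, recomputed every frame.  Canonical binding sites
are the slabs between consecutive planes — S4 at the bottom up to S1, with
S0 above the top plane — and "in-plane" sites sit at the plane positions
themselves (half-width 0.5 Å by default).  The instantaneous pore axis is
the mean x,y of all filter carbonyls.

An ion's frame-wise compartment is *below* (z < bottom plane −
entry_margin), *above* (z > top plane + exit_margin), or *inside*;
inside additionally requires the ion to lie within `cylinder_radius` of
the pore axis — an ion passing beside the filter neither progresses nor
resets a traversal.  A completed outward permeation event is the ordered
sequence below→inside→above; inward is the reverse; incomplete excursions
count nothing.  Axial jumps larger than half the box height between frames
are treated as periodic wrap-around and reset the state machine.

Defaults: entry_margin = exit_margin = 1.0 Å (hysteresis against boundary
jitter double-counting) and cylinder_radius = 5.0 Å.  Neither value has an
experimental definition; both are configuration keys, and the margins are
deliberately larger than the toy generator's ion jitter (sd 0.3 Å) so that
planted events are unambiguous.

Pooled rates are events of a species/direction divided by total simulated
time across runs; per-run counts are also reported because run-to-run
heterogeneity is itself an observable.  The count-based selectivity ratio
is p_Na/p_K = n_Na/n_K with the reciprocal exposed alongside.

Block detection assigns each in-pore frame to a canonical or in-plane site
with a sticky hysteresis (0.5 Å beyond the site half-width): an ion keeps
its previous site label while it stays within tolerance, so jitter at a
boundary does not fragment a dwell.  Maximal single-site dwells of at
least `min_dwell` (default 50 ns; closed threshold) are reported with
their site label.

Occupancy profiles histogram in-cylinder ion z positions over a region
spanning the time-mean planes plus the margins; densities are mean counts
per bin per frame, so their sum equals the mean number of in-region ions —
an identity the tests check to 1e-12.

## Filter geometry

Opposing-subunit distances pair the sorted chains diagonally (A–C, B–D)
and average the two diagonals per frame; only chains carrying the queried
residue count toward the tetramer check, so solvent "chains" are ignored.
Minimum inter-residue distances enumerate heavy-atom pairs.  φ dihedrals
use the standard four-atom signed convention (verified against an
independent structural library); values are reported in (−180°, 180°].

Hydrogen bonds are geometric: a (donor, H, acceptor) triple counts when
H–A ≤ 2.5 Å, D–A ≤ 3.5 Å and the D–H–A angle is ≥ 120°.  All three
criteria are configuration keys.  The reported distance series is
explicitly the hydrogen–acceptor distance.  Donor hydrogens are found by
covalent proximity (≤ 1.25 Å) in the first frame; topologies without
hydrogens either raise an error or, if enabled, place a hydrogen 1.0 Å
from the donor along the donor→acceptor direction — a documented
approximation that makes the criterion effectively heavy-atom based.
"Water behind the filter" is defined geometrically as water oxygens within
6.0 Å of a selected sidechain oxygen while radially outside the pore
cylinder; the cutoff is configurable because no experimental definition
exists.

## Functional mode analysis

The trajectory is first rigid-body superposed (Kabsch) on the same
selection used for the analysis, then the flattened coordinates are
reduced by PCA (SVD of the centred data matrix; eigenvalues are covariance
variances in Å²).  Fifty components are retained by default, clipped with
a warning when rank-limited, and flexible residue ranges can be excluded
before the decomposition.  The functional quantity f(t) is regressed onto
the component projections by ordinary least squares over a build window;
on an orthonormal basis this is exactly the maximally-correlated-motion
formulation, so no iterative partial-least-squares scheme is needed.  The
fitted subspace, not the individual components, determines the prediction:
rotating the retained basis changes nothing (tested to 1e-8).

Two displacement vectors are exposed: the maximally correlated motion
Σβₖvₖ, and the ensemble-weighted MCM Σβₖλₖvₖ (both unit norm).  The
eigenvalue weighting damps directions the ensemble barely explores — in
synthetic recovery runs with a noisy functional series the ewMCM aligns
with the planted mode at |cos| ≈ 1.0 while the raw MCM carries visible
regression noise — and the per-atom magnitudes of the ewMCM (squared
weights summing to 1) are the per-atom correlation weights used for
structure colouring.  The ensemble weighting is stated here as this
package's definition of the term.

Cross-validation evaluates Pearson's R and mutual information between f
and the model prediction on a window disjoint from the build window.
Build/validation splits are expressed in time and converted to frame
indices; a 40/60 split is the default in the recovery experiments.

Mutual information uses an equal-width 2-D histogram with Miller–Madow
bias correction on each entropy.  The bin count per marginal defaults to
max(8, n^(1/3)): the more common Freedman–Diaconis count (still available
via `bins="fd"`) leaves the joint histogram so sparse that even the
corrected estimate of independent series carries ~0.04 nats of positive
bias at n = 10⁴, whereas the cube-root rule stays within ~0.005 nats of
the closed-form Gaussian value in the regimes tested.  A k-NN estimator
(scikit-learn) is available as an alternative.  MI(x, x) equals the
bias-corrected binned entropy of x; constant inputs return 0 with a
warning.

## Electrophysiology

Reversal potentials are the linearly interpolated zero crossing of the net
I–V curve (optional 5-point median pre-smoothing, off by default); no sign
change raises a range error and several raise an ambiguity error listing
the crossings.  Net curves are pointwise differences after interpolating
the reference onto the raw grid (exact subtraction when grids coincide),
restricted to the overlap; the subtraction mode (blocker-insensitive
residual vs naive-cell average) is recorded in the label.

F_ir divides the interpolated current 50 mV above V_rev by the current
50 mV below.  Since the two currents straddle the zero crossing with
opposite signs on any net curve, the index is reported as the magnitude
ratio: exactly 1 for an ohmic or odd-symmetric curve, ≪1 for an inward
rectifier, 0 for a fully suppressed outward limb, and an error rather
than ±∞ when the inward-limb current is below 1e-12 nA.

The decade slope s = RT/zF defaults to the constant 58.17 mV used in the
experiments this package models (strictly corresponding to ≈20 °C although
the recordings are described at 22 °C; the printed constant is followed
and exposed as a parameter).  The two-solution GHK estimator computes
A = 10^((V_rev(1)−V_rev(2))/s) and r = (A·K₂−K₁)/(Na₁−A·Na₂); internal
concentrations cancel exactly, a property the suite verifies to 1e-10 over
random solution pairs and r ∈ [0, 2].  Negative recovered r — possible
under measurement noise for nearly perfectly selective channels — is
returned with a warning rather than clamped, keeping cross-cell averages
unbiased.

Hill fits run nonlinear least squares in (log10 IC50, h) with the initial
IC50 at the dose nearest 50% inhibition, h = 1, and a few perturbed
restarts; the log parameterisation keeps IC50 positive and makes the fit
exactly scale-equivariant (tested to 1e-8).  Inhibition outside
[−10, 110]% is a data error, and fewer than three distinct concentrations
cannot constrain the two parameters.

## Synthetic data: what it emulates, and what it does not

The toy channel is a rigid four-fold scaffold: backbone N/CA/C pseudo-atoms
at an 8 Å chain radius with deliberately asymmetric offsets (so dihedrals
are well defined), carbonyl O atoms framing five planes 2 Å apart, a 2.5 Å
pore radius, optional serine hydroxyls (with explicit HG placed to donate
a ~1.8 Å H-bond to the carbonyl below) and explicit-hydrogen waters inside
or behind the filter.  Scripted ions perform axial walks: full traversals
are linear ramps with bounded Gaussian jitter (sd 0.3 Å, clipped at 3 sd)
forced monotone so each traversal crosses each boundary exactly once;
blocking dwells hold a site with tighter jitter; loiterers stay below the
filter.  Plane spacing, radii and jitter are package choices made so that
canonical and in-plane sites are geometrically distinguishable — none of
them is an experimental measurement.

The coupled ensemble is `base + a(t)·mode + isotropic thermal noise
(sd 0.1 Å)` with a(t) ~ N(0, 1 Å²) and f(t) = a(t) + ε(t), ε scaled so the
population corr(f, a) hits the requested target.  Thermal noise projects
onto the mode with sd 0.1 Å, so the best achievable cross-validated R is
≈ 0.995 × target — e.g. ≈ 0.726 at a target of 0.73, well within the
±0.05 recovery band.  Synthetic I–V curves are linear in driving force
around the closed-form GHK reversal potential, optionally shaped by a
logistic rectification factor that is a test device, not a biophysical
model.  Dose–response noise is additive Gaussian on the % scale, clipped
to [0, 100] — the simplest model supporting fit recovery.

All generators are pure functions of (spec, seed) and return their ground
truth alongside the data.  Passing the recovery suite therefore shows that
the estimators are correct and well calibrated on data satisfying their
assumptions; it does not show that real trajectories meet those
assumptions (force-field realism, multi-ion knock-on correlations,
non-Gaussian noise, drift within recordings are all absent from the
generators).  Real trajectory and oocyte data can be fed through the same
interfaces (toy format, PDB/GRO/XTC adapters, CSV tables), but results on
such data carry the usual caveats of the chosen cutoffs.

## Problem sizes in the recovery experiments

The selectivity benchmark pools six 1 µs segments at 1 ns/frame with 40
outward K⁺ and 1 outward Na⁺ traversal planted round-robin, the counts a
6.67 and 0.16 ions/µs process would produce in 6 µs.  Hill recovery uses
200 replicates of 7 log-spaced doses (1–1000 µM) with 2-percentage-point
noise.  FMA recovery uses 10 000-frame, 100-atom ensembles, a
50-component basis and a 40/60 build/validation split, averaged over 20
seeds in the acceptance script (6 in the faster test suite).  These sizes
were chosen as the smallest at which the estimators' sampling noise is
comfortably inside the stated recovery tolerances.

## Known limitations

* No PMF/free-energy computation, no classification of multi-ion
  conduction mechanisms, and no nonlinear (kernel) FMA variants.
* The event detector assumes ions are resolvable every frame; large
  temporal gaps only produce a warning.
* H-bond hydrogen placement (when enabled) is a crude geometric stand-in;
  use explicit-hydrogen topologies where possible.
* The CLI covers the common paths; compositions beyond it (e.g. custom
  functional quantities for FMA) are intended to be scripted against the
  library API, as in `examples/`.
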