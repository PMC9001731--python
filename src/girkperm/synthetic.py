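"""Synthetic data with planted ground truth.

Every analysis in this package is validated against data whose answer is
known by construction: toy channel trajectories with scripted ion walks
(full traversals, blocking dwells, loitering), ensembles with one planted
collective motion linearly coupled to a scalar functional quantity, GHK-
shaped I–V curves and Hill-shaped dose–response tables.

All generators are pure functions of (spec, seed): identical inputs give
bit-identical outputs.  Generators return their ground truth alongside the
data so recovery tests need no re-derivation.

The toy channel is a four-fold symmetric stand-in for a K+ channel
selectivity filter: five carbonyl-oxygen planes (ascending z, 2 Å apart by
default) frame the canonical ion binding sites S0 (above the top plane)
through S4 (between the two bottom planes); "in-plane" sites sit at the
plane z values themselves.  It makes no attempt at force-field realism —
its purpose is unambiguous planted events, not physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from girkperm.ephys import DoseResponse, IVCurve, ghk_vrev, hill_inhibition
from girkperm.errors import SpecError
from girkperm.trajectory import Topology, Trajectory

__all__ = [
    "ToyChannelSpec",
    "PlantedIonScript",
    "ToyGroundTruth",
    "CoupledEnsembleSpec",
    "CoupledEnsemble",
    "generate_toy_trajectory",
    "generate_coupled_ensemble",
    "generate_ghk_iv",
    "generate_hill_dose_response",
    "site_z_positions",
]

_ONE_LETTER = {"T": "THR", "I": "ILE", "G": "GLY", "Y": "TYR", "S": "SER", "A": "ALA"}


@dataclass(frozen=True)
class ToyChannelSpec:
    """Geometry and timing of the toy selectivity filter.

    ``plane_z`` are the five carbonyl-plane z positions (Å, ascending);
    ``filter_sequence`` gives one-letter residue identities for the five
    filter residues (``"TIGYG"`` wild-type-like, ``"TISYG"`` for the
    glycine→serine mutant; serines carry an explicit hydroxyl OG/HG pair).
    """

    n_chains: int = 4
    sf_residue_indices: tuple[int, ...] = (154, 155, 156, 157, 158)
    plane_z: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0)
    pore_radius: float = 2.5
    chain_radius: float = 8.0
    frame_interval: float = 1.0  # ns
    duration: float = 100.0  # ns
    seed: int = 0
    filter_sequence: str = "TIGYG"
    ion_jitter_sd: float = 0.3  # Å, bounded at 3 sd
    chain_jitter_sd: float = 0.0  # Å; 0 = rigid scaffold

    def __post_init__(self):
        if len(self.sf_residue_indices) != 5 or len(self.plane_z) != 5:
            raise SpecError("toy filter needs exactly 5 residues and 5 planes")
        if not np.all(np.diff(self.plane_z) > 0):
            raise SpecError("plane_z must be strictly increasing")
        if self.duration < self.frame_interval:
            raise SpecError("duration must be at least one frame interval")
        if len(self.filter_sequence) != 5:
            raise SpecError("filter_sequence must have 5 letters")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval


@dataclass(frozen=True)
class PlantedIonScript:
    """One scripted ion.  Traversals are monotone in z with bounded jitter.

    path_type: "traverse_out" (below→inside→above), "traverse_in" (the
    reverse), "block" (dwell at ``block_site``), or "loiter_below".
    """

    species: str  # "K" | "Na"
    path_type: str
    start_time: float  # ns
    end_time: float  # ns
    block_site: str | None = None  # e.g. "S3/S4 in-plane" or "S2"
    ion_id: int | None = None

    def __post_init__(self):
        if self.species not in ("K", "Na"):
            raise SpecError(f"unknown ion species {self.species!r}")
        if self.path_type not in ("traverse_out", "traverse_in", "block", "loiter_below"):
            raise SpecError(f"unknown path type {self.path_type!r}")
        if not self.start_time < self.end_time:
            raise SpecError("script start_time must precede end_time")
        if self.path_type == "block" and self.block_site is None:
            raise SpecError("block script needs a block_site label")


@dataclass
class ToyGroundTruth:
    """What was planted: per-species traversal counts and blocking dwells."""

    n_outward: dict[str, int] = field(default_factory=dict)
    n_inward: dict[str, int] = field(default_factory=dict)
    blocks: list[tuple[str, str, float, float]] = field(default_factory=list)
    ion_atom_ids: dict[int, int] = field(default_factory=dict)  # script index -> atom id


def site_z_positions(spec: ToyChannelSpec) -> dict[str, float]:
    """Representative z (Å) of every canonical and in-plane site label."""
    p = spec.plane_z
    sites = {
        "S4": 0.5 * (p[0] + p[1]),
        "S3": 0.5 * (p[1] + p[2]),
        "S2": 0.5 * (p[2] + p[3]),
        "S1": 0.5 * (p[3] + p[4]),
        "S0": p[4] + 1.0,
        "S4/cavity in-plane": p[0],
        "S3/S4 in-plane": p[1],
        "S2/S3 in-plane": p[2],
        "S1/S2 in-plane": p[3],
        "S0/S1 in-plane": p[4],
    }
    return sites


def _build_channel_topology(spec: ToyChannelSpec):
    """Static scaffold coordinates and the matching topology records."""
    names, elements, resnames, resids, chains, coords = [], [], [], [], [], []
    chain_labels = [chr(ord("A") + c) for c in range(spec.n_chains)]
    for c, chain in enumerate(chain_labels):
        theta = 2.0 * np.pi * c / spec.n_chains
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        perp = np.array([-np.sin(theta), np.cos(theta), 0.0])
        for k, resid in enumerate(spec.sf_residue_indices):
            letter = spec.filter_sequence[k]
            resname = _ONE_LETTER.get(letter, "UNK")
            z = spec.plane_z[k]
            ca = u * spec.chain_radius + np.array([0.0, 0.0, z])
            # asymmetric offsets keep consecutive backbone bonds
            # non-collinear so dihedrals are well defined
            atoms = [
                ("N", "N", ca - 0.6 * perp + 0.2 * u + np.array([0, 0, -0.7])),
                ("CA", "C", ca),
                ("C", "C", ca + 0.8 * perp - 0.3 * u + np.array([0, 0, 0.5])),
                # carbonyl O points into the pore: this is the atom whose z
                # defines the binding-site plane for this residue
                ("O", "O", u * (spec.pore_radius + 0.5) + np.array([0, 0, z])),
            ]
            if letter == "S":
                # hydroxyl placed ~2.8 Å from the carbonyl O of the residue
                # below, with HG on the O-H...O line: a donatable H-bond
                og = u * (spec.pore_radius + 2.5) + np.array([0, 0, z])
                target = u * (spec.pore_radius + 0.5) + np.array([0, 0, spec.plane_z[max(k - 1, 0)]])
                hdir = target - og
                hg = og + hdir / np.linalg.norm(hdir)
                atoms += [("OG", "O", og), ("HG", "H", hg)]
            for name, element, xyz in atoms:
                names.append(name)
                elements.append(element)
                resnames.append(resname)
                resids.append(resid)
                chains.append(chain)
                coords.append(xyz)
    return names, elements, resnames, resids, chains, coords


def _script_z_series(script, times, spec, rng):
    """Axial walk for one scripted ion; traversals are forced monotone."""
    p = spec.plane_z
    z_low = p[0] - 5.0
    z_high = p[4] + 5.0
    t0, t1 = script.start_time, script.end_time
    jit = rng.normal(0.0, spec.ion_jitter_sd, times.size)
    np.clip(jit, -3 * spec.ion_jitter_sd, 3 * spec.ion_jitter_sd, out=jit)
    if script.path_type in ("traverse_out", "traverse_in"):
        frac = np.clip((times - t0) / (t1 - t0), 0.0, 1.0)
        if script.path_type == "traverse_out":
            z = z_low + frac * (z_high - z_low) + jit
            return np.maximum.accumulate(z)  # monotone: exactly one crossing
        z = z_high - frac * (z_high - z_low) + jit
        return np.minimum.accumulate(z)
    if script.path_type == "block":
        sites = site_z_positions(spec)
        if script.block_site not in sites:
            raise SpecError(f"unknown block site {script.block_site!r}")
        # tighter bound during the dwell so the ion stays in its slab
        dwell_jit = np.clip(rng.normal(0.0, spec.ion_jitter_sd / 2.0, times.size), -0.45, 0.45)
        z = np.where((times >= t0) & (times <= t1), sites[script.block_site] + dwell_jit, z_low + jit)
        return z
    # loiter_below
    return z_low + jit


def generate_toy_trajectory(
    spec: ToyChannelSpec,
    scripts: list[PlantedIonScript],
    n_waters_in_sf: int = 0,
    waters_behind_sf: bool = False,
) -> tuple[Trajectory, ToyGroundTruth]:
    """Build a toy-channel trajectory realising the given ion scripts.

    Returns the trajectory and a :class:`ToyGroundTruth` with the planted
    traversal counts and blocking dwells.  Every "traverse_out" script
    yields exactly one ground-truth outward crossing by construction.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.times
    n_frames = times.size

    # reject overlapping scripts that claim the same ion id
    by_id: dict[int, list[PlantedIonScript]] = {}
    for s in scripts:
        if s.ion_id is not None:
            by_id.setdefault(s.ion_id, []).append(s)
        if s.end_time > spec.duration + 1e-9:
            raise SpecError(f"script ends at {s.end_time} ns, after the {spec.duration} ns duration")
    for ion_id, group in by_id.items():
        group = sorted(group, key=lambda s: s.start_time)
        for a, b in zip(group, group[1:]):
            if b.start_time < a.end_time:
                raise SpecError(f"overlapping scripts for ion id {ion_id}")

    names, elements, resnames, resids, chains, static = _build_channel_topology(spec)
    n_scaffold = len(names)

    truth = ToyGroundTruth(n_outward={"K": 0, "Na": 0}, n_inward={"K": 0, "Na": 0})
    ion_z = []
    for i, s in enumerate(scripts):
        ion_z.append(_script_z_series(s, times, spec, rng))
        atom_id = n_scaffold + i
        truth.ion_atom_ids[i] = atom_id
        if s.path_type == "traverse_out":
            truth.n_outward[s.species] += 1
        elif s.path_type == "traverse_in":
            truth.n_inward[s.species] += 1
        elif s.path_type == "block":
            truth.blocks.append((s.species, s.block_site, s.start_time, s.end_time))
        upper = s.species.upper()
        names.append(upper)
        elements.append(s.species)
        resnames.append(upper)
        resids.append(1000 + i)
        chains.append("I")

    water_static = []
    span0, span1 = spec.plane_z[0], spec.plane_z[4]
    for w in range(n_waters_in_sf):
        zw = span0 + (w + 1) * (span1 - span0) / (n_waters_in_sf + 1)
        o = np.array([0.0, 0.0, zw])
        water_static += [o, o + np.array([0.96, 0.0, 0.0]), o + np.array([-0.24, 0.93, 0.0])]
        for name, element in (("OW", "O"), ("HW1", "H"), ("HW2", "H")):
            names.append(name)
            elements.append(element)
            resnames.append("SOL")
            resids.append(2000 + w)
            chains.append("W")
    if waters_behind_sf:
        k_mid = 2
        z = spec.plane_z[k_mid]
        for c in range(spec.n_chains):
            theta = 2.0 * np.pi * c / spec.n_chains
            u = np.array([np.cos(theta), np.sin(theta), 0.0])
            # behind the filter: outside the pore cylinder, near the
            # middle-residue sidechain position, H pointing inward
            og = u * (spec.pore_radius + 2.5) + np.array([0.0, 0.0, z])
            o = og + u * 2.8
            h1 = o + (og - o) / np.linalg.norm(og - o) * 0.96
            h2 = o + np.array([0.0, 0.0, 0.96])
            water_static += [o, h1, h2]
            for name, element in (("OW", "O"), ("HW1", "H"), ("HW2", "H")):
                names.append(name)
                elements.append(element)
                resnames.append("SOL")
                resids.append(3000 + c)
                chains.append("W")

    top = Topology(tuple(names), tuple(elements), tuple(resnames), tuple(resids), tuple(chains))
    n_atoms = top.n_atoms
    coords = np.empty((n_frames, n_atoms, 3))

    scaffold = np.array(static)
    coords[:, :n_scaffold] = scaffold[None, :, :]
    if spec.chain_jitter_sd > 0:
        coords[:, :n_scaffold] += rng.normal(0.0, spec.chain_jitter_sd, (n_frames, n_scaffold, 3))

    for i in range(len(scripts)):
        col = n_scaffold + i
        xy = np.clip(rng.normal(0.0, spec.ion_jitter_sd, (n_frames, 2)), -1.5, 1.5)
        coords[:, col, 0] = xy[:, 0]
        coords[:, col, 1] = xy[:, 1]
        coords[:, col, 2] = ion_z[i]

    if water_static:
        wat = np.array(water_static)
        w0 = n_atoms - wat.shape[0]
        coords[:, w0:] = wat[None, :, :]
        coords[:, w0:] += np.clip(rng.normal(0.0, 0.1, (n_frames, wat.shape[0], 3)), -0.3, 0.3)

    z_extent = (span1 - span0) + 30.0
    box = np.tile(np.array([4 * spec.chain_radius, 4 * spec.chain_radius, z_extent]), (n_frames, 1))
    traj = Trajectory(top, coords, times, box)
    return traj, truth


def generate_selectivity_ensemble(
    n_k_traversals: int,
    n_na_traversals: int,
    n_segments: int = 6,
    segment_ns: float = 1000.0,
    frame_interval: float = 1.0,
    seed: int = 0,
) -> tuple[list[tuple[Trajectory, ToyGroundTruth]], float]:
    """Multi-segment ensemble with planted outward traversal counts.

    Emulates a pooled set of independent simulation runs: the requested
    outward K+ and Na+ traversals are distributed round-robin over
    ``n_segments`` segments of ``segment_ns`` each.  Returns the list of
    (trajectory, ground truth) pairs and the total simulated time in µs.
    """
    per_segment: list[list[PlantedIonScript]] = [[] for _ in range(n_segments)]
    order = [("K", i) for i in range(n_k_traversals)] + [("Na", i) for i in range(n_na_traversals)]
    counts = [0] * n_segments
    for k, (species, _) in enumerate(order):
        per_segment[k % n_segments].append((species, counts[k % n_segments]))
        counts[k % n_segments] += 1
    out = []
    for s, seg in enumerate(per_segment):
        n = max(len(seg), 1)
        window = segment_ns / n
        scripts = [
            PlantedIonScript(species, "traverse_out", slot * window + 0.02 * window, (slot + 0.9) * window)
            for species, slot in seg
        ]
        spec = ToyChannelSpec(
            duration=segment_ns, frame_interval=frame_interval, seed=seed * 1009 + s
        )
        out.append(generate_toy_trajectory(spec, scripts))
    return out, n_segments * segment_ns / 1000.0


# ---------------------------------------------------------------------------
# coupled ensemble (functional-mode-analysis ground truth)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoupledEnsembleSpec:
    """Ensemble with one planted collective mode coupled to a scalar.

    Frames are ``base + a(t) · mode + thermal noise`` with a(t) ~
    N(0, amplitude_sd²); the functional quantity is ``f(t) = a(t) + ε(t)``.
    Exactly one of ``noise_sd_functional`` and ``target_correlation`` sets
    the ε scale; ``target_correlation`` fixes the population corr(f, a).
    """

    n_frames: int
    n_atoms: int
    mode_vector: np.ndarray | None = None  # (n_atoms, 3), unit Frobenius norm
    amplitude_sd: float = 1.0  # Å
    noise_sd_functional: float | None = None
    target_correlation: float | None = None
    thermal_sd: float = 0.1  # Å
    seed: int = 0

    def __post_init__(self):
        given = (self.noise_sd_functional is not None) + (self.target_correlation is not None)
        if given != 1:
            raise SpecError("give exactly one of noise_sd_functional and target_correlation")
        if self.target_correlation is not None and not 0.0 < self.target_correlation <= 1.0:
            raise SpecError("target_correlation must lie in (0, 1]")
        if self.mode_vector is not None:
            mv = np.asarray(self.mode_vector, float)
            if mv.shape != (self.n_atoms, 3):
                raise SpecError("mode_vector must have shape (n_atoms, 3)")
            if abs(np.linalg.norm(mv) - 1.0) > 1e-8:
                raise SpecError("mode_vector must have unit norm")


@dataclass
class CoupledEnsemble:
    trajectory: Trajectory
    functional: np.ndarray  # per-frame scalar
    amplitudes: np.ndarray  # planted a(t)
    mode_vector: np.ndarray  # (n_atoms, 3) unit norm
    true_correlation: float  # population corr(f, a)


def generate_coupled_ensemble(spec: CoupledEnsembleSpec) -> CoupledEnsemble:
    """Generate frames with a planted mode and the coupled functional series."""
    rng = np.random.default_rng(spec.seed)
    base = rng.normal(0.0, 5.0, (spec.n_atoms, 3))
    if spec.mode_vector is None:
        mode = rng.normal(size=(spec.n_atoms, 3))
        mode /= np.linalg.norm(mode)
    else:
        mode = np.asarray(spec.mode_vector, float)
    a = rng.normal(0.0, spec.amplitude_sd, spec.n_frames)
    coords = base[None] + a[:, None, None] * mode[None] + rng.normal(
        0.0, spec.thermal_sd, (spec.n_frames, spec.n_atoms, 3)
    )
    if spec.target_correlation is not None:
        rho = spec.target_correlation
        eps_sd = 0.0 if rho == 1.0 else spec.amplitude_sd * np.sqrt(1.0 / rho**2 - 1.0)
        true_corr = rho
    else:
        eps_sd = spec.noise_sd_functional
        true_corr = spec.amplitude_sd / np.hypot(spec.amplitude_sd, eps_sd)
    functional = a + (rng.normal(0.0, eps_sd, spec.n_frames) if eps_sd > 0 else 0.0)

    names = tuple("CA" for _ in range(spec.n_atoms))
    top = Topology(
        names,
        tuple("C" for _ in range(spec.n_atoms)),
        tuple("ALA" for _ in range(spec.n_atoms)),
        tuple(range(spec.n_atoms)),
        tuple("A" for _ in range(spec.n_atoms)),
    )
    times = np.arange(spec.n_frames, dtype=float)
    box = np.tile(np.array([200.0, 200.0, 200.0]), (spec.n_frames, 1))
    traj = Trajectory(top, coords, times, box)
    return CoupledEnsemble(traj, functional, a, mode, true_corr)


# ---------------------------------------------------------------------------
# electrophysiology generators
# ---------------------------------------------------------------------------


def generate_ghk_iv(
    r: float,
    K_o: float,
    Na_o: float,
    K_i: float,
    Na_i: float,
    voltages: np.ndarray,
    current_scale: float = 1.0,
    rectification: str = "none",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IVCurve:
    """GHK-shaped I–V curve crossing zero at the closed-form reversal potential.

    ``rectification="inward"`` multiplies the driving force by a logistic
    factor of (V − V_rev) that suppresses the outward limb — a shape factor
    for testing the rectification index, with no biophysical claim.
    """
    if min(K_o, Na_o, K_i, Na_i) <= 0:
        raise SpecError("concentrations must be positive")
    voltages = np.asarray(voltages, float)
    v_rev = ghk_vrev(K_o, Na_o, K_i, Na_i, r)
    current = current_scale * (voltages - v_rev) / 50.0
    if rectification == "inward":
        current = current * 2.0 / (1.0 + np.exp((voltages - v_rev) / 20.0))
    elif rectification != "none":
        raise SpecError(f"unknown rectification tag {rectification!r}")
    if noise_sd > 0:
        current = current + np.random.default_rng(seed).normal(0.0, noise_sd, voltages.size)
    return IVCurve(
        voltage=voltages,
        current=current,
        solution=(K_o, Na_o),
        label=f"synthetic GHK r={r} {K_o:g}K/{Na_o:g}Na",
    )


def generate_hill_dose_response(
    h: float,
    ic50: float,
    doses,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[DoseResponse]:
    """Replicate dose–response tables: Hill curve plus clipped Gaussian noise."""
    doses = np.asarray(doses, float)
    if np.any(doses <= 0) or h <= 0 or ic50 <= 0:
        raise SpecError("doses, h and IC50 must all be positive")
    rng = np.random.default_rng(seed)
    clean = hill_inhibition(doses, h, ic50)
    out = []
    for rep in range(n_replicates):
        inh = clean + (rng.normal(0.0, noise_sd, doses.size) if noise_sd > 0 else 0.0)
        out.append(
            DoseResponse(
                concentration=doses,
                inhibition=np.clip(inh, 0.0, 100.0),
                label=f"synthetic Hill h={h} IC50={ic50} rep{rep}",
            )
        )
    return out
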