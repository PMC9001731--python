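"""Selectivity-filter geometry: inter-subunit distances, φ dihedrals, H-bonds.

All series are per-frame scalars with explicit units.  Distances are in Å;
dihedral angles follow the IUPAC sign convention and are reported in
degrees in (−180°, 180°].  Hydrogen-bond detection is geometric, with
configurable donor–hydrogen–acceptor criteria; the reported H-bond
distance is explicitly the hydrogen–acceptor (H–A) distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from girkperm.errors import DataError, DefinitionError
from girkperm.trajectory import AtomSelection, Trajectory, select

__all__ = [
    "GeometrySeries",
    "HBondCriteria",
    "opposing_ca_distance",
    "min_residue_distance",
    "phi_angle",
    "dihedral",
    "hbond_series",
    "histogram",
    "waters_behind_sf",
]


@dataclass
class GeometrySeries:
    """Per-frame scalar observable with a label and units."""

    values: np.ndarray
    label: str
    units: str
    times: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    Defaults: H–A ≤ 2.5 Å, donor–acceptor ≤ 3.5 Å, D–H–A angle ≥ 120°.
    """

    max_ha_distance: float = 2.5  # Å
    max_da_distance: float = 3.5  # Å
    min_dha_angle: float = 120.0  # degrees

    def __post_init__(self):
        if min(self.max_ha_distance, self.max_da_distance, self.min_dha_angle) <= 0:
            raise DataError("hydrogen-bond criteria must be positive")
        if self.max_ha_distance > self.max_da_distance:
            raise DataError("H-A cutoff cannot exceed D-A cutoff")


def _opposing_pairs(chains) -> list[tuple[str, str]]:
    chains = sorted(set(chains))
    if len(chains) != 4:
        raise DefinitionError(f"opposing-pair analysis needs a tetramer, got {len(chains)} chains")
    return [(chains[0], chains[2]), (chains[1], chains[3])]


def opposing_ca_distance(traj: Trajectory, residue_index: int, atom_name: str = "CA") -> GeometrySeries:
    """Mean of the two diagonal (opposing-subunit) atom distances per frame.

    In a four-fold channel, chains A–C and B–D face each other across the
    pore; the two diagonal distances are averaged.  Only chains that carry
    the residue/atom count toward the tetramer (solvent chains are ignored).
    """
    top = traj.topology
    carrying = [
        top.chain_ids[i]
        for i in range(top.n_atoms)
        if top.residue_indices[i] == residue_index and top.atom_names[i] == atom_name
    ]
    pairs = _opposing_pairs(carrying)
    dists = []
    for ca, cb in pairs:
        ids_a = select(traj, f"chain {ca} and resid {residue_index} and name {atom_name}").ids
        ids_b = select(traj, f"chain {cb} and resid {residue_index} and name {atom_name}").ids
        if len(ids_a) != 1 or len(ids_b) != 1:
            raise DefinitionError(
                f"residue {residue_index} atom {atom_name} not uniquely resolved on chains {ca}/{cb}"
            )
        d = np.linalg.norm(traj.coordinates[:, ids_a[0]] - traj.coordinates[:, ids_b[0]], axis=1)
        dists.append(d)
    return GeometrySeries(
        values=0.5 * (dists[0] + dists[1]),
        label=f"mean opposing {atom_name} distance, residue {residue_index}",
        units="Å",
        times=traj.times,
    )


def min_residue_distance(traj: Trajectory, residue_index: int, chain_pair: tuple[str, str]) -> GeometrySeries:
    """Per-frame minimum heavy-atom distance between the residue on two chains."""
    ca, cb = chain_pair
    elems = np.asarray(traj.topology.elements)
    ids_a = [i for i in select(traj, f"chain {ca} and resid {residue_index}").ids if elems[i] != "H"]
    ids_b = [i for i in select(traj, f"chain {cb} and resid {residue_index}").ids if elems[i] != "H"]
    if not ids_a or not ids_b:
        raise DefinitionError(f"residue {residue_index} missing on chain {ca} or {cb}")
    a = traj.coordinates[:, ids_a]  # (F, na, 3)
    b = traj.coordinates[:, ids_b]
    diff = a[:, :, None, :] - b[:, None, :, :]
    dmin = np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))
    return GeometrySeries(
        values=dmin,
        label=f"min heavy-atom distance, residue {residue_index}, chains {ca}-{cb}",
        units="Å",
        times=traj.times,
    )


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral (degrees) of four points, vectorised over frames."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - (b0 * b1n).sum(-1, keepdims=True) * b1n
    w = b2 - (b2 * b1n).sum(-1, keepdims=True) * b1n
    x = (v * w).sum(-1)
    y = (np.cross(b1n, v) * w).sum(-1)
    ang = np.degrees(np.arctan2(y, x))
    # report in (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


def phi_angle(traj: Trajectory, residue_index: int, chain: str) -> GeometrySeries:
    """Backbone φ dihedral C(i−1)–N(i)–CA(i)–C(i) per frame, degrees."""

    def one(resid, name):
        ids = select(traj, f"chain {chain} and resid {resid} and name {name}").ids
        if len(ids) != 1:
            raise DefinitionError(f"atom {name} of residue {resid} chain {chain} not uniquely resolved")
        return traj.coordinates[:, ids[0]]

    prev_c_ids = select(traj, f"chain {chain} and resid {residue_index - 1} and name C").ids
    if len(prev_c_ids) != 1:
        raise DefinitionError(
            f"φ undefined: residue {residue_index - 1} (preceding C) missing on chain {chain}"
        )
    p0 = traj.coordinates[:, prev_c_ids[0]]
    vals = dihedral(p0, one(residue_index, "N"), one(residue_index, "CA"), one(residue_index, "C"))
    return GeometrySeries(
        values=vals, label=f"φ residue {residue_index} chain {chain}", units="deg", times=traj.times
    )


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def _attached_hydrogens(traj: Trajectory, donor_id: int, frame: int = 0, cutoff: float = 1.25):
    """Hydrogens covalently bound to the donor, found geometrically in one frame."""
    top = traj.topology
    elems = np.asarray(top.elements)
    resid = top.residue_indices[donor_id]
    chain = top.chain_ids[donor_id]
    cand = [
        i
        for i in range(top.n_atoms)
        if elems[i] == "H" and top.residue_indices[i] == resid and top.chain_ids[i] == chain
    ]
    if not cand:
        return []
    d = np.linalg.norm(traj.coordinates[frame, cand] - traj.coordinates[frame, donor_id], axis=1)
    return [c for c, dd in zip(cand, d) if dd <= cutoff]


def hbond_series(
    traj: Trajectory,
    donor_selection: AtomSelection,
    acceptor_selection: AtomSelection,
    criteria: HBondCriteria = HBondCriteria(),
    place_missing_hydrogens: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Count (D, H, A) triples meeting all criteria, per frame.

    Returns ``(counts, min_ha_distance)``; the distance series is the
    per-frame minimum hydrogen–acceptor distance over all donor/acceptor
    pairs (NaN when a donor has no hydrogen candidates), suited to
    histogramming H-bond distance distributions.

    Donors without explicit hydrogens raise a configuration error unless
    ``place_missing_hydrogens`` is set, in which case a hydrogen is placed
    1.0 Å from the donor along the donor→acceptor direction (a documented
    approximation for hydrogen-free topologies).
    """
    donors = list(donor_selection.ids)
    acceptors = list(acceptor_selection.ids)
    if not donors or not acceptors:
        raise DataError("empty donor or acceptor selection")
    donor_h = {d: _attached_hydrogens(traj, d) for d in donors}
    if not place_missing_hydrogens:
        missing = [d for d, hs in donor_h.items() if not hs]
        if missing:
            raise DataError(
                f"donors {missing} carry no hydrogens; set place_missing_hydrogens=True "
                "to place one geometrically"
            )

    n_frames = traj.n_frames
    counts = np.zeros(n_frames, dtype=int)
    min_ha = np.full(n_frames, np.nan)
    cos_min = np.cos(np.radians(criteria.min_dha_angle))
    X = traj.coordinates
    for f in range(n_frames):
        best = np.inf
        n = 0
        for d in donors:
            dpos = X[f, d]
            for a in acceptors:
                if a == d:
                    continue
                apos = X[f, a]
                da = np.linalg.norm(apos - dpos)
                hs = donor_h[d]
                if not hs:  # geometric placement along D→A
                    hpos_list = [dpos + (apos - dpos) / da * 1.0] if da > 1e-9 else []
                else:
                    hpos_list = [X[f, h] for h in hs]
                for hpos in hpos_list:
                    ha = np.linalg.norm(apos - hpos)
                    best = min(best, ha)
                    if da > criteria.max_da_distance or ha > criteria.max_ha_distance:
                        continue
                    v1 = dpos - hpos
                    v2 = apos - hpos
                    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                    if denom < 1e-12:
                        continue
                    # D–H–A angle >= threshold  <=>  cos(angle at H) <= cos(threshold)
                    if (v1 @ v2) / denom <= cos_min:
                        n += 1
        counts[f] = n
        min_ha[f] = best if np.isfinite(best) else np.nan
    return counts, min_ha


def waters_behind_sf(
    traj: Trajectory,
    sidechain_oxygen: AtomSelection,
    pore_axis_xy: np.ndarray,
    pore_radius: float,
    cutoff: float = 6.0,
    water_resnames: tuple[str, ...] = ("SOL", "HOH", "WAT", "TIP3"),
) -> np.ndarray:
    """Per-frame count of waters near a sidechain oxygen but outside the pore.

    "Behind the filter" is defined geometrically: water oxygen within
    ``cutoff`` Å of any selected sidechain oxygen and radially outside the
    pore cylinder.
    """
    top = traj.topology
    names = np.asarray(top.atom_names).astype(str)
    resn = np.asarray(top.residue_names)
    wids = np.nonzero(np.isin(resn, water_resnames) & np.char.startswith(names, "O"))[0]
    counts = np.zeros(traj.n_frames, dtype=int)
    og = traj.coordinates[:, sidechain_oxygen.ids]  # (F, n_og, 3)
    for w in wids:
        wpos = traj.coordinates[:, w]
        near = (np.linalg.norm(og - wpos[:, None, :], axis=2) <= cutoff).any(axis=1)
        radial = np.linalg.norm(wpos[:, :2] - pore_axis_xy, axis=1)
        counts += (near & (radial > pore_radius)).astype(int)
    return counts


def histogram(series: GeometrySeries, bin_width: float, range_: tuple[float, float] | None = None):
    """Fixed-width histogram; total count equals the number of samples."""
    if bin_width <= 0:
        raise DataError("bin width must be positive")
    v = series.values
    lo, hi = range_ if range_ is not None else (v.min(), v.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(v, bins=edges)
    return 0.5 * (edges[:-1] + edges[1:]), counts
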