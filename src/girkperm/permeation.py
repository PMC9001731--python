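"""Permeation-event detection, rates, selectivity ratios, occupancy and block.

The selectivity filter is modelled as five carbonyl-oxygen planes (one per
filter residue, averaged over the four chains) stacked along z.  Canonical
binding sites sit between consecutive planes — S4 between the two bottom
planes up to S1 between the top two, with S0 above the top plane — and
"in-plane" sites sit at the plane z values themselves.

An ion permeates outward when its axial coordinate runs through the ordered
compartment sequence below → inside → above, where

* below:  z < bottom plane − entry_margin
* above:  z > top plane + exit_margin
* inside: in between, and within ``cylinder_radius`` of the pore axis
  (mean x, y of the carbonyl oxygens).

Re-entries that do not complete the sequence produce no event; periodic-
boundary jumps in z (|Δz| > box_z/2 between frames) reset the state machine
instead of counting as traversal.  +z is the extracellular/outward
direction by convention (flip ``outward_is_positive_z`` otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from girkperm.errors import DataError, DefinitionError
from girkperm.trajectory import AtomSelection, Trajectory, select

__all__ = [
    "SFDefinition",
    "SiteMap",
    "PermeationEvent",
    "OccupancyProfile",
    "BlockInterval",
    "PermeabilityRatio",
    "build_site_map",
    "detect_permeation_events",
    "permeation_rate",
    "permeability_ratio_from_counts",
    "occupancy_profile",
    "detect_block",
    "water_count_in_sf",
    "ion_selection",
]

_SITE_LABELS = ["S4", "S3", "S2", "S1"]  # slabs between planes 0-1 ... 3-4, bottom up


@dataclass
class SFDefinition:
    """Which residues form the filter and how the pore region is delimited."""

    residue_indices: tuple[int, ...]  # 5 filter residues, bottom to top
    cylinder_radius: float = 5.0  # Å around the instantaneous pore axis
    entry_margin: float = 1.0  # Å below the bottom plane
    exit_margin: float = 1.0  # Å above the top plane
    carbonyl_name: str = "O"
    outward_is_positive_z: bool = True

    def __post_init__(self):
        if len(self.residue_indices) != 5:
            raise DefinitionError("selectivity filter needs exactly 5 residues")

    def carbonyl_selection(self, traj: Trajectory, residue_index: int) -> AtomSelection:
        sel = select(traj, f"resid {residue_index} and name {self.carbonyl_name}")
        if len(sel) == 0:
            raise DefinitionError(f"no carbonyl atom ({self.carbonyl_name}) found for residue {residue_index}")
        return sel


@dataclass
class SiteMap:
    """Per-frame carbonyl-plane positions and derived site geometry."""

    plane_z: np.ndarray  # (n_frames, 5), mean carbonyl z per residue, ascending
    axis_xy: np.ndarray  # (n_frames, 2), mean carbonyl x,y (pore axis)
    sf: SFDefinition

    @property
    def bottom(self) -> np.ndarray:
        return self.plane_z[:, 0]

    @property
    def top(self) -> np.ndarray:
        return self.plane_z[:, -1]

    def slab_label(self, frame: int, z: float) -> str | None:
        """Canonical site containing z at this frame (S0 above the top plane)."""
        p = self.plane_z[frame]
        if z > p[-1]:
            return "S0" if z <= p[-1] + self.sf.exit_margin else None
        if z < p[0]:
            return None
        j = int(np.searchsorted(p, z, side="right")) - 1
        j = min(j, 3)
        return _SITE_LABELS[j]

    def in_plane_label(self, plane_index: int) -> str:
        if plane_index == 0:
            return "S4/cavity in-plane"
        return f"S{4 - plane_index}/S{5 - plane_index} in-plane"

    def site_centers(self, frame: int) -> dict[str, float]:
        """Representative z of every canonical and in-plane site label."""
        p = self.plane_z[frame]
        centers = {
            "S4": 0.5 * (p[0] + p[1]),
            "S3": 0.5 * (p[1] + p[2]),
            "S2": 0.5 * (p[2] + p[3]),
            "S1": 0.5 * (p[3] + p[4]),
            "S0": p[4] + 0.5 * self.sf.exit_margin,
        }
        for j in range(5):
            centers[self.in_plane_label(j)] = p[j]
        return centers


@dataclass(frozen=True)
class PermeationEvent:
    """One full traversal of one ion through the filter."""

    ion_id: int
    species: str
    direction: str  # "outward" | "inward"
    t_enter: float  # ns
    t_exit: float  # ns
    visited_sites: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.t_enter < self.t_exit:
            raise ValueError("t_enter must precede t_exit")


@dataclass
class OccupancyProfile:
    """Mean in-region ion count per z bin per frame."""

    z_bin_centers: np.ndarray  # Å
    density: dict[str, np.ndarray]  # species -> mean count per bin per frame
    region: tuple[float, float]  # Å
    site_centers: dict[str, float] = field(default_factory=dict)

    def integral(self, species: str) -> float:
        """Mean number of in-region ions per frame (conservation check)."""
        return float(self.density[species].sum())


@dataclass(frozen=True)
class BlockInterval:
    ion_id: int
    species: str
    site: str
    t_start: float  # ns
    t_end: float  # ns


@dataclass(frozen=True)
class PermeabilityRatio:
    """n_Na/n_K with its reciprocal; floats freely via ``float(...)``."""

    p_na_over_p_k: float
    p_k_over_p_na: float

    def __float__(self) -> float:
        return self.p_na_over_p_k


# ---------------------------------------------------------------------------
# site map
# ---------------------------------------------------------------------------


def build_site_map(traj: Trajectory, sf: SFDefinition) -> SiteMap:
    """Per-frame plane z = mean carbonyl z over chains, per filter residue."""
    plane_z = np.empty((traj.n_frames, 5))
    all_ids = []
    for k, resid in enumerate(sf.residue_indices):
        ids = sf.carbonyl_selection(traj, resid).ids
        all_ids.append(ids)
        plane_z[:, k] = traj.coordinates[:, ids, 2].mean(axis=1)
    if not np.all(np.diff(plane_z, axis=1) > 0):
        raise DefinitionError("carbonyl planes are not in ascending z order; check residue ordering")
    carbonyls = np.concatenate(all_ids)
    axis_xy = traj.coordinates[:, carbonyls, :2].mean(axis=1)
    return SiteMap(plane_z=plane_z, axis_xy=axis_xy, sf=sf)


def ion_selection(traj: Trajectory, species: str) -> AtomSelection:
    """Default ion selection by residue/atom name ("K" or "Na")."""
    return select(traj, f"resname {species.upper()}")


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

_BELOW, _INSIDE, _ABOVE, _LIMBO = 0, 1, 2, 3


def _compartments(traj, sitemap, atom_id):
    """Per-frame compartment of one ion: below / inside / above / limbo.

    "limbo" marks frames in the filter z-range but radially outside the
    pore cylinder; the state machine ignores them (ion passing beside the
    filter must not progress the traversal sequence).
    """
    z = traj.coordinates[:, atom_id, 2]
    xy = traj.coordinates[:, atom_id, :2]
    sf = sitemap.sf
    lo = sitemap.bottom - sf.entry_margin
    hi = sitemap.top + sf.exit_margin
    radial = np.linalg.norm(xy - sitemap.axis_xy, axis=1)
    comp = np.full(traj.n_frames, _INSIDE, dtype=int)
    comp[z < lo] = _BELOW
    comp[z > hi] = _ABOVE
    comp[(comp == _INSIDE) & (radial > sf.cylinder_radius)] = _LIMBO
    return comp, z


def detect_permeation_events(
    traj: Trajectory,
    sf: SFDefinition,
    species_selections: dict[str, AtomSelection] | None = None,
    max_frame_gap: float | None = None,
) -> list[PermeationEvent]:
    """Three-compartment state machine per ion on the axial coordinate.

    ``species_selections`` maps species name to the ions to track; by
    default K+ and Na+ ions are found by residue name.  An outward event
    is the completed sequence below→inside→above, an inward event the
    reverse; incomplete excursions yield nothing.
    """
    sitemap = build_site_map(traj, sf)
    if species_selections is None:
        species_selections = {}
        for sp in ("K", "Na"):
            sel = ion_selection(traj, sp)
            if len(sel):
                species_selections[sp] = sel

    if max_frame_gap is not None and traj.n_frames > 1:
        gaps = np.diff(traj.times)
        if np.any(gaps > max_frame_gap):
            warnings.warn(
                f"frame gap up to {gaps.max():.3g} ns exceeds max_frame_gap={max_frame_gap}; "
                "events spanning the gap may be missed",
                stacklevel=2,
            )

    box_z = traj.box[:, 2]
    events: list[PermeationEvent] = []
    for species, selection in species_selections.items():
        for atom_id in selection.ids:
            comp, z = _compartments(traj, sitemap, int(atom_id))
            # wrap-around: a |dz| > box_z/2 jump is periodic imaging, not traversal
            wrap = np.zeros(traj.n_frames, dtype=bool)
            if traj.n_frames > 1:
                wrap[1:] = np.abs(np.diff(z)) > box_z[1:] / 2.0
            state = None  # compartment the sequence last progressed from
            t_enter = None
            visited: list[str] = []
            direction = None
            entered_from = None
            for f in range(traj.n_frames):
                c = comp[f]
                if wrap[f]:
                    state, t_enter, visited, direction = (c if c != _LIMBO else None), None, [], None
                    continue
                if c == _LIMBO:
                    continue
                if c == _INSIDE:
                    if state in (_BELOW, _ABOVE):
                        t_enter = traj.times[f]
                        came_from_below = state == _BELOW
                        # moving up is outward under the +z convention
                        direction = (
                            "outward" if came_from_below == sf.outward_is_positive_z else "inward"
                        )
                        visited = []
                        state = _INSIDE
                        entered_from = _BELOW if came_from_below else _ABOVE
                    if state == _INSIDE and t_enter is not None:
                        lab = sitemap.slab_label(f, z[f])
                        if lab is not None and (not visited or visited[-1] != lab):
                            visited.append(lab)
                    continue
                # c is below or above
                if state == _INSIDE and t_enter is not None and direction is not None:
                    if c != entered_from:  # sequence completed on the far side
                        events.append(
                            PermeationEvent(
                                ion_id=int(atom_id),
                                species=species,
                                direction=direction,
                                t_enter=float(t_enter),
                                t_exit=float(traj.times[f]),
                                visited_sites=tuple(visited),
                            )
                        )
                state, t_enter, visited, direction = c, None, [], None
    events.sort(key=lambda e: (e.t_exit, e.ion_id))
    return events


def permeation_rate(events, total_time_us: float, species: str, direction: str = "outward") -> float:
    """Pooled event rate in ions/µs: matching events / total simulated time."""
    if total_time_us <= 0:
        raise DataError("total_time must be positive")
    n = sum(1 for e in events if e.species == species and e.direction == direction)
    return n / total_time_us


def permeability_ratio_from_counts(n_na: int, n_k: int) -> PermeabilityRatio:
    """Selectivity ratio p_Na/p_K = n_Na/n_K from pooled traversal counts."""
    if n_k == 0:
        raise DataError("p_Na/p_K undefined with zero K+ events")
    r = n_na / n_k
    return PermeabilityRatio(p_na_over_p_k=r, p_k_over_p_na=np.inf if n_na == 0 else n_k / n_na)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------


def occupancy_profile(
    traj: Trajectory,
    sf: SFDefinition,
    species: tuple[str, ...] = ("K", "Na"),
    z_bin_width: float = 0.25,
) -> OccupancyProfile:
    """Histogram of in-cylinder ion axial positions, mean count/bin/frame.

    The region spans [bottom plane − entry_margin, top plane + exit_margin]
    using time-mean plane positions; densities sum to the mean number of
    in-region ions per frame (conservation).
    """
    if z_bin_width <= 0:
        raise DataError("bin width must be positive")
    sitemap = build_site_map(traj, sf)
    lo = float(sitemap.bottom.mean() - sf.entry_margin)
    hi = float(sitemap.top.mean() + sf.exit_margin)
    n_bins = max(1, int(np.ceil((hi - lo) / z_bin_width)))
    edges = lo + np.arange(n_bins + 1) * z_bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])

    density: dict[str, np.ndarray] = {}
    for sp in species:
        sel = ion_selection(traj, sp)
        zs = []
        for atom_id in sel.ids:
            z = traj.coordinates[:, atom_id, 2]
            radial = np.linalg.norm(traj.coordinates[:, atom_id, :2] - sitemap.axis_xy, axis=1)
            inside = (z >= lo) & (z <= edges[-1]) & (radial <= sf.cylinder_radius)
            zs.append(z[inside])
        pooled = np.concatenate(zs) if zs else np.empty(0)
        counts, _ = np.histogram(pooled, bins=edges)
        density[sp] = counts / traj.n_frames
    mean_planes = sitemap.plane_z.mean(axis=0)
    static = SiteMap(plane_z=mean_planes[None, :], axis_xy=np.zeros((1, 2)), sf=sf)
    return OccupancyProfile(
        z_bin_centers=centers,
        density=density,
        region=(lo, float(edges[-1])),
        site_centers=static.site_centers(0),
    )


# ---------------------------------------------------------------------------
# block detection
# ---------------------------------------------------------------------------


def _site_assignment(z, sitemap, frame_idx, in_plane_halfwidth, hysteresis):
    """Per-frame site label (canonical or in-plane) with sticky hysteresis."""
    labels = []
    prev = None
    for f, zf in zip(frame_idx, z):
        centers = sitemap.site_centers(f)
        # stickiness: keep the previous label while still within tolerance
        if prev is not None:
            half = in_plane_halfwidth if "in-plane" in prev else 1.0
            if abs(zf - centers[prev]) <= half + hysteresis:
                labels.append(prev)
                continue
        p = sitemap.plane_z[f]
        lab = None
        d_plane = np.abs(p - zf)
        j = int(np.argmin(d_plane))
        if d_plane[j] <= in_plane_halfwidth:
            lab = sitemap.in_plane_label(j)
        else:
            lab = sitemap.slab_label(f, zf)
        labels.append(lab)
        prev = lab
    return labels


def detect_block(
    traj: Trajectory,
    sf: SFDefinition,
    species: str,
    min_dwell: float = 50.0,
    in_plane_halfwidth: float = 0.5,
    hysteresis: float = 0.5,
) -> list[BlockInterval]:
    """Maximal intervals an ion stays in one site for at least ``min_dwell`` ns.

    Sites include the canonical slabs S0–S4 and the in-plane positions at
    the carbonyl planes (band half-width ``in_plane_halfwidth`` Å); the
    sticky ``hysteresis`` tolerance prevents boundary jitter from cutting
    a dwell.  The threshold is closed: a dwell of exactly ``min_dwell``
    is reported.
    """
    sitemap = build_site_map(traj, sf)
    sel = ion_selection(traj, species)
    frames = np.arange(traj.n_frames)
    out: list[BlockInterval] = []
    for atom_id in sel.ids:
        z = traj.coordinates[:, atom_id, 2]
        radial = np.linalg.norm(traj.coordinates[:, atom_id, :2] - sitemap.axis_xy, axis=1)
        labels = _site_assignment(z, sitemap, frames, in_plane_halfwidth, hysteresis)
        for f in range(traj.n_frames):
            if radial[f] > sf.cylinder_radius:
                labels[f] = None
        start = 0
        for f in range(1, traj.n_frames + 1):
            if f == traj.n_frames or labels[f] != labels[start]:
                lab = labels[start]
                if lab is not None:
                    t0, t1 = traj.times[start], traj.times[f - 1]
                    if t1 - t0 >= min_dwell - 1e-9:
                        out.append(BlockInterval(int(atom_id), species, lab, float(t0), float(t1)))
                start = f
    out.sort(key=lambda b: (b.t_start, b.ion_id))
    return out


# ---------------------------------------------------------------------------
# water
# ---------------------------------------------------------------------------


def water_count_in_sf(
    traj: Trajectory,
    sf: SFDefinition,
    water_resnames: tuple[str, ...] = ("SOL", "HOH", "WAT", "TIP3"),
) -> np.ndarray:
    """Per-frame count of water oxygens inside the filter cylinder."""
    sitemap = build_site_map(traj, sf)
    top = traj.topology
    names = np.asarray(top.atom_names)
    resn = np.asarray(top.residue_names)
    ids = np.nonzero(np.isin(resn, water_resnames) & np.char.startswith(names.astype(str), "O"))[0]
    counts = np.zeros(traj.n_frames, dtype=int)
    for atom_id in ids:
        z = traj.coordinates[:, atom_id, 2]
        radial = np.linalg.norm(traj.coordinates[:, atom_id, :2] - sitemap.axis_xy, axis=1)
        inside = (z >= sitemap.bottom) & (z <= sitemap.top) & (radial <= sf.cylinder_radius)
        counts += inside.astype(int)
    return counts
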