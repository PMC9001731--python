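"""Trajectory data model, toy-format I/O, atom selections and superposition.

Internal units are Angstrom for lengths and nanoseconds for time throughout
the package; converters are applied only at I/O boundaries.  Boxes are
orthorhombic (the analyses only ever need the axial extent); triclinic
inputs are rejected.

The plain-text toy trajectory format::

    natoms N
    unit ang            # or "nm"; nm coordinates/boxes are converted x10
    <N topology lines>  # id name element resname resid chain
    frame t=<ns> box=<Lx,Ly,Lz>
    <N coordinate lines "x y z">
    ...                 # further frames

Optional adapters from MDAnalysis Universes are provided for standard
formats (PDB/GRO/XTC); they produce the same :class:`Trajectory` type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from girkperm.errors import DegeneracyError, ParseError, SelectionError

__all__ = [
    "Topology",
    "Trajectory",
    "AtomSelection",
    "read_toy_trajectory",
    "write_toy_trajectory",
    "select",
    "superpose",
    "kabsch_rotation",
]


@dataclass(frozen=True)
class Topology:
    """Ordered atom records; ``atom_id`` is the 0-based position in the arrays."""

    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    residue_names: tuple[str, ...]
    residue_indices: tuple[int, ...]
    chain_ids: tuple[str, ...]

    def __post_init__(self):
        n = len(self.atom_names)
        for f in ("elements", "residue_names", "residue_indices", "chain_ids"):
            if len(getattr(self, f)) != n:
                raise ValueError(f"topology field {f!r} length mismatch")
        triples = set(zip(self.chain_ids, self.residue_indices, self.atom_names))
        if len(triples) != n:
            raise ValueError("duplicate (chain, resid, atom name) triple in topology")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_chains(self) -> int:
        return len(set(self.chain_ids))

    @property
    def chains(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.chain_ids)))


@dataclass
class Trajectory:
    """Topology plus per-frame coordinates (Å), times (ns) and box lengths (Å)."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3), Å
    times: np.ndarray  # (n_frames,), ns, strictly increasing
    box: np.ndarray  # (n_frames, 3), Å, orthorhombic lengths

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate array has {self.coordinates.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.times.shape != (self.n_frames,):
            raise ValueError("times length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.box.shape != (self.n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if not np.all(self.box > 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


@dataclass(frozen=True)
class AtomSelection:
    """A selection expression resolved against a fixed topology."""

    expression: str
    resolved_ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.resolved_ids)

    @property
    def ids(self) -> np.ndarray:
        return np.asarray(self.resolved_ids, dtype=int)


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

_FIELDS = {
    "chain": "chain_ids",
    "resid": "residue_indices",
    "resname": "residue_names",
    "name": "atom_names",
    "element": "elements",
}


def _clause_mask(top: Topology, tokens: list[str]) -> np.ndarray:
    key, values = tokens[0], tokens[1:]
    if key not in _FIELDS or not values:
        raise SelectionError(f"invalid selection clause: {' '.join(tokens)!r}")
    col = np.asarray(getattr(top, _FIELDS[key]))
    mask = np.zeros(top.n_atoms, dtype=bool)
    for v in values:
        if key == "resid":
            if "-" in v[1:]:  # range "lo-hi"; leading "-" of a negative index is not a separator
                cut = v.index("-", 1)
                lo, hi = v[:cut], v[cut + 1 :]
            else:
                lo = hi = v
            try:
                lo_i, hi_i = int(lo), int(hi)
            except ValueError as exc:
                raise SelectionError(f"invalid resid value {v!r}") from exc
            ints = col.astype(int)
            mask |= (ints >= lo_i) & (ints <= hi_i)
        else:
            mask |= col == v
    return mask


def select(traj: Trajectory | Topology, expression: str) -> AtomSelection:
    """Resolve a selection like ``"chain A and resid 155 and name CA"``.

    Clauses joined by ``and`` intersect; within a clause multiple values
    (``name CA CB``) union, and ``resid`` accepts ``lo-hi`` ranges.  The
    special expression ``all`` selects every atom.  Resolution is
    deterministic (ascending atom id) and an empty result is not an error.
    """
    top = traj.topology if isinstance(traj, Trajectory) else traj
    expr = expression.strip()
    if not expr:
        raise SelectionError("empty selection expression")
    if expr == "all":
        mask = np.ones(top.n_atoms, dtype=bool)
    else:
        mask = np.ones(top.n_atoms, dtype=bool)
        for part in expr.split(" and "):
            tokens = part.split()
            if not tokens:
                raise SelectionError(f"empty clause in expression {expression!r}")
            mask &= _clause_mask(top, tokens)
    ids = tuple(int(i) for i in np.nonzero(mask)[0])
    return AtomSelection(expression=expression, resolved_ids=ids)


# ---------------------------------------------------------------------------
# toy format I/O
# ---------------------------------------------------------------------------


def write_toy_trajectory(traj: Trajectory, path) -> None:
    """Write the toy plain-text format (always in Å) with full precision."""
    top = traj.topology
    with open(path, "w") as fh:
        fh.write(f"natoms {top.n_atoms}\n")
        fh.write("unit ang\n")
        for i in range(top.n_atoms):
            fh.write(
                f"{i} {top.atom_names[i]} {top.elements[i]} "
                f"{top.residue_names[i]} {top.residue_indices[i]} {top.chain_ids[i]}\n"
            )
        for f in range(traj.n_frames):
            bx = ",".join(repr(float(v)) for v in traj.box[f])
            fh.write(f"frame t={float(traj.times[f])!r} box={bx}\n")
            for xyz in traj.coordinates[f]:
                fh.write(" ".join(repr(float(v)) for v in xyz) + "\n")


def read_toy_trajectory(path) -> Trajectory:
    """Parse the toy format; errors name the 1-based offending line."""
    with open(path) as fh:
        lines = fh.read().splitlines()

    def err(lineno, msg):
        raise ParseError(f"{path}, line {lineno}: {msg}")

    if not lines or not lines[0].startswith("natoms "):
        err(1, "expected 'natoms N' header")
    try:
        n_atoms = int(lines[0].split()[1])
    except (IndexError, ValueError):
        err(1, "unparseable atom count")
    if len(lines) < 2 or not lines[1].startswith("unit "):
        err(2, "expected 'unit ang|nm' header")
    unit = lines[1].split()[1]
    if unit not in ("ang", "nm"):
        err(2, f"unknown unit {unit!r}")
    scale = 10.0 if unit == "nm" else 1.0

    names, elements, resnames, resids, chains = [], [], [], [], []
    for k in range(n_atoms):
        lineno = 3 + k
        if lineno - 1 >= len(lines):
            err(lineno, "truncated topology block")
        tok = lines[lineno - 1].split()
        if len(tok) != 6:
            err(lineno, f"expected 6 topology fields, got {len(tok)}")
        try:
            atom_id = int(tok[0])
        except ValueError:
            err(lineno, f"bad atom id {tok[0]!r}")
        if atom_id != k:
            err(lineno, f"atom ids must be contiguous from 0; got {atom_id}, expected {k}")
        names.append(tok[1])
        elements.append(tok[2])
        resnames.append(tok[3])
        try:
            resids.append(int(tok[4]))
        except ValueError:
            err(lineno, f"bad residue index {tok[4]!r}")
        chains.append(tok[5])
    top = Topology(tuple(names), tuple(elements), tuple(resnames), tuple(resids), tuple(chains))

    frames, times, boxes = [], [], []
    i = 2 + n_atoms
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        lineno = i + 1
        if not line.startswith("frame "):
            err(lineno, f"expected frame header, got {line!r}")
        try:
            fields = dict(tok.split("=", 1) for tok in line.split()[1:])
            t = float(fields["t"])
            box = [float(v) * scale for v in fields["box"].split(",")]
        except (ValueError, KeyError) as exc:
            err(lineno, f"malformed frame header ({exc})")
        if len(box) != 3:
            err(lineno, "box must list 3 orthorhombic lengths; triclinic boxes are not supported")
        coords = np.empty((n_atoms, 3))
        for k in range(n_atoms):
            j = i + 1 + k
            if j >= len(lines) or lines[j].startswith("frame "):
                err(j + 1, f"frame at line {lineno} lists fewer than {n_atoms} atoms")
            tok = lines[j].split()
            if len(tok) != 3:
                err(j + 1, f"expected 3 coordinates, got {len(tok)}")
            try:
                coords[k] = [float(v) for v in tok]
            except ValueError:
                err(j + 1, "unparseable coordinate")
        if times and t <= times[-1]:
            err(lineno, f"non-monotonic frame time {t} after {times[-1]}")
        frames.append(coords * scale)
        times.append(t)
        boxes.append(box)
        i += 1 + n_atoms
    if not frames:
        err(len(lines) + 1, "trajectory contains no frames")
    return Trajectory(top, np.array(frames), np.array(times), np.array(boxes))


def from_mdanalysis(universe, in_nm: bool = False) -> Trajectory:
    """Adapter: build a :class:`Trajectory` from an MDAnalysis Universe.

    Pass-through reader for standard formats (PDB topology + GRO/XTC
    coordinates).  Not required by any analysis; provided for convenience
    when applying the pipeline to deposited simulation data.
    """
    ag = universe.atoms
    top = Topology(
        tuple(ag.names),
        tuple(getattr(ag, "elements", [n[0] for n in ag.names])),
        tuple(ag.resnames),
        tuple(int(r) for r in ag.resids),
        tuple(getattr(ag, "chainIDs", ag.segids)),
    )
    scale = 10.0 if in_nm else 1.0  # MDAnalysis already reports Å by default
    coords, times, boxes = [], [], []
    for ts in universe.trajectory:
        coords.append(ag.positions.copy() * scale)
        times.append(ts.time / 1000.0)  # ps → ns
        if ts.dimensions is None or np.any(np.abs(ts.dimensions[3:] - 90.0) > 1e-3):
            raise ValueError("only orthorhombic boxes are supported")
        boxes.append(ts.dimensions[:3] * scale)
    return Trajectory(top, np.array(coords), np.array(times), np.array(boxes))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Proper rotation matrix R minimising ||mobile @ R.T - reference||.

    Both inputs must already be centred on their centroids.
    """
    H = mobile.T @ reference
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(traj: Trajectory, reference_frame: int, fit_selection: AtomSelection) -> Trajectory:
    """Rigid-body least-squares superposition of every frame onto a reference.

    Each frame is translated and rotated so the RMSD of ``fit_selection``
    to the reference frame is minimal; the transform is applied to all
    atoms.  The fit set must contain at least 3 non-collinear atoms.
    """
    ids = fit_selection.ids
    if len(ids) < 3:
        raise DegeneracyError("superposition needs at least 3 fit atoms")
    ref = traj.coordinates[reference_frame, ids]
    ref_c = ref - ref.mean(axis=0)
    # rank < 2 means collinear or coincident points: rotation underdetermined
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise DegeneracyError("fit selection is collinear or coincident in the reference frame")
    ref_centroid = ref.mean(axis=0)
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        mob = traj.coordinates[f, ids]
        mob_centroid = mob.mean(axis=0)
        R = kabsch_rotation(mob - mob_centroid, ref_c)
        out[f] = (traj.coordinates[f] - mob_centroid) @ R.T + ref_centroid
    return replace(traj, coordinates=out)
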