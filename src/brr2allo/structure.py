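"""Topology and trajectory containers plus PDB / binary-format readers.

Residue identity is ``(chain_id, author_residue_number)`` with the 1-based
author numbering preserved everywhere, so residues referenced in the Brr2
literature (G506, G1353, E616, ...) resolve unchanged.  The native
text-fixture format is multi-model PDB; DCD/XTC-class binary trajectories
are read through mdtraj behind the same surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "Topology",
    "Trajectory",
    "read_structure",
    "read_trajectory",
    "write_trajectory_pdb",
    "covalent_adjacency",
    "infer_hbond_participants",
]

Residue = tuple[str, int]  # (chain id, author residue number)


@dataclass
class Topology:
    """Static atom/residue description of a structure.

    ``bonds`` holds covalent atom-index pairs (from CONECT records and
    inferred donor-hydrogen bonds).  ``donors`` is a list of
    (heavy-donor, hydrogen) atom-index pairs, ``acceptors`` a list of
    heavy-atom indices; both are populated by
    :func:`infer_hbond_participants`.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    bonds: set[tuple[int, int]] = field(default_factory=set)
    donors: list[tuple[int, int]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residues(self) -> list[Residue]:
        """Unique residues in file order."""
        seen: dict[Residue, None] = {}
        for c, r in zip(self.chain_ids, self.res_ids):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def residue_of(self, atom_index: int) -> Residue:
        return (str(self.chain_ids[atom_index]), int(self.res_ids[atom_index]))

    def atom_indices(self, chain: str, res_id: int, name: str | None = None) -> np.ndarray:
        mask = (self.chain_ids == chain) & (self.res_ids == res_id)
        if name is not None:
            mask &= self.atom_names == name
        return np.flatnonzero(mask)


@dataclass
class Trajectory:
    """Multi-frame coordinate set bound to a Topology.

    Coordinates are in Angstrom, frame times in ns.  ``window`` is the
    (start, end) time span, inclusive, used by occupancy and flexibility
    analyses; it defaults to the final half of the total time.
    """

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # ns
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)"
            )
        if len(self.times) != len(self.coords):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.window is None:
            self.window = (float(self.times[len(self.times) // 2]), float(self.times[-1]))

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def window_frames(self, window: tuple[float, float] | None = None) -> np.ndarray:
        """Indices of frames inside the analysis window."""
        w = window or self.window
        if w[0] < self.times[0] - 1e-9 or w[1] > self.times[-1] + 1e-9:
            raise ValueError(
                f"window {w} outside trajectory time range "
                f"[{self.times[0]}, {self.times[-1]}] ns"
            )
        idx = np.flatnonzero((self.times >= w[0] - 1e-12) & (self.times <= w[1] + 1e-12))
        if idx.size == 0:
            raise ValueError(f"no frames in window {w}")
        return idx


def _structure_to_topology(atoms: struc.AtomArray, conect: set[tuple[int, int]]) -> Topology:
    elements = np.array([e.strip() for e in atoms.element], dtype="U2")
    missing = elements == ""
    if missing.any():
        warnings.warn(
            f"{missing.sum()} atoms lack element records; inferring from atom names",
            stacklevel=3,
        )
        inferred = np.array(
            [n.strip()[:1] if n.strip()[:1].isalpha() else n.strip()[1:2]
             for n in atoms.atom_name],
            dtype="U2",
        )
        elements = np.where(missing, inferred, elements)
    return Topology(
        atom_names=np.array(atoms.atom_name, dtype="U6"),
        elements=elements,
        chain_ids=np.array(atoms.chain_id, dtype="U4"),
        res_ids=np.array(atoms.res_id, dtype=int),
        res_names=np.array(atoms.res_name, dtype="U5"),
        bonds=conect,
    )


def _parse_conect(path: Path) -> dict[int, set[int]]:
    """CONECT records as serial -> set of bonded serials."""
    out: dict[int, set[int]] = {}
    for line in path.read_text().splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = [line[i : i + 5].strip() for i in range(6, len(line.rstrip()), 5)]
        serials = [int(f) for f in fields if f]
        if len(serials) >= 2:
            for other in serials[1:]:
                out.setdefault(serials[0], set()).add(other)
                out.setdefault(other, set()).add(serials[0])
    return out


def _read_pdb(path: Path) -> tuple[struc.AtomArrayStack, set[tuple[int, int]]]:
    pdb = pdbio.PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except struc.BadStructureError as exc:
        raise ValueError(f"unparseable PDB file {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    serial_map: dict[int, int] = {}
    try:
        serials = pdb.get_structure(model=1, altloc="occupancy", extra_fields=["atom_id"]).atom_id
        serial_map = {int(s): i for i, s in enumerate(serials)}
    except Exception:  # pragma: no cover - serial numbers are optional
        pass
    conect: set[tuple[int, int]] = set()
    for serial, partners in _parse_conect(path).items():
        for other in partners:
            if serial in serial_map and other in serial_map:
                i, j = serial_map[serial], serial_map[other]
                conect.add((min(i, j), max(i, j)))
    return stack, conect


def read_structure(path: str | Path) -> tuple[Topology, np.ndarray]:
    """Read a PDB file into a Topology plus first-model coordinates.

    Alternate-location records keep the highest-occupancy conformer.
    Donor/acceptor lists are populated from the first model's geometry;
    structures without hydrogens get an empty donor list and a warning.
    """
    path = Path(path)
    stack, conect = _read_pdb(path)
    top = _structure_to_topology(stack[0], conect)
    coords = np.asarray(stack.coord[0], dtype=float)
    infer_hbond_participants(top, coords)
    return top, coords


def read_trajectory(
    topology_or_path: "Topology | str | Path",
    paths: list[str | Path] | str | Path,
    frame_spacing_ns: float = 0.1,
    window: tuple[float, float] | None = None,
) -> Trajectory:
    """Read one or more trajectory files and concatenate frames in order.

    Multi-model PDB files are read natively; ``.dcd``/``.xtc``/``.trr``
    files go through mdtraj and require the topology to come from a PDB
    path.  Frame times are assigned from ``frame_spacing_ns``; the analysis
    window defaults to the final half of the total time.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if isinstance(topology_or_path, Topology):
        top = topology_or_path
        top_path = None
    else:
        top_path = Path(topology_or_path)
        top, _ = read_structure(top_path)

    frames: list[np.ndarray] = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() in (".pdb", ".ent"):
            stack, _ = _read_pdb(p)
            coords = np.asarray(stack.coord, dtype=float)
        else:
            import mdtraj

            if top_path is None:
                raise ValueError(
                    "binary trajectory formats require the topology as a PDB path"
                )
            traj = mdtraj.load(str(p), top=str(top_path))
            coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Angstrom
        if coords.shape[1] != top.n_atoms:
            raise ValueError(
                f"atom count mismatch in {p}: file has {coords.shape[1]} atoms, "
                f"topology has {top.n_atoms}"
            )
        frames.append(coords)
    allc = np.concatenate(frames, axis=0)
    times = np.arange(len(allc)) * frame_spacing_ns
    return Trajectory(top, allc, times, window)


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB file."""
    top = traj.topology
    n = top.n_atoms
    template = struc.AtomArray(n)
    template.atom_name = top.atom_names
    template.element = top.elements
    template.chain_id = top.chain_ids
    template.res_id = top.res_ids
    template.res_name = top.res_names
    template.hetero = np.zeros(n, dtype=bool)
    arrays = []
    for f in range(traj.n_frames):
        arr = template.copy()
        arr.coord = traj.coords[f].astype(np.float32)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = pdbio.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def covalent_adjacency(top: Topology) -> set[tuple[Residue, Residue]]:
    """Pairs of consecutive, covalently bound residues within each chain.

    Residues with consecutive author numbers within a chain are adjacent;
    a numbering gap breaks the chain unless an explicit inter-residue bond
    record connects the flanking residues.
    """
    by_chain: dict[str, list[int]] = {}
    for c, r in zip(top.chain_ids, top.res_ids):
        lst = by_chain.setdefault(str(c), [])
        if int(r) not in lst:
            lst.append(int(r))
    # explicit inter-residue bonds from CONECT records
    bonded_pairs: set[tuple[Residue, Residue]] = set()
    for i, j in top.bonds:
        ri, rj = top.residue_of(i), top.residue_of(j)
        if ri != rj:
            bonded_pairs.add((min(ri, rj), max(ri, rj)))
    out: set[tuple[Residue, Residue]] = set()
    for chain, rids in by_chain.items():
        rids = sorted(rids)
        for r1, r2 in zip(rids, rids[1:]):
            pair = ((chain, r1), (chain, r2))
            if r2 == r1 + 1 or pair in bonded_pairs:
                out.add(pair)
    return out


def infer_hbond_participants(
    top: Topology,
    coords: np.ndarray,
    include_sulfur: bool = False,
    dh_max: float = 1.4,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Populate hydrogen-bond donor and acceptor lists on the topology.

    Donors are N/O heavy atoms with a covalently bonded hydrogen (every
    (D, H) pair is listed, so a lysine NZ with three hydrogens yields three
    pairs); acceptors are all N/O heavy atoms.  Sulfur participation is off
    by default.  Donor-hydrogen covalency is taken from explicit bond
    records when present, otherwise inferred from same-residue
    geometry (D-H distance <= ``dh_max`` Angstrom).
    """
    heavy_elems = {"N", "O"} | ({"S"} if include_sulfur else set())
    heavy = np.flatnonzero(np.isin(top.elements, sorted(heavy_elems)))
    hydro = np.flatnonzero(top.elements == "H")
    donors: list[tuple[int, int]] = []
    if hydro.size == 0:
        warnings.warn(
            "no hydrogens in structure: donor list is empty; hydrogen-bond "
            "detection will find nothing",
            stacklevel=2,
        )
    else:
        bonded_h: dict[int, set[int]] = {}
        for i, j in top.bonds:
            if top.elements[i] == "H":
                i, j = j, i
            if top.elements[j] == "H":
                bonded_h.setdefault(i, set()).add(j)
        for d in heavy:
            hs = set(bonded_h.get(int(d), set()))
            same_res = hydro[
                (top.chain_ids[hydro] == top.chain_ids[d])
                & (top.res_ids[hydro] == top.res_ids[d])
            ]
            if same_res.size:
                dist = np.linalg.norm(coords[same_res] - coords[d], axis=1)
                hs |= set(same_res[dist <= dh_max].tolist())
            donors.extend((int(d), int(h)) for h in sorted(hs))
    top.donors = donors
    top.acceptors = [int(a) for a in heavy]
    return donors, top.acceptors
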