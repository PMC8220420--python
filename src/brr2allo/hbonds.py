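"""Geometric hydrogen-bond detection and residue-pair occupancy matrices.

A hydrogen bond D-H···A is recorded when the donor-acceptor distance is at
most ``d_max`` (default 3.2 Angstrom) and the deviation of the D-H···A
arrangement from linearity is at most ``theta_max`` (default 42 degrees).
The deviation is defined as 180 deg minus the angle at the hydrogen between
the H->D and H->A directions, so a perfectly linear bond deviates by 0.
Both cutoffs are inclusive.

Occupancies are aggregated per residue pair over an analysis window:
``frame-union`` counts a frame if *any* hydrogen bond bridges the pair,
``max-single-bond`` takes the highest per-(D,H,A)-triplet occupancy.
No periodic-boundary imaging is applied (the analyses target solvated
monomeric proteins; minimum-image conventions are unsupported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import Residue, Topology, Trajectory

__all__ = [
    "HBondCriterion",
    "HBondProbabilityMatrix",
    "detect_hbonds_frame",
    "occupancy_matrix",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition (inclusive cutoffs)."""

    d_max: float = 3.2  # donor-acceptor distance, Angstrom
    theta_max: float = 42.0  # max deviation from linearity, degrees

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError("d_max must be > 0")
        if not 0 < self.theta_max < 90:
            raise ValueError("theta_max must be in (0, 90) degrees")


@dataclass
class HBondProbabilityMatrix:
    """Sparse symmetric residue-pair hydrogen-bond occurrence probabilities."""

    residues: list[Residue]
    probabilities: dict[tuple[Residue, Residue], float]
    n_frames: int
    aggregation: str = "frame-union"

    def __post_init__(self) -> None:
        for pair, p in self.probabilities.items():
            if pair[0] == pair[1]:
                raise ValueError(f"diagonal entry not allowed: {pair}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} for {pair} outside [0, 1]")

    @staticmethod
    def _key(a: Residue, b: Residue) -> tuple[Residue, Residue]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: Residue, b: Residue) -> float:
        return self.probabilities.get(self._key(a, b), 0.0)

    def write_triplets(self, path: str | Path) -> None:
        """Write as delimited triplets: chain:resnum_i chain:resnum_j prob."""
        lines = [f"# aggregation={self.aggregation} n_frames={self.n_frames}"]
        # record the full residue universe so graphs rebuilt from this file
        # keep nodes (and covalent adjacency) for hydrogen-bond-free residues
        lines += [f"# residue {c}:{r}" for c, r in self.residues]
        for (a, b), p in sorted(self.probabilities.items()):
            lines.append(f"{a[0]}:{a[1]} {b[0]}:{b[1]} {p:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_triplets(cls, path: str | Path) -> "HBondProbabilityMatrix":
        probs: dict[tuple[Residue, Residue], float] = {}
        residues: dict[Residue, None] = {}
        n_frames, aggregation = 0, "frame-union"
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").split()
                if len(body) == 2 and body[0] == "residue":
                    chain, _, num = body[1].partition(":")
                    residues.setdefault((chain, int(num)))
                    continue
                for token in body:
                    key, _, val = token.partition("=")
                    if key == "n_frames":
                        n_frames = int(val)
                    elif key == "aggregation":
                        aggregation = val
                continue
            fa, fb, fp = line.split()
            a = (fa.split(":")[0], int(fa.split(":")[1]))
            b = (fb.split(":")[0], int(fb.split(":")[1]))
            probs[cls._key(a, b)] = float(fp)
            residues.setdefault(a)
            residues.setdefault(b)
        return cls(sorted(residues), probs, n_frames, aggregation)


def detect_hbonds_frame(
    topology: Topology,
    coords: np.ndarray,
    criterion: HBondCriterion = HBondCriterion(),
) -> list[tuple[int, int, int]]:
    """Hydrogen bonds in one frame as (donor, hydrogen, acceptor) atom triplets.

    Donor and acceptor in the same residue are excluded.  Requires the
    topology's donor/acceptor lists to be populated
    (:func:`brr2allo.structure.infer_hbond_participants`).
    """
    donors = topology.donors
    acceptors = np.asarray(topology.acceptors, dtype=int)
    if not donors or acceptors.size == 0:
        return []
    d_idx = np.array([d for d, _ in donors], dtype=int)
    h_idx = np.array([h for _, h in donors], dtype=int)

    d_xyz = coords[d_idx][:, None, :]  # (nd, 1, 3)
    a_xyz = coords[acceptors][None, :, :]  # (1, na, 3)
    h_xyz = coords[h_idx][:, None, :]

    dist = np.linalg.norm(d_xyz - a_xyz, axis=2)
    hd = d_xyz - h_xyz  # H -> D
    ha = a_xyz - h_xyz  # H -> A
    norm = np.linalg.norm(hd, axis=2) * np.linalg.norm(ha, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("dax,dax->da", hd, ha) / np.where(norm > 0, norm, np.inf)
    deviation = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    same_res = (topology.chain_ids[d_idx][:, None] == topology.chain_ids[acceptors][None, :]) & (
        topology.res_ids[d_idx][:, None] == topology.res_ids[acceptors][None, :]
    )
    same_atom = d_idx[:, None] == acceptors[None, :]
    hit = (dist <= criterion.d_max) & (deviation <= criterion.theta_max)
    hit &= ~same_res & ~same_atom
    di, ai = np.nonzero(hit)
    return [(int(d_idx[i]), int(h_idx[i]), int(acceptors[j])) for i, j in zip(di, ai)]


def occupancy_matrix(
    trajectory: Trajectory,
    criterion: HBondCriterion = HBondCriterion(),
    aggregation: str = "frame-union",
    window: tuple[float, float] | None = None,
    protein_only: bool = True,
    exclude_res_names: tuple[str, ...] = ("HOH", "WAT", "NA", "CL", "MG", "ADP", "ATP"),
) -> HBondProbabilityMatrix:
    """Residue-pair hydrogen-bond occurrence probabilities over a window.

    ``frame-union`` (default): HB_ij = fraction of window frames with at
    least one hydrogen bond between residues i and j.
    ``max-single-bond``: maximum over distinct (D, H, A) triplets of the
    per-triplet occupancy.  Union-mode occupancy is always >= max-mode.
    """
    if aggregation not in ("frame-union", "max-single-bond"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    frames = trajectory.window_frames(window)
    if frames.size == 0:
        raise ValueError("empty analysis window")
    top = trajectory.topology

    excluded: set[Residue] | None = None
    if protein_only:
        excluded = {
            top.residue_of(i)
            for i in range(top.n_atoms)
            if top.res_names[i] in exclude_res_names
        }

    pair_counts: dict[tuple[Residue, Residue], int] = {}
    triplet_counts: dict[tuple[int, int, int], int] = {}
    residues = [r for r in top.residues() if not (excluded and r in excluded)]
    for f in frames:
        seen_pairs: set[tuple[Residue, Residue]] = set()
        for d, h, a in detect_hbonds_frame(top, trajectory.coords[f], criterion):
            ra, rb = top.residue_of(d), top.residue_of(a)
            if excluded and (ra in excluded or rb in excluded):
                continue
            seen_pairs.add(HBondProbabilityMatrix._key(ra, rb))
            triplet_counts[(d, h, a)] = triplet_counts.get((d, h, a), 0) + 1
        for pair in seen_pairs:
            pair_counts[pair] = pair_counts.get(pair, 0) + 1

    n = frames.size
    if aggregation == "frame-union":
        probs = {pair: c / n for pair, c in pair_counts.items()}
    else:
        probs = {}
        for (d, _h, a), c in triplet_counts.items():
            pair = HBondProbabilityMatrix._key(top.residue_of(d), top.residue_of(a))
            probs[pair] = max(probs.get(pair, 0.0), c / n)
    return HBondProbabilityMatrix(residues, probs, n, aggregation)
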