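"""Per-residue flexibility analyses: superposition, RMSF with block-averaged
errors, dynamic cross-correlation, and binding-pocket width series.

Fluctuation measures require removal of global rigid-body motion, done by
least-squares superposition (proper rotations only, so chirality is
preserved).  Errors are estimated by block averaging: the analysis window
is split into ``n_blocks`` contiguous spans (the canonical choice is five
20-ns blocks over a 100-ns window) and the between-block spread gives the
SEM of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Residue, Trajectory

__all__ = [
    "FlexibilityProfile",
    "CorrelationMatrix",
    "PocketWidthSeries",
    "superpose",
    "rmsf",
    "cross_correlation",
    "pocket_width",
    "ca_selection",
]


@dataclass
class FlexibilityProfile:
    residues: list[Residue]
    rmsf_mean: np.ndarray  # Angstrom, per residue
    rmsf_sem: np.ndarray  # Angstrom; NaN when undefined (n_blocks < 2)
    n_blocks: int
    reference: str  # "block-mean" | "global-mean"


@dataclass
class CorrelationMatrix:
    """Normalized Cα fluctuation covariances, C_ij in [-1, 1]."""

    residues: list[Residue]
    matrix: np.ndarray
    undefined: np.ndarray  # bool mask of zero-variance atoms


@dataclass
class PocketWidthSeries:
    pair: tuple[Residue, Residue]
    distances: np.ndarray  # Angstrom, per window frame
    mean: float
    sem: float | None


def ca_selection(traj: Trajectory, residues: "list[Residue] | None" = None) -> np.ndarray:
    """Atom indices of Cα atoms, optionally restricted to given residues."""
    top = traj.topology
    mask = top.atom_names == "CA"
    idx = np.flatnonzero(mask)
    if residues is not None:
        wanted = set(residues)
        idx = np.array([i for i in idx if top.residue_of(i) in wanted], dtype=int)
    return idx


def superpose(
    traj: Trajectory,
    selection: np.ndarray,
    reference: str = "first",
) -> Trajectory:
    """Least-squares rigid-body fit of every frame onto a reference.

    ``reference`` is ``"first"`` (frame 0) or ``"mean"`` (iterated mean
    structure).  Only proper rotations are used; a mirror-image frame
    cannot be superposed to zero RMSD.  Returns a new Trajectory with all
    atoms transformed.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    coords = traj.coords.copy()

    def _fit_to(ref_sel: np.ndarray) -> None:
        ref_c = ref_sel - ref_sel.mean(axis=0)
        for f in range(len(coords)):
            mob = coords[f][selection]
            cent = mob.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_c, mob - cent)
            coords[f] = rot.apply(coords[f] - cent) + ref_sel.mean(axis=0)

    if reference == "first":
        _fit_to(coords[0][selection])
    elif reference == "mean":
        _fit_to(coords[0][selection])
        for _ in range(3):  # iterate mean structure to convergence
            _fit_to(coords[:, selection].mean(axis=0))
    else:
        raise ValueError("reference must be 'first' or 'mean'")
    return Trajectory(traj.topology, coords, traj.times.copy(), traj.window)


def _blocks(n_frames: int, n_blocks: int) -> list[np.ndarray]:
    edges = np.linspace(0, n_frames, n_blocks + 1).astype(int)
    return [np.arange(a, b) for a, b in zip(edges, edges[1:])]


def rmsf(
    traj: Trajectory,
    selection: np.ndarray,
    n_blocks: int = 5,
    window: tuple[float, float] | None = None,
    reference: str = "block-mean",
) -> FlexibilityProfile:
    """Per-residue RMSF with SEM from block averaging.

    RMSF_i = sqrt(mean_t |r_i(t) - <r_i>|^2) is computed per block, with
    the fluctuation reference being each block's own mean structure
    (``"block-mean"``, default) or the whole-window mean
    (``"global-mean"``); the profile is the mean over blocks and the SEM
    the between-block standard error.
    """
    if reference not in ("block-mean", "global-mean"):
        raise ValueError("reference must be 'block-mean' or 'global-mean'")
    selection = np.asarray(selection, dtype=int)
    frames = traj.window_frames(window)
    if n_blocks > frames.size:
        raise ValueError(f"n_blocks={n_blocks} exceeds {frames.size} window frames")
    xyz = traj.coords[frames][:, selection]  # (F, A, 3)
    global_mean = xyz.mean(axis=0)
    per_block = []
    for block in _blocks(len(frames), n_blocks):
        sub = xyz[block]
        ref = sub.mean(axis=0) if reference == "block-mean" else global_mean
        per_block.append(np.sqrt(np.mean(np.sum((sub - ref) ** 2, axis=2), axis=0)))
    per_block = np.array(per_block)  # (n_blocks, A)
    mean = per_block.mean(axis=0)
    if n_blocks >= 2:
        sem = per_block.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    else:
        sem = np.full_like(mean, np.nan)
    residues = [traj.topology.residue_of(int(i)) for i in selection]
    return FlexibilityProfile(residues, mean, sem, n_blocks, reference)


def cross_correlation(
    traj: Trajectory,
    selection: np.ndarray,
    window: tuple[float, float] | None = None,
) -> CorrelationMatrix:
    """Dynamic cross-correlation map of positional fluctuations.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>) with dr the
    deviation from the time-mean position — the standard 3D-vector
    definition.  Zero-variance atoms give undefined rows/columns (NaN),
    flagged in the result.
    """
    selection = np.asarray(selection, dtype=int)
    frames = traj.window_frames(window)
    if frames.size < 2:
        raise ValueError("correlation needs at least 2 frames")
    xyz = traj.coords[frames][:, selection]
    dr = xyz - xyz.mean(axis=0)
    cov = np.einsum("fix,fjx->ij", dr, dr) / len(frames)
    var = np.diag(cov).copy()
    undefined = var <= 0
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / denom
    corr = np.clip(corr, -1.0, 1.0)  # guards rounding just past +/-1; NaN passes
    corr[undefined, :] = np.nan
    corr[:, undefined] = np.nan
    np.fill_diagonal(corr, np.where(undefined, np.nan, 1.0))
    residues = [traj.topology.residue_of(int(i)) for i in selection]
    return CorrelationMatrix(residues, corr, undefined)


def pocket_width(
    traj: Trajectory,
    pair: tuple[Residue, Residue],
    n_blocks: int = 5,
    atom_name: str = "CA",
    window: tuple[float, float] | None = None,
) -> PocketWidthSeries:
    """Per-frame distance between two residues' reference atoms.

    The canonical pocket-width pairs for the Brr2 cassettes are
    G506-G854 (NC) and G1353-G1689 (CC), measured between Cα atoms.
    """
    top = traj.topology
    idx = []
    for res in pair:
        found = top.atom_indices(res[0], res[1], atom_name)
        if found.size == 0:
            raise ValueError(f"residue {res[0]}:{res[1]} has no atom {atom_name!r}")
        idx.append(int(found[0]))
    frames = traj.window_frames(window)
    d = np.linalg.norm(
        traj.coords[frames, idx[0]] - traj.coords[frames, idx[1]], axis=1
    )
    if n_blocks >= 2 and n_blocks <= frames.size:
        block_means = [d[b].mean() for b in _blocks(len(frames), n_blocks)]
        sem = float(np.std(block_means, ddof=1) / np.sqrt(n_blocks))
    else:
        sem = None
    return PocketWidthSeries(pair, d, float(d.mean()), sem)
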