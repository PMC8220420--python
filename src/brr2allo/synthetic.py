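"""Synthetic-data generators for both pipeline arms.

Kinetics arm: stopped-flow trace sets following the experimental design of
the Brr2 rapid-kinetics measurements — association titrations over a
nucleotide concentration series at fixed protein concentration, chase
experiments against a 100 uM unlabelled competitor, 1000 log-spaced points
per trace, seven replicates per condition, additive Gaussian noise at 1%
of the total amplitude, with the published rate constants as generating
truth.

Structural arm: toy two-cassette pseudo-proteins with planted
hydrogen-bond communication structure, either as a fast occupancy network
(binomially sampled occurrence frequencies, no geometry) or as a full
multi-frame trajectory in which planted bonds toggle between bonded and
broken donor/acceptor geometries frame-by-frame.  These stand in for MD
trajectories, which are not distributed with the underlying structures;
they exercise the analysis machinery, not force-field physics.

All generators are pure functions of (design, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hbonds import HBondProbabilityMatrix
from .kinetics import io as kio
from .kinetics.model import (
    BindingScheme,
    ExperimentSpec,
    KineticTrace,
    PseudoFirstOrderWarning,
    apparent_rate,
    model_association,
    model_chase,
)
from .kinetics.reference import binding_scheme
from .structure import Residue, Topology, Trajectory, infer_hbond_participants

__all__ = [
    "KineticsDesign",
    "KineticsDataset",
    "generate_kinetics_dataset",
    "NetworkDesign",
    "generate_occupancy_network",
    "generate_synthetic_trajectory",
]


# ---------------------------------------------------------------------------
# kinetics arm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsDesign:
    """Experimental design for one construct/nucleotide dataset.

    Defaults mirror the stopped-flow protocol: association series at
    {1, 2.5, 5, 10, 20} uM labelled nucleotide, chase with 5 uM labelled
    complex against 100 uM unlabelled competitor, 7 replicates, 1000
    log-sampled points, noise sigma = 1% of total amplitude.
    """

    construct: str = "hBrr2-NC"
    nucleotide: str = "mant-ADP"
    scheme: BindingScheme | None = None  # default: published rate constants
    protein_conc: float | None = None
    association_concs: tuple[float, ...] = (1.0, 2.5, 5.0, 10.0, 20.0)
    chase_labeled_conc: float = 5.0
    chase_competitor_conc: float = 100.0
    replicates: int = 7
    n_points: int = 1000
    noise_sigma: float = 0.01  # fraction of total amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.association_concs):
            raise ValueError("concentrations must be > 0")
        if self.replicates < 3:
            raise ValueError("need >= 3 replicates")

    def resolved_scheme(self) -> BindingScheme:
        if self.scheme is not None:
            return self.scheme
        return binding_scheme(self.construct, self.nucleotide, self.protein_conc)


@dataclass
class KineticsDataset:
    design: KineticsDesign
    association: dict[float, list[KineticTrace]]  # conc -> replicates
    chase: list[KineticTrace]
    truth: dict


def _association_span(scheme: BindingScheme, conc: float) -> tuple[float, float]:
    rates = [apparent_rate(s, conc) for s in scheme.sites]
    t_min = min(1e-3, 0.02 / max(rates))
    t_max = 7.0 / min(rates)
    return (t_min, t_max)


def _chase_span(scheme: BindingScheme) -> tuple[float, float]:
    koffs = [s.k_off for s in scheme.sites if s.k_off > 0]
    if not koffs:
        return (1e-3, 10.0)
    return (min(1e-3, 0.02 / max(koffs)), 7.0 / min(koffs))


def _noisy(trace: KineticTrace, sigma_abs: float, rng: np.random.Generator) -> KineticTrace:
    noisy = trace.signal + rng.normal(0.0, sigma_abs, size=trace.signal.shape)
    meta = dict(trace.meta)
    meta["noise_sigma"] = sigma_abs
    return KineticTrace(trace.time.copy(), noisy, meta)


def generate_kinetics_dataset(
    design: KineticsDesign,
    out_dir: str | Path | None = None,
    include_association: bool = True,
    include_chase: bool = True,
) -> KineticsDataset:
    """Simulate a full association + chase dataset for one design.

    With ``out_dir`` set, traces are written as two-column text files plus
    a manifest table and a ground-truth JSON for recovery scoring.
    """
    scheme = design.resolved_scheme()
    rng = np.random.default_rng(design.seed)
    total_amp = sum(s.amplitude for s in scheme.sites)
    sigma_abs = design.noise_sigma * total_amp

    association: dict[float, list[KineticTrace]] = {}
    if include_association:
        for conc in design.association_concs:
            spec = ExperimentSpec(
                mode="association",
                nucleotide_conc=conc,
                time_span=_association_span(scheme, conc),
                n_points=design.n_points,
            )
            with warnings.catch_warnings():
                # the closed form *is* the generating model here, so the
                # ligand-excess caveat does not apply to synthetic traces
                warnings.simplefilter("ignore", PseudoFirstOrderWarning)
                clean = model_association(scheme, spec)
            association[conc] = [
                _noisy(clean, sigma_abs, rng) for _ in range(design.replicates)
            ]
    chase: list[KineticTrace] = []
    if include_chase:
        spec = ExperimentSpec(
            mode="chase",
            nucleotide_conc=design.chase_labeled_conc,
            chase_conc=design.chase_competitor_conc,
            time_span=_chase_span(scheme),
            n_points=design.n_points,
        )
        clean = model_chase(scheme, spec)
        chase = [_noisy(clean, sigma_abs, rng) for _ in range(design.replicates)]

    truth = {
        "construct": design.construct,
        "nucleotide": design.nucleotide,
        "seed": design.seed,
        "noise_sigma_fraction": design.noise_sigma,
        "sites": [
            {
                "cassette": s.label,
                "k1": s.k_on,
                "k_minus1": s.k_off,
                "amplitude": s.amplitude,
            }
            for s in scheme.sites
        ],
    }
    dataset = KineticsDataset(design, association, chase, truth)
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(dataset: KineticsDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = ["construct\tnucleotide\tmode\tconc_uM\treplicate\ttrace_path"]
    d = dataset.design
    for conc, traces in dataset.association.items():
        for i, tr in enumerate(traces):
            name = f"assoc_{conc:g}uM_rep{i}.txt"
            kio.write_trace(tr, out_dir / name)
            manifest_rows.append(
                f"{d.construct}\t{d.nucleotide}\tassociation\t{conc:g}\t{i}\t{name}"
            )
    for i, tr in enumerate(dataset.chase):
        name = f"chase_rep{i}.txt"
        kio.write_trace(tr, out_dir / name)
        manifest_rows.append(
            f"{d.construct}\t{d.nucleotide}\tchase\t{d.chase_labeled_conc:g}\t{i}\t{name}"
        )
    (out_dir / "manifest.tsv").write_text("\n".join(manifest_rows) + "\n")
    (out_dir / "truth.json").write_text(json.dumps(dataset.truth, indent=1) + "\n")


# ---------------------------------------------------------------------------
# structural arm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkDesign:
    """Planted-communication network for a toy two-cassette protein.

    Residues are numbered like a miniature Brr2: the NC block starts at
    ``nc_start`` and the CC block at ``cc_start`` (past the 1282 cassette
    boundary), each block covalently consecutive.  One interface hydrogen
    bond is planted at occupancy ``p_path`` between ``interface_pair``;
    the planted communication chain is the backbone route
    source -> interface pair -> target.  ``n_interface_decoys`` competing
    interface bonds at occupancy ``p_bg`` and ``n_background`` random
    intra-cassette bonds at occupancies up to ``p_bg`` form the noise
    floor.  Occupancies are realised as Bernoulli frequencies over
    ``n_frames`` frames, so equal planted and background probabilities
    make recovery a coin flip (negative control).
    """

    n_residues: int = 30  # per cassette
    nc_start: int = 401
    cc_start: int = 1301
    source_offset: int = 2  # source = nc_start + offset
    target_offset: int = 27  # target = cc_start + offset
    interface_offsets: tuple[int, int] = (20, 8)  # (NC res offset, CC res offset)
    p_path: float = 0.95
    p_bg: float = 0.3
    n_interface_decoys: int = 3
    n_background: int = 30
    n_frames: int = 500
    jitter: float = 0.05  # Angstrom, positional noise in trajectory mode
    chain_id: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.p_path > 0 or not self.p_bg > 0:
            raise ValueError("occupancies must be > 0")
        if self.p_path < self.p_bg:
            raise ValueError("p_path must be >= p_bg")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    @property
    def source(self) -> Residue:
        return (self.chain_id, self.nc_start + self.source_offset)

    @property
    def target(self) -> Residue:
        return (self.chain_id, self.cc_start + self.target_offset)

    @property
    def interface_pair(self) -> tuple[Residue, Residue]:
        return (
            (self.chain_id, self.nc_start + self.interface_offsets[0]),
            (self.chain_id, self.cc_start + self.interface_offsets[1]),
        )

    def residues(self) -> list[Residue]:
        nc = [(self.chain_id, self.nc_start + i) for i in range(self.n_residues)]
        cc = [(self.chain_id, self.cc_start + i) for i in range(self.n_residues)]
        return nc + cc

    def adjacency(self) -> set[tuple[Residue, Residue]]:
        res = self.residues()
        nc, cc = res[: self.n_residues], res[self.n_residues :]
        pairs = set()
        for block in (nc, cc):
            pairs.update(zip(block, block[1:]))
        return pairs

    def planted_chain(self) -> tuple[Residue, ...]:
        """Backbone route source -> interface crossing -> target."""
        c = self.chain_id
        nc_if, cc_if = self.interface_pair
        lo, hi = sorted((self.source[1], nc_if[1]))
        nc_leg = [(c, r) for r in range(lo, hi + 1)]
        if nc_leg[0] != self.source:
            nc_leg.reverse()
        lo, hi = sorted((cc_if[1], self.target[1]))
        cc_leg = [(c, r) for r in range(lo, hi + 1)]
        if cc_leg[0] != cc_if:
            cc_leg.reverse()
        return tuple(nc_leg + cc_leg)


def _sample_bonds(
    design: NetworkDesign, rng: np.random.Generator
) -> dict[tuple[Residue, Residue], float]:
    """True occurrence probabilities for all planted and background bonds."""
    res = design.residues()
    nc, cc = res[: design.n_residues], res[design.n_residues :]
    adjacency = design.adjacency()
    nc_if, cc_if = design.interface_pair
    bonds: dict[tuple[Residue, Residue], float] = {(nc_if, cc_if): design.p_path}

    # competing interface crossings at background occupancy
    choices = [
        (a, b)
        for a in nc
        for b in cc
        if (a, b) != (nc_if, cc_if)
    ]
    for i in rng.choice(len(choices), size=design.n_interface_decoys, replace=False):
        bonds[choices[int(i)]] = design.p_bg

    # random intra-cassette bonds, occupancy uniform in (0.05, p_bg]
    intra = [
        (a, b)
        for block in (nc, cc)
        for ai, a in enumerate(block)
        for b in block[ai + 1 :]
        if (a, b) not in adjacency
    ]
    n_bg = min(design.n_background, len(intra))
    for i in rng.choice(len(intra), size=n_bg, replace=False):
        pair = intra[int(i)]
        if pair not in bonds:
            bonds[pair] = float(rng.uniform(0.05, design.p_bg))
    return bonds


def generate_occupancy_network(
    design: NetworkDesign,
) -> tuple[HBondProbabilityMatrix, set[tuple[Residue, Residue]], dict]:
    """Occupancy matrix + covalent adjacency with planted structure.

    Fast path that skips geometry: each designed bond's occupancy is the
    empirical frequency of ``n_frames`` Bernoulli draws at its true
    probability.  Returns (matrix, adjacency, ground truth).
    """
    rng = np.random.default_rng(design.seed)
    bonds = _sample_bonds(design, rng)
    probs: dict[tuple[Residue, Residue], float] = {}
    for pair, p in bonds.items():
        freq = rng.binomial(design.n_frames, p) / design.n_frames
        if freq > 0:
            key = pair if pair[0] <= pair[1] else (pair[1], pair[0])
            probs[key] = float(freq)
    matrix = HBondProbabilityMatrix(
        design.residues(), probs, design.n_frames, "frame-union"
    )
    truth = _truth(design, bonds)
    return matrix, design.adjacency(), truth


def _truth(design: NetworkDesign, bonds: dict) -> dict:
    return {
        "seed": design.seed,
        "source": list(design.source),
        "target": list(design.target),
        "interface_pair": [list(r) for r in design.interface_pair],
        "planted_chain": [list(r) for r in design.planted_chain()],
        "p_path": design.p_path,
        "p_bg": design.p_bg,
        "bond_probabilities": [
            {"res_i": list(a), "res_j": list(b), "p": p} for (a, b), p in sorted(bonds.items())
        ],
    }


# geometry constants for the trajectory realisation (Angstrom)
_GRID_SPACING = 20.0
_DA_BONDED = 2.9
_DA_BROKEN = 6.5


def _base_positions(design: NetworkDesign) -> dict[Residue, np.ndarray]:
    out = {}
    for k, res in enumerate(design.residues()):
        cassette_shift = 0.0 if k < design.n_residues else 120.0
        i = k % design.n_residues
        out[res] = np.array(
            [
                (i % 5) * _GRID_SPACING,
                ((i // 5) % 5) * _GRID_SPACING + cassette_shift,
                (i // 25) * _GRID_SPACING,
            ]
        )
    return out


def generate_synthetic_trajectory(
    design: NetworkDesign,
) -> tuple[Trajectory, dict]:
    """Multi-frame pseudo-protein trajectory with planted hydrogen bonds.

    Each residue carries CA, a donor N-H, and an acceptor O.  For every
    designed bond, the donor of one residue points at the partner's
    acceptor; the acceptor sits at donor-acceptor distance 2.9 Angstrom
    (within the 3.2 Angstrom / 42 degree criterion) in a Bernoulli(p)
    subset of frames and at 6.5 Angstrom otherwise.  Gaussian positional
    jitter (sigma = ``design.jitter``) is added to all atoms in every
    frame.  Residues sit on a 20 Angstrom grid so no accidental contacts
    arise.  Each residue's donor and acceptor can serve one designed bond
    apiece; infeasible designs raise.
    """
    if design.jitter > 0.3:
        raise ValueError(
            "jitter above 0.3 Angstrom can break planted bond geometry"
        )
    rng = np.random.default_rng(design.seed)
    bonds = _sample_bonds(design, rng)

    # assign donor/acceptor slots: bond (a, b) uses donor of a, acceptor of b
    nc_if, cc_if = design.interface_pair
    donor_used: dict[Residue, tuple[Residue, float]] = {}
    acceptor_used: dict[Residue, Residue] = {}
    realized: list[tuple[Residue, Residue, float]] = []
    # planted interface bond claims its donor/acceptor slots first
    ordered = sorted(bonds.items(), key=lambda kv: (kv[0] != (nc_if, cc_if), kv[0]))
    for (a, b), p in ordered:
        if a in donor_used or b in acceptor_used:
            if b not in donor_used and a not in acceptor_used:
                a, b = b, a  # try the reverse orientation
            else:
                continue  # slot conflict: drop this background bond
        donor_used[a] = (b, p)
        acceptor_used[b] = a
        realized.append((a, b, p))
    if not any({x, y} == {nc_if, cc_if} for x, y, _ in realized):
        raise ValueError("infeasible geometry: planted interface bond lost to slot conflict")

    base = _base_positions(design)
    residues = design.residues()
    names = ["N", "H", "CA", "O"]
    elements = ["N", "H", "C", "O"]
    n_atoms = 4 * len(residues)
    atom_of: dict[tuple[Residue, str], int] = {}
    top = Topology(
        atom_names=np.array(names * len(residues), dtype="U6"),
        elements=np.array(elements * len(residues), dtype="U2"),
        chain_ids=np.array(
            [r[0] for r in residues for _ in names], dtype="U4"
        ),
        res_ids=np.array([r[1] for r in residues for _ in names], dtype=int),
        res_names=np.array(["SYN"] * n_atoms, dtype="U5"),
    )
    for i, res in enumerate(residues):
        for j, nm in enumerate(names):
            atom_of[(res, nm)] = 4 * i + j
        top.bonds.add((4 * i, 4 * i + 1))  # N-H covalent

    # static template coordinates (acceptor positions are overwritten
    # per frame for residues serving a designed bond)
    template = np.zeros((n_atoms, 3))
    directions: dict[Residue, np.ndarray] = {}
    for res in residues:
        p0 = base[res]
        if res in donor_used:
            partner, _ = donor_used[res]
            u = base[partner] - p0
            u = u / np.linalg.norm(u)
        else:
            u = np.array([0.0, 0.0, 1.0])
        directions[res] = u
        template[atom_of[(res, "N")]] = p0 + 1.5 * u
        template[atom_of[(res, "H")]] = p0 + 2.5 * u
        template[atom_of[(res, "CA")]] = p0
        # default acceptor sits opposite the donor arm so it can never be
        # mistaken for a donor-bonded hydrogen partner
        template[atom_of[(res, "O")]] = p0 - 1.2 * u

    frames = np.repeat(template[None, :, :], design.n_frames, axis=0)
    bond_states: dict[tuple[Residue, Residue], np.ndarray] = {}
    for a, b, p in realized:
        present = rng.random(design.n_frames) < p
        bond_states[(a, b)] = present
        n_pos = template[atom_of[(a, "N")]]
        u = directions[a]
        o_idx = atom_of[(b, "O")]
        frames[:, o_idx] = np.where(
            present[:, None],
            n_pos + _DA_BONDED * u,
            n_pos + _DA_BROKEN * u,
        )
    frames += rng.normal(0.0, design.jitter, size=frames.shape)

    times = np.arange(design.n_frames) * 0.1  # ns
    traj = Trajectory(top, frames, times, window=(0.0, float(times[-1])))
    infer_hbond_participants(top, frames[0])
    truth = _truth(design, {(a, b): p for a, b, p in realized})
    truth["realized_frames"] = {
        f"{a[0]}:{a[1]}-{b[0]}:{b[1]}": int(v.sum()) for (a, b), v in bond_states.items()
    }
    return traj, truth
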