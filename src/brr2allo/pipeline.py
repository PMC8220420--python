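"""Config-driven end-to-end runs tying the analysis stages together.

Two entry points:

- :func:`run_kinetics`: simulate (or load) stopped-flow trace sets, average
  replicates, fit exponentials with phase-count selection, assign phases to
  cassettes, regress apparent rates against concentration, and emit rate
  constant / affinity / fold-ratio tables.
- :func:`run_allostery`: build hydrogen-bond occupancy matrices from a
  trajectory (or load a precomputed matrix), construct the communication
  graph, extract k-shortest pocket-to-pocket paths with participation and
  interface-crossing summaries plus block-averaged path lengths, and — when
  a trajectory is available — RMSF, cross-correlation, and pocket-width
  flexibility reports.

Configs are pydantic-validated (unknown keys rejected); every run writes
its effective config, seed, and package version to the run directory so
deterministic stages reproduce byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .commgraph import (
    NoPath,
    aggregate_crossings,
    build_graph,
    k_shortest_paths,
    participation_frequency,
    path_length_statistics,
)
from .flexibility import ca_selection, cross_correlation, pocket_width, rmsf, superpose
from .hbonds import HBondCriterion, HBondProbabilityMatrix, occupancy_matrix
from .kinetics import io as kio
from .kinetics.fit import (
    RateConstantSet,
    TitrationSeries,
    derive_affinity_table,
    fit_exponentials,
    fold_ratios,
    normalize_and_average,
    regress_kapp,
    select_phase_count,
)
from .structure import covalent_adjacency, read_trajectory
from .synthetic import (
    KineticsDesign,
    NetworkDesign,
    generate_kinetics_dataset,
    generate_occupancy_network,
    generate_synthetic_trajectory,
)

__all__ = ["KineticsRunConfig", "AllosteryRunConfig", "run_kinetics", "run_allostery"]

log = logging.getLogger(__name__)


warnings.filterwarnings(
    "ignore", message='Field name "construct".*shadows an attribute'
)


class KineticsRunConfig(BaseModel):
    """Configuration of a kinetics run (synthetic design or trace manifest).

    The ``construct`` field intentionally shadows pydantic's deprecated
    ``BaseModel.construct`` classmethod, which this package never calls.
    """

    model_config = ConfigDict(extra="forbid")

    construct: str = "hBrr2-T1"
    nucleotide: str = "mant-ADP"
    manifest: str | None = None  # trace manifest; None -> simulate
    replicates: int = 7
    noise_sigma: float = 0.01
    association_concs: tuple[float, ...] = (1.0, 2.5, 5.0, 10.0, 20.0)
    auto_phase_selection: bool = True
    seed: int = 0


class AllosteryRunConfig(BaseModel):
    """Configuration of a communication/flexibility run."""

    model_config = ConfigDict(extra="forbid")

    occupancy_matrix: str | None = None  # triplet table; skips trajectory stage
    topology: str | None = None  # PDB path
    trajectory: list[str] | None = None
    synthetic: bool = False  # generate a planted-network trajectory
    d_max: float = 3.2
    theta_max: float = 42.0
    aggregation: str = "frame-union"
    k: int = 10
    n_blocks: int = 5
    endpoints: list[tuple[str, int, str, int]] | None = None  # chain,res,chain,res
    pocket_pairs: list[tuple[str, int, str, int]] | None = None
    frame_spacing_ns: float = 0.1
    seed: int = 0


def _write_run_manifest(out_dir: Path, config: BaseModel) -> None:
    payload = config.model_dump()
    text = json.dumps(payload, sort_keys=True, default=str)
    manifest = {
        "config": payload,
        "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "package_version": __version__,
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str) + "\n"
    )


def _load_manifest_traces(manifest_path: Path):
    table = pd.read_csv(manifest_path, sep="\t")
    base = manifest_path.parent
    assoc: dict[float, list] = defaultdict(list)
    chase = []
    for _, row in table.iterrows():
        trace = kio.read_trace(base / row.trace_path)
        if row["mode"] == "association":
            assoc[float(row.conc_uM)].append(trace)
        else:
            chase.append(trace)
    return dict(assoc), chase


def run_kinetics(config: KineticsRunConfig, out_dir: str | Path) -> dict:
    """Average -> fit -> select phases -> assign -> regress -> Kd/folds.

    Returns a summary dict; persists every intermediate table to
    ``out_dir``.  Raises if fewer than three concentrations are usable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_run_manifest(out_dir, config)

    if config.manifest:
        association, chase = _load_manifest_traces(Path(config.manifest))
    else:
        design = KineticsDesign(
            construct=config.construct,
            nucleotide=config.nucleotide,
            replicates=config.replicates,
            noise_sigma=config.noise_sigma,
            association_concs=config.association_concs,
            seed=config.seed,
        )
        ds = generate_kinetics_dataset(design, out_dir / "traces")
        association, chase = ds.association, ds.chase

    # fit every concentration, selecting the phase count on the fly
    kapp_rows = []
    n_phases_seen = []
    for conc in sorted(association):
        traces = association[conc]
        trace = normalize_and_average(traces)
        if config.auto_phase_selection:
            sel = select_phase_count(trace)
            fit, n_phases = sel.best_fit, sel.n_phases
        else:
            fit = fit_exponentials(trace, 1)
            n_phases = 1
        n_phases_seen.append(n_phases)
        for idx in range(n_phases):
            kapp_rows.append(
                {
                    "conc_uM": conc,
                    "phase": idx,
                    "k_app": fit.k_app[idx],
                    "k_app_se": fit.k_app_se[idx],
                    "n_phases": n_phases,
                    "converged": fit.converged,
                }
            )
    kapp_table = pd.DataFrame(kapp_rows)
    kapp_table.to_csv(out_dir / "kapp_table.csv", index=False)
    n_phases = int(np.median(n_phases_seen)) if n_phases_seen else 1
    cassettes = ["NC"] if n_phases == 1 else ["NC", "CC"]

    # chase-derived dissociation rates (authoritative for k_minus1)
    chase_koff: dict[str, tuple[float, float]] = {}
    if len(chase) >= 2:
        chase_fit = fit_exponentials(normalize_and_average(chase), n_phases)
        for idx, cas in enumerate(cassettes):
            chase_koff[cas] = (chase_fit.k_app[idx], chase_fit.k_app_se[idx])

    records = []
    for idx, cas in enumerate(cassettes):
        sub = kapp_table[kapp_table.phase == idx]
        if sub.conc_uM.nunique() < 3:
            raise RuntimeError(
                f"phase {idx} resolved at only {sub.conc_uM.nunique()} "
                "concentrations; need >= 3 for regression"
            )
        series = TitrationSeries(
            [(r.conc_uM, r.k_app, 0.0, 1) for r in sub.itertuples()], cas
        )
        reg = regress_kapp(series)
        km1, km1_se = chase_koff.get(cas, (reg.k_minus1, reg.k_minus1_se))
        records.append(
            {
                "construct": config.construct,
                "nucleotide": config.nucleotide,
                "cassette": cas,
                "k1": reg.k1,
                "k1_se": reg.k1_se,
                "k_minus1": km1,
                "k_minus1_se": km1_se,
                "provenance": "chase" if cas in chase_koff else "regression-intercept",
                "intercept_k_minus1": reg.k_minus1,
            }
        )
    rate_table = pd.DataFrame(records)
    rate_table.to_csv(out_dir / "rate_constants.csv", index=False)

    rates = RateConstantSet(rate_table.drop(columns=["intercept_k_minus1"]))
    affinity = derive_affinity_table(rates)
    affinity.to_csv(out_dir / "affinity_table.csv", index=False)
    folds = fold_ratios(affinity)
    folds.to_csv(out_dir / "fold_ratios.csv", index=False)
    return {
        "n_phases": n_phases,
        "rate_constants": rate_table,
        "affinity": affinity,
        "folds": folds,
    }


def _paths_to_json(paths) -> list:
    if isinstance(paths, NoPath):
        return []
    return [
        {
            "residues": [f"{c}:{r}" for c, r in p.residues],
            "cost": p.cost,
            "length": p.length,
        }
        for p in paths
    ]


def run_allostery(config: AllosteryRunConfig, out_dir: str | Path) -> dict:
    """Occupancy matrix -> graph -> k-shortest paths -> flexibility reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_run_manifest(out_dir, config)
    criterion = HBondCriterion(config.d_max, config.theta_max)

    traj = None
    truth = None
    if config.occupancy_matrix:
        matrix = HBondProbabilityMatrix.read_triplets(config.occupancy_matrix)
        adjacency = _adjacency_from_residues(matrix.residues)
        block_matrices = [matrix]  # single block: no temporal resolution
    else:
        if config.synthetic:
            traj, truth = generate_synthetic_trajectory(NetworkDesign(seed=config.seed))
        elif config.topology and config.trajectory:
            traj = read_trajectory(
                config.topology, list(config.trajectory), config.frame_spacing_ns
            )
        else:
            raise ValueError(
                "allostery run needs an occupancy matrix, a topology + "
                "trajectory, or synthetic=true"
            )
        adjacency = covalent_adjacency(traj.topology)
        matrix = occupancy_matrix(traj, criterion, config.aggregation)
        matrix.write_triplets(out_dir / "occupancy.tsv")
        frames = traj.window_frames()
        edges = np.linspace(0, frames.size, config.n_blocks + 1).astype(int)
        block_matrices = []
        for a, b in zip(edges, edges[1:]):
            if b - a == 0:
                continue
            w = (float(traj.times[frames[a]]), float(traj.times[frames[b - 1]]))
            block_matrices.append(occupancy_matrix(traj, criterion, config.aggregation, w))

    graph = build_graph(matrix, adjacency)
    nx_edges = [
        {
            "res_i": f"{u[0]}:{u[1]}",
            "res_j": f"{v[0]}:{v[1]}",
            "probability": d.get("probability", ""),
            "cost": d["cost"],
            "provenance": d["provenance"],
        }
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(nx_edges).to_csv(out_dir / "graph_edges.csv", index=False)

    if config.endpoints is not None:
        endpoint_pairs = [((c1, r1), (c2, r2)) for c1, r1, c2, r2 in config.endpoints]
    elif truth is not None:
        endpoint_pairs = [(tuple(truth["source"]), tuple(truth["target"]))]
    else:
        from .commgraph import DEFAULT_ENDPOINT_PAIRS

        endpoint_pairs = DEFAULT_ENDPOINT_PAIRS

    report: dict = {"pairs": {}}
    for source, target in endpoint_pairs:
        name = f"{source[0]}:{source[1]}-{target[0]}:{target[1]}"
        paths = k_shortest_paths(graph, source, target, config.k)
        entry: dict = {"paths": _paths_to_json(paths)}
        if not isinstance(paths, NoPath):
            entry["participation"] = {
                f"{c}:{r}": f for (c, r), f in participation_frequency(paths).items()
            }
            entry["interface_crossings"] = {
                f"{a[0]}:{a[1]}-{b[0]}:{b[1]}": n
                for (a, b), n in aggregate_crossings(paths).items()
            }
        block_sets = [
            k_shortest_paths(build_graph(m, adjacency), source, target, config.k)
            for m in block_matrices
        ]
        try:
            stats = path_length_statistics(block_sets)
            entry["path_length"] = {
                "mean": stats.mean_length,
                "sem": stats.sem_length,
                "n_blocks_used": stats.n_blocks_used,
                "excluded_blocks": stats.excluded_blocks,
            }
        except ValueError:
            entry["path_length"] = None
        report["pairs"][name] = entry
    (out_dir / "paths.json").write_text(json.dumps(report, indent=1) + "\n")

    if traj is not None:
        sel = ca_selection(traj)
        aligned = superpose(traj, sel)
        prof = rmsf(aligned, sel, n_blocks=min(config.n_blocks, traj.n_frames))
        pd.DataFrame(
            {
                "chain": [r[0] for r in prof.residues],
                "resnum": [r[1] for r in prof.residues],
                "rmsf_mean_A": prof.rmsf_mean,
                "rmsf_sem_A": prof.rmsf_sem,
            }
        ).to_csv(out_dir / "rmsf.csv", index=False)
        corr = cross_correlation(aligned, sel)
        pd.DataFrame(
            corr.matrix,
            index=[f"{c}:{r}" for c, r in corr.residues],
            columns=[f"{c}:{r}" for c, r in corr.residues],
        ).to_csv(out_dir / "correlation.csv")
        for pair4 in config.pocket_pairs or []:
            pair = ((pair4[0], pair4[1]), (pair4[2], pair4[3]))
            pw = pocket_width(traj, pair, n_blocks=config.n_blocks)
            name = f"pocket_{pair4[0]}{pair4[1]}_{pair4[2]}{pair4[3]}.csv"
            pd.DataFrame({"distance_A": pw.distances}).to_csv(out_dir / name, index=False)
    if truth is not None:
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    return report


def _adjacency_from_residues(residues) -> set:
    """Consecutive-numbering adjacency for matrix-only inputs."""
    by_chain: dict[str, list[int]] = defaultdict(list)
    for c, r in residues:
        by_chain[c].append(r)
    pairs = set()
    for c, rids in by_chain.items():
        for r1, r2 in zip(sorted(rids), sorted(rids)[1:]):
            if r2 == r1 + 1:
                pairs.add(((c, r1), (c, r2)))
    return pairs
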