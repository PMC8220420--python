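"""Shared fixtures: inline PDB builders and small reference objects."""

from __future__ import annotations

import numpy as np
import pytest

from brr2allo.structure import Topology


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resid: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.0,
    element: str = "",
    altloc: str = " ",
) -> str:
    element = element or name[0]
    pad_name = f" {name:<3}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5} {pad_name}{altloc}{resname:>3} {chain}{resid:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}"
    )


@pytest.fixture
def write_pdb(tmp_path):
    """Write a PDB file from raw record lines; returns the path."""

    def _write(lines: list[str], name: str = "fixture.pdb"):
        path = tmp_path / name
        path.write_text("\n".join(lines + ["END"]) + "\n")
        return path

    return _write


def toy_topology(residue_atoms: list[tuple[str, int, list[tuple[str, str]]]]) -> Topology:
    """Topology from [(chain, resnum, [(atom_name, element), ...]), ...]."""
    names, elements, chains, resids, resnames = [], [], [], [], []
    for chain, resnum, atoms in residue_atoms:
        for nm, el in atoms:
            names.append(nm)
            elements.append(el)
            chains.append(chain)
            resids.append(resnum)
            resnames.append("SYN")
    return Topology(
        atom_names=np.array(names, dtype="U6"),
        elements=np.array(elements, dtype="U2"),
        chain_ids=np.array(chains, dtype="U4"),
        res_ids=np.array(resids, dtype=int),
        res_names=np.array(resnames, dtype="U5"),
    )
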