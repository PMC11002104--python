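"""Shared fixtures: handcrafted PDB text and small reference units."""

from __future__ import annotations

import numpy as np
import pytest

from fodm import make_micelle, unit_to_pdb


def atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
              x: float, y: float, z: float, occ: float = 1.0,
              altloc: str = " ", element: str = "C") -> str:
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )


def make_pdb_text(residues, chain: str = "A") -> str:
    """residues: list of (resname, resseq, [(atom, x, y, z), ...])."""
    lines = []
    serial = 1
    for resname, resseq, atoms in residues:
        for name, x, y, z in atoms:
            lines.append(atom_line(serial, name, resname, chain, resseq, x, y, z,
                                   element=name[0]))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_ala_pdb(tmp_path):
    """Minimal handcrafted PDB: one chain, three alanines."""
    residues = [
        ("ALA", 1, [("N", 0.0, 0.0, 0.0), ("CA", 1.5, 0.0, 0.0), ("C", 2.2, 1.2, 0.0)]),
        ("ALA", 2, [("N", 3.5, 1.5, 0.5), ("CA", 4.8, 2.0, 0.8), ("C", 5.5, 3.0, 1.0)]),
        ("ALA", 3, [("N", 6.8, 3.5, 1.5), ("CA", 8.0, 4.0, 2.0), ("C", 9.0, 5.0, 2.5)]),
    ]
    p = tmp_path / "three_ala.pdb"
    p.write_text(make_pdb_text(residues))
    return p


@pytest.fixture
def micelle_pdb(tmp_path):
    """Synthetic micelle-like unit written as a CA-only PDB."""
    p = tmp_path / "micelle.pdb"
    unit_to_pdb(make_micelle(100, seed=11), p)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
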