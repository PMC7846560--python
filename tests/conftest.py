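"""Shared fixtures: hand-written PDB micro-fixtures and small synthetic
ensemble specs.  All fixture data is generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from pvrscan.structure_io import Atom, Chain, MetalAtom, Residue, ResidueRef, Structure
from pvrscan.synthetic import PlantedRegion, SyntheticEnsembleSpec


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    element: str,
    occ: float = 1.0,
    altloc: str = " ",
    icode: str = " ",
    record: str = "ATOM",
) -> str:
    pad_name = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:5d} {pad_name}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Minimal 1-chain, 3-residue PDB file with full backbones."""
    lines = []
    serial = 1
    for i, (resname, x0) in enumerate([("ALA", 0.0), ("GLY", 3.8), ("SER", 7.6)], start=1):
        for name, elem, dx, dy in [("N", "N", -1.2, 0.3), ("CA", "C", 0.0, 0.0),
                                   ("C", "C", 1.1, 0.8), ("O", "O", 1.2, 2.0)]:
            lines.append(
                pdb_atom_line(serial, name, resname, "A", i, x0 + dx, dy, 0.0, elem)
            )
            serial += 1
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def assembly_pdb(tmp_path):
    """3-residue chain plus a REMARK 350 assembly with two operators
    (identity and a 180° rotation + shift)."""
    remark = """\
REMARK 350 BIOMOLECULE: 1
REMARK 350 APPLY THE FOLLOWING TO CHAINS: A
REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000
REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000
REMARK 350   BIOMT1   2 -1.000000  0.000000  0.000000       20.00000
REMARK 350   BIOMT2   2  0.000000 -1.000000  0.000000        0.00000
REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000        0.00000
"""
    lines = [remark.rstrip("\n")]
    serial = 1
    for i, resname in enumerate(["ALA", "GLY", "SER"], start=1):
        lines.append(
            pdb_atom_line(serial, "CA", resname, "A", i, 3.8 * i, 0.5 * i, 0.0, "C")
        )
        serial += 1
    path = tmp_path / "asm.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def identity_assembly_pdb(tmp_path):
    """3-residue chain with an identity-only assembly."""
    remark = """\
REMARK 350 BIOMOLECULE: 1
REMARK 350 APPLY THE FOLLOWING TO CHAINS: A
REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000
REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000
"""
    lines = [remark.rstrip("\n")]
    serial = 1
    for i, resname in enumerate(["ALA", "GLY", "SER"], start=1):
        lines.append(
            pdb_atom_line(serial, "CA", resname, "A", i, 3.8 * i, 0.0, 0.0, "C")
        )
        serial += 1
    path = tmp_path / "idasm.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def make_residue(sid, chain, seq, resname, atoms):
    """atoms: list of (name, element, xyz)."""
    return Residue(
        ref=ResidueRef(sid, chain, seq),
        name=resname,
        atoms=[Atom(name=n, element=e, pos=tuple(map(float, p))) for n, e, p in atoms],
    )


def ca_only_structure(sid: str, coords: np.ndarray, chain: str = "A", names=None) -> Structure:
    names = names or ["ALA"] * len(coords)
    residues = [
        make_residue(sid, chain, i + 1, names[i], [("CA", "C", coords[i])])
        for i in range(len(coords))
    ]
    return Structure(id=sid, chains=[Chain(chain_id=chain, residues=residues)])


@pytest.fixture
def zinc_site_structure():
    """A zinc ion with His/Asp-like ligands at controlled distances,
    including one exactly at the 3.0 Å boundary."""
    zn = np.array([0.0, 0.0, 0.0])
    residues = [
        make_residue("site", "A", 54, "HIS", [("CA", "C", (5.0, 0, 0)), ("NE2", "N", (2.1, 0, 0))]),
        make_residue("site", "A", 58, "ASP", [("CA", "C", (0, 5.0, 0)), ("OD1", "O", (0, 2.2, 0))]),
        make_residue("site", "A", 60, "HIS", [("CA", "C", (0, 0, 6.0)), ("ND1", "N", (0, 0, 3.0))]),
        make_residue("site", "A", 70, "SER", [("CA", "C", (8, 8, 8)), ("OG", "O", (7, 7, 7))]),
    ]
    s = Structure(
        id="site",
        chains=[Chain(chain_id="A", residues=residues)],
        metals=[MetalAtom(element="Zn", name="ZN", chain_id="A", seq_id=201, pos=tuple(zn))],
    )
    return s


@pytest.fixture
def small_spec():
    """Fast 3-structure spec with one planted region (range 15)."""
    return SyntheticEnsembleSpec(
        n_structures=3,
        core_blocks=(40, 40),
        planted_regions=(PlantedRegion(0, (0, 0, 15)),),
        noise_sigma=0.2,
        seed=11,
    )


@pytest.fixture
def benchmark_spec():
    """The standard benchmark conditions (5 structures, 250-residue core,
    planted ranges 15/25/40, noise 0.3 Å)."""
    return SyntheticEnsembleSpec(seed=0)
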