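"""Macromolecular structure I/O.

Reads PDB/mmCIF files into a light-weight in-memory model (chains of
residues with explicit atoms, hetero metal ions, biological-assembly
operators), resolves alternate conformations, and extracts CA traces for
structural alignment.  Parsing is delegated to gemmi; this module only
normalises the result into the small domain types the rest of the package
consumes.

Conventions
-----------
* Residues are identified by *author* numbering plus insertion code, the
  naming used throughout the literature on this fold (His54, Asp144, ...).
* Alternate locations are resolved to the highest-occupancy conformer
  (first wins on ties); resolution never changes the residue count.
* Only model 1 of multi-model files is read.
* Waters are never part of assemblies; hetero metal ions are.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

import gemmi

logger = logging.getLogger(__name__)

#: hetero elements treated as metal cofactors by default
DEFAULT_METAL_ELEMENTS = frozenset({"Zn", "Ni", "Fe", "Mn", "Cu", "Co", "Mg", "Ca"})

_CHAIN_ID_POOL = string.ascii_uppercase + string.digits + string.ascii_lowercase


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed into a usable model."""


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Identity of one residue: structure, chain, author seq number, icode."""

    structure_id: str
    chain_id: str
    seq_id: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.structure_id}/{self.chain_id}/{self.seq_id}{self.icode}"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: tuple[float, float, float]
    occ: float = 1.0
    altloc: str = ""

    @property
    def coord(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass
class Residue:
    ref: ResidueRef
    name: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)

    @property
    def ca(self) -> Optional[np.ndarray]:
        """Coordinate of the alpha carbon, or None if absent."""
        for a in self.atoms:
            if a.name == "CA" and a.element == "C":
                return a.coord
        return None

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def sequence(self) -> list[str]:
        return [r.name for r in self.residues]


@dataclass(frozen=True)
class MetalAtom:
    element: str
    name: str
    chain_id: str
    seq_id: int
    pos: tuple[float, float, float]

    @property
    def coord(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)

    @property
    def label(self) -> str:
        return f"{self.element}_{self.chain_id}{self.seq_id}"


@dataclass
class AssemblyOp:
    """One (chain set, rigid operator) generator of a biological assembly."""

    chain_ids: list[str]
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # 3

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


@dataclass
class Structure:
    """A parsed macromolecular model (single coordinate model)."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    metals: list[MetalAtom] = field(default_factory=list)
    assembly_ops: dict[str, list[AssemblyOp]] = field(default_factory=dict)
    source_format: str = "pdb"
    n_heavy_atoms: int = 0  # all non-H atoms in the file, incl. ligands/solvent

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in structure {self.id}: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(
            f"chain {chain_id!r} not in structure {self.id} "
            f"(have {[c.chain_id for c in self.chains]})"
        )

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def first_polymer_chain(self) -> Chain:
        if not self.chains:
            raise ValueError(f"structure {self.id} has no polymer chains")
        return self.chains[0]

    @property
    def n_polymer_residues(self) -> int:
        return sum(len(c) for c in self.chains)


def _resolve_altlocs(atoms: Sequence[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, first on tie."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occ > best[a.name].occ:
            best[a.name] = a
    return [replace(best[n], altloc="") for n in order]


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    return res.het_flag == "A"


def read_structure(
    path: str | Path,
    format: Optional[str] = None,
    metal_elements: frozenset[str] = DEFAULT_METAL_ELEMENTS,
    structure_id: Optional[str] = None,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        Coordinate file.  Format is inferred from the extension unless
        ``format`` ("pdb" or "mmcif") overrides it.
    metal_elements:
        Hetero atoms of these elements are collected as metal cofactors.
    structure_id:
        Label for the structure; defaults to the file stem.

    Only model 1 is read.  Altlocs are resolved to the highest-occupancy
    conformer.  No hydrogens are synthesised; ``n_heavy_atoms`` counts every
    non-hydrogen atom in the file (macromolecule, ligands and solvent) before
    altloc resolution collapses conformers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt_map = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
    try:
        if format is not None:
            if format not in fmt_map:
                raise StructureParseError(f"unknown format {format!r}")
            st = gemmi.read_structure(str(path), format=fmt_map[format])
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no coordinate model")
    st.setup_entities()
    model = st[0]
    sid = structure_id or path.stem

    src_fmt = "mmcif" if (
        format == "mmcif" or (format is None and path.suffix.lower() in {".cif", ".mmcif"})
    ) else "pdb"

    chains: list[Chain] = []
    metals: list[MetalAtom] = []
    n_heavy = 0
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            heavy = [a for a in gres if a.element.name != "H"]
            n_heavy += len(heavy)
            if gres.is_water():
                continue
            if _is_polymer_residue(gres):
                atoms = [
                    Atom(
                        name=a.name,
                        element=a.element.name,
                        pos=(a.pos.x, a.pos.y, a.pos.z),
                        occ=a.occ,
                        altloc=a.altloc if a.altloc != "\x00" else "",
                    )
                    for a in gres
                    if a.element.name != "H"
                ]
                ref = ResidueRef(sid, gchain.name, gres.seqid.num, gres.seqid.icode.strip())
                residues.append(Residue(ref=ref, name=gres.name, atoms=_resolve_altlocs(atoms)))
            else:
                for a in gres:
                    if a.element.name in metal_elements:
                        metals.append(
                            MetalAtom(
                                element=a.element.name,
                                name=a.name,
                                chain_id=gchain.name,
                                seq_id=gres.seqid.num,
                                pos=(a.pos.x, a.pos.y, a.pos.z),
                            )
                        )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    if not chains:
        raise StructureParseError(f"{path}: no polymer residues found (empty model)")

    assembly_ops: dict[str, list[AssemblyOp]] = {}
    for asm in st.assemblies:
        ops: list[AssemblyOp] = []
        for gen in asm.generators:
            chain_ids = [c for c in gen.chains]
            for op in gen.operators:
                tr = op.transform
                ops.append(
                    AssemblyOp(
                        chain_ids=chain_ids,
                        rotation=np.array(tr.mat.tolist(), dtype=float),
                        translation=np.array(tr.vec.tolist(), dtype=float),
                    )
                )
        if ops:
            assembly_ops[asm.name] = ops

    return Structure(
        id=sid,
        chains=chains,
        metals=metals,
        assembly_ops=assembly_ops,
        source_format=src_fmt,
        n_heavy_atoms=n_heavy,
    )


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure as a PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    gchains: dict[str, gemmi.Chain] = {}
    for chain in s.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.ref.seq_id, res.ref.icode or " ")
            gres.het_flag = "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occ
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gchains[chain.chain_id] = gchain
    # metals are appended as HETATM residues of their parent chain
    for m in s.metals:
        ch = gchains.setdefault(m.chain_id, gemmi.Chain(m.chain_id))
        gres = gemmi.Residue()
        gres.name = m.element.upper()
        gres.seqid = gemmi.SeqId(m.seq_id, " ")
        gres.het_flag = "H"
        ga = gemmi.Atom()
        ga.name = m.name
        ga.element = gemmi.Element(m.element)
        ga.pos = gemmi.Position(*m.pos)
        gres.add_atom(ga)
        ch.add_residue(gres)
    for ch in gchains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def build_assembly(s: Structure, assembly_id: str) -> Structure:
    """Expand a biological assembly into an explicit multi-chain Structure.

    One chain copy is produced per (chain x operator); copies get fresh
    single-character chain ids.  Metals belonging to an included chain are
    transformed along with it.  The input structure is left unmodified.
    """
    if assembly_id not in s.assembly_ops:
        raise KeyError(
            f"assembly {assembly_id!r} not defined for {s.id}; "
            f"available: {sorted(s.assembly_ops)}"
        )
    ops = s.assembly_ops[assembly_id]
    if not ops:
        raise ValueError(f"assembly {assembly_id!r} of {s.id} has no operators")

    new_chains: list[Chain] = []
    new_metals: list[MetalAtom] = []
    used: set[str] = set()

    def next_chain_id() -> str:
        for cand in _CHAIN_ID_POOL:
            if cand not in used:
                used.add(cand)
                return cand
        raise ValueError("ran out of chain ids while expanding assembly")

    n_atoms = 0
    for op in ops:
        for cid in op.chain_ids:
            try:
                chain = s.chain(cid)
            except KeyError:
                continue  # operator may reference het-only chains
            new_id = next_chain_id()
            residues = []
            for res in chain.residues:
                atoms = [
                    Atom(
                        name=a.name,
                        element=a.element,
                        pos=tuple(op.apply(a.coord)),
                        occ=a.occ,
                    )
                    for a in res.atoms
                ]
                n_atoms += len(atoms)
                ref = ResidueRef(s.id, new_id, res.ref.seq_id, res.ref.icode)
                residues.append(Residue(ref=ref, name=res.name, atoms=atoms))
            new_chains.append(Chain(chain_id=new_id, residues=residues))
            for m in s.metals:
                if m.chain_id == cid:
                    new_metals.append(
                        MetalAtom(
                            element=m.element,
                            name=m.name,
                            chain_id=new_id,
                            seq_id=m.seq_id,
                            pos=tuple(op.apply(m.coord)),
                        )
                    )
    return Structure(
        id=f"{s.id}_asm{assembly_id}",
        chains=new_chains,
        metals=new_metals,
        assembly_ops={},
        source_format=s.source_format,
        n_heavy_atoms=n_atoms + len(new_metals),
    )


def ca_trace(s: Structure, chain_id: Optional[str] = None) -> list[tuple[ResidueRef, np.ndarray]]:
    """Ordered (ResidueRef, CA coordinate) list for one chain.

    Residues without a CA atom are skipped with a warning; downstream
    alignment treats them as gaps.
    """
    chain = s.chain(chain_id) if chain_id is not None else s.first_polymer_chain()
    trace = []
    for res in chain.residues:
        ca = res.ca
        if ca is None:
            logger.warning("residue %s (%s) has no CA atom; skipped", res.ref, res.name)
            continue
        if not np.all(np.isfinite(ca)):
            raise ValueError(f"non-finite CA coordinate at {res.ref}")
        trace.append((res.ref, ca))
    return trace


def trace_names(s: Structure, chain_id: Optional[str] = None) -> list[str]:
    """Residue 3-letter codes matching the entries of :func:`ca_trace`."""
    chain = s.chain(chain_id) if chain_id is not None else s.first_polymer_chain()
    return [r.name for r in chain.residues if r.ca is not None]


ONE_LETTER_FALLBACK = "X"


def one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return ONE_LETTER_FALLBACK
    code = info.one_letter_code.upper()
    return code if code.isalpha() else ONE_LETTER_FALLBACK
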