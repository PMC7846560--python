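"""Metal coordination spheres, buried interface area, interface H-bonds.

Solvent-accessible surface area uses a deterministic Shrake-Rupley sampler
(Fibonacci sphere, 960 points per atom, probe 1.4 Å) over a pinned
Bondi-style van der Waals radius table.  Interface area is reported as half
the buried SASA (the PISA convention).  Hydrogen bonds are counted by
heavy-atom donor/acceptor distance only — X-ray models carry no hydrogens,
so no angle criterion is applied; donor/acceptor capability comes from a
fixed per-residue atom dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import MetalAtom, ResidueRef, Structure

#: Bondi-style van der Waals radii (Å); unknown elements fall back to 1.80
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "Se": 1.90,
    "Zn": 1.39,
    "Fe": 1.40,
    "Ni": 1.63,
    "Cu": 1.40,
    "Mn": 1.40,
    "Co": 1.40,
    "Mg": 1.73,
    "Ca": 1.70,
}
VDW_DEFAULT = 1.80

DEFAULT_SASA_POINTS = 960
DEFAULT_PROBE = 1.4

#: residue/atom -> hydrogen-bond capability (heavy atoms only)
_BACKBONE_DONORS = {"N"}
_BACKBONE_ACCEPTORS = {"O", "OXT"}
_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
}
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "MET": set(),
}


@dataclass(frozen=True)
class Ligand:
    ref: ResidueRef
    resname: str
    atom: str
    distance: float


@dataclass
class CoordinationSite:
    metal: MetalAtom
    ligands: list[Ligand]

    @property
    def residues(self) -> set[tuple[str, int]]:
        """Coordinating residues as (3-letter name, author number) pairs."""
        return {(lig.resname, lig.ref.seq_id) for lig in self.ligands}


def find_metal_sites(
    s: Structure,
    cutoff: float = 3.0,
    ligand_elements: Sequence[str] = ("N", "O", "S"),
) -> list[CoordinationSite]:
    """Coordination sphere of every metal: polymer N/O/S atoms within
    ``cutoff`` (inclusive), grouped by residue, sorted by metal id."""
    elem_set = set(ligand_elements)
    atoms: list[tuple[ResidueRef, str, str, np.ndarray]] = []
    for chain in s.chains:
        for res in chain.residues:
            for a in res.atoms:
                if a.element in elem_set:
                    atoms.append((res.ref, res.name, a.name, a.coord))
    sites: list[CoordinationSite] = []
    if atoms:
        coords = np.array([a[3] for a in atoms])
        tree = cKDTree(coords)
    for m in sorted(s.metals, key=lambda m: (m.chain_id, m.seq_id, m.element)):
        ligands: list[Ligand] = []
        if atoms:
            for idx in tree.query_ball_point(m.coord, cutoff):
                ref, resname, aname, coord = atoms[idx]
                dist = float(np.linalg.norm(coord - m.coord))
                if dist <= cutoff:
                    ligands.append(Ligand(ref=ref, resname=resname, atom=aname, distance=dist))
        ligands.sort(key=lambda x: x.distance)
        sites.append(CoordinationSite(metal=m, ligands=ligands))
    return sites


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere point set."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    sphere = fibonacci_sphere(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    max_r = ext.max()
    out = np.zeros(n)
    for i in range(n):
        ri = ext[i]
        pts = coords[i] + ri * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i]
        if neigh:
            nc = coords[neigh]
            nr = ext[neigh]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        out[i] = 4.0 * np.pi * ri * ri * n_acc / n_points
    return out


def _chain_atoms(
    s: Structure, chain_id: str
) -> tuple[list[tuple[ResidueRef, str, str, str]], np.ndarray, np.ndarray]:
    chain = s.chain(chain_id)
    meta: list[tuple[ResidueRef, str, str, str]] = []  # (ref, resname, atom, element)
    coords = []
    for res in chain.residues:
        for a in res.atoms:
            meta.append((res.ref, res.name, a.name, a.element))
            coords.append(a.coord)
    coords = np.array(coords) if coords else np.zeros((0, 3))
    radii = np.array([VDW_RADII.get(e, VDW_DEFAULT) for *_, e in meta])
    return meta, coords, radii


def interface_area(
    assembly: Structure,
    chains: tuple[str, str],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
    radii_override: Optional[dict[str, float]] = None,
) -> float:
    """Buried interface area between two chains (Å², PISA convention).

    buried = SASA(A alone) + SASA(B alone) - SASA(A and B together); half of
    that is reported as the interface area.
    """
    ca, cb = chains
    _, xa, ra = _chain_atoms(assembly, ca)
    _, xb, rb = _chain_atoms(assembly, cb)
    if radii_override:
        meta_a, _, _ = _chain_atoms(assembly, ca)
        meta_b, _, _ = _chain_atoms(assembly, cb)
        ra = np.array([radii_override.get(e, VDW_RADII.get(e, VDW_DEFAULT)) for *_, e in meta_a])
        rb = np.array([radii_override.get(e, VDW_RADII.get(e, VDW_DEFAULT)) for *_, e in meta_b])
    sasa_a = shrake_rupley_sasa(xa, ra, probe, n_points).sum()
    sasa_b = shrake_rupley_sasa(xb, rb, probe, n_points).sum()
    xab = np.vstack([xa, xb])
    rab = np.concatenate([ra, rb])
    sasa_ab = shrake_rupley_sasa(xab, rab, probe, n_points).sum()
    return float((sasa_a + sasa_b - sasa_ab) / 2.0)


def _is_donor(resname: str, atom: str) -> bool:
    if atom in _BACKBONE_DONORS and resname != "PRO":
        return True
    return atom in _SIDECHAIN_DONORS.get(resname, set())


def _is_acceptor(resname: str, atom: str) -> bool:
    if atom in _BACKBONE_ACCEPTORS:
        return True
    return atom in _SIDECHAIN_ACCEPTORS.get(resname, set())


@dataclass
class InterfaceReport:
    chains: tuple[str, str]
    buried_area: Optional[float]
    hbonds: list[tuple[ResidueRef, str, ResidueRef, str, float]]

    @property
    def hbond_count(self) -> int:
        return len(self.hbonds)


def count_interface_hbonds(
    assembly: Structure,
    chains: tuple[str, str],
    d_max: float = 3.5,
    buried_area: Optional[float] = None,
) -> InterfaceReport:
    """Inter-chain hydrogen bonds by heavy-atom donor/acceptor distance.

    A bond is a (donor-capable N/O in one chain, acceptor-capable N/O in the
    other) pair at distance <= ``d_max``; each unordered atom pair counts
    once even when both atoms are amphoteric.
    """
    ca, cb = chains
    meta_a, xa, _ = _chain_atoms(assembly, ca)
    meta_b, xb, _ = _chain_atoms(assembly, cb)
    polar_a = [
        (i, ref, rn, an) for i, (ref, rn, an, el) in enumerate(meta_a) if el in ("N", "O")
    ]
    polar_b = [
        (i, ref, rn, an) for i, (ref, rn, an, el) in enumerate(meta_b) if el in ("N", "O")
    ]
    bonds: list[tuple[ResidueRef, str, ResidueRef, str, float]] = []
    seen: set[tuple] = set()
    if polar_a and polar_b:
        pa = xa[[i for i, *_ in polar_a]]
        pb = xb[[i for i, *_ in polar_b]]
        tree_b = cKDTree(pb)
        for k, (ia, ref_a, rn_a, an_a) in enumerate(polar_a):
            for kb in tree_b.query_ball_point(pa[k], d_max):
                ib, ref_b, rn_b, an_b = polar_b[kb]
                dist = float(np.linalg.norm(pa[k] - pb[kb]))
                if dist > d_max:
                    continue
                ab = _is_donor(rn_a, an_a) and _is_acceptor(rn_b, an_b)
                ba = _is_donor(rn_b, an_b) and _is_acceptor(rn_a, an_a)
                if not (ab or ba):
                    continue
                key = (ref_a, an_a, ref_b, an_b)
                if key in seen:
                    continue
                seen.add(key)
                bonds.append((ref_a, an_a, ref_b, an_b, dist))
    bonds.sort(key=lambda b: b[4])
    return InterfaceReport(chains=chains, buried_area=buried_area, hbonds=bonds)


def two_sphere_buried_area(r1: float, r2: float, d: float, probe: float = 0.0) -> float:
    """Analytic buried SASA for two spheres (radii already include any probe
    expansion when probe=0).  Used as an independent oracle for the sampler.

    Returns the total area of both spherical caps hidden inside the other
    sphere; 0 when the (probe-expanded) spheres do not intersect.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 0.0
    if d <= abs(R1 - R2):
        rs = min(R1, R2)
        return 4.0 * np.pi * rs * rs
    # distance from center 1 to the plane of intersection
    x1 = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    h1 = R1 - x1
    h2 = R2 - (d - x1)
    return float(2.0 * np.pi * R1 * h1 + 2.0 * np.pi * R2 * h2)
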