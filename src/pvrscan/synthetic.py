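"""Synthetic structure ensembles with known variable regions.

The generator emulates the statistical situation the PVR analysis assumes:
a set of single-chain CA-resolved structures sharing a rigid conserved core
(inter-structure positional noise well below the anchor threshold),
interrupted at chosen points by planted segments whose length differs per
structure (differences exceeding the length-range threshold), each
structure under an arbitrary rigid-body motion.  Because the planted
regions and the core correspondence are known exactly, the generator also
emits the ground-truth multiple alignment and PVR table against which every
other module is tested.

Geometry: the core is a smooth self-avoiding CA walk with exact 3.8 Å
consecutive-CA spacing; a planted segment of n residues is laid out on a
circular arc of n+2 equal 3.8 Å chords joining its two flanking core
residues, in a plane rotated randomly about the flank-flank axis (exact
chain closure by construction), with an excluded-volume check against the
core.  Structures are CA-only; that is all the alignment stack consumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .multi_alignment import Column, Insertion, MultipleAlignment
from .pvr_analysis import PVR, PVRTable, Segment
from .structure_io import Atom, Chain, MetalAtom, Residue, ResidueRef, Structure, write_structure
from .superposition import RigidTransform

CA_SPACING = 3.8
MIN_CLEARANCE = 2.5

AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


@dataclass(frozen=True)
class PlantedRegion:
    """A variable segment planted between core blocks.

    ``after_block`` is the index of the core block the segment follows
    (0-based); ``lengths`` gives the number of inserted residues for each
    structure (0 allowed).
    """

    after_block: int
    lengths: tuple[int, ...]

    @property
    def length_range(self) -> int:
        return max(self.lengths) - min(self.lengths)


@dataclass(frozen=True)
class MetalSpec:
    """Plant one metal ion at the centroid of the given core CA positions."""

    element: str = "ZN"
    anchor_core_indices: tuple[int, ...] = ()


@dataclass(frozen=True)
class SyntheticEnsembleSpec:
    """Generative parameters of one synthetic ensemble.

    Defaults are the package's standard benchmark conditions: five
    structures over a 250-residue conserved core with three planted regions
    whose per-structure length ranges are 15, 25 and 40 residues, core
    noise 0.3 Å per axis, and a random rigid motion per structure.
    """

    n_structures: int = 5
    core_blocks: tuple[int, ...] = (63, 62, 63, 62)
    planted_regions: tuple[PlantedRegion, ...] = (
        PlantedRegion(0, (0, 4, 8, 11, 15)),
        PlantedRegion(1, (0, 6, 12, 19, 25)),
        PlantedRegion(2, (0, 10, 20, 30, 40)),
    )
    noise_sigma: float = 0.3
    transforms: str | tuple = "random"  # "random", "identity", or explicit list
    seed: int = 0
    metal: Optional[MetalSpec] = None
    n_copies: int = 1
    range_cut: int = 10
    structure_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for pr in self.planted_regions:
            if len(pr.lengths) != self.n_structures:
                raise ValueError(
                    f"planted region after block {pr.after_block} has "
                    f"{len(pr.lengths)} lengths for {self.n_structures} structures"
                )
            if pr.after_block < 0 or pr.after_block >= len(self.core_blocks) - 1:
                raise ValueError("planted region must sit between two core blocks")

    @property
    def core_length(self) -> int:
        return sum(self.core_blocks)

    @property
    def structure_ids(self) -> list[str]:
        return [f"{self.structure_prefix}{i}" for i in range(self.n_structures)]


def perturb_case(spec: SyntheticEnsembleSpec, overrides: dict) -> SyntheticEnsembleSpec:
    """Copy of ``spec`` with the given fields replaced (for parameter sweeps)."""
    valid = {f.name for f in dataclasses.fields(SyntheticEnsembleSpec)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown SyntheticEnsembleSpec fields: {sorted(unknown)}")
    return dataclasses.replace(spec, **overrides)


def _core_walk(n: int, rng: np.random.Generator, max_restarts: int = 20) -> np.ndarray:
    """Smooth self-avoiding walk of n points with exact 3.8 Å steps."""
    for _ in range(max_restarts):
        pts = np.zeros((n, 3))
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        ok = True
        for i in range(1, n):
            placed = False
            for _attempt in range(60):
                cand_dir = d + 0.45 * rng.standard_normal(3)
                cand_dir /= np.linalg.norm(cand_dir)
                cand = pts[i - 1] + CA_SPACING * cand_dir
                prev = pts[: max(i - 1, 0)]
                if prev.size == 0 or np.min(np.linalg.norm(prev - cand, axis=1)) >= MIN_CLEARANCE:
                    pts[i] = cand
                    d = cand_dir
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    raise RuntimeError("could not generate a self-avoiding core walk")


def _arc_loop(
    start: np.ndarray,
    end: np.ndarray,
    n: int,
    core: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 72,
    exclude: tuple[int, int] = (-1, -1),
) -> np.ndarray:
    """n loop residues on a circular arc of n+1 equal 3.8 Å chords from
    ``start`` to ``end``, in a plane rotated randomly about the start-end
    axis, keeping >= 2.5 Å clearance from the non-local core (residues in
    ``exclude``'s index window are chain neighbours of the loop and are
    exempt from the clash check)."""
    d = float(np.linalg.norm(end - start))
    steps = n + 1
    if d >= steps * CA_SPACING:
        raise RuntimeError("gap too wide for requested loop length")

    # arc angle per chord phi solves d/step = sin(steps*phi/2)/sin(phi/2)
    def f(phi: float) -> float:
        return CA_SPACING * np.sin(steps * phi / 2.0) / np.sin(phi / 2.0) - d

    # the relevant root lies below 2*pi/steps (arc opening past half circle)
    hi = 2.0 * np.pi / steps
    lo = hi * 1e-6
    # f(lo) ~ steps*3.8 - d > 0, f(hi) = -d < 0  -> bracketed
    phi = brentq(f, lo, hi - 1e-12)
    total = steps * phi
    R = CA_SPACING / (2.0 * np.sin(phi / 2.0))

    axis = (end - start) / d
    # seed perpendicular
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, axis)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    perp0 = seed - np.dot(seed, axis) * axis
    perp0 /= np.linalg.norm(perp0)

    mid = (start + end) / 2.0
    # circle center is offset from the chord midpoint by sqrt(R^2 - (d/2)^2)
    off = np.sqrt(max(R * R - (d / 2.0) ** 2, 0.0))
    angles = phi * np.arange(1, n + 1)  # interior vertices along the arc

    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    for k in range(max_attempts):
        theta = theta0 + 2.0 * np.pi * k / max_attempts
        perp = Rotation.from_rotvec(axis * theta).apply(perp0)
        center = mid + off * perp
        u = (start - center) / np.linalg.norm(start - center)
        v_end = (end - center) / np.linalg.norm(end - center)
        # rotate u about the circle normal towards v_end through `total`
        normal = np.cross(u, v_end)
        nn = np.linalg.norm(normal)
        if nn < 1e-9:  # antipodal chord: pick any normal orthogonal to u
            normal = np.cross(u, axis)
            nn = np.linalg.norm(normal)
        normal /= nn
        pts = np.array(
            [center + R * Rotation.from_rotvec(normal * a).apply(u) for a in angles]
        )
        # closure sanity: last interior vertex must be one chord from `end`
        if abs(np.linalg.norm(pts[-1] - end) - CA_SPACING) > 1e-6:
            # arc may run the wrong way round; flip the normal
            pts = np.array(
                [center + R * Rotation.from_rotvec(-normal * a).apply(u) for a in angles]
            )
            if abs(np.linalg.norm(pts[-1] - end) - CA_SPACING) > 1e-6:
                continue
        mask = np.ones(len(core), dtype=bool)
        lo, hi_ex = exclude
        if hi_ex >= lo >= 0:
            mask[max(lo, 0) : hi_ex + 1] = False
        dmin = np.min(
            np.linalg.norm(core[mask][None, :, :] - pts[:, None, :], axis=2)
        )
        if dmin >= MIN_CLEARANCE:
            return pts
    raise RuntimeError(
        f"no clash-free loop orientation found for {n}-residue segment "
        f"after {max_attempts} attempts"
    )


def _random_transform(rng: np.random.Generator) -> RigidTransform:
    q = rng.standard_normal(4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-30.0, 30.0, size=3)
    return RigidTransform(R, t)


@dataclass
class SyntheticEnsemble:
    spec: SyntheticEnsembleSpec
    structures: list[Structure]
    truth: PVRTable
    truth_msa: MultipleAlignment
    applied_transforms: list[RigidTransform] = field(default_factory=list)


def generate_ensemble(spec: SyntheticEnsembleSpec) -> SyntheticEnsemble:
    """Generate the ensemble, its ground-truth MSA and PVR table.

    Same seed, same spec -> bit-identical structures.
    """
    rng = np.random.default_rng(spec.seed)
    n_core = spec.core_length
    core = _core_walk(n_core, rng)
    core_names = [AA3[i] for i in rng.integers(0, 20, size=n_core)]

    # block boundaries: planted region r sits after core index bounds[r]-1
    cum = np.cumsum(spec.core_blocks)
    junction_after = {pr.after_block: cum[pr.after_block] - 1 for pr in spec.planted_regions}

    # per-structure loop geometry (in the shared frame, pre-noise/transform)
    loops: dict[tuple[int, int], np.ndarray] = {}  # (struct, region) -> (n,3)
    for r_idx, pr in enumerate(spec.planted_regions):
        j = junction_after[pr.after_block]
        for s_idx, ln in enumerate(pr.lengths):
            if ln == 0:
                continue
            loops[(s_idx, r_idx)] = _arc_loop(
                core[j], core[j + 1], ln, core, rng, exclude=(j - 2, j + 3)
            )

    # transforms
    if spec.transforms == "random":
        transforms = [_random_transform(rng) for _ in range(spec.n_structures)]
    elif spec.transforms == "identity":
        transforms = [RigidTransform.identity() for _ in range(spec.n_structures)]
    else:
        transforms = list(spec.transforms)
        if len(transforms) != spec.n_structures:
            raise ValueError("need one transform per structure")

    region_by_junction = {
        junction_after[pr.after_block]: (r_idx, pr)
        for r_idx, pr in enumerate(spec.planted_regions)
    }

    ids = spec.structure_ids
    structures: list[Structure] = []
    traces_truth: dict[str, list] = {}
    names_truth: dict[str, list[str]] = {}
    core_trace_idx: dict[str, list[int]] = {}  # trace index of each core residue
    loop_trace_idx: dict[tuple[int, int], list[int]] = {}

    for s_idx, sid in enumerate(ids):
        noisy_core = core + (
            rng.normal(0.0, spec.noise_sigma, size=core.shape) if spec.noise_sigma > 0 else 0.0
        )
        coords: list[np.ndarray] = []
        names: list[str] = []
        c_idx: list[int] = []
        for j in range(n_core):
            c_idx.append(len(coords))
            coords.append(noisy_core[j])
            names.append(core_names[j])
            if j in region_by_junction:
                r_idx, pr = region_by_junction[j]
                ln = pr.lengths[s_idx]
                if ln:
                    loop_trace_idx[(s_idx, r_idx)] = list(
                        range(len(coords), len(coords) + ln)
                    )
                    for p in loops[(s_idx, r_idx)]:
                        coords.append(p)
                        names.append(AA3[rng.integers(0, 20)])
                else:
                    loop_trace_idx[(s_idx, r_idx)] = []
        xyz = transforms[s_idx].apply(np.array(coords))
        residues = [
            Residue(
                ref=ResidueRef(sid, "A", i + 1),
                name=names[i],
                atoms=[Atom(name="CA", element="C", pos=tuple(xyz[i]))],
            )
            for i in range(len(coords))
        ]
        chains = [Chain(chain_id="A", residues=residues)]
        metals: list[MetalAtom] = []
        if spec.metal is not None and spec.metal.anchor_core_indices:
            anchor_pts = xyz[[c_idx[i] for i in spec.metal.anchor_core_indices]]
            pos = anchor_pts.mean(axis=0)  # centroid of the anchor CAs
            metals.append(
                MetalAtom(
                    element=spec.metal.element.capitalize(),
                    name=spec.metal.element.upper(),
                    chain_id="A",
                    seq_id=9000,
                    pos=tuple(pos),
                )
            )
        if spec.n_copies > 1:
            base = chains[0]
            centroid = xyz.mean(axis=0)
            axis_point = centroid + np.array([60.0, 0.0, 0.0])
            new_chains = []
            new_metals = []
            for k in range(spec.n_copies):
                ang = 2.0 * np.pi * k / spec.n_copies
                Rk = Rotation.from_rotvec(np.array([0.0, 0.0, ang])).as_matrix()
                cid = chr(ord("A") + k)
                res_k = [
                    Residue(
                        ref=ResidueRef(sid, cid, r.ref.seq_id),
                        name=r.name,
                        atoms=[
                            Atom(
                                name=a.name,
                                element=a.element,
                                pos=tuple((a.coord - axis_point) @ Rk.T + axis_point),
                            )
                            for a in r.atoms
                        ],
                    )
                    for r in base.residues
                ]
                new_chains.append(Chain(chain_id=cid, residues=res_k))
                for m in metals:
                    new_metals.append(
                        MetalAtom(
                            element=m.element,
                            name=m.name,
                            chain_id=cid,
                            seq_id=m.seq_id,
                            pos=tuple((m.coord - axis_point) @ Rk.T + axis_point),
                        )
                    )
            chains = new_chains
            metals = new_metals
        n_atoms = sum(len(r.atoms) for c in chains for r in c.residues) + len(metals)
        structures.append(
            Structure(
                id=sid,
                chains=chains,
                metals=metals,
                source_format="pdb",
                n_heavy_atoms=n_atoms,
            )
        )
        trace = [(r.ref, r.ca) for r in structures[-1].chains[0].residues]
        traces_truth[sid] = trace
        names_truth[sid] = list(names)
        core_trace_idx[sid] = c_idx

    # ---- ground-truth MSA -------------------------------------------------
    columns = [
        Column(index=j, cells={ids[s]: core_trace_idx[ids[s]][j] for s in range(len(ids))})
        for j in range(n_core)
    ]
    insertions = [
        Insertion(
            structure_id=ids[s_idx],
            after_col=junction_after[pr.after_block],
            trace_indices=loop_trace_idx[(s_idx, r_idx)],
        )
        for r_idx, pr in enumerate(spec.planted_regions)
        for s_idx in range(len(ids))
        if loop_trace_idx.get((s_idx, r_idx))
    ]
    # star convention: map each structure into the reference's frame
    msa_transforms = {
        ids[s]: transforms[0].compose(transforms[s].inverse()) for s in range(len(ids))
    }
    truth_msa = MultipleAlignment(
        reference_id=ids[0],
        structure_ids=list(ids),
        columns=columns,
        insertions=insertions,
        transforms=msa_transforms,
        traces=traces_truth,
        names=names_truth,
    )

    # ---- ground-truth PVR table ------------------------------------------
    pvrs: list[PVR] = []
    for r_idx, pr in enumerate(spec.planted_regions):
        if pr.length_range <= spec.range_cut:
            continue
        j = junction_after[pr.after_block]
        segments: dict[str, Segment] = {}
        for s_idx, sid in enumerate(ids):
            idxs = loop_trace_idx.get((s_idx, r_idx), [])
            if idxs:
                trace = traces_truth[sid]
                segments[sid] = Segment(
                    first=trace[idxs[0]][0], last=trace[idxs[-1]][0], length=len(idxs)
                )
            else:
                segments[sid] = Segment(first=None, last=None, length=0)
        pvrs.append(
            PVR(
                pvr_id=len(pvrs) + 1,
                kind="internal",
                start_anchor=j,
                end_anchor=j + 1,
                segments=segments,
                length_range=pr.length_range,
            )
        )
    ref = ids[0]
    sigma_abs = {
        sid: int(
            sum(abs(p.segments[sid].length - p.segments[ref].length) for p in pvrs)
        )
        for sid in ids
    }
    truth = PVRTable(
        pvrs=pvrs,
        sigma_abs=sigma_abs,
        reference_id=ref,
        rmsd_cut=2.0,
        range_cut=spec.range_cut,
    )
    return SyntheticEnsemble(
        spec=spec,
        structures=structures,
        truth=truth,
        truth_msa=truth_msa,
        applied_transforms=transforms,
    )


def write_ensemble(ens: SyntheticEnsemble, out_dir: str | Path) -> list[Path]:
    """Write each structure as a PDB file (plus a seed note in the name)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in ens.structures:
        p = out_dir / f"{s.id}.pdb"
        write_structure(s, p)
        paths.append(p)
    return paths
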