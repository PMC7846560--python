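"""Protein Variable Region (PVR) calling and divergence scoring.

A PVR is a stretch of structure between two *anchor* positions — alignment
columns occupied by every structure whose cross-structure CA spread (RMSD
about the column centroid, measured after one global superposition per
structure) is below a cut-off (default 2 Å) — whose length varies across
the structure set by more than a range threshold (default 10 residues).
The N- and C-terminal regions are bounded by a single anchor.  Per
structure, the divergence score sigma_abs is the sum over PVRs of the
absolute difference between that structure's segment length and the
reference's.

Both thresholds are strict inequalities and both are configurable; for
protein families with a less rigid conserved core a higher RMSD cut-off is
appropriate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .multi_alignment import MultipleAlignment
from .structure_io import ResidueRef


class PVRError(ValueError):
    pass


@dataclass
class AnchorProfile:
    """Per-column occupancy and positional spread of the alignment."""

    occupancy: np.ndarray  # (n_cols,) int
    column_rmsd: np.ndarray  # (n_cols,) float, +inf where not fully occupied
    n_structures: int

    def __len__(self) -> int:
        return len(self.occupancy)


@dataclass
class Segment:
    """One structure's residues within a PVR (empty segments allowed)."""

    first: Optional[ResidueRef]
    last: Optional[ResidueRef]
    length: int


@dataclass
class PVR:
    pvr_id: int  # 1-based, N->C
    kind: str  # internal | N_terminal | C_terminal
    start_anchor: Optional[int]  # column index; None for N_terminal
    end_anchor: Optional[int]  # column index; None for C_terminal
    segments: dict[str, Segment]
    length_range: int

    @property
    def lengths(self) -> dict[str, int]:
        return {sid: seg.length for sid, seg in self.segments.items()}


@dataclass
class PVRTable:
    pvrs: list[PVR]
    sigma_abs: dict[str, int]
    reference_id: str
    rmsd_cut: float
    range_cut: int

    @property
    def n_pvrs(self) -> int:
        return len(self.pvrs)

    def lengths_frame(self) -> pd.DataFrame:
        """PVR lengths per structure, one row per structure."""
        data = {f"PVR{p.pvr_id}": p.lengths for p in self.pvrs}
        return pd.DataFrame(data).astype(int)


def column_profile(msa: MultipleAlignment) -> AnchorProfile:
    """Occupancy and cross-structure CA RMSD for every alignment column.

    Each structure's CA is mapped into the reference frame with the global
    transform recorded in the alignment; a column's RMSD is the root mean
    square distance of the mapped CAs to their centroid.  Columns missing
    any structure get +inf (they can never be anchors).
    """
    n_struct = msa.n_structures
    for sid in msa.structure_ids:
        if sid not in msa.transforms:
            raise PVRError(f"no transform into reference frame for {sid}")
    occ = np.zeros(len(msa.columns), dtype=int)
    rmsd = np.full(len(msa.columns), np.inf)
    # pre-transform all traces once
    mapped = {
        sid: msa.transforms[sid].apply(np.array([c for _, c in msa.traces[sid]]))
        for sid in msa.structure_ids
    }
    for k, col in enumerate(msa.columns):
        occ[k] = col.occupancy
        if col.occupancy != n_struct:
            continue
        pts = np.stack([mapped[sid][col.cells[sid]] for sid in msa.structure_ids])
        centroid = pts.mean(axis=0)
        rmsd[k] = float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
    return AnchorProfile(occupancy=occ, column_rmsd=rmsd, n_structures=n_struct)


def call_anchors(
    profile: AnchorProfile, rmsd_cut: float = 2.0, min_run: int = 1
) -> np.ndarray:
    """Columns qualifying as anchors: full occupancy, RMSD strictly below
    ``rmsd_cut``, in runs of at least ``min_run`` consecutive columns."""
    if rmsd_cut <= 0:
        raise PVRError("rmsd_cut must be positive")
    if min_run < 1:
        raise PVRError("min_run must be >= 1")
    ok = (profile.occupancy == profile.n_structures) & (profile.column_rmsd < rmsd_cut)
    if min_run == 1:
        return np.flatnonzero(ok)
    keep = np.zeros_like(ok)
    n = len(ok)
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i >= min_run:
                keep[i:j] = True
            i = j
        else:
            i += 1
    return np.flatnonzero(keep)


def _region_segment(
    msa: MultipleAlignment,
    sid: str,
    col_lo: int,
    col_hi: int,
    ins_lo: int,
    ins_hi: int,
) -> Segment:
    """Residues of ``sid`` in columns [col_lo, col_hi] plus insertions
    attached after columns in [ins_lo, ins_hi]."""
    idxs: list[int] = []
    for c in range(max(col_lo, 0), min(col_hi + 1, len(msa.columns))):
        v = msa.columns[c].cells.get(sid)
        if v is not None:
            idxs.append(v)
    idxs.extend(msa.insertions_at(sid, ins_lo, ins_hi))
    if not idxs:
        return Segment(first=None, last=None, length=0)
    idxs.sort()
    trace = msa.traces[sid]
    return Segment(first=trace[idxs[0]][0], last=trace[idxs[-1]][0], length=len(idxs))


def delineate_pvrs(
    msa: MultipleAlignment,
    anchors: Sequence[int] | np.ndarray,
    range_cut: int = 10,
    reference_id: Optional[str] = None,
    rmsd_cut: float = 2.0,
) -> PVRTable:
    """Delineate PVRs from anchor columns and score per-structure divergence.

    Candidate regions are the maximal stretches strictly between consecutive
    anchors (including insertions attached there) plus the two terminal
    regions bounded by a single anchor.  A region is reported as a PVR when
    its per-structure length range (max - min) strictly exceeds
    ``range_cut``.  Segment lengths exclude the bounding anchor residues.
    """
    anchors = np.asarray(sorted(anchors), dtype=int)
    if anchors.size == 0:
        raise PVRError("no anchor columns: no conserved core to delineate against")
    reference_id = reference_id or msa.reference_id
    if reference_id not in msa.structure_ids:
        raise PVRError(f"reference {reference_id!r} not in alignment")

    n_cols = len(msa.columns)
    candidates: list[tuple[str, Optional[int], Optional[int], dict[str, Segment]]] = []

    # N-terminal region: everything before the first anchor
    a0 = int(anchors[0])
    segs = {
        sid: _region_segment(msa, sid, 0, a0 - 1, -1, a0 - 1) for sid in msa.structure_ids
    }
    candidates.append(("N_terminal", None, a0, segs))
    # internal regions between consecutive anchors
    for a, b in zip(anchors[:-1], anchors[1:]):
        a, b = int(a), int(b)
        segs = {
            sid: _region_segment(msa, sid, a + 1, b - 1, a, b - 1)
            for sid in msa.structure_ids
        }
        candidates.append(("internal", a, b, segs))
    # C-terminal region: everything after the last anchor
    aN = int(anchors[-1])
    segs = {
        sid: _region_segment(msa, sid, aN + 1, n_cols - 1, aN, n_cols - 1)
        for sid in msa.structure_ids
    }
    candidates.append(("C_terminal", aN, None, segs))

    pvrs: list[PVR] = []
    for kind, start, end, segs in candidates:
        lengths = [seg.length for seg in segs.values()]
        length_range = max(lengths) - min(lengths)
        if length_range > range_cut:
            pvrs.append(
                PVR(
                    pvr_id=len(pvrs) + 1,
                    kind=kind,
                    start_anchor=start,
                    end_anchor=end,
                    segments=segs,
                    length_range=length_range,
                )
            )

    ref_lengths = {p.pvr_id: p.segments[reference_id].length for p in pvrs}
    sigma_abs = {
        sid: int(
            sum(abs(p.segments[sid].length - ref_lengths[p.pvr_id]) for p in pvrs)
        )
        for sid in msa.structure_ids
    }
    return PVRTable(
        pvrs=pvrs,
        sigma_abs=sigma_abs,
        reference_id=reference_id,
        rmsd_cut=rmsd_cut,
        range_cut=range_cut,
    )


def pvr_report(
    table: PVRTable, msa: MultipleAlignment
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Tabulate PVR segments and build visualisation selection strings.

    Returns (per-segment table, sigma_abs series, {structure: [selection
    strings, one per PVR]}).  Selections use the ``chain/first-last``
    residue-range syntax common to molecular viewers; zero-length segments
    yield an empty string.
    """
    rows = []
    selections: dict[str, list[str]] = {sid: [] for sid in msa.structure_ids}
    for p in table.pvrs:
        for sid in msa.structure_ids:
            seg = p.segments[sid]
            rows.append(
                {
                    "structure": sid,
                    "pvr_id": p.pvr_id,
                    "kind": p.kind,
                    "chain": seg.first.chain_id if seg.first else "",
                    "first": seg.first.seq_id if seg.first else "",
                    "last": seg.last.seq_id if seg.last else "",
                    "length": seg.length,
                }
            )
            if seg.length and seg.first is not None and seg.last is not None:
                selections[sid].append(
                    f"{seg.first.chain_id}/{seg.first.seq_id}-{seg.last.seq_id}"
                )
            else:
                selections[sid].append("")
    df = pd.DataFrame(
        rows, columns=["structure", "pvr_id", "kind", "chain", "first", "last", "length"]
    )
    sigma = pd.Series(table.sigma_abs, name="sigma_abs")
    return df, sigma, selections
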