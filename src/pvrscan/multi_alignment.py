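"""Reference-anchored multiple structural alignment (star alignment).

Every structure is aligned pairwise to one reference chain; the columns of
the multiple alignment are exactly the reference residues, and each target
residue is placed in the column of its reference partner.  Target residues
with no reference partner are kept as *insertions* attached between the two
flanking columns (or to the virtual N-/C-terminal anchors), rather than as
ragged gap columns — this makes variable-region length bookkeeping exact
and independent of column ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .structure_io import ResidueRef, Structure, ca_trace, trace_names, one_letter
from .superposition import (
    AlignParams,
    AlignmentError,
    PairwiseAlignment,
    RigidTransform,
    align_pair,
    kabsch,
)


@dataclass
class Column:
    """One alignment column: the reference residue and its partners."""

    index: int
    cells: dict[str, Optional[int]]  # structure id -> trace index (None = gap)

    @property
    def occupancy(self) -> int:
        return sum(1 for v in self.cells.values() if v is not None)


@dataclass
class Insertion:
    """A run of target residues unaligned to the reference, attached after
    column ``after_col`` (-1 = before the first column)."""

    structure_id: str
    after_col: int
    trace_indices: list[int]


@dataclass
class MultipleAlignment:
    reference_id: str
    structure_ids: list[str]
    columns: list[Column]
    insertions: list[Insertion]
    transforms: dict[str, RigidTransform]  # into the reference frame
    traces: dict[str, list[tuple[ResidueRef, np.ndarray]]]
    names: dict[str, list[str]]
    pairwise: dict[str, PairwiseAlignment] = field(default_factory=dict)

    @property
    def n_structures(self) -> int:
        return len(self.structure_ids)

    def residue_ref(self, col: Column, structure_id: str) -> Optional[ResidueRef]:
        idx = col.cells[structure_id]
        return None if idx is None else self.traces[structure_id][idx][0]

    def insertions_at(self, structure_id: str, lo: int, hi: int) -> list[int]:
        """Trace indices of ``structure_id`` residues inserted after any
        column c with lo <= c <= hi."""
        out: list[int] = []
        for ins in self.insertions:
            if ins.structure_id == structure_id and lo <= ins.after_col <= hi:
                out.extend(ins.trace_indices)
        return out

    def residue_count(self, structure_id: str) -> int:
        in_cols = sum(1 for c in self.columns if c.cells[structure_id] is not None)
        in_ins = sum(
            len(i.trace_indices) for i in self.insertions if i.structure_id == structure_id
        )
        return in_cols + in_ins

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "structure_ids": self.structure_ids,
            "columns": [{"index": c.index, "cells": c.cells} for c in self.columns],
            "insertions": [
                {
                    "structure_id": i.structure_id,
                    "after_col": i.after_col,
                    "trace_indices": i.trace_indices,
                }
                for i in self.insertions
            ],
            "transforms": {
                sid: {
                    "rotation": tr.rotation.tolist(),
                    "translation": tr.translation.tolist(),
                }
                for sid, tr in self.transforms.items()
            },
            "traces": {
                sid: [
                    {
                        "chain_id": ref.chain_id,
                        "seq_id": ref.seq_id,
                        "icode": ref.icode,
                        "xyz": [float(x) for x in coord],
                    }
                    for ref, coord in trace
                ]
                for sid, trace in self.traces.items()
            },
            "names": self.names,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "MultipleAlignment":
        traces = {
            sid: [
                (
                    ResidueRef(sid, e["chain_id"], e["seq_id"], e["icode"]),
                    np.asarray(e["xyz"], dtype=float),
                )
                for e in entries
            ]
            for sid, entries in d["traces"].items()
        }
        return cls(
            reference_id=d["reference_id"],
            structure_ids=list(d["structure_ids"]),
            columns=[Column(c["index"], dict(c["cells"])) for c in d["columns"]],
            insertions=[
                Insertion(i["structure_id"], i["after_col"], list(i["trace_indices"]))
                for i in d["insertions"]
            ],
            transforms={
                sid: RigidTransform(
                    np.asarray(tr["rotation"], dtype=float),
                    np.asarray(tr["translation"], dtype=float),
                )
                for sid, tr in d["transforms"].items()
            },
            traces=traces,
            names={sid: list(n) for sid, n in d["names"].items()},
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "MultipleAlignment":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _structure_inputs(structures: Sequence, chain_ids: Optional[dict[str, str]] = None):
    """Normalise Structure objects / (trace, names, id) triples."""
    out = []
    for s in structures:
        if isinstance(s, Structure):
            cid = (chain_ids or {}).get(s.id)
            out.append((ca_trace(s, cid), trace_names(s, cid), s.id))
        else:
            out.append((list(s[0]), list(s[1]), s[2]))
    return out


def star_align(
    structures: Sequence,
    reference_id: str,
    params: Optional[AlignParams] = None,
    chain_ids: Optional[dict[str, str]] = None,
) -> MultipleAlignment:
    """Build a star multiple alignment centred on ``reference_id``.

    Each non-reference structure is aligned pairwise to the reference.
    Columns are the reference residues in order; target residues unaligned
    to the reference become insertions between the flanking columns.
    """
    inputs = _structure_inputs(structures, chain_ids)
    ids = [sid for _, _, sid in inputs]
    if reference_id not in ids:
        raise AlignmentError(f"reference {reference_id!r} not among inputs {ids}")
    by_id = {sid: (trace, names) for trace, names, sid in inputs}
    ref_trace, ref_names = by_id[reference_id]
    n_ref = len(ref_trace)

    columns = [Column(index=i, cells={reference_id: i}) for i in range(n_ref)]
    insertions: list[Insertion] = []
    transforms: dict[str, RigidTransform] = {reference_id: RigidTransform.identity()}
    pairwise: dict[str, PairwiseAlignment] = {}

    for trace, names, sid in inputs:
        if sid == reference_id:
            continue
        try:
            al = align_pair(
                (ref_trace, ref_names, reference_id), (trace, names, sid), params=params
            )
        except AlignmentError as exc:
            raise AlignmentError(f"pairwise alignment {reference_id} vs {sid} failed: {exc}")
        pairwise[sid] = al
        transforms[sid] = al.transform
        b_to_col = {j: i for i, j in al.pair_indices}
        for col in columns:
            col.cells[sid] = None
        for i, j in al.pair_indices:
            columns[i].cells[sid] = j
        # unaligned target residues -> insertion runs between flanking columns
        run: list[int] = []
        prev_col = -1
        for j in range(len(trace)):
            if j in b_to_col:
                if run:
                    insertions.append(Insertion(sid, prev_col, run))
                    run = []
                prev_col = b_to_col[j]
            else:
                run.append(j)
        if run:
            insertions.append(Insertion(sid, prev_col, run))

    return MultipleAlignment(
        reference_id=reference_id,
        structure_ids=ids,
        columns=columns,
        insertions=insertions,
        transforms=transforms,
        traces={sid: trace for trace, _, sid in inputs},
        names={sid: names for _, names, sid in inputs},
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# FASTA-with-gaps import/export


def export_fasta(msa: MultipleAlignment) -> str:
    """Render the alignment as gapped one-letter sequences.

    Insertions become columns where only the inserting structures have
    residues (left-justified within the inter-column slot).
    """
    seqs = {sid: [] for sid in msa.structure_ids}

    def emit_slot(after_col: int) -> None:
        slot = {
            sid: [
                idx
                for ins in msa.insertions
                if ins.structure_id == sid and ins.after_col == after_col
                for idx in ins.trace_indices
            ]
            for sid in msa.structure_ids
        }
        width = max((len(v) for v in slot.values()), default=0)
        for k in range(width):
            for sid in msa.structure_ids:
                if k < len(slot[sid]):
                    seqs[sid].append(one_letter(msa.names[sid][slot[sid][k]]))
                else:
                    seqs[sid].append("-")

    emit_slot(-1)
    for col in msa.columns:
        for sid in msa.structure_ids:
            idx = col.cells.get(sid)
            seqs[sid].append("-" if idx is None else one_letter(msa.names[sid][idx]))
        emit_slot(col.index)
    lines = []
    for sid in msa.structure_ids:
        lines.append(f">{sid}")
        lines.append("".join(seqs[sid]))
    return "\n".join(lines) + "\n"


def _parse_fasta(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, list[str]]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            records.append((line[1:].split()[0], []))
        else:
            if not records:
                raise AlignmentError("FASTA data before first header")
            records[-1][1].append(line)
    return [(h, "".join(parts)) for h, parts in records]


def import_alignment(
    fasta: str,
    structures: Sequence,
    reference_id: Optional[str] = None,
    chain_ids: Optional[dict[str, str]] = None,
) -> MultipleAlignment:
    """Build a MultipleAlignment from an externally produced gapped FASTA.

    Record order/ids must match the structures; each record's ungapped
    sequence must equal the chain's one-letter sequence exactly.  Transforms
    into the reference frame are recomputed by Kabsch on fully occupied
    columns.
    """
    inputs = _structure_inputs(structures, chain_ids)
    by_id = {sid: (trace, names) for trace, names, sid in inputs}
    records = _parse_fasta(fasta)
    rec_ids = [h for h, _ in records]
    if set(rec_ids) != set(by_id):
        raise AlignmentError(
            f"FASTA ids {rec_ids} do not match structure ids {sorted(by_id)}"
        )
    reference_id = reference_id or rec_ids[0]
    if reference_id not in by_id:
        raise AlignmentError(f"reference {reference_id!r} not among inputs")
    width = len(records[0][1])
    for h, seq in records:
        if len(seq) != width:
            raise AlignmentError(f"record {h} has width {len(seq)} != {width}")
        trace, names = by_id[h]
        ungapped = [c for c in seq if c != "-"]
        expected = [one_letter(n) for n in names]
        if len(ungapped) != len(expected):
            raise AlignmentError(
                f"{h}: alignment has {len(ungapped)} residues, structure has {len(expected)}"
            )
        for pos, (got, want) in enumerate(zip(ungapped, expected)):
            if got != want:
                raise AlignmentError(
                    f"{h}: residue mismatch at ungapped position {pos}: "
                    f"alignment {got!r} vs structure {want!r}"
                )

    seq_by_id = dict(records)
    ref_seq = seq_by_id[reference_id]
    # map alignment columns -> per-structure trace indices
    cursors = {sid: 0 for sid in by_id}
    columns: list[Column] = []
    insertions: list[Insertion] = []
    pending: dict[str, list[int]] = {sid: [] for sid in by_id}

    ids = [sid for _, _, sid in inputs]
    for p in range(width):
        if ref_seq[p] != "-":
            col = Column(index=len(columns), cells={sid: None for sid in ids})
            for sid in ids:
                if seq_by_id[sid][p] != "-":
                    col.cells[sid] = cursors[sid]
                    cursors[sid] += 1
            columns.append(col)
            for sid in ids:
                if pending[sid]:
                    insertions.append(Insertion(sid, col.index - 1, pending[sid]))
                    pending[sid] = []
        else:
            for sid in ids:
                if sid != reference_id and seq_by_id[sid][p] != "-":
                    pending[sid].append(cursors[sid])
                    cursors[sid] += 1
    for sid in ids:
        if pending[sid]:
            insertions.append(Insertion(sid, len(columns) - 1, pending[sid]))

    # recompute transforms on fully occupied columns
    traces = {sid: trace for trace, _, sid in inputs}
    ref_trace = traces[reference_id]
    full = [c for c in columns if c.occupancy == len(ids)]
    transforms = {reference_id: RigidTransform.identity()}
    for sid in ids:
        if sid == reference_id:
            continue
        if len(full) >= 3:
            P = np.array([ref_trace[c.cells[reference_id]][1] for c in full])
            Q = np.array([traces[sid][c.cells[sid]][1] for c in full])
            tr, _ = kabsch(P, Q)
        else:
            tr = RigidTransform.identity()
        transforms[sid] = tr

    return MultipleAlignment(
        reference_id=reference_id,
        structure_ids=ids,
        columns=columns,
        insertions=insertions,
        transforms=transforms,
        traces=traces,
        names={sid: names for _, names, sid in inputs},
    )
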