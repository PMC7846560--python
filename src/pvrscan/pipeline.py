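"""End-to-end orchestration: parse -> pairwise align -> subset filter ->
star MSA -> anchor profile -> PVR table -> sigma_abs -> geometry reports.

The run is deterministic given the configuration; a provenance record
(thresholds, package version, input checksums) accompanies every output so
results can be traced back to their inputs.  Per-structure failures (parse
errors, failed alignments) are collected and reported without aborting the
batch, except for the reference structure, whose failure is fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .multi_alignment import MultipleAlignment, star_align
from .pvr_analysis import (
    AnchorProfile,
    PVRTable,
    call_anchors,
    column_profile,
    delineate_pvrs,
    pvr_report,
)
from .site_geometry import count_interface_hbonds, find_metal_sites, interface_area
from .structure_io import Structure, build_assembly, read_structure
from .superposition import AlignParams, PairwiseAlignment, select_subset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.  Defaults are the thresholds used
    throughout: anchor RMSD cut 2 Å, PVR length-range cut 10 residues, and
    the subset rule "> 220 aligned residues or RMSD < 3 Å"."""

    inputs: list[str] = field(default_factory=list)
    reference_id: str = ""
    chain_ids: dict[str, str] = field(default_factory=dict)  # structure -> chain
    rmsd_cut: float = 2.0
    range_cut: int = 10
    min_run: int = 1
    min_aligned: int = 220
    max_rmsd: float = 3.0
    apply_subset_filter: bool = True
    metal_cutoff: float = 3.0
    hbond_d_max: float = 3.5
    probe_radius: float = 1.4
    norm: str = "ref"
    gap_penalty: float = 0.6
    assembly_id: Optional[str] = None  # expand reference assembly for geometry
    interface_chains: list[tuple[str, str]] = field(default_factory=list)
    out_dir: str = "pvrscan_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["interface_chains"] = [list(p) for p in d["interface_chains"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "interface_chains" in d:
            d["interface_chains"] = [tuple(p) for p in d["interface_chains"]]
        return cls(**d)

    def align_params(self) -> AlignParams:
        return AlignParams(gap_penalty=self.gap_penalty, norm=self.norm)


@dataclass
class PipelineResult:
    structures: list[Structure]
    pairwise: list[PairwiseAlignment]
    msa: MultipleAlignment
    profile: AnchorProfile
    anchors: np.ndarray
    pvr_table: PVRTable
    sites: dict[str, list]
    interfaces: list[dict]
    provenance: dict

    @property
    def sigma_abs(self) -> dict[str, int]:
        return self.pvr_table.sigma_abs


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    structures: Optional[list[Structure]] = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run the full analysis.

    Structures may be passed in-memory (e.g. a synthetic ensemble);
    otherwise they are read from ``config.inputs``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    failures: dict[str, str] = {}
    checksums: dict[str, str] = {}

    if structures is None:
        structures = []
        for p in config.inputs:
            path = Path(p)
            try:
                structures.append(read_structure(path))
                checksums[path.stem] = _checksum(path)
            except Exception as exc:
                if path.stem == config.reference_id:
                    raise
                failures[path.stem] = f"parse: {exc}"
                logger.warning("skipping %s: %s", path, exc)

    ids = [s.id for s in structures]
    reference_id = config.reference_id or ids[0]
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not among inputs {ids}")
    by_id = {s.id: s for s in structures}

    params = config.align_params()
    msa_all = star_align(structures, reference_id, params=params, chain_ids=config.chain_ids)
    pairwise = list(msa_all.pairwise.values())

    kept_ids = [reference_id]
    if config.apply_subset_filter:
        kept = select_subset(pairwise, config.min_aligned, config.max_rmsd)
        dropped = [al.b_id for al in pairwise if al not in kept]
        for d in dropped:
            failures[d] = (
                f"subset filter: n_aligned <= {config.min_aligned} and "
                f"rmsd >= {config.max_rmsd}"
            )
        kept_ids += [al.b_id for al in kept]
    else:
        kept_ids += [al.b_id for al in pairwise]
    if len(kept_ids) < 2:
        raise ValueError("no structure passes the subset filter against the reference")

    if set(kept_ids) != set(ids):
        msa = star_align(
            [by_id[i] for i in kept_ids], reference_id, params=params, chain_ids=config.chain_ids
        )
    else:
        msa = msa_all

    profile = column_profile(msa)
    anchors = call_anchors(profile, rmsd_cut=config.rmsd_cut, min_run=config.min_run)
    table = delineate_pvrs(
        msa, anchors, range_cut=config.range_cut, rmsd_cut=config.rmsd_cut
    )

    sites: dict[str, list] = {}
    for s in structures:
        if s.id not in kept_ids:
            continue
        found = find_metal_sites(s, cutoff=config.metal_cutoff)
        if found:
            sites[s.id] = [
                {
                    "metal": f"{site.metal.element} {site.metal.chain_id}{site.metal.seq_id}",
                    "ligands": [
                        {
                            "residue": f"{lig.resname}{lig.ref.seq_id}",
                            "chain": lig.ref.chain_id,
                            "atom": lig.atom,
                            "distance": round(lig.distance, 3),
                        }
                        for lig in site.ligands
                    ],
                }
                for site in found
            ]

    interfaces: list[dict] = []
    if config.assembly_id is not None or config.interface_chains:
        ref_struct = by_id[reference_id]
        target = (
            build_assembly(ref_struct, config.assembly_id)
            if config.assembly_id is not None
            else ref_struct
        )
        chain_pairs = config.interface_chains or [
            (a, b)
            for i, a in enumerate(target.chain_ids)
            for b in target.chain_ids[i + 1 :]
        ]
        for a, b in chain_pairs:
            try:
                area = interface_area(target, (a, b), probe=config.probe_radius)
                rep = count_interface_hbonds(
                    target, (a, b), d_max=config.hbond_d_max, buried_area=area
                )
                interfaces.append(
                    {
                        "structure": target.id,
                        "chains": [a, b],
                        "buried_area": round(area, 1),
                        "hbond_count": rep.hbond_count,
                    }
                )
            except Exception as exc:
                failures[f"interface {a}-{b}"] = str(exc)

    provenance = {
        "package": "pvrscan",
        "version": __version__,
        "reference_id": reference_id,
        "structure_ids": ids,
        "kept_ids": kept_ids,
        "thresholds": {
            "rmsd_cut": config.rmsd_cut,
            "range_cut": config.range_cut,
            "min_run": config.min_run,
            "min_aligned": config.min_aligned,
            "max_rmsd": config.max_rmsd,
            "metal_cutoff": config.metal_cutoff,
            "hbond_d_max": config.hbond_d_max,
            "probe_radius": config.probe_radius,
            "norm": config.norm,
            "gap_penalty": config.gap_penalty,
        },
        "seed": config.seed,
        "input_checksums": checksums,
        "failures": failures,
    }

    result = PipelineResult(
        structures=structures,
        pairwise=pairwise,
        msa=msa,
        profile=profile,
        anchors=anchors,
        pvr_table=table,
        sites=sites,
        interfaces=interfaces,
        provenance=provenance,
    )
    if write_outputs:
        write_result(result, Path(config.out_dir))
    return result


def write_result(result: PipelineResult, out_dir: Path) -> None:
    """Dump the machine-readable output bundle (TSV/JSON)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "a_id": al.a_id,
                "b_id": al.b_id,
                "n_aligned": al.n_aligned,
                "rmsd": round(al.rmsd, 4),
                "tm_score": round(al.tm_score, 4),
                "seq_identity": round(al.seq_identity, 2),
                "converged": al.converged,
            }
            for al in result.pairwise
        ]
    ).to_csv(out_dir / "pairwise.tsv", sep="\t", index=False)
    result.msa.save_json(out_dir / "msa.json")
    pd.DataFrame(
        {
            "column": np.arange(len(result.profile.occupancy)),
            "occupancy": result.profile.occupancy,
            "column_rmsd": [
                round(float(x), 4) if np.isfinite(x) else ""
                for x in result.profile.column_rmsd
            ],
            "is_anchor": np.isin(
                np.arange(len(result.profile.occupancy)), result.anchors
            ),
        }
    ).to_csv(out_dir / "anchors.tsv", sep="\t", index=False)
    df, sigma, selections = pvr_report(result.pvr_table, result.msa)
    df.to_csv(out_dir / "pvrs.tsv", sep="\t", index=False)
    sigma.rename_axis("structure").to_csv(out_dir / "sigma_abs.tsv", sep="\t")
    (out_dir / "selections.json").write_text(json.dumps(selections, indent=1))
    (out_dir / "sites.json").write_text(json.dumps(result.sites, indent=1))
    (out_dir / "interfaces.json").write_text(json.dumps(result.interfaces, indent=1))
    (out_dir / "provenance.json").write_text(json.dumps(result.provenance, indent=1))
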