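"""Export of results: community PDB files with pseudobonds, graphs, manifests.

Each community can be written as a PDB file holding the residues that
participate in its member series at one chosen frame, with one CONECT
"pseudobond" per distance time series connecting a representative atom of
each residue (CA for CA-CA series; for side-chain series the side-chain
heavy atom closest to the side chain's geometric center).  The community id
is encoded in the B-factor column so viewers can color by community.
CONECT records are used (rather than viewer-specific pseudobond syntax) so
files open in common molecular viewers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import igraph as ig
import numpy as np

from .component_network import ComponentGraph
from .contacts import DistanceTimeSeries
from .domain_motions import DynamicComponent
from .exceptions import ConsistencyError, ValidationError
from .trajectory_io import Trajectory, try_atom_selection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PseudobondRecord:
    """One emitted CONECT pseudobond (atom serials in the written PDB)."""

    community_id: int
    series_id: str
    atom_a: int
    atom_b: int


def format_pdb_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    xyz: np.ndarray,
    occupancy: float = 1.0,
    b_factor: float = 0.0,
    element: str = "",
) -> str:
    """One fixed-width PDB ATOM record (v3 column conventions)."""
    name_field = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name_field:<4s} {res_name:<3s} {chain[:1]}{res_seq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}{b_factor:6.2f}"
        f"          {element[:2]:>2s}"
    )


def representative_atom_index(
    traj: Trajectory, resindex: int, mode: str, frame: int
) -> int:
    """Global atom index representing a residue for pseudobond drawing.

    CA for CA-CA series.  For side-chain series: the side-chain heavy atom
    closest to the side chain's geometric center at ``frame`` (deterministic;
    ties resolved by atom order).  Residues without side-chain heavy atoms
    (glycine) fall back to CA.
    """
    if mode == "calpha":
        sel = try_atom_selection(traj, resindex, "calpha")
        if sel is None:
            raise ConsistencyError(f"residue {traj.residues[resindex]} has no CA atom")
        return int(sel.atom_indices[0])
    sel = try_atom_selection(traj, resindex, "sidechain_nonH")
    if sel is None:
        return representative_atom_index(traj, resindex, "calpha", frame)
    coords = traj.coords[frame, sel.atom_indices]
    center = coords.mean(axis=0)
    return int(sel.atom_indices[np.argmin(np.linalg.norm(coords - center, axis=1))])


def write_community_pdb(
    traj: Trajectory,
    frame: int,
    community: Sequence[DynamicComponent],
    series_lookup: Dict[str, DistanceTimeSeries],
    path: str,
    community_id: int = 0,
) -> List[PseudobondRecord]:
    """Write one community's residues + pseudobonds as a PDB file.

    Emits ATOM records for every residue participating in the community's
    series at ``frame`` (B-factor = community id) and one CONECT record per
    series between the two representative atoms.  Returns the pseudobond
    records actually written.
    """
    if frame < 0:
        frame = traj.n_frames + frame
    if not (0 <= frame < traj.n_frames):
        raise ValidationError(f"frame {frame} out of range (n_frames={traj.n_frames})")
    if not community or not any(c.member_series for c in community):
        raise ConsistencyError("community is empty; nothing to write")

    res_lookup = {(r.chain, r.seq_index): i for i, r in enumerate(traj.residues)}
    bonds_by_res: List[Tuple[int, int, str, str]] = []
    resindices: set = set()
    for comp in community:
        for sid in comp.member_series:
            if sid not in series_lookup:
                raise ConsistencyError(f"series {sid} unknown to the exporter")
            pair = series_lookup[sid].pair
            try:
                ia = res_lookup[(pair.res_a.chain, pair.res_a.seq_index)]
                ib = res_lookup[(pair.res_b.chain, pair.res_b.seq_index)]
            except KeyError as exc:
                raise ConsistencyError(
                    f"residue of series {sid} absent from the trajectory"
                ) from exc
            resindices.update((ia, ib))
            bonds_by_res.append((ia, ib, pair.mode, sid))

    serial_of_atom: Dict[int, int] = {}
    lines: List[str] = []
    serial = 0
    for ri in sorted(resindices):
        rid = traj.residues[ri]
        for ai in traj.residue_atom_indices(ri):
            serial += 1
            serial_of_atom[int(ai)] = serial
            lines.append(
                format_pdb_atom_line(
                    serial,
                    str(traj.atom_names[ai]),
                    rid.res_name,
                    rid.chain,
                    rid.seq_index,
                    traj.coords[frame, ai],
                    b_factor=float(community_id),
                    element=str(traj.atom_elements[ai]),
                )
            )

    records: List[PseudobondRecord] = []
    sel_mode = {"calpha": "calpha", "sidechain_vdw": "sidechain", "polar": "sidechain"}
    for ia, ib, mode, sid in bonds_by_res:
        rep_mode = "calpha" if sel_mode.get(mode, "sidechain") == "calpha" else "sidechain"
        aa = representative_atom_index(traj, ia, rep_mode, frame)
        ab = representative_atom_index(traj, ib, rep_mode, frame)
        sa, sb = serial_of_atom[aa], serial_of_atom[ab]
        records.append(PseudobondRecord(community_id, sid, sa, sb))
        lines.append(f"CONECT{sa:5d}{sb:5d}")

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\nEND\n")
    logger.info("wrote community %d: %d residues, %d pseudobonds -> %s",
                community_id, len(resindices), len(records), path)
    return records


def write_graphml(graph: ComponentGraph, path: str) -> None:
    """GraphML export with node kind/size/community and edge weights."""
    ids = graph.component_ids
    index = {cid: i for i, cid in enumerate(ids)}
    g = ig.Graph(n=len(ids))
    g.vs["name"] = ids
    g.vs["kind"] = [c.kind for c in graph.components]
    g.vs["size"] = [c.size for c in graph.components]
    comm = graph.communities or {}
    g.vs["community"] = [comm.get(cid, -1) for cid in ids]
    g.add_edges([(index[a], index[b]) for a, b, _ in graph.edges])
    g.es["weight"] = [w for _, _, w in graph.edges]
    g.write_graphml(path)


def write_run_manifest(manifest: dict, path: str) -> None:
    """Single structured file capturing cutoffs, seeds, counts and versions.

    Content is fully deterministic (no timestamps) so a rerun with the same
    inputs reproduces the file byte for byte.
    """
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_run_manifest(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
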