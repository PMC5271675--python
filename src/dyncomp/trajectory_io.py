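"""Topology/trajectory loading and the minimum-distance primitive.

A :class:`Trajectory` is an in-memory array of coordinates (frames x atoms x 3,
in Angstrom) over the standard protein residues of the input, together with
per-atom names/elements and an ordered residue list.  Loading goes through
MDAnalysis, so PDB topologies with multi-model PDB, DCD or XTC trajectories are
all accepted.  Hetero residues, waters, lipids and ions are skipped (logged);
only the 20 standard amino acids are analyzed.

Three atom-selection modes drive every distance in the pipeline:

``sidechain_nonH``
    all non-hydrogen side-chain atoms (backbone N, CA, C, O and termini
    excluded);
``polar_head``
    the non-hydrogen polar head-group atoms of the polar residues (explicit
    per-residue table, :func:`polar_head_atoms`);
``calpha``
    exactly the CA atom.

Distances between residues are minimum distances over all cross pairs of the
selected atoms, which captures complete formation and breaking of side-chain
contacts without any structure superposition.
"""

from __future__ import annotations

import hashlib
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

from .exceptions import (
    EmptyInputError,
    FormatError,
    SelectionError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: The 20 standard 3-letter residue codes.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Common force-field residue-name variants folded onto standard codes.
RESNAME_ALIASES = {
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS",
    "CYX": "CYS", "CYM": "CYS",
    "ASH": "ASP", "GLH": "GLU", "LYN": "LYS",
}

#: Backbone / terminal heavy atoms excluded from side-chain selections.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "OT1", "OT2"})

# Non-hydrogen polar head-group atoms per polar residue; non-polar residues
# map to the empty set.
_POLAR_HEAD_TABLE = {
    "ARG": {"NE", "CZ", "NH1", "NH2"},
    "ASN": {"CG", "OD1", "ND2"},
    "ASP": {"CG", "OD1", "OD2"},
    "CYS": {"SG"},
    "GLN": {"CD", "OE1", "NE2"},
    "GLU": {"CD", "OE1", "OE2"},
    "HIS": {"CG", "ND1", "CE1", "NE2", "CD2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
}

_HYDROGEN_NAME = re.compile(r"^[0-9]*H")

#: Valid selection modes.
SELECTION_MODES = ("sidechain_nonH", "polar_head", "calpha")


class ResidueID(NamedTuple):
    """Identity of one residue: chain, author sequence number, 3-letter code."""

    chain: str
    seq_index: int
    res_name: str

    def __str__(self) -> str:  # used in series ids and reports
        return f"{self.chain}:{self.seq_index}:{self.res_name}"


@dataclass(frozen=True)
class AtomSelection:
    """A residue's selected atoms under one selection mode.

    ``atom_indices`` are global indices into ``Trajectory.coords``.
    """

    residue: ResidueID
    atom_names: frozenset
    mode: str
    atom_indices: np.ndarray

    def __len__(self) -> int:
        return len(self.atom_indices)


@dataclass
class Trajectory:
    """Coordinates of the analyzed protein atoms over all loaded frames."""

    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    atom_names: np.ndarray  # (n_atoms,) str
    atom_elements: np.ndarray  # (n_atoms,) str, '' when unknown
    atom_resindex: np.ndarray  # (n_atoms,) int, index into `residues`
    residues: list  # list[ResidueID], ordering fixed across frames
    stride: int = 1
    frame_interval: Optional[float] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if self.n_frames == 0:
            raise EmptyInputError("trajectory contains zero frames")
        if self.n_frames < 2:
            raise ValidationError("a trajectory needs at least 2 frames to analyze dynamics")
        if not np.isfinite(self.coords).all():
            raise ValidationError("trajectory coordinates contain non-finite values")
        if len(self.atom_names) != self.n_atoms or len(self.atom_resindex) != self.n_atoms:
            raise ValidationError("per-atom metadata length does not match coordinate array")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def residue_atom_indices(self, resindex: int) -> np.ndarray:
        """Global atom indices belonging to residue ``resindex``."""
        return np.nonzero(self.atom_resindex == resindex)[0]

    def checksum(self) -> str:
        """SHA-256 over coordinates and atom metadata (reproducibility manifest)."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.coords).tobytes())
        h.update("|".join(self.atom_names.tolist()).encode())
        h.update(self.atom_resindex.astype(np.int64).tobytes())
        return h.hexdigest()


def polar_head_atoms(res_name: str) -> set:
    """Non-hydrogen polar head-group atom names for a standard residue.

    Polar residues map to their explicit head-group table (e.g. ARG ->
    {NE, CZ, NH1, NH2}, TRP -> {NE1}); non-polar standard residues map to the
    empty set.  Unknown codes raise :class:`ValidationError`.
    """
    name = RESNAME_ALIASES.get(res_name.upper(), res_name.upper())
    if name not in STANDARD_RESIDUES:
        raise ValidationError(f"unknown residue code: {res_name!r}")
    return set(_POLAR_HEAD_TABLE.get(name, set()))


def is_hydrogen(name: str, element: str = "") -> bool:
    """Hydrogen by element field when present, else by name (H/1H/2H/3H...)."""
    if element:
        return element.upper() == "H"
    return bool(_HYDROGEN_NAME.match(name.strip()))


def _guess_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    if _HYDROGEN_NAME.match(stripped):
        return "H"
    return stripped[0].upper()


def load_trajectory(
    topology_path: str,
    trajectory_path: Optional[str] = None,
    stride: int = 1,
) -> Trajectory:
    """Load a topology (PDB) plus optional trajectory (multi-model PDB/DCD/XTC).

    Keeps every ``stride``-th frame starting at the first, so the loaded frame
    count is ``ceil(raw_frames / stride)``.  Only standard amino-acid residues
    are retained; alternate locations keep the highest-occupancy conformer.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            topo = mda.Universe(topology_path)
        except Exception as exc:  # noqa: BLE001 - wrap parser errors
            raise FormatError(f"could not parse topology {topology_path!r}: {exc}") from exc
        n_top = len(topo.atoms)
        if trajectory_path is None:
            u = topo
        else:
            try:
                u = mda.Universe(topology_path, trajectory_path)
            except Exception as exc:  # noqa: BLE001
                raise FormatError(
                    f"trajectory {trajectory_path!r} does not match topology "
                    f"{topology_path!r} ({n_top} atoms): {exc}"
                ) from exc

        n_raw = len(u.trajectory)
        if n_raw == 0:
            raise EmptyInputError("trajectory contains zero frames")

        atoms = u.atoms
        names = [a.name for a in atoms]
        resnames = [RESNAME_ALIASES.get(a.resname.upper(), a.resname.upper()) for a in atoms]
        resindices = np.asarray([a.resindex for a in atoms])
        try:
            occupancies = np.asarray(atoms.occupancies, dtype=float)
        except Exception:  # noqa: BLE001 - attribute absent for some formats
            occupancies = np.ones(len(atoms))
        try:
            elements = [str(e) for e in atoms.elements]
        except Exception:  # noqa: BLE001
            elements = [_guess_element(n) for n in names]
        try:
            chains = [str(c) for c in atoms.chainIDs]
        except Exception:  # noqa: BLE001
            try:
                chains = [str(s) for s in atoms.segids]
            except Exception:  # noqa: BLE001
                chains = ["A"] * len(atoms)
        chains = [c if c.strip() else "A" for c in chains]
        resids = np.asarray([a.resid for a in atoms])

        # keep standard residues only
        keep = np.asarray([rn in STANDARD_RESIDUES for rn in resnames])
        n_skipped_res = len({int(r) for r, k in zip(resindices, keep) if not k})
        if n_skipped_res:
            logger.warning(
                "skipping %d non-standard residues (hetero/solvent/lipid/ion)", n_skipped_res
            )

        # altloc: keep highest-occupancy conformer per (residue, atom name)
        best: dict = {}
        for i in np.nonzero(keep)[0]:
            key = (int(resindices[i]), names[i])
            if key not in best or occupancies[i] > occupancies[best[key]]:
                best[key] = int(i)
        kept_idx = np.asarray(sorted(best.values()), dtype=int)
        if kept_idx.size == 0:
            raise EmptyInputError("no standard amino-acid atoms found in topology")

        # residue table in topology order
        res_order: list = []
        res_map: dict = {}
        seen_keys: set = set()
        for i in kept_idx:
            ri = int(resindices[i])
            if ri not in res_map:
                rid = ResidueID(chains[i], int(resids[i]), resnames[i])
                key = (rid.chain, rid.seq_index)
                if key in seen_keys:
                    logger.warning("duplicate residue number %s (insertion codes folded)", key)
                seen_keys.add(key)
                res_map[ri] = len(res_order)
                res_order.append(rid)

        frame_indices = range(0, n_raw, stride)
        coords = np.empty((len(frame_indices), kept_idx.size, 3))
        for out_f, f in enumerate(frame_indices):
            u.trajectory[f]
            coords[out_f] = atoms.positions[kept_idx]

        dt = getattr(u.trajectory, "dt", None)

    traj = Trajectory(
        coords=coords,
        atom_names=np.asarray([names[i] for i in kept_idx]),
        atom_elements=np.asarray([elements[i] for i in kept_idx]),
        atom_resindex=np.asarray([res_map[int(resindices[i])] for i in kept_idx]),
        residues=res_order,
        stride=stride,
        frame_interval=(dt * stride) if dt else None,
        source=str(topology_path),
    )
    logger.info(
        "loaded %d frames x %d atoms over %d residues (stride %d)",
        traj.n_frames, traj.n_atoms, len(traj.residues), stride,
    )
    assert traj.n_frames == math.ceil(n_raw / stride)
    return traj


def atom_selection(traj: Trajectory, resindex: int, mode: str) -> AtomSelection:
    """Build the :class:`AtomSelection` for one residue under ``mode``.

    Raises :class:`SelectionError` when the selection is empty (glycine side
    chain, non-polar residue in polar mode, missing CA).
    """
    sel = try_atom_selection(traj, resindex, mode)
    if sel is None:
        rid = traj.residues[resindex]
        raise SelectionError(f"empty {mode} selection for residue {rid}")
    return sel


def try_atom_selection(traj: Trajectory, resindex: int, mode: str) -> Optional[AtomSelection]:
    """Like :func:`atom_selection` but returns None for empty selections."""
    if mode not in SELECTION_MODES:
        raise ValidationError(f"unknown selection mode {mode!r}; expected one of {SELECTION_MODES}")
    rid = traj.residues[resindex]
    idx = traj.residue_atom_indices(resindex)
    names = traj.atom_names[idx]
    elements = traj.atom_elements[idx]

    if mode == "calpha":
        mask = names == "CA"
    elif mode == "sidechain_nonH":
        mask = np.asarray(
            [
                (n not in BACKBONE_ATOMS) and not is_hydrogen(n, e)
                for n, e in zip(names, elements)
            ]
        )
    else:  # polar_head
        table = polar_head_atoms(rid.res_name)
        mask = np.asarray([n in table for n in names]) if table else np.zeros(len(names), bool)

    chosen = idx[mask] if len(idx) else idx
    if chosen.size == 0:
        return None
    return AtomSelection(
        residue=rid,
        atom_names=frozenset(names[mask].tolist()),
        mode=mode,
        atom_indices=np.asarray(chosen, dtype=int),
    )


def min_distance(traj: Trajectory, frame: int, sel_a: AtomSelection, sel_b: AtomSelection) -> float:
    """Minimum Euclidean distance (Angstrom) over all cross atom pairs at ``frame``."""
    if sel_a.residue == sel_b.residue:
        raise SelectionError(f"self-pair distance requested for residue {sel_a.residue}")
    if len(sel_a) == 0 or len(sel_b) == 0:
        empty = sel_a.residue if len(sel_a) == 0 else sel_b.residue
        raise SelectionError(f"empty selection for residue {empty}")
    a = traj.coords[frame, sel_a.atom_indices]
    b = traj.coords[frame, sel_b.atom_indices]
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt(np.einsum("ijk,ijk->ij", diff, diff).min()))


def min_distance_series(
    traj: Trajectory, sel_a: AtomSelection, sel_b: AtomSelection, frames: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Per-frame minimum cross-pair distance; vectorized over frames."""
    if sel_a.residue == sel_b.residue:
        raise SelectionError(f"self-pair distance requested for residue {sel_a.residue}")
    if len(sel_a) == 0 or len(sel_b) == 0:
        empty = sel_a.residue if len(sel_a) == 0 else sel_b.residue
        raise SelectionError(f"empty selection for residue {empty}")
    coords = traj.coords if frames is None else traj.coords[list(frames)]
    a = coords[:, sel_a.atom_indices]  # (F, na, 3)
    b = coords[:, sel_b.atom_indices]  # (F, nb, 3)
    if a.shape[1] == 1 and b.shape[1] == 1:
        return np.linalg.norm(a[:, 0] - b[:, 0], axis=1)
    diff = a[:, :, None, :] - b[:, None, :, :]
    d2 = np.einsum("fijk,fijk->fij", diff, diff)
    return np.sqrt(d2.reshape(d2.shape[0], -1).min(axis=1))
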