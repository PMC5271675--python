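"""Contact-pair enumeration and distance time series.

A residue pair is a *contact candidate* when its minimum inter-selection
distance drops below the mode's cutoff in at least one frame of the
simulation: 5 A for side-chain van der Waals and polar head-group contacts,
15 A for CA-CA pairs feeding the domain-motion analysis.  Pairs on the same
chain must be at least ``min_seq_sep`` (default 3) residues apart in sequence;
pairs across chains (e.g. receptor-ligand) are always eligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import SelectionError, ValidationError
from .trajectory_io import (
    AtomSelection,
    ResidueID,
    Trajectory,
    min_distance_series,
    polar_head_atoms,
    try_atom_selection,
)

logger = logging.getLogger(__name__)

#: Contact modes and the selection mode each one uses.
CONTACT_MODES = {
    "sidechain_vdw": "sidechain_nonH",
    "polar": "polar_head",
    "calpha": "calpha",
}

#: The cutoffs of the method, Angstrom, by contact mode.
DEFAULT_CUTOFFS = {"sidechain_vdw": 5.0, "polar": 5.0, "calpha": 15.0}


def _residue_key(r: ResidueID) -> Tuple[str, int]:
    return (r.chain, r.seq_index)


@dataclass(frozen=True)
class ContactPair:
    """An unordered residue pair under one contact mode (stored with a < b)."""

    res_a: ResidueID
    res_b: ResidueID
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in CONTACT_MODES:
            raise ValidationError(f"unknown contact mode {self.mode!r}")
        if self.res_a == self.res_b:
            raise ValidationError(f"self-pair not allowed: {self.res_a}")
        if _residue_key(self.res_a) > _residue_key(self.res_b):
            a, b = self.res_a, self.res_b
            object.__setattr__(self, "res_a", b)
            object.__setattr__(self, "res_b", a)

    @property
    def pair_id(self) -> str:
        return f"{self.mode}|{self.res_a}|{self.res_b}"

    def seq_separation(self) -> Optional[int]:
        """Sequence separation when on the same chain, else None."""
        if self.res_a.chain != self.res_b.chain:
            return None
        return abs(self.res_a.seq_index - self.res_b.seq_index)


@dataclass
class DistanceTimeSeries:
    """One scalar distance per frame for a residue pair, tagged by mode."""

    pair: ContactPair
    values: np.ndarray
    series_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("series values must be one-dimensional")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValidationError(f"series {self.series_id or self.pair.pair_id} has "
                                  "negative or non-finite distances")
        if not self.series_id:
            self.series_id = self.pair.pair_id

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def mode(self) -> str:
        return self.pair.mode


def _mode_selections(traj: Trajectory, mode: str) -> Dict[int, AtomSelection]:
    """Per-residue selections for a contact mode; empty selections skipped."""
    sel_mode = CONTACT_MODES[mode]
    out: Dict[int, AtomSelection] = {}
    skipped = 0
    for ri, rid in enumerate(traj.residues):
        if mode == "polar" and not polar_head_atoms(rid.res_name):
            continue
        sel = try_atom_selection(traj, ri, sel_mode)
        if sel is None:
            skipped += 1  # e.g. glycine side chain
            continue
        out[ri] = sel
    if skipped:
        logger.info("mode %s: %d residues with empty selections skipped", mode, skipped)
    return out


def _eligible(a: ResidueID, b: ResidueID, min_seq_sep: int) -> bool:
    if a.chain != b.chain:
        return True  # inter-chain pairs always eligible
    return abs(a.seq_index - b.seq_index) >= min_seq_sep


def enumerate_pairs(
    traj: Trajectory,
    mode: str,
    cutoff: Optional[float] = None,
    min_seq_sep: int = 3,
    screen_stride: int = 1,
) -> List[ContactPair]:
    """All eligible pairs whose minimum distance is <= ``cutoff`` in >= 1 frame.

    ``screen_stride`` > 1 screens on a frame subset (logged); the default
    evaluates every frame so "at any point during the simulation" is exact.
    """
    if mode not in CONTACT_MODES:
        raise ValidationError(f"unknown contact mode {mode!r}")
    if cutoff is None:
        cutoff = DEFAULT_CUTOFFS[mode]
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    if screen_stride > 1:
        logger.warning("contact screening on every %d-th frame only", screen_stride)
    frames = range(0, traj.n_frames, screen_stride)
    sels = _mode_selections(traj, mode)
    indices = sorted(sels)
    pairs: List[ContactPair] = []
    for ii, ri in enumerate(indices):
        for rj in indices[ii + 1:]:
            ra, rb = traj.residues[ri], traj.residues[rj]
            if not _eligible(ra, rb, min_seq_sep):
                continue
            d = min_distance_series(traj, sels[ri], sels[rj], frames=frames)
            if d.min() <= cutoff:
                pairs.append(ContactPair(ra, rb, mode))
    logger.info("mode %s: %d contact pairs at cutoff %.2f A", mode, len(pairs), cutoff)
    return pairs


def compute_series(traj: Trajectory, pairs: Sequence[ContactPair]) -> List[DistanceTimeSeries]:
    """Full-precision per-frame minimum-distance series for each pair."""
    res_lookup = {_residue_key(r): i for i, r in enumerate(traj.residues)}
    out: List[DistanceTimeSeries] = []
    for pair in pairs:
        sel_mode = CONTACT_MODES[pair.mode]
        try:
            ia = res_lookup[_residue_key(pair.res_a)]
            ib = res_lookup[_residue_key(pair.res_b)]
        except KeyError as exc:
            raise SelectionError(f"residue of pair {pair.pair_id} not in trajectory") from exc
        sa = try_atom_selection(traj, ia, sel_mode)
        sb = try_atom_selection(traj, ib, sel_mode)
        if sa is None or sb is None:
            raise SelectionError(f"empty selection computing series for pair {pair.pair_id}")
        out.append(DistanceTimeSeries(pair=pair, values=min_distance_series(traj, sa, sb)))
    return out


# ---------------------------------------------------------------------------
# CSV interchange: one file per mode; frame columns are 1-based in reports.

def write_series_csv(series_list: Sequence[DistanceTimeSeries], path: str) -> None:
    """Write series to CSV (distances rounded to 3 decimals)."""
    if not series_list:
        raise ValidationError("no series to write")
    n = series_list[0].n_frames
    rows = []
    for s in series_list:
        if s.n_frames != n:
            raise ValidationError("series of differing lengths cannot share a CSV")
        p = s.pair
        rows.append(
            [s.series_id, p.res_a.chain, p.res_a.seq_index, p.res_a.res_name,
             p.res_b.chain, p.res_b.seq_index, p.res_b.res_name]
            + [round(v, 3) for v in s.values]
        )
    cols = ["series_id", "chain_a", "resnum_a", "resname_a",
            "chain_b", "resnum_b", "resname_b"] + [f"f{i}" for i in range(1, n + 1)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_series_csv(path: str, mode: Optional[str] = None) -> List[DistanceTimeSeries]:
    """Read series written by :func:`write_series_csv`.

    The contact mode is parsed from each series_id prefix unless given.
    """
    df = pd.read_csv(path)
    frame_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    out = []
    for _, row in df.iterrows():
        sid = str(row["series_id"])
        m = mode or sid.split("|", 1)[0]
        pair = ContactPair(
            ResidueID(str(row["chain_a"]), int(row["resnum_a"]), str(row["resname_a"])),
            ResidueID(str(row["chain_b"]), int(row["resnum_b"]), str(row["resname_b"])),
            m,
        )
        out.append(DistanceTimeSeries(pair=pair, values=row[frame_cols].to_numpy(float),
                                      series_id=sid))
    return out


def write_pair_manifest(pairs: Sequence[ContactPair], path: str) -> None:
    """Manifest of enumerated pairs (one row per pair)."""
    rows = [
        [p.pair_id, p.mode, p.res_a.chain, p.res_a.seq_index, p.res_a.res_name,
         p.res_b.chain, p.res_b.seq_index, p.res_b.res_name, p.seq_separation()]
        for p in pairs
    ]
    cols = ["pair_id", "mode", "chain_a", "resnum_a", "resname_a",
            "chain_b", "resnum_b", "resname_b", "seq_separation"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
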