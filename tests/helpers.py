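"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np

from dyncomp.contacts import ContactPair, DistanceTimeSeries
from dyncomp.trajectory_io import ResidueID, Trajectory


def make_series(values, mode: str = "calpha", idx: int = 0, resname: str = "ALA",
                series_id: str = "") -> DistanceTimeSeries:
    """A series with a fabricated, unique residue pair."""
    pair = ContactPair(
        ResidueID("A", 10 * idx + 1, resname),
        ResidueID("A", 10 * idx + 4, resname),
        mode,
    )
    return DistanceTimeSeries(pair=pair, values=np.asarray(values, float),
                              series_id=series_id)


def build_traj(coords, names, resindex, resnames, chain: str = "A",
               seq_indices=None, elements=None) -> Trajectory:
    """An in-memory Trajectory without file I/O."""
    coords = np.asarray(coords, float)
    seq = seq_indices if seq_indices is not None else range(1, len(resnames) + 1)
    residues = [ResidueID(chain, int(s), rn) for s, rn in zip(seq, resnames)]
    return Trajectory(
        coords=coords,
        atom_names=np.asarray(names),
        atom_elements=np.asarray(elements if elements is not None else [""] * len(names)),
        atom_resindex=np.asarray(resindex, int),
        residues=residues,
    )


def ca_chain_traj(ca_coords, chain: str = "A", seq_indices=None) -> Trajectory:
    """A CA-only chain: ca_coords has shape (n_frames, n_residues, 3)."""
    ca = np.asarray(ca_coords, float)
    n_res = ca.shape[1]
    return build_traj(
        coords=ca,
        names=["CA"] * n_res,
        resindex=list(range(n_res)),
        resnames=["ALA"] * n_res,
        chain=chain,
        seq_indices=seq_indices,
    )


def correlated_pair(rho: float, n: int = 200, seed: int = 0):
    """Two zero-mean unit-variance vectors with Pearson r exactly ~ rho."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    e = rng.standard_normal(n)
    z = (z - z.mean()) / z.std()
    e = e - e.mean()
    e -= (e @ z) / (z @ z) * z  # orthogonalize
    e /= e.std()
    return z, rho * z + np.sqrt(1 - rho ** 2) * e
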