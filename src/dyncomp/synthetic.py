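"""Synthetic benchmark data with planted ground truth.

Two generators emulate, at desk scale (tens of residues, 10^2-10^4 frames),
the structure the pipeline expects from a long packed-protein trajectory:

* :func:`generate_series_set` emits abstract distance time series — two-state
  side-chain switches (piecewise-constant means with Gaussian noise), domain
  blocks (a shared smooth latent drift scaled per member plus independent
  noise) and stationary background — together with ground-truth labels.
* :func:`generate_trajectory` realizes such a spec geometrically as a
  coarse-grained multi-model PDB: an antiparallel two-segment hairpin whose
  second segment (the mobile body) translates away from the first along the
  inter-segment axis following the latent drift, so that every cross-segment
  CA-CA distance co-varies; a planted switch pair's side-chain tips are
  placed directly at the planted distance.

The latent drift is a sigmoidal transition with a small smooth stochastic
wiggle rather than white noise, mimicking domain shifts that accumulate over
hundreds of nanoseconds when compressed into a few hundred frames.  Follower
switches transition at the latent's steepest frame, so switch/block coupling
is high by construction.  Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .contacts import ContactPair, DistanceTimeSeries
from .exceptions import GenerationError, ValidationError
from .exporters import format_pdb_atom_line
from .trajectory_io import ResidueID

logger = logging.getLogger(__name__)

CA_SPACING = 3.8       # A, consecutive CA along a segment
SEGMENT_GAP = 7.5      # A, resting distance between the two segments
_ELEMENT = {"N": "N", "O": "O", "S": "S"}

# Coarse side-chain templates: (atom name, extension along the side-chain
# direction from CA, perpendicular x offset), Angstrom.
SIDECHAIN_TEMPLATES: Dict[str, List[Tuple[str, float, float]]] = {
    "GLY": [],
    "ALA": [("CB", 1.3, 0.0)],
    "SER": [("CB", 1.3, 0.0), ("OG", 2.2, 0.0)],
    "THR": [("CB", 1.3, 0.0), ("OG1", 2.2, 0.0), ("CG2", 2.0, 0.9)],
    "CYS": [("CB", 1.3, 0.0), ("SG", 2.4, 0.0)],
    "VAL": [("CB", 1.3, 0.0), ("CG1", 2.2, 0.6), ("CG2", 2.2, -0.6)],
    "TYR": [("CB", 1.3, 0.0), ("CG", 2.5, 0.0), ("CD1", 3.1, 1.0),
            ("CD2", 3.1, -1.0), ("CE1", 4.4, 1.0), ("CE2", 4.4, -1.0),
            ("CZ", 5.0, 0.0), ("OH", 6.3, 0.0)],
}


@dataclass(frozen=True)
class SwitchSpec:
    """A planted side-chain switch between distance substates."""

    name: str = "switch-1"
    residues: Optional[Tuple[int, int]] = None  # 1-based resids (trajectory mode)
    means: Tuple[float, ...] = (2.7, 5.5)       # A, one per substate
    sigma: float = 0.3                          # A, within-substate noise
    transitions: Optional[Tuple[int, ...]] = None  # 1-based frame of each regime change
    follows: Optional[str] = None               # block name to synchronize with


@dataclass(frozen=True)
class DomainBlockSpec:
    """A planted block of co-drifting distance series (one domain motion)."""

    name: str = "block-1"
    n_members: int = 6          # series count (series-set mode)
    residues: Optional[Tuple[int, ...]] = None  # 1-based mobile resids (trajectory mode)
    amplitude: float = 4.0      # A, latent drift amplitude
    noise_sigma: float = 0.2    # A, independent per-series noise
    baseline: float = 10.0      # A, resting distance of member series
    midpoint_frac: float = 0.5  # latent transition midpoint as fraction of frames
    tau_frac: float = 1.0 / 24.0  # latent transition width as fraction of frames


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a planted synthetic data set."""

    n_frames: int = 1000
    n_residues: int = 12
    switches: Tuple[SwitchSpec, ...] = (SwitchSpec(),)
    blocks: Tuple[DomainBlockSpec, ...] = (DomainBlockSpec(),)
    n_background: int = 0
    background_sigma: float = 0.3
    jitter: float = 0.03         # A, per-coordinate atomic jitter (trajectory mode)
    drift_wiggle_frac: float = 0.05
    seed: int = 0
    residue_names: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        block_names = [b.name for b in self.blocks]
        if len(set(block_names)) != len(block_names):
            raise ValidationError("duplicate block names")
        for sw in self.switches:
            if len(sw.means) < 2:
                raise ValidationError(f"switch {sw.name} needs >= 2 substate means")
            if sw.sigma <= 0:
                raise ValidationError(f"switch {sw.name} sigma must be > 0")
            if sw.transitions is not None:
                t = sw.transitions
                if list(t) != sorted(set(t)) or t[0] < 1 or t[-1] > self.n_frames:
                    raise ValidationError(
                        f"switch {sw.name}: transition frames must be strictly "
                        f"increasing within [1, {self.n_frames}]"
                    )
            if sw.follows is not None and sw.follows not in block_names:
                raise ValidationError(f"switch {sw.name} follows unknown block {sw.follows!r}")
        for b in self.blocks:
            if b.noise_sigma <= 0:
                raise ValidationError(f"block {b.name} noise_sigma must be > 0")
            if b.amplitude < 0:
                raise ValidationError(f"block {b.name} amplitude must be >= 0")
        if self.residue_names is not None and len(self.residue_names) != self.n_residues:
            raise ValidationError("residue_names length must equal n_residues")


@dataclass
class SeriesSet:
    """Generated series plus ground truth (labels partition the series)."""

    series: List[DistanceTimeSeries]
    labels: Dict[str, str]               # series_id -> "switch:NAME" | "block:NAME" | "background"
    latents: Dict[str, np.ndarray]       # block name -> latent drift (A)
    transition_frames: Dict[str, Tuple[int, ...]]  # switch name -> 1-based frames
    spec: SyntheticSpec


def _latent_drift(
    n: int,
    rng: np.random.Generator,
    midpoint: float,
    wiggle_frac: float,
    tau_frac: float = 1.0 / 24.0,
) -> np.ndarray:
    """Sigmoidal 0->1 transition plus a small low-pass-filtered wiggle."""
    t = np.arange(n, dtype=float)
    tau = max(n * tau_frac, 1.0)
    base = 1.0 / (1.0 + np.exp(-(t - midpoint) / tau))
    if wiggle_frac > 0:
        w = gaussian_filter1d(rng.standard_normal(n), sigma=max(n / 50.0, 1.0))
        peak = np.abs(w).max()
        if peak > 0:
            base = base + wiggle_frac * w / peak
    lo, hi = base.min(), base.max()
    return (base - lo) / (hi - lo)


def _regimes(n: int, means: Sequence[float], transitions: Sequence[int]) -> np.ndarray:
    """Per-frame substate mean; regime r starts at 1-based frame transitions[r-1]."""
    idx = np.searchsorted(np.asarray(transitions), np.arange(1, n + 1), side="right")
    return np.asarray(means)[idx % len(means)]


def _switch_transitions(
    sw: SwitchSpec, spec: SyntheticSpec, steepest: Dict[str, int]
) -> Tuple[int, ...]:
    if sw.transitions is not None:
        return tuple(sw.transitions)
    if sw.follows is not None:
        return (steepest[sw.follows],)
    k = len(sw.means)
    return tuple(int(round(spec.n_frames * i / k)) for i in range(1, k))


def _fake_pair(counter: List[int], mode: str, res_name: str = "ALA") -> ContactPair:
    r = counter[0]
    counter[0] += 7
    return ContactPair(
        ResidueID("A", r, res_name), ResidueID("A", r + 3, res_name), mode
    )


def generate_series_set(spec: SyntheticSpec) -> SeriesSet:
    """Emit planted distance series with ground-truth labels (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    counter = [1]
    series: List[DistanceTimeSeries] = []
    labels: Dict[str, str] = {}
    latents: Dict[str, np.ndarray] = {}
    steepest: Dict[str, int] = {}

    for b in spec.blocks:
        lat = _latent_drift(n, rng, b.midpoint_frac * n, spec.drift_wiggle_frac, b.tau_frac)
        latents[b.name] = b.amplitude * lat
        steepest[b.name] = int(np.argmax(np.diff(gaussian_filter1d(lat, 3)))) + 1
        for _ in range(b.n_members):
            base = b.baseline + rng.uniform(-2.0, 2.0)
            scale = rng.uniform(0.7, 1.3)
            vals = base + scale * b.amplitude * lat + rng.normal(0.0, b.noise_sigma, n)
            s = DistanceTimeSeries(pair=_fake_pair(counter, "calpha"), values=np.maximum(vals, 0.0))
            series.append(s)
            labels[s.series_id] = f"block:{b.name}"

    transition_frames: Dict[str, Tuple[int, ...]] = {}
    for sw in spec.switches:
        trans = _switch_transitions(sw, spec, steepest)
        transition_frames[sw.name] = trans
        vals = _regimes(n, sw.means, trans) + rng.normal(0.0, sw.sigma, n)
        s = DistanceTimeSeries(
            pair=_fake_pair(counter, "sidechain_vdw", "TYR"), values=np.maximum(vals, 0.0)
        )
        series.append(s)
        labels[s.series_id] = f"switch:{sw.name}"

    for _ in range(spec.n_background):
        base = rng.uniform(4.0, 12.0)
        vals = base + rng.normal(0.0, spec.background_sigma, n)
        s = DistanceTimeSeries(pair=_fake_pair(counter, "calpha"), values=np.maximum(vals, 0.0))
        series.append(s)
        labels[s.series_id] = "background"

    return SeriesSet(series, labels, latents, transition_frames, spec)


# ---------------------------------------------------------------------------
# Geometric realization as a multi-model PDB


@dataclass
class TrajectoryTruth:
    """Ground truth of a generated trajectory."""

    path: str
    switch_residues: List[Tuple[int, int]]     # 1-based resid pairs
    mobile_residues: Tuple[int, ...]           # 1-based resids of the drifting body
    transition_frames: Dict[str, Tuple[int, ...]]
    drift: np.ndarray                          # latent drift (A) per frame
    spec: SyntheticSpec


def _residue_layout(spec: SyntheticSpec) -> Tuple[np.ndarray, Tuple[int, ...]]:
    """Resting CA positions of the antiparallel hairpin; returns mobile resids."""
    n = spec.n_residues
    if n < 6:
        raise ValidationError("trajectory generation needs n_residues >= 6")
    if len(spec.blocks) > 1:
        raise GenerationError(
            "geometric realization supports one domain block (one mobile body); "
            f"got {len(spec.blocks)}"
        )
    if spec.blocks and spec.blocks[0].residues is not None:
        mobile = tuple(sorted(spec.blocks[0].residues))
        if mobile != tuple(range(mobile[0], n + 1)) or mobile[0] < 2:
            raise GenerationError(
                "mobile body must be a contiguous suffix of the chain "
                f"(got residues {mobile})"
            )
    else:
        mobile = tuple(range(n // 2 + 1, n + 1))
    n_static = n - len(mobile)
    ca = np.zeros((n, 3))
    for i in range(n_static):  # static segment along +x at y = 0
        ca[i] = (CA_SPACING * i, 0.0, 0.0)
    for j in range(len(mobile)):  # antiparallel segment at y = SEGMENT_GAP
        ca[n_static + j] = (CA_SPACING * (len(mobile) - 1 - j), SEGMENT_GAP, 0.0)
    return ca, mobile


def _sidechain_template(res_name: str) -> List[Tuple[str, float, float]]:
    if res_name in SIDECHAIN_TEMPLATES:
        return SIDECHAIN_TEMPLATES[res_name]
    logger.warning("no side-chain template for %s; using a single CB", res_name)
    return [("CB", 1.3, 0.0)]


def generate_trajectory(spec: SyntheticSpec, path: str) -> TrajectoryTruth:
    """Write a multi-model PDB realizing the spec; return the ground truth.

    Residues sit on a two-segment antiparallel hairpin.  The mobile segment
    translates along +y by the latent drift, making every cross-segment CA-CA
    distance increase together (one correlated cluster).  Each switch pair
    must span the two segments with sequence separation >= 3; the mobile
    partner's side-chain tip is placed at the planted distance from the
    static partner's tip.  All atoms get independent Gaussian jitter.
    """
    rng = np.random.default_rng(spec.seed)
    n_res, n_frames = spec.n_residues, spec.n_frames
    ca0, mobile = _residue_layout(spec)
    mobile_set = set(mobile)
    res_names = tuple(spec.residue_names) if spec.residue_names else ("ALA",) * n_res

    block = spec.blocks[0] if spec.blocks else None
    if block is not None:
        lat = _latent_drift(n_frames, rng, block.midpoint_frac * n_frames,
                            spec.drift_wiggle_frac, block.tau_frac)
        drift = block.amplitude * lat
        steepest = {block.name: int(np.argmax(np.diff(gaussian_filter1d(lat, 3)))) + 1}
    else:
        drift = np.zeros(n_frames)
        steepest = {}

    switch_d: Dict[Tuple[int, int], np.ndarray] = {}
    transition_frames: Dict[str, Tuple[int, ...]] = {}
    for sw in spec.switches:
        if sw.residues is None:
            raise GenerationError(f"switch {sw.name} needs explicit residue indices")
        i, j = sw.residues
        if not (1 <= i <= n_res and 1 <= j <= n_res):
            raise GenerationError(f"switch {sw.name}: residues {sw.residues} out of range")
        if (i in mobile_set) == (j in mobile_set):
            raise GenerationError(
                f"switch {sw.name}: pair {sw.residues} must span the hinge "
                "(one static, one mobile residue)"
            )
        if abs(i - j) < 3:
            raise GenerationError(f"switch {sw.name}: sequence separation < 3")
        static_r, mobile_r = (i, j) if j in mobile_set else (j, i)
        if res_names[static_r - 1] == "GLY" or res_names[mobile_r - 1] == "GLY":
            raise GenerationError(f"switch {sw.name}: glycine has no side chain to switch")
        trans = _switch_transitions(sw, spec, steepest)
        transition_frames[sw.name] = trans
        d = _regimes(n_frames, sw.means, trans) + rng.normal(0.0, sw.sigma, n_frames)
        switch_d[(static_r, mobile_r)] = np.maximum(d, 0.1)

    switch_static = {p[0]: p for p in switch_d}
    switch_mobile = {p[1]: p for p in switch_d}
    up, down = np.array([0.0, 1.0, 0.0]), np.array([0.0, -1.0, 0.0])

    lines: List[str] = []
    for f in range(n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 0
        shift = np.array([0.0, drift[f], 0.0])
        tip_static: Dict[int, np.ndarray] = {}
        # pass 1: static-residue switch tips (mobile partners depend on them)
        for r in switch_static:
            tmpl = _sidechain_template(res_names[r - 1])
            reach = max(a for _, a, _ in tmpl)
            tip_static[r] = ca0[r - 1] + up * reach
        for r in range(1, n_res + 1):
            name3 = res_names[r - 1]
            base = ca0[r - 1] + (shift if r in mobile_set else 0.0)
            atoms: List[Tuple[str, np.ndarray]] = [
                ("N", base + np.array([-1.2, 0.4, 0.0])),
                ("CA", base),
                ("C", base + np.array([1.2, 0.4, 0.0])),
                ("O", base + np.array([1.5, 1.2, 0.2])),
            ]
            tmpl = _sidechain_template(name3)
            if r in switch_mobile:
                pair = switch_mobile[r]
                reach = max(a for _, a, _ in tmpl)
                tip = tip_static[pair[0]] + up * switch_d[pair][f]
                for aname, along, perp in tmpl:
                    atoms.append((aname, tip + up * (reach - along) + np.array([perp, 0.0, 0.0])))
            else:
                u = up if (r in switch_static) else (down if r not in mobile_set else up)
                for aname, along, perp in tmpl:
                    atoms.append((aname, base + u * along + np.array([perp, 0.0, 0.0])))
            for aname, pos in atoms:
                serial += 1
                xyz = pos + rng.normal(0.0, spec.jitter, 3)
                lines.append(
                    format_pdb_atom_line(
                        serial, aname, name3, "A", r, xyz,
                        element=_ELEMENT.get(aname[0], "C"),
                    )
                )
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    logger.info("wrote synthetic trajectory: %d residues x %d frames -> %s",
                n_res, n_frames, path)

    return TrajectoryTruth(
        path=str(path),
        switch_residues=sorted(switch_d),
        mobile_residues=mobile,
        transition_frames=transition_frames,
        drift=drift,
        spec=spec,
    )


def two_block_component_spec(seed: int = 0, n_frames: int = 1000) -> SyntheticSpec:
    """Two independent domain blocks, each with two follower switches.

    The blocks transition at well-separated times (15% and 85% of the run)
    with a sharp latent (tau = n/60) and a small wiggle, so member series
    within a block couple strongly (absolute average DCC >= 0.9) while
    series across blocks stay weakly coupled (<= 0.3).  This is the planted
    two-community benchmark for the network stage.
    """
    return SyntheticSpec(
        n_frames=n_frames,
        switches=(
            SwitchSpec("switch-A1", follows="block-A"),
            SwitchSpec("switch-A2", follows="block-A"),
            SwitchSpec("switch-B1", follows="block-B"),
            SwitchSpec("switch-B2", follows="block-B"),
        ),
        blocks=(
            DomainBlockSpec("block-A", n_members=4, midpoint_frac=0.15, tau_frac=1 / 60),
            DomainBlockSpec("block-B", n_members=4, midpoint_frac=0.85, tau_frac=1 / 60),
        ),
        drift_wiggle_frac=0.02,
        seed=seed,
    )


def planted_components(series_set: SeriesSet):
    """Ground-truth components of a series set: one per switch and per block."""
    from .domain_motions import DynamicComponent

    by_label: Dict[str, List[str]] = {}
    for s in series_set.series:
        by_label.setdefault(series_set.labels[s.series_id], []).append(s.series_id)
    comps = []
    for label in sorted(by_label):
        if label == "background":
            continue
        kind = "sidechain" if label.startswith("switch:") else "domain"
        comps.append(DynamicComponent(label, kind, tuple(by_label[label])))
    return comps


def two_state_trajectory_spec(
    n_frames: int = 500, seed: int = 0, drift_amplitude: float = 2.8
) -> SyntheticSpec:
    """The canonical benchmark: 12 residues, 1 switch following 1 domain block.

    A polyalanine hairpin whose mobile half drifts 2.8 A along the
    inter-segment axis, with one 2.7/5.5 A side-chain switch (residues 3 and
    10) transitioning at the drift midpoint.
    """
    return SyntheticSpec(
        n_frames=n_frames,
        n_residues=12,
        switches=(SwitchSpec(name="switch-1", residues=(3, 10), follows="block-1"),),
        blocks=(DomainBlockSpec(name="block-1", amplitude=drift_amplitude),),
        seed=seed,
    )
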