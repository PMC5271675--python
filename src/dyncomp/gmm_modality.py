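"""Gaussian-mixture modality screen for side-chain distance series.

Each inter-residue distance time series is treated purely as a sample from a
1-D probability density: a Gaussian mixture model is fitted by
expectation-maximization for k = 1..k_max components, the Bayesian information
criterion

    BIC = k_params * ln(n) - 2 * lnL,   k_params = 3k - 1

selects k, and the series is classified *unimodal* (a stable contact) or
*multimodal* (a rearranging contact sampling >= 2 distance substates).  Two
guard rails keep heavy-tailed unimodal densities from being split into
spurious substates: mixture components with weight < ``min_weight`` are
dropped, and components whose means are closer than ``min_separation`` are
merged (set both to 0 to recover the raw BIC verdict).

Because the verdict is density-based (time-blind), samples are sorted before
fitting; the classification is therefore exactly invariant under permutation
of the frame order.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .contacts import DistanceTimeSeries
from .domain_motions import DynamicComponent
from .exceptions import FitError, ValidationError

logger = logging.getLogger(__name__)

_EM_TOL = 1e-4        # mean log-likelihood gain per sample at convergence
_EM_MAX_ITER = 500
_RETRIES = 3          # re-seeds on non-convergence
_WEIGHT_EPS = 1e-6    # a component below this is "empty"
_VAR_FLOOR = 1e-12

ArrayLike = Union[np.ndarray, Sequence[float], DistanceTimeSeries]


@dataclass(frozen=True)
class GMMFit:
    """Mixture fit for one series, with the post-merge modality verdict.

    ``weights/means/variances`` are the raw EM parameters sorted by mean;
    ``substate_*`` hold the surviving components after the weight-floor and
    mean-separation merge rules, and are None until
    :func:`classify_modality` runs.
    """

    series_id: str
    k: int
    weights: Tuple[float, ...]
    means: Tuple[float, ...]
    variances: Tuple[float, ...]
    bic: float
    seed: int
    converged: bool = True
    modality: Optional[str] = None  # "unimodal" | "multimodal"
    substate_weights: Optional[Tuple[float, ...]] = None
    substate_means: Optional[Tuple[float, ...]] = None
    substate_variances: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.k < 1 or len(self.weights) != self.k or len(self.means) != self.k:
            raise ValidationError("inconsistent mixture parameter lengths")
        if abs(sum(self.weights) - 1.0) > 1e-9 or min(self.weights) < 0:
            raise ValidationError("mixture weights must be non-negative and sum to 1")
        if min(self.variances) <= 0:
            raise ValidationError("mixture variances must be positive")

    @property
    def n_substates(self) -> Optional[int]:
        return None if self.substate_means is None else len(self.substate_means)


def _series_values(series: ArrayLike) -> Tuple[str, np.ndarray]:
    if isinstance(series, DistanceTimeSeries):
        return series.series_id, series.values
    arr = np.asarray(series, dtype=float)
    return "", arr


def fit_gmm(series: ArrayLike, k: int, seed: int = 0) -> GMMFit:
    """EM fit of a k-component 1-D Gaussian mixture to the series' density.

    Non-convergence triggers re-seeded retries; a fit that never converges is
    returned flagged (``converged=False``) with a logged warning.  Series
    shorter than 10*k samples are rejected.
    """
    sid, values = _series_values(series)
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    n = len(values)
    if n < 10 * k:
        raise ValidationError(f"series {sid or '<anon>'} too short for k={k}: n={n} < {10 * k}")
    x = np.sort(values).reshape(-1, 1)  # density-based: order is irrelevant

    gm = None
    for attempt in range(_RETRIES):
        cand = GaussianMixture(
            n_components=k,
            covariance_type="full",
            tol=_EM_TOL,
            max_iter=_EM_MAX_ITER,
            n_init=1,
            init_params="kmeans",
            random_state=seed + 9973 * attempt,
        )
        cand.fit(x)
        gm = cand
        if cand.converged_:
            break
    assert gm is not None
    if not gm.converged_:
        logger.warning("EM did not converge for series %s at k=%d after %d seeds",
                       sid, k, _RETRIES)

    weights = gm.weights_.ravel()
    means = gm.means_.ravel()
    variances = np.maximum(gm.covariances_.reshape(-1), _VAR_FLOOR)
    order = np.argsort(means)
    return GMMFit(
        series_id=sid,
        k=k,
        weights=tuple(float(w) for w in weights[order]),
        means=tuple(float(m) for m in means[order]),
        variances=tuple(float(v) for v in variances[order]),
        bic=float(gm.bic(x)),
        seed=seed,
        converged=bool(gm.converged_),
    )


def _constant_fit(sid: str, values: np.ndarray, seed: int) -> GMMFit:
    return GMMFit(
        series_id=sid, k=1, weights=(1.0,), means=(float(values.mean()),),
        variances=(max(float(values.var()), _VAR_FLOOR),), bic=float("nan"),
        seed=seed, converged=True, modality="unimodal",
        substate_weights=(1.0,), substate_means=(float(values.mean()),),
        substate_variances=(max(float(values.var()), _VAR_FLOOR),),
    )


def select_model(series: ArrayLike, k_max: int = 5, seed: int = 0) -> GMMFit:
    """Fit k = 1..k_max and return the minimum-BIC fit (ties -> smaller k).

    Candidates with an effectively empty component are rejected (BIC must not
    select a k whose mixture wastes a component).  Constant series are
    classified unimodal without fitting.
    """
    sid, values = _series_values(series)
    if k_max < 1:
        raise ValidationError(f"k_max must be >= 1, got {k_max}")
    if float(values.var()) <= _VAR_FLOOR:
        return _constant_fit(sid, values, seed)

    best: Optional[GMMFit] = None
    for k in range(1, k_max + 1):
        if len(values) < 10 * k:
            break  # larger k is under-determined; skip
        fit = fit_gmm(series, k, seed=seed)
        if min(fit.weights) < _WEIGHT_EPS:
            continue  # empty component: reject this k
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise FitError(f"no usable mixture fit for series {sid or '<anon>'}")
    return best


def _merge_two(
    w1: float, m1: float, v1: float, w2: float, m2: float, v2: float
) -> Tuple[float, float, float]:
    w = w1 + w2
    m = (w1 * m1 + w2 * m2) / w
    v = (w1 * (v1 + m1 ** 2) + w2 * (v2 + m2 ** 2)) / w - m ** 2
    return w, m, max(v, _VAR_FLOOR)


def classify_modality(
    fit: GMMFit, min_weight: float = 0.05, min_separation: float = 1.0
) -> GMMFit:
    """Apply the weight floor and mean-separation merge, set the verdict.

    Components with weight < ``min_weight`` are dropped (weights
    renormalized); remaining components whose means differ by less than
    ``min_separation`` (Angstrom) are merged by moment matching.  The verdict
    is multimodal iff >= 2 components survive.
    """
    comps = [
        (w, m, v)
        for w, m, v in zip(fit.weights, fit.means, fit.variances)
        if w >= min_weight
    ]
    if not comps:  # degenerate: keep the heaviest raw component
        i = int(np.argmax(fit.weights))
        comps = [(fit.weights[i], fit.means[i], fit.variances[i])]
    total = sum(w for w, _, _ in comps)
    comps = sorted(((w / total, m, v) for w, m, v in comps), key=lambda c: c[1])

    merged = True
    while merged and len(comps) > 1:
        merged = False
        gaps = [comps[i + 1][1] - comps[i][1] for i in range(len(comps) - 1)]
        i = int(np.argmin(gaps))
        if gaps[i] < min_separation:
            comps[i:i + 2] = [_merge_two(*comps[i], *comps[i + 1])]
            merged = True

    return dataclasses.replace(
        fit,
        modality="multimodal" if len(comps) >= 2 else "unimodal",
        substate_weights=tuple(w for w, _, _ in comps),
        substate_means=tuple(m for _, m, _ in comps),
        substate_variances=tuple(v for _, _, v in comps),
    )


@dataclass
class ScreenResult:
    """Outcome of the side-chain modality screen (a partition of the input)."""

    components: List[DynamicComponent]   # one per multimodal series
    stable_series_ids: List[str]         # unimodal ("stable contacts")
    fits: Dict[str, GMMFit]
    failed_series_ids: List[str]


def screen_sidechain_components(
    series_list: Sequence[DistanceTimeSeries],
    k_max: int = 5,
    seed: int = 0,
    min_weight: float = 0.05,
    min_separation: float = 1.0,
    id_prefix: str = "sc",
) -> ScreenResult:
    """Classify every side-chain series; multimodal ones become components.

    Each side-chain dynamic component contains exactly one series.  Unimodal
    series are reported separately as stable contacts; series whose fits all
    fail are excluded with a logged reason.
    """
    components: List[DynamicComponent] = []
    stable: List[str] = []
    fits: Dict[str, GMMFit] = {}
    failed: List[str] = []
    for s in series_list:
        try:
            fit = classify_modality(
                select_model(s, k_max=k_max, seed=seed),
                min_weight=min_weight,
                min_separation=min_separation,
            )
        except FitError as exc:
            logger.warning("excluding series %s from screen: %s", s.series_id, exc)
            failed.append(s.series_id)
            continue
        fits[s.series_id] = fit
        if fit.modality == "multimodal":
            components.append(
                DynamicComponent(
                    component_id=f"{id_prefix}-{len(components) + 1:04d}",
                    kind="sidechain",
                    member_series=(s.series_id,),
                )
            )
        else:
            stable.append(s.series_id)
    logger.info("modality screen: %d multimodal, %d stable, %d failed",
                len(components), len(stable), len(failed))
    return ScreenResult(components, stable, fits, failed)


def fits_dataframe(fits: Dict[str, GMMFit]) -> pd.DataFrame:
    """Tabular report: one row per series with per-substate parameters."""
    kmax = max((f.n_substates or f.k) for f in fits.values()) if fits else 0
    rows = []
    for sid, f in fits.items():
        row = {
            "series_id": sid,
            "k_selected": f.k,
            "modality": f.modality,
            "n_substates": f.n_substates,
            "bic": f.bic,
            "converged": f.converged,
            "seed": f.seed,
        }
        for i in range(kmax):
            sw = f.substate_weights or ()
            sm = f.substate_means or ()
            sv = f.substate_variances or ()
            row[f"weight_{i + 1}"] = sw[i] if i < len(sw) else np.nan
            row[f"mean_{i + 1}"] = sm[i] if i < len(sm) else np.nan
            row[f"stddev_{i + 1}"] = float(np.sqrt(sv[i])) if i < len(sv) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
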