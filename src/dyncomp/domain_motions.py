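"""Dynamic cross-correlation of distance time series and domain-motion clustering.

Global domain motions are detected as clusters of highly correlated CA-CA
distance time series.  The dynamic cross-correlation (DCC) between two scalar
distance series is their zero-lag normalized cross-correlation, i.e. the
Pearson coefficient

    r = cov(a, b) / (sigma_a * sigma_b)  in [-1, 1].

The full pairwise DCC matrix is clustered by agglomerative single-linkage
(nearest-point) hierarchical clustering on the dissimilarity d = 1 - r, and
the dendrogram is cut at d = 1 - r_min so that clusters are groups of series
correlated at >= r_min (default 0.95).  Clustering uses the *signed* r:
anti-correlated series do not cluster together; absolute values enter only at
the network stage.  Because distances are invariant to rigid-body motion, no
structure superposition is performed anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .contacts import DistanceTimeSeries
from .exceptions import UndefinedCorrelationError, ValidationError

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-24  # variance below this counts as a constant series

ArrayLike = Union[np.ndarray, Sequence[float], DistanceTimeSeries]


@dataclass(frozen=True)
class DynamicComponent:
    """A node of the component network.

    Either a single rearranging side-chain series (kind="sidechain", size 1)
    or a cluster of correlated CA-CA series (kind="domain", size >= 2).
    """

    component_id: str
    kind: str  # "sidechain" | "domain"
    member_series: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("sidechain", "domain"):
            raise ValidationError(f"unknown component kind {self.kind!r}")
        if self.kind == "sidechain" and len(self.member_series) != 1:
            raise ValidationError("a side-chain component holds exactly one series")
        if len(self.member_series) == 0:
            raise ValidationError("component has no member series")
        if len(set(self.member_series)) != len(self.member_series):
            raise ValidationError("duplicate member series in component")

    @property
    def size(self) -> int:
        return len(self.member_series)


@dataclass
class DCCMatrix:
    """Symmetric matrix of pairwise DCC coefficients over named series."""

    series_ids: List[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.series_ids)
        if self.r.shape != (n, n):
            raise ValidationError("DCC matrix shape does not match series count")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValidationError("DCC matrix must be symmetric")
        if np.abs(self.r).max(initial=0.0) > 1 + 1e-9:
            raise ValidationError("DCC entries must lie in [-1, 1]")
        self._index = {sid: i for i, sid in enumerate(self.series_ids)}

    def index(self, series_id: str) -> int:
        try:
            return self._index[series_id]
        except KeyError as exc:
            raise ValidationError(f"series {series_id!r} not in DCC matrix") from exc

    def lookup(self, sid_a: str, sid_b: str) -> float:
        return float(self.r[self.index(sid_a), self.index(sid_b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.series_ids, columns=self.series_ids)


def _values(series: ArrayLike) -> np.ndarray:
    if isinstance(series, DistanceTimeSeries):
        return series.values
    return np.asarray(series, dtype=float)


def dcc(series_a: ArrayLike, series_b: ArrayLike) -> float:
    """Zero-lag Pearson correlation of two equal-length series.

    Invariant to adding constants and positive rescaling; flips sign when one
    series is negated.  Zero-variance input raises
    :class:`UndefinedCorrelationError`.
    """
    a, b = _values(series_a), _values(series_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("series must be one-dimensional and of equal length")
    if len(a) < 2:
        raise ValidationError("correlation needs at least 2 frames")
    a0 = a - a.mean()
    b0 = b - b.mean()
    va, vb = float(a0 @ a0), float(b0 @ b0)
    if va <= _VAR_FLOOR * len(a) or vb <= _VAR_FLOOR * len(b):
        raise UndefinedCorrelationError("correlation undefined for zero-variance series")
    return float(np.clip((a0 @ b0) / np.sqrt(va * vb), -1.0, 1.0))


def drop_zero_variance(
    series_list: Sequence[DistanceTimeSeries],
) -> Tuple[List[DistanceTimeSeries], List[str]]:
    """Split series into usable and zero-variance (excluded, logged)."""
    kept, dropped = [], []
    for s in series_list:
        v = s.values - s.values.mean()
        if float(v @ v) <= _VAR_FLOOR * len(v):
            dropped.append(s.series_id)
        else:
            kept.append(s)
    if dropped:
        logger.warning("excluding %d zero-variance series from DCC: %s",
                       len(dropped), ", ".join(dropped[:10]))
    return kept, dropped


def dcc_matrix(series_list: Sequence[DistanceTimeSeries]) -> DCCMatrix:
    """Full pairwise DCC matrix (deterministic; diagonal exactly 1)."""
    if len(series_list) < 2:
        raise ValidationError("need at least 2 series for a DCC matrix")
    ids = [s.series_id for s in series_list]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate series ids")
    x = np.stack([s.values for s in series_list])
    var = x.var(axis=1)
    bad = [ids[i] for i in np.nonzero(var <= _VAR_FLOOR)[0]]
    if bad:
        raise UndefinedCorrelationError(
            f"zero-variance series must be excluded first: {', '.join(bad)}"
        )
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return DCCMatrix(series_ids=ids, r=r)


def single_linkage(matrix: DCCMatrix) -> np.ndarray:
    """Nearest-point linkage on the condensed dissimilarity d = 1 - r."""
    d = 1.0 - matrix.r
    np.fill_diagonal(d, 0.0)
    condensed = np.maximum(squareform(d, checks=False), 0.0)
    return linkage(condensed, method="single")


def cluster_series(
    matrix: DCCMatrix,
    r_min: float = 0.95,
    min_cluster_size: int = 2,
    id_prefix: str = "dm",
) -> List[DynamicComponent]:
    """Domain components: single-linkage clusters at correlation >= ``r_min``.

    The dendrogram is cut at dissimilarity 1 - r_min (inclusive, so series
    correlated at exactly r_min merge).  Clusters smaller than
    ``min_cluster_size`` (default 2) are discarded: a domain motion is a
    *collection* of correlated series, so singletons are not collective.
    """
    if not (0.0 < r_min < 1.0):
        raise ValidationError(f"r_min must be in (0, 1), got {r_min}")
    z = single_linkage(matrix)
    labels = fcluster(z, t=1.0 - r_min, criterion="distance")
    groups: Dict[int, List[str]] = {}
    order: List[int] = []
    for sid, lab in zip(matrix.series_ids, labels):
        if lab not in groups:
            groups[lab] = []
            order.append(lab)
        groups[lab].append(sid)
    components = []
    for lab in order:
        members = groups[lab]
        if len(members) >= min_cluster_size:
            components.append(
                DynamicComponent(
                    component_id=f"{id_prefix}-{len(components) + 1:04d}",
                    kind="domain",
                    member_series=tuple(members),
                )
            )
    logger.info("%d clusters total, %d domain components (size >= %d) at r_min %.3f",
                len(groups), len(components), min_cluster_size, r_min)
    return components


def linkage_dataframe(matrix: DCCMatrix) -> pd.DataFrame:
    """Linkage table (scipy convention) for export alongside the clusters."""
    z = single_linkage(matrix)
    return pd.DataFrame(z, columns=["node_i", "node_j", "dissimilarity", "n_members"])
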