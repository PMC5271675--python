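"""The DCC-based network over dynamic components and its communities.

Every dynamic component (a rearranging side-chain series or a cluster of
domain-motion series) becomes one node.  The coupling between components x
and y is the absolute value of the *average* DCC over all cross pairs of
their member series,

    c(x, y) = | mean_{i in x, j in y} r(i, j) |,

average first, absolute value second — so a component whose members correlate
+0.9 and -0.9 with another couples at 0, not 0.9.  Edges connect components
with c >= the coupling cutoff (inclusive; default 0.75).  Communities are
found by Girvan-Newman edge-betweenness removal; the partition returned is
the one maximizing modularity over the removal sequence, ties resolved toward
fewer communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import igraph as ig
import numpy as np
import pandas as pd

from .domain_motions import DCCMatrix, DynamicComponent
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CouplingMatrix:
    """Absolute average DCC between every pair of components (diagonal 1)."""

    component_ids: List[str]
    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        n = len(self.component_ids)
        if self.c.shape != (n, n):
            raise ValidationError("coupling matrix shape mismatch")
        if not np.allclose(self.c, self.c.T, atol=1e-12):
            raise ValidationError("coupling matrix must be symmetric")
        if self.c.min(initial=1.0) < -1e-12 or self.c.max(initial=0.0) > 1 + 1e-9:
            raise ValidationError("couplings must lie in [0, 1]")
        self._index = {cid: i for i, cid in enumerate(self.component_ids)}

    def lookup(self, cid_a: str, cid_b: str) -> float:
        return float(self.c[self._index[cid_a], self._index[cid_b]])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.c, index=self.component_ids, columns=self.component_ids)


@dataclass
class ComponentGraph:
    """Weighted undirected graph over dynamic components.

    ``edges`` hold (component_id_a, component_id_b, weight) with weight =
    absolute average DCC >= the cutoff used to build the graph.
    ``communities`` maps component_id -> integer label once
    :func:`detect_communities` has run.
    """

    components: List[DynamicComponent]
    edges: List[Tuple[str, str, float]]
    coupling_cutoff: float
    communities: Optional[Dict[str, int]] = None
    coupling: Optional[CouplingMatrix] = None

    def __post_init__(self) -> None:
        ids = [c.component_id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate component ids in graph")
        known = set(ids)
        seen = set()
        for a, b, w in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a}")
            if a not in known or b not in known:
                raise ValidationError(f"edge references unknown component: {a}-{b}")
            if not (-1e-12 <= w <= 1 + 1e-9):
                raise ValidationError(f"edge weight out of [0, 1]: {w}")
            if w < self.coupling_cutoff - 1e-12:
                raise ValidationError(f"edge {a}-{b} below the coupling cutoff")
            key = frozenset((a, b))
            if key in seen:
                raise ValidationError(f"duplicate edge {a}-{b}")
            seen.add(key)

    @property
    def component_ids(self) -> List[str]:
        return [c.component_id for c in self.components]

    def isolated_ids(self) -> List[str]:
        touched = {cid for a, b, _ in self.edges for cid in (a, b)}
        return [cid for cid in self.component_ids if cid not in touched]

    def n_communities(self) -> Optional[int]:
        if self.communities is None:
            return None
        return len(set(self.communities.values()))


def component_coupling(
    comp_x: DynamicComponent, comp_y: DynamicComponent, matrix: DCCMatrix
) -> float:
    """|mean over all cross pairs of r(i, j)| — average first, then absolute."""
    if set(comp_x.member_series) & set(comp_y.member_series):
        raise ValidationError(
            f"components {comp_x.component_id} and {comp_y.component_id} share series"
        )
    ix = [matrix.index(s) for s in comp_x.member_series]
    iy = [matrix.index(s) for s in comp_y.member_series]
    return abs(float(np.mean(matrix.r[np.ix_(ix, iy)])))


def coupling_matrix(
    components: Sequence[DynamicComponent], matrix: DCCMatrix
) -> CouplingMatrix:
    """All pairwise component couplings; c(x, x) = 1 by convention."""
    n = len(components)
    c = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            c[i, j] = c[j, i] = component_coupling(components[i], components[j], matrix)
    return CouplingMatrix([comp.component_id for comp in components], c)


def build_network(
    components: Sequence[DynamicComponent],
    matrix: Optional[DCCMatrix] = None,
    coupling: Optional[CouplingMatrix] = None,
    coupling_cutoff: float = 0.75,
    drop_isolates: bool = False,
) -> ComponentGraph:
    """Connect components whose absolute average DCC is >= ``coupling_cutoff``.

    Pass either the full series-level DCC ``matrix`` (couplings computed here)
    or a precomputed ``coupling`` matrix.  Isolated nodes are retained unless
    ``drop_isolates`` is set.
    """
    if len(components) == 0:
        raise ValidationError("need at least one component to build a network")
    if coupling is None:
        if matrix is None:
            raise ValidationError("provide a DCC matrix or a coupling matrix")
        coupling = coupling_matrix(components, matrix)
    if list(coupling.component_ids) != [c.component_id for c in components]:
        raise ValidationError("coupling matrix does not match the component list")

    edges = []
    for i in range(len(components)):
        for j in range(i + 1, len(components)):
            w = float(coupling.c[i, j])
            if w >= coupling_cutoff:
                edges.append(
                    (components[i].component_id, components[j].component_id, w)
                )
    comps = list(components)
    if drop_isolates:
        touched = {cid for a, b, _ in edges for cid in (a, b)}
        dropped = [c.component_id for c in comps if c.component_id not in touched]
        if dropped:
            logger.info("dropping %d isolated components", len(dropped))
        comps = [c for c in comps if c.component_id in touched]
        keep = {c.component_id for c in comps}
        coupling = None if not comps else CouplingMatrix(
            [cid for cid in coupling.component_ids if cid in keep],
            coupling.c[np.ix_(
                [i for i, cid in enumerate(coupling.component_ids) if cid in keep],
                [i for i, cid in enumerate(coupling.component_ids) if cid in keep],
            )],
        )
        if not comps:
            raise ValidationError("all components isolated and dropped; nothing to build")
    logger.info("network: %d nodes, %d edges at coupling cutoff %.3f",
                len(comps), len(edges), coupling_cutoff)
    return ComponentGraph(
        components=comps, edges=edges, coupling_cutoff=coupling_cutoff, coupling=coupling
    )


def _to_igraph(graph: ComponentGraph) -> ig.Graph:
    ids = graph.component_ids
    index = {cid: i for i, cid in enumerate(ids)}
    g = ig.Graph(n=len(ids))
    g.vs["name"] = ids
    g.add_edges([(index[a], index[b]) for a, b, _ in graph.edges])
    g.es["weight"] = [w for _, _, w in graph.edges]
    return g


def detect_communities(graph: ComponentGraph, weighted: bool = False) -> ComponentGraph:
    """Girvan-Newman edge-betweenness communities, cut at maximum modularity.

    Betweenness runs on the unweighted topology by default (``weighted=True``
    treats 1/weight as edge length).  Labels are renumbered by first
    appearance in node insertion order, so the labeling is deterministic.
    Disconnected graph components necessarily end up in different
    communities; an empty graph yields an empty labeling.
    """
    ids = graph.component_ids
    if not ids:
        return replace(graph, communities={})
    g = _to_igraph(graph)
    if g.ecount() == 0:
        membership = list(range(len(ids)))
    else:
        lengths = [1.0 / w for w in g.es["weight"]] if weighted else None
        dendro = g.community_edge_betweenness(directed=False, weights=lengths)
        best_q, best_membership = -np.inf, None
        for n in range(1, g.vcount() + 1):
            try:
                clustering = dendro.as_clustering(n)
            except Exception:  # noqa: BLE001 - n below the number of graph components
                continue
            q = g.modularity(clustering.membership)
            if q > best_q + 1e-12:  # strict improvement: ties keep fewer communities
                best_q, best_membership = q, clustering.membership
        assert best_membership is not None
        membership = best_membership

    relabel: Dict[int, int] = {}
    communities: Dict[str, int] = {}
    for cid, lab in zip(ids, membership):
        if lab not in relabel:
            relabel[lab] = len(relabel)
        communities[cid] = relabel[lab]
    logger.info("detected %d communities over %d nodes", len(relabel), len(ids))
    return replace(graph, communities=communities)


def node_dataframe(graph: ComponentGraph) -> pd.DataFrame:
    comm = graph.communities or {}
    return pd.DataFrame(
        [
            {
                "component_id": c.component_id,
                "kind": c.kind,
                "size": c.size,
                "community": comm.get(c.component_id),
            }
            for c in graph.components
        ]
    )


def edge_dataframe(graph: ComponentGraph) -> pd.DataFrame:
    comm = graph.communities or {}
    return pd.DataFrame(
        [
            {
                "source": a,
                "target": b,
                "weight": w,
                "community_source": comm.get(a),
                "community_target": comm.get(b),
            }
            for a, b, w in graph.edges
        ],
        columns=["source", "target", "weight", "community_source", "community_target"],
    )
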