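"""End-to-end orchestration: trajectory -> dynamic components -> community network.

Stages, with the method's default cutoffs:

1. contacts: side-chain van der Waals and polar head-group pairs that come
   within 5 A in at least one frame; CA-CA pairs within 15 A.
2. modality screen: GMM/BIC classification of every side-chain series;
   multimodal series become side-chain dynamic components.
3. domain motions: DCC matrix of CA-CA series, single-linkage clusters at
   r >= 0.95 become domain components.
4. network: absolute average inter-component DCC; edges at >= 0.75;
   Girvan-Newman edge-betweenness communities.
5. export: CSV tables, GraphML, per-community PDB files, run manifest.

All outputs are deterministic given the seed, so a rerun reproduces every
file byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .component_network import (
    ComponentGraph,
    build_network,
    detect_communities,
    edge_dataframe,
    node_dataframe,
)
from .contacts import (
    DistanceTimeSeries,
    compute_series,
    enumerate_pairs,
    write_pair_manifest,
    write_series_csv,
)
from .domain_motions import (
    DCCMatrix,
    DynamicComponent,
    cluster_series,
    dcc_matrix,
    drop_zero_variance,
    linkage_dataframe,
)
from .exceptions import ValidationError
from .exporters import write_community_pdb, write_graphml, write_run_manifest
from .gmm_modality import ScreenResult, fits_dataframe, screen_sidechain_components
from .trajectory_io import Trajectory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, with the method's defaults."""

    contact_cutoff: float = 5.0      # A, side-chain vdW and polar contacts
    calpha_cutoff: float = 15.0      # A, CA-CA pairs
    min_seq_sep: int = 3             # residues, same-chain pairs
    screen_stride: int = 1           # frame stride for contact screening only
    k_max: int = 5                   # largest mixture size tried
    gmm_min_weight: float = 0.05     # substate weight floor
    gmm_min_separation: float = 1.0  # A, substate mean separation floor
    r_min: float = 0.95              # DCC cutoff for domain clusters
    min_cluster_size: int = 2        # smallest collective domain motion
    coupling_cutoff: float = 0.75    # absolute average DCC for network edges
    drop_isolates: bool = False
    weighted_betweenness: bool = False
    seed: int = 0
    visualization_frame: int = -1    # frame written to community PDBs (-1 = last)


@dataclass
class PipelineResult:
    """All intermediates and outputs of one pipeline run."""

    config: PipelineConfig
    trajectory: Trajectory
    sidechain_series: List[DistanceTimeSeries]
    polar_series: List[DistanceTimeSeries]
    calpha_series: List[DistanceTimeSeries]
    screen: ScreenResult
    domain_components: List[DynamicComponent]
    components: List[DynamicComponent]
    component_dccm: Optional[DCCMatrix]
    calpha_dccm: Optional[DCCMatrix]
    graph: Optional[ComponentGraph]
    series_by_id: Dict[str, DistanceTimeSeries]
    counts: Dict[str, int]
    manifest: dict

    @property
    def sidechain_components(self) -> List[DynamicComponent]:
        return self.screen.components

    def communities(self) -> Dict[int, List[DynamicComponent]]:
        """Components grouped by community label (empty before detection)."""
        if self.graph is None or self.graph.communities is None:
            return {}
        by_id = {c.component_id: c for c in self.graph.components}
        out: Dict[int, List[DynamicComponent]] = {}
        for cid, lab in self.graph.communities.items():
            out.setdefault(lab, []).append(by_id[cid])
        return out


def run_pipeline(
    traj: Trajectory,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[str] = None,
) -> PipelineResult:
    """Run every stage on a loaded trajectory; optionally write all outputs."""
    cfg = config or PipelineConfig()

    # stage 1: contacts and series
    vdw_pairs = enumerate_pairs(traj, "sidechain_vdw", cfg.contact_cutoff,
                                cfg.min_seq_sep, cfg.screen_stride)
    polar_pairs = enumerate_pairs(traj, "polar", cfg.contact_cutoff,
                                  cfg.min_seq_sep, cfg.screen_stride)
    ca_pairs = enumerate_pairs(traj, "calpha", cfg.calpha_cutoff,
                               cfg.min_seq_sep, cfg.screen_stride)
    vdw_series = compute_series(traj, vdw_pairs)
    polar_series = compute_series(traj, polar_pairs)
    ca_series = compute_series(traj, ca_pairs)

    # stage 2: side-chain modality screen (vdW and polar series both feed it)
    screen = screen_sidechain_components(
        vdw_series + polar_series,
        k_max=cfg.k_max,
        seed=cfg.seed,
        min_weight=cfg.gmm_min_weight,
        min_separation=cfg.gmm_min_separation,
    )

    # stage 3: domain motions from CA-CA series
    ca_usable, ca_dropped = drop_zero_variance(ca_series)
    calpha_dccm = dcc_matrix(ca_usable) if len(ca_usable) >= 2 else None
    domain_components = (
        cluster_series(calpha_dccm, cfg.r_min, cfg.min_cluster_size)
        if calpha_dccm is not None
        else []
    )

    components = screen.components + domain_components
    series_by_id = {s.series_id: s for s in vdw_series + polar_series + ca_series}

    # stage 4: component network and communities
    graph: Optional[ComponentGraph] = None
    component_dccm: Optional[DCCMatrix] = None
    if components:
        member_ids = [sid for c in components for sid in c.member_series]
        member_series = [series_by_id[sid] for sid in member_ids]
        component_dccm = dcc_matrix(member_series) if len(member_series) >= 2 else None
        if component_dccm is not None:
            graph = detect_communities(
                build_network(
                    components,
                    matrix=component_dccm,
                    coupling_cutoff=cfg.coupling_cutoff,
                    drop_isolates=cfg.drop_isolates,
                ),
                weighted=cfg.weighted_betweenness,
            )

    counts = {
        "n_frames": traj.n_frames,
        "n_residues": len(traj.residues),
        "n_sidechain_vdw_series": len(vdw_series),
        "n_polar_series": len(polar_series),
        "n_calpha_series": len(ca_series),
        "n_calpha_zero_variance_excluded": len(ca_dropped),
        "n_multimodal": len(screen.components),
        "n_stable_contacts": len(screen.stable_series_ids),
        "n_screen_failed": len(screen.failed_series_ids),
        "n_domain_components": len(domain_components),
        "n_components": len(components),
        "n_edges": len(graph.edges) if graph else 0,
        "n_isolated_components": len(graph.isolated_ids()) if graph else len(components),
        "n_communities": graph.n_communities() if graph else 0,
    }
    if graph is not None and graph.isolated_ids():
        # the community count excluding isolated nodes, reported alongside
        iso = set(graph.isolated_ids())
        counts["n_communities_without_isolates"] = len(
            {lab for cid, lab in (graph.communities or {}).items() if cid not in iso}
        )

    manifest = {
        "dyncomp_version": __version__,
        "config": asdict(cfg),
        "input": {
            "source": traj.source,
            "checksum_sha256": traj.checksum(),
            "stride": traj.stride,
            "frame_interval": traj.frame_interval,
        },
        "counts": counts,
        "versions": _library_versions(),
    }

    result = PipelineResult(
        config=cfg,
        trajectory=traj,
        sidechain_series=vdw_series,
        polar_series=polar_series,
        calpha_series=ca_series,
        screen=screen,
        domain_components=domain_components,
        components=components,
        component_dccm=component_dccm,
        calpha_dccm=calpha_dccm,
        graph=graph,
        series_by_id=series_by_id,
        counts=counts,
        manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _library_versions() -> Dict[str, str]:
    import igraph
    import MDAnalysis
    import numpy
    import pandas
    import scipy
    import sklearn

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "MDAnalysis": MDAnalysis.__version__,
        "igraph": igraph.__version__,
    }


def write_outputs(result: PipelineResult, outdir: str) -> None:
    """Write every table, graph, community PDB and the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    for name, series in (
        ("series_sidechain_vdw", result.sidechain_series),
        ("series_polar", result.polar_series),
        ("series_calpha", result.calpha_series),
    ):
        if series:
            write_series_csv(series, str(out / f"{name}.csv"))
            write_pair_manifest([s.pair for s in series], str(out / f"{name}_pairs.csv"))

    if result.screen.fits:
        fits_dataframe(result.screen.fits).to_csv(out / "gmm_modality.csv", index=False)
    if result.calpha_dccm is not None:
        result.calpha_dccm.to_dataframe().to_csv(out / "dcc_calpha.csv")
        linkage_dataframe(result.calpha_dccm).to_csv(out / "calpha_linkage.csv", index=False)
    if result.domain_components:
        import pandas as pd

        pd.DataFrame(
            [
                {"component_id": c.component_id, "series_id": sid}
                for c in result.domain_components
                for sid in c.member_series
            ]
        ).to_csv(out / "domain_clusters.csv", index=False)

    if result.graph is not None:
        node_dataframe(result.graph).to_csv(out / "network_nodes.csv", index=False)
        edge_dataframe(result.graph).to_csv(out / "network_edges.csv", index=False)
        write_graphml(result.graph, str(out / "network.graphml"))
        if result.graph.coupling is not None:
            result.graph.coupling.to_dataframe().to_csv(out / "component_coupling.csv")
        for lab, comps in sorted(result.communities().items()):
            write_community_pdb(
                result.trajectory,
                result.config.visualization_frame,
                comps,
                result.series_by_id,
                str(out / f"community_{lab}.pdb"),
                community_id=lab,
            )

    write_run_manifest(result.manifest, str(out / "run_manifest.json"))
    logger.info("wrote pipeline outputs to %s", out)
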