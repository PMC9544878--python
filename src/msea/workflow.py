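"""End-to-end single-run pipeline: detect -> annotate -> enrich -> cluster."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .aberrant_detection import AberrantCall, call_aberrant
from .annotation import DEFAULT_TOL_PPM, Annotation, annotate_run, map_to_pathways
from .clustering import ClusterMode, PathwayCluster, cluster_pathways
from .feature_io import SampleRun
from .msea_core import EnrichmentResult, run_msea
from .reference_db import MetaboliteIndex, MetaboliteRecord, PathwayRecord

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    run: SampleRun
    calls: list[AberrantCall]
    annotations: list[Annotation]
    associations: pd.DataFrame
    enrichment: list[EnrichmentResult]
    clusters: list[PathwayCluster]

    @property
    def significant(self) -> list[EnrichmentResult]:
        return [r for r in self.enrichment if r.significant]


def run_pipeline(
    run: SampleRun,
    metabolites: list[MetaboliteRecord] | MetaboliteIndex,
    pathways: list[PathwayRecord],
    *,
    alpha: float = 0.05,
    tol_ppm: float = DEFAULT_TOL_PPM,
    drop_rt_inconsistent: bool = False,
    cluster_mode: ClusterMode | str = ClusterMode.exact,
    per_source_family: bool = False,
) -> PipelineResult:
    """Run the whole per-sample workflow with default settings."""
    index = metabolites if isinstance(metabolites, MetaboliteIndex) else MetaboliteIndex(metabolites)
    calls = call_aberrant(run, alpha=alpha)
    annotations = annotate_run(run, index, tol_ppm=tol_ppm)
    associations = map_to_pathways(annotations, pathways, drop_rt_inconsistent=drop_rt_inconsistent)
    enrichment = run_msea(
        calls, associations, pathways, annotations,
        alpha=alpha, per_source_family=per_source_family,
    )
    clusters = cluster_pathways(
        enrichment, mode=cluster_mode,
        pathway_records={p.pathway_id: p for p in pathways},
    )
    return PipelineResult(run, calls, annotations, associations, enrichment, clusters)
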