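"""Tabular serialisation of workflow results (TSV, one table per stage)."""

from __future__ import annotations

import pandas as pd

from .aberrant_detection import AberrantCall
from .annotation import Annotation
from .clustering import PathwayCluster
from .msea_core import EnrichmentResult

__all__ = ["calls_frame", "annotations_frame", "enrichment_frame", "clusters_frame"]


def calls_frame(calls: list[AberrantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "statistic": [c.statistic for c in calls],
            "raw_p": [c.raw_p for c in calls],
            "adjusted_p": [c.adjusted_p for c in calls],
            "is_aberrant": [c.is_aberrant for c in calls],
            "direction": [c.direction.value for c in calls],
        }
    )


def annotations_frame(annotations: list[Annotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [a.feature_id for a in annotations],
            "metabolite_id": [a.metabolite_id for a in annotations],
            "source": [a.source.value for a in annotations],
            "adduct": [a.adduct.value for a in annotations],
            "neutral_mass_obs": [a.neutral_mass_obs for a in annotations],
            "ppm_error": [a.ppm_error for a in annotations],
            "rt_status": [a.rt_status.value for a in annotations],
        }
    )


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "source": [r.source.value for r in results],
            "a": [r.counts.a for r in results],
            "b": [r.counts.b for r in results],
            "c": [r.counts.c for r in results],
            "d": [r.counts.d for r in results],
            "raw_p": [r.raw_p for r in results],
            "holm_p": [r.holm_p for r in results],
            "significant": [r.significant for r in results],
            "aberrant_metabolite_ids": [
                ";".join(sorted(r.aberrant_metabolite_ids)) for r in results
            ],
        }
    )


def clusters_frame(clusters: list[PathwayCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "source": [c.source.value for c in clusters],
            "representative_pathway_id": [c.representative_pathway_id for c in clusters],
            "member_pathway_ids": [";".join(sorted(c.member_pathway_ids)) for c in clusters],
            "cluster_p": [c.cluster_p for c in clusters],
            "aberrant_metabolite_union": [
                ";".join(sorted(c.aberrant_metabolite_union)) for c in clusters
            ],
            "cross_source_links": [";".join(c.cross_source_links) for c in clusters],
        }
    )
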