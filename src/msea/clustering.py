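"""Redundancy clustering of enriched pathways.

Reference pathways overlap heavily, so one root set of aberrant
metabolites typically enriches several near-identical pathways.  Enriched
pathways are therefore grouped: two pathways of the same source database
are linked when their aberrant metabolite sets overlap 100% -- either
identical sets (``exact`` mode, the default) or one set fully contained
in the other (``subset`` mode) -- and clusters are the connected
components of the link graph.  HMDB/SMPDB and KEGG identifiers are not
reliably cross-linked, so the two pathway sources are clustered
separately; clusters of different sources driven by the identical set of
aberrant *features* are cross-referenced in the output instead.

Each cluster is summarised by one representative pathway, chosen by three
sequential filters: (1) most associated aberrant features; (2) lowest raw
enrichment p; (3) preferred category ("Metabolic" for SMPDB, "Metabolism"
for KEGG); remaining ties break on the lexicographically smallest pathway
id.  The cluster's p-value is its representative's raw Fisher p.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import networkx as nx

from .msea_core import EnrichmentResult
from .reference_db import PREFERRED_CATEGORY, PathwayRecord, PathwaySource

__all__ = ["ClusterMode", "LinkKey", "PathwayCluster", "cluster_pathways", "select_representative"]


class ClusterMode(str, enum.Enum):
    exact = "exact"
    subset = "subset"


class LinkKey(str, enum.Enum):
    """Whether 100% overlap is evaluated on aberrant metabolite ids (the
    default) or on aberrant feature ids."""

    metabolites = "metabolites"
    features = "features"


@dataclass(frozen=True)
class PathwayCluster:
    cluster_id: str
    source: PathwaySource
    member_pathway_ids: frozenset[str]
    representative_pathway_id: str
    cluster_p: float
    aberrant_metabolite_union: frozenset[str]
    aberrant_feature_union: frozenset[str]
    cross_source_links: tuple[str, ...] = field(default=())


def _linked(x: frozenset, y: frozenset, mode: ClusterMode) -> bool:
    if mode is ClusterMode.exact:
        return x == y
    return x <= y or y <= x


def select_representative(
    members: list[EnrichmentResult],
    pathway_records: dict[str, PathwayRecord] | None = None,
) -> str:
    """Representative pathway id by the three-rule filter cascade."""
    if not members:
        raise ValueError("empty cluster")
    pool = list(members)
    # (1) highest number of associated aberrant features
    top = max(len(r.aberrant_feature_ids) for r in pool)
    pool = [r for r in pool if len(r.aberrant_feature_ids) == top]
    # (2) lowest raw p
    best = min(r.raw_p for r in pool)
    pool = [r for r in pool if r.raw_p == best]
    # (3) preferred category, when pathway records are known
    if pathway_records and len(pool) > 1:
        preferred = [
            r
            for r in pool
            if r.pathway_id in pathway_records
            and pathway_records[r.pathway_id].category
            == PREFERRED_CATEGORY.get(r.source.value)
        ]
        if preferred:
            pool = preferred
    return min(r.pathway_id for r in pool)


def cluster_pathways(
    results: list[EnrichmentResult],
    mode: ClusterMode | str = ClusterMode.exact,
    *,
    link_key: LinkKey | str = LinkKey.metabolites,
    pathway_records: dict[str, PathwayRecord] | None = None,
    significant_only: bool = True,
) -> list[PathwayCluster]:
    """Cluster one run's enriched pathways, per source database.

    Returns clusters of both sources together, sorted by ascending
    cluster p (ties by representative id) and numbered ``<SOURCE>_C<k>``
    in that order.  Cross-source links list cluster ids from the other
    source whose aberrant feature unions are identical.
    """
    mode = ClusterMode(mode)
    link_key = LinkKey(link_key)
    pool = [r for r in results if r.significant or not significant_only]

    def key_set(r: EnrichmentResult) -> frozenset[str]:
        if link_key is LinkKey.metabolites:
            return r.aberrant_metabolite_ids
        return r.aberrant_feature_ids

    clusters: list[PathwayCluster] = []
    for source in PathwaySource:
        members = [r for r in pool if r.source is source]
        if not members:
            continue
        g = nx.Graph()
        g.add_nodes_from(r.pathway_id for r in members)
        for i, ri in enumerate(members):
            for rj in members[i + 1 :]:
                if _linked(key_set(ri), key_set(rj), mode):
                    g.add_edge(ri.pathway_id, rj.pathway_id)
        by_id = {r.pathway_id: r for r in members}
        for comp in nx.connected_components(g):
            comp_members = [by_id[pid] for pid in comp]
            rep = select_representative(comp_members, pathway_records)
            clusters.append(
                PathwayCluster(
                    cluster_id="",  # numbered after sorting
                    source=source,
                    member_pathway_ids=frozenset(comp),
                    representative_pathway_id=rep,
                    cluster_p=by_id[rep].raw_p,
                    aberrant_metabolite_union=frozenset().union(
                        *(r.aberrant_metabolite_ids for r in comp_members)
                    ),
                    aberrant_feature_union=frozenset().union(
                        *(r.aberrant_feature_ids for r in comp_members)
                    ),
                )
            )

    clusters.sort(key=lambda c: (c.cluster_p, c.representative_pathway_id))
    numbered: list[PathwayCluster] = []
    counter: dict[PathwaySource, int] = {s: 0 for s in PathwaySource}
    for c in clusters:
        counter[c.source] += 1
        numbered.append(
            PathwayCluster(
                cluster_id=f"{c.source.value}_C{counter[c.source]}",
                source=c.source,
                member_pathway_ids=c.member_pathway_ids,
                representative_pathway_id=c.representative_pathway_id,
                cluster_p=c.cluster_p,
                aberrant_metabolite_union=c.aberrant_metabolite_union,
                aberrant_feature_union=c.aberrant_feature_union,
            )
        )
    # cross-source links: identical aberrant feature unions
    linked: list[PathwayCluster] = []
    for c in numbered:
        links = tuple(
            sorted(
                o.cluster_id
                for o in numbered
                if o.source is not c.source
                and o.aberrant_feature_union == c.aberrant_feature_union
            )
        )
        linked.append(
            PathwayCluster(
                cluster_id=c.cluster_id,
                source=c.source,
                member_pathway_ids=c.member_pathway_ids,
                representative_pathway_id=c.representative_pathway_id,
                cluster_p=c.cluster_p,
                aberrant_metabolite_union=c.aberrant_metabolite_union,
                aberrant_feature_union=c.aberrant_feature_union,
                cross_source_links=links,
            )
        )
    return linked
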