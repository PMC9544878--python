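"""Pathway over-representation of aberrant features (the enrichment core).

For each pathway, the run's features are cross-classified into a 2x2
table: aberrant vs non-aberrant against pathway-associated vs not.  The
background universe is every detected feature of the run (both ion modes,
annotated or not).  Enrichment is the one-sided Fisher exact tail
P(X >= a) under the hypergeometric null with the table's margins.

Only pathways associated with more than one aberrant feature (a >= 2) are
tested; the others do not enter the multiple-testing family.  P-values
are Bonferroni-Holm adjusted across the tested pathways of both pathway
databases jointly (a per-source family is available via
``per_source_family``), and pathways with adjusted p < alpha are flagged
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .aberrant_detection import AberrantCall
from .annotation import Annotation
from .reference_db import PATHWAY_METABOLITE_SOURCE, PathwayRecord, PathwaySource

__all__ = [
    "ContingencyCounts",
    "EnrichmentResult",
    "fisher_one_sided",
    "holm_adjust",
    "run_msea",
    "MIN_ABERRANT_ASSOCIATED",
]

#: Pathways need strictly more than one associated aberrant feature to be
#: tested.
MIN_ABERRANT_ASSOCIATED = 2


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 feature counts for one pathway.

    a: aberrant and pathway-associated; b: non-aberrant, associated;
    c: aberrant, unassociated; d: non-aberrant, unassociated.
    a+b+c+d equals the background feature universe of the run.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_one_sided(counts: ContingencyCounts) -> float:
    """One-sided (enrichment direction) Fisher exact p: the upper
    hypergeometric tail P(X >= a) with margins fixed."""
    N = counts.total
    K = counts.a + counts.c  # aberrant features
    n = counts.a + counts.b  # pathway-associated features
    return float(stats.hypergeom.sf(counts.a - 1, N, K, n))


def _fisher_tail_arrays(a, b, c, d) -> np.ndarray:
    """Vectorised upper-tail Fisher over parallel count arrays."""
    a = np.asarray(a)
    N = a + np.asarray(b) + np.asarray(c) + np.asarray(d)
    return stats.hypergeom.sf(a - 1, N, a + np.asarray(c), a + np.asarray(b))


def holm_adjust(raw_ps) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, input order preserved."""
    p = np.asarray(raw_ps, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    source: PathwaySource
    counts: ContingencyCounts
    raw_p: float
    holm_p: float
    significant: bool
    aberrant_feature_ids: frozenset[str]
    aberrant_metabolite_ids: frozenset[str]


def run_msea(
    calls: list[AberrantCall],
    associations: pd.DataFrame,
    pathways: list[PathwayRecord],
    annotations: list[Annotation] | None = None,
    *,
    alpha: float = 0.05,
    per_source_family: bool = False,
) -> list[EnrichmentResult]:
    """Enrichment over all pathways of one run.

    ``associations`` is the binary feature-to-pathway table from
    :func:`msea.annotation.map_to_pathways`.  ``annotations`` (optional)
    supplies the aberrant metabolite ids per pathway -- the pathway members
    annotated to the pathway's aberrant features -- which downstream
    clustering and candidate extraction consume.

    Pathways with a < 2 are skipped entirely: they appear neither in the
    output nor in the Holm correction denominator.  Results are sorted by
    ascending raw p, ties broken by pathway id.
    """
    aberrant = {c.feature_id for c in calls if c.is_aberrant}
    universe = len(calls)
    if not aberrant or associations.empty:
        return []

    assoc_by_pathway: dict[str, set[str]] = {
        pid: set(grp["feature_id"]) for pid, grp in associations.groupby("pathway_id")
    }
    # (source, member metabolite id) -> annotated feature ids
    met_features: dict[tuple[str, str], set[str]] = {}
    if annotations is not None:
        for ann in annotations:
            met_features.setdefault((ann.source.value, ann.metabolite_id), set()).add(
                ann.feature_id
            )

    tested: list[EnrichmentResult] = []
    raw_ps: list[float] = []
    for pw in pathways:
        assoc = assoc_by_pathway.get(pw.pathway_id, set())
        ab_assoc = assoc & aberrant
        a = len(ab_assoc)
        if a < MIN_ABERRANT_ASSOCIATED:
            continue
        counts = ContingencyCounts(
            a=a,
            b=len(assoc) - a,
            c=len(aberrant) - a,
            d=universe - len(assoc) - len(aberrant) + a,
        )
        raw_p = fisher_one_sided(counts)
        met_source = PATHWAY_METABOLITE_SOURCE[pw.source].value
        ab_mets = frozenset(
            mid
            for mid in pw.member_metabolite_ids
            if met_features.get((met_source, mid), set()) & ab_assoc
        )
        tested.append(
            EnrichmentResult(
                pathway_id=pw.pathway_id,
                source=pw.source,
                counts=counts,
                raw_p=raw_p,
                holm_p=np.nan,  # filled below
                significant=False,
                aberrant_feature_ids=frozenset(ab_assoc),
                aberrant_metabolite_ids=ab_mets,
            )
        )
        raw_ps.append(raw_p)

    if not tested:
        return []

    holm = np.empty(len(tested))
    if per_source_family:
        for src in PathwaySource:
            idx = [i for i, r in enumerate(tested) if r.source is src]
            if idx:
                holm[idx] = holm_adjust([raw_ps[i] for i in idx])
    else:
        holm[:] = holm_adjust(raw_ps)

    out = [
        EnrichmentResult(
            pathway_id=r.pathway_id,
            source=r.source,
            counts=r.counts,
            raw_p=r.raw_p,
            holm_p=float(h),
            significant=bool(h < alpha),
            aberrant_feature_ids=r.aberrant_feature_ids,
            aberrant_metabolite_ids=r.aberrant_metabolite_ids,
        )
        for r, h in zip(tested, holm)
    ]
    out.sort(key=lambda r: (r.raw_p, r.pathway_id))
    return out
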