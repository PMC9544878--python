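"""Cross-run analyses: pathway sharing across disorders and novel
biomarker candidates.

Pathways that come up enriched in patients with many unrelated disorders
are unlikely to be disease-specific: shared medication (e.g. NSAIDs) and
diet enrich the same pathways across a cohort and can obscure genuine
biomarkers.  Binning each pathway by the number of distinct disorders
sharing its enrichment surfaces such confounders, and a rank-sum
comparison of sharing counts between biomarker-containing and other
pathways quantifies whether biomarker pathways are the more
disorder-specific group.

Conversely, within a single run, every aberrant metabolite of a
significantly enriched biomarker pathway that is not itself a known
biomarker is a putative novel biomarker candidate, pending validation;
RT-implausible annotations are flagged as the main known false-positive
mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .annotation import Annotation, RtStatus
from .msea_core import EnrichmentResult
from .reference_db import BiomarkerPanel, PathwayRecord, biomarker_pathways

__all__ = [
    "SharingRecord",
    "pathway_sharing",
    "specificity_test",
    "novel_biomarker_candidates",
]


@dataclass(frozen=True)
class SharingRecord:
    pathway_id: str
    source: str
    n_disorders_shared: int
    n_runs_shared: int
    is_biomarker_pathway_for_any: bool


def pathway_sharing(
    results_by_run: dict[str, list[EnrichmentResult]],
    run_disorders: dict[str, str],
    panels: list[BiomarkerPanel],
    pathways: list[PathwayRecord],
) -> list[SharingRecord]:
    """Per pathway, the number of distinct disorders (and runs) in which
    it was significantly enriched, flagged if it is a biomarker pathway
    for any panel."""
    biomarker_ids: set[str] = set()
    for panel in panels:
        biomarker_ids |= biomarker_pathways(panel, pathways)

    disorders: dict[tuple[str, str], set[str]] = {}
    runs: dict[tuple[str, str], set[str]] = {}
    for run_id, results in results_by_run.items():
        for r in results:
            if not r.significant:
                continue
            key = (r.pathway_id, r.source.value)
            disorders.setdefault(key, set()).add(run_disorders[run_id])
            runs.setdefault(key, set()).add(run_id)

    records = [
        SharingRecord(
            pathway_id=pid,
            source=src,
            n_disorders_shared=len(disorders[(pid, src)]),
            n_runs_shared=len(runs[(pid, src)]),
            is_biomarker_pathway_for_any=pid in biomarker_ids,
        )
        for pid, src in sorted(disorders)
    ]
    return records


def specificity_test(records: list[SharingRecord]) -> float:
    """Two-sided Wilcoxon rank-sum p comparing disorder-sharing counts of
    biomarker vs non-biomarker pathways (exact for small untied samples,
    tie-corrected normal approximation otherwise)."""
    bio = [r.n_disorders_shared for r in records if r.is_biomarker_pathway_for_any]
    other = [r.n_disorders_shared for r in records if not r.is_biomarker_pathway_for_any]
    if not bio or not other:
        raise ValueError("need both biomarker and non-biomarker pathways")
    return float(stats.mannwhitneyu(bio, other, alternative="two-sided", method="auto").pvalue)


def novel_biomarker_candidates(
    results: list[EnrichmentResult],
    panel: BiomarkerPanel,
    pathways: list[PathwayRecord],
    annotations: list[Annotation] | None = None,
) -> pd.DataFrame:
    """Candidate novel biomarkers from one run's enriched biomarker
    pathways.

    For each significant pathway containing a known panel biomarker, the
    candidates are its aberrant member metabolites minus the known
    biomarkers.  Columns: pathway_id, source, metabolite_id,
    rt_inconsistent (True when every annotation supporting the metabolite
    on this run is RT-implausible).
    """
    bio_pw = biomarker_pathways(panel, pathways)
    rt_bad: dict[str, bool] = {}
    if annotations:
        for a in annotations:
            prev = rt_bad.get(a.metabolite_id, True)
            rt_bad[a.metabolite_id] = prev and (a.rt_status is RtStatus.inconsistent)
    rows = []
    for r in results:
        if not r.significant or r.pathway_id not in bio_pw:
            continue
        for mid in sorted(r.aberrant_metabolite_ids - panel.biomarker_metabolite_ids):
            rows.append((r.pathway_id, r.source.value, mid, rt_bad.get(mid, False)))
    return pd.DataFrame(rows, columns=["pathway_id", "source", "metabolite_id", "rt_inconsistent"])
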