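"""Biomarker rank metrics: how early do known biomarkers surface?

The ranking universe is the run's set of aberrant feature-metabolite
pairs: one entry per distinct (feature, metabolite) annotation of an
aberrant feature, deduplicated across adduct routes.  Ranks are reported
as 1-based row indices; rank 1 means first of the list.

Three feature-level orderings are compared:

* ``feature_rank`` -- pairs sorted by patient intensity, descending.
* ``pathway_sorted_rank`` -- enriched pathways (or clusters) sorted by
  ascending enrichment p, each expanded into its aberrant pairs sorted by
  intensity; a pair's first occurrence defines its rank.  Its universe is
  the set of pathway-associated pairs, a subset of the full pair list.
* ``pathway_biomarker_rank`` -- the 1-based position of the best
  biomarker-containing pathway (or cluster) in the p-sorted list.

A biomarker's rank is the minimum over the pairs annotating it; a
biomarker with no aberrant associated pair has no rank and is reported as
absent.  Significance of observed median ranks against a
uniform-placement null is assessed by permutation, and the choice of
intensity as the within-pathway ordering score can be checked with
ROC AUCs of intensity, absolute fold change and feature p-value as
binary classifiers of biomarker status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .aberrant_detection import AberrantCall
from .annotation import Annotation
from .clustering import PathwayCluster
from .feature_io import SampleRun
from .msea_core import EnrichmentResult
from .reference_db import BiomarkerPanel

__all__ = [
    "RankReport",
    "build_aberrant_pairs",
    "feature_rank",
    "pathway_sorted_rank",
    "pathway_biomarker_rank",
    "rank_permutation_test",
    "score_roc",
]


def build_aberrant_pairs(
    run: SampleRun, calls: list[AberrantCall], annotations: list[Annotation]
) -> pd.DataFrame:
    """Aberrant feature-metabolite pairs with the scores ranking needs.

    Columns: feature_id, metabolite_id, intensity (patient), fold_change
    (patient / median control; +inf when the control median is 0), raw_p
    (feature-level).  One row per distinct (feature, metabolite).
    """
    aberrant = {c.feature_id: c for c in calls if c.is_aberrant}
    feats = {f.feature_id: f for f in run.features}
    rows = {}
    for a in annotations:
        if a.feature_id not in aberrant:
            continue
        key = (a.feature_id, a.metabolite_id)
        if key in rows:
            continue
        f = feats[a.feature_id]
        med = float(np.median(f.control_intensities))
        fold = f.patient_intensity / med if med > 0 else np.inf
        rows[key] = (
            a.feature_id,
            a.metabolite_id,
            f.patient_intensity,
            fold,
            aberrant[a.feature_id].raw_p,
        )
    df = pd.DataFrame(
        rows.values(),
        columns=["feature_id", "metabolite_id", "intensity", "fold_change", "raw_p"],
    )
    return df


def _intensity_sorted(pairs: pd.DataFrame) -> pd.DataFrame:
    # descending intensity; deterministic tie-break on ids
    return pairs.sort_values(
        ["intensity", "feature_id", "metabolite_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


@dataclass
class RankReport:
    """Per-biomarker ranks for one run.

    ``ranks`` maps biomarker metabolite id -> 1-based rank; biomarkers
    without an aberrant associated pair are listed in ``unranked``.
    """

    ranks: dict[str, int] = field(default_factory=dict)
    unranked: tuple[str, ...] = ()
    universe_size: int = 0

    @property
    def best(self) -> int | None:
        return min(self.ranks.values()) if self.ranks else None


def feature_rank(pairs: pd.DataFrame, panel: BiomarkerPanel) -> RankReport:
    """Biomarker ranks in the intensity-sorted aberrant pair list."""
    ordered = _intensity_sorted(pairs)
    ranks: dict[str, int] = {}
    for pos, mid in enumerate(ordered["metabolite_id"], start=1):
        if mid in panel.biomarker_metabolite_ids and mid not in ranks:
            ranks[mid] = pos
    unranked = tuple(sorted(panel.biomarker_metabolite_ids - ranks.keys()))
    return RankReport(ranks=ranks, unranked=unranked, universe_size=len(ordered))


def _item_pairs(item, pairs: pd.DataFrame) -> pd.DataFrame:
    if isinstance(item, PathwayCluster):
        feats, mets = item.aberrant_feature_union, item.aberrant_metabolite_union
    else:
        feats, mets = item.aberrant_feature_ids, item.aberrant_metabolite_ids
    mask = pairs["feature_id"].isin(feats) & pairs["metabolite_id"].isin(mets)
    return pairs[mask]


def _sorted_items(items):
    def key(it):
        if isinstance(it, PathwayCluster):
            return (it.cluster_p, it.representative_pathway_id)
        return (it.raw_p, it.pathway_id)

    return sorted(items, key=key)


def pathway_sorted_rank(
    pairs: pd.DataFrame,
    items: list[EnrichmentResult] | list[PathwayCluster],
    panel: BiomarkerPanel,
) -> RankReport:
    """Biomarker ranks after sorting pairs by enrichment p then intensity.

    ``items`` are enriched pathways or pathway clusters; each, in
    ascending-p order, is expanded into its aberrant pairs sorted by
    descending intensity, and the concatenated list (first occurrence
    wins) is ranked.
    """
    seen: set[tuple[str, str]] = set()
    order: list[tuple[str, str]] = []
    for item in _sorted_items(items):
        expanded = _intensity_sorted(_item_pairs(item, pairs))
        for f, m in zip(expanded["feature_id"], expanded["metabolite_id"]):
            if (f, m) not in seen:
                seen.add((f, m))
                order.append((f, m))
    ranks: dict[str, int] = {}
    for pos, (_, mid) in enumerate(order, start=1):
        if mid in panel.biomarker_metabolite_ids and mid not in ranks:
            ranks[mid] = pos
    unranked = tuple(sorted(panel.biomarker_metabolite_ids - ranks.keys()))
    return RankReport(ranks=ranks, unranked=unranked, universe_size=len(order))


def pathway_biomarker_rank(
    items: list[EnrichmentResult] | list[PathwayCluster],
    panel: BiomarkerPanel,
    pathway_members: dict[str, frozenset[str]],
) -> int | None:
    """1-based position of the first biomarker-containing pathway/cluster
    in the p-sorted list, or None if no item contains a biomarker.

    Containment means pathway membership of a panel biomarker id
    (``pathway_members`` maps pathway id -> member metabolite ids); a
    cluster contains a biomarker when any member pathway does.
    """
    ids = panel.biomarker_metabolite_ids
    for pos, item in enumerate(_sorted_items(items), start=1):
        if isinstance(item, PathwayCluster):
            pws = item.member_pathway_ids
        else:
            pws = {item.pathway_id}
        if any(ids & pathway_members.get(p, frozenset()) for p in pws):
            return pos
    return None


def rank_permutation_test(
    observed_ranks: list[int],
    universe_sizes: list[int],
    n_biomarker_pairs: list[int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p for the observed median best-biomarker rank.

    Null model: within each run, the run's biomarker pairs occupy
    positions drawn uniformly without replacement from its universe; the
    run's null rank is the minimum position, and the null statistic the
    median over runs.  p = (1 + #{null median <= observed median}) /
    (n_perm + 1).
    """
    if not (len(observed_ranks) == len(universe_sizes) == len(n_biomarker_pairs)):
        raise ValueError("per-run inputs must have equal lengths")
    rng = np.random.default_rng(seed)
    observed = float(np.median(observed_ranks))
    null_medians = np.empty(n_perm)
    mins = np.empty(len(observed_ranks))
    for b in range(n_perm):
        for i, (u, k) in enumerate(zip(universe_sizes, n_biomarker_pairs)):
            mins[i] = rng.choice(u, size=min(k, u), replace=False).min() + 1
        null_medians[b] = np.median(mins)
    return float((1 + np.sum(null_medians <= observed)) / (n_perm + 1))


def score_roc(pairs: pd.DataFrame, panel: BiomarkerPanel, score: str) -> float:
    """AUC of a ranking score as a classifier of biomarker pairs.

    score: "intensity" or "abs_fold_change" (higher = more
    biomarker-like) or "p_value" (lower = more biomarker-like).
    """
    labels = pairs["metabolite_id"].isin(panel.biomarker_metabolite_ids).to_numpy()
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both biomarker and non-biomarker pairs")
    if score == "intensity":
        values = pairs["intensity"].to_numpy(float)
    elif score == "abs_fold_change":
        fc = pairs["fold_change"].to_numpy(float)
        with np.errstate(divide="ignore"):
            values = np.abs(np.log2(fc))
        values[np.isnan(values)] = np.inf  # 0/0: treat as maximally deviant
    elif score == "p_value":
        values = -pairs["raw_p"].to_numpy(float)
    else:
        raise ValueError(f"unknown score {score!r}")
    # map infinities to finite extremes; AUC depends on order only
    finite = values[np.isfinite(values)]
    top = (finite.max() + 1) if finite.size else 1.0
    bot = (finite.min() - 1) if finite.size else -1.0
    values = np.nan_to_num(values, posinf=top, neginf=bot)
    return float(roc_auc_score(labels, values))
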