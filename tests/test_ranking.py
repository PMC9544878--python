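"""Biomarker rank metrics, permutation significance and score ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msea.ranking import (
    build_aberrant_pairs,
    feature_rank,
    pathway_biomarker_rank,
    pathway_sorted_rank,
    rank_permutation_test,
    score_roc,
)
from msea.reference_db import BiomarkerPanel

from ._oracles import auc_from_u


def _pairs(rows):
    return pd.DataFrame(rows, columns=["feature_id", "metabolite_id", "intensity",
                                       "fold_change", "raw_p"])


def test_feature_rank_min_rule():
    pairs = _pairs(
        [(f"f{i}", f"m{i}", 1000.0 - i, 2.0, 0.01) for i in range(10)]
    )
    panel = BiomarkerPanel("d", frozenset({"m0"}))
    assert feature_rank(pairs, panel).ranks == {"m0": 1}
    # biomarker annotated by two features at positions 4 and 9 -> rank 4
    pairs2 = pairs.copy()
    pairs2.loc[3, "metabolite_id"] = "bio"
    pairs2.loc[8, "metabolite_id"] = "bio"
    report = feature_rank(pairs2, BiomarkerPanel("d", frozenset({"bio"})))
    assert report.ranks == {"bio": 4}
    assert report.universe_size == 10


def test_unranked_biomarker_reported():
    pairs = _pairs([("f1", "m1", 10.0, 2.0, 0.01)])
    report = feature_rank(pairs, BiomarkerPanel("d", frozenset({"absent"})))
    assert report.ranks == {}
    assert report.unranked == ("absent",)
    assert report.best is None


def test_feature_rank_matches_sort_scan_oracle(spike_run, spike_result):
    spec, refs, run, truth = spike_run
    pairs = build_aberrant_pairs(run, spike_result.calls, spike_result.annotations)
    panel = refs.panel
    report = feature_rank(pairs, panel)
    ordered = sorted(
        pairs.itertuples(), key=lambda r: (-r.intensity, r.feature_id, r.metabolite_id)
    )
    expected = {}
    for pos, row in enumerate(ordered, start=1):
        if row.metabolite_id in panel.biomarker_metabolite_ids:
            expected.setdefault(row.metabolite_id, pos)
    assert report.ranks == expected


def test_pathway_sorted_rank_counting(demo, demo_result):
    """First pathways expand to 5+4 pairs, then the biomarker pathway's
    three pairs follow: ranks 10 (methionine-like) and 12 (sulphoxide)."""
    pairs = build_aberrant_pairs(demo.run, demo_result.calls, demo_result.annotations)
    report = pathway_sorted_rank(pairs, demo_result.significant, demo.panel)
    assert report.ranks == {"C00073": 10, "C02989": 12}
    assert report.universe_size == 26
    # universe never exceeds the feature-rank universe
    assert report.universe_size <= feature_rank(pairs, demo.panel).universe_size


def test_pathway_biomarker_rank_positions(demo, demo_result):
    members = {p.pathway_id: p.member_metabolite_ids for p in demo.pathways}
    assert pathway_biomarker_rank(demo_result.significant, demo.panel, members) == 6
    assert pathway_biomarker_rank(demo_result.clusters, demo.panel, members) == 3
    no_panel = BiomarkerPanel("d", frozenset({"unseen"}))
    assert pathway_biomarker_rank(demo_result.significant, no_panel, members) is None


def test_permutation_floor_for_perfect_ranks():
    n_runs = 20
    p = rank_permutation_test([1] * n_runs, [1000] * n_runs, [1] * n_runs,
                              n_perm=999, seed=1)
    assert p == pytest.approx(1 / 1000)


def test_permutation_self_consistency():
    """Observed ranks drawn from the null itself give p centred on 0.5."""
    rng = np.random.default_rng(9)
    ps = []
    for rep in range(20):
        observed = [int(rng.integers(1, 201)) for _ in range(9)]
        ps.append(
            rank_permutation_test(observed, [200] * 9, [1] * 9, n_perm=400, seed=rep)
        )
    assert 0.25 < np.mean(ps) < 0.75


def test_permutation_matches_exact_enumeration():
    """Single run, universe 10, one biomarker pair: null min-rank is
    uniform on 1..10, so P(rank <= r) = r/10 exactly."""
    for observed in (1, 3, 7):
        p = rank_permutation_test([observed], [10], [1], n_perm=20000, seed=4)
        exact = observed / 10
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(p - exact) < 4 * se + 1e-4


def test_roc_extremes():
    pairs = _pairs(
        [(f"f{i}", "bio" if i < 5 else f"m{i}", 100.0 - i, 2.0, 0.01) for i in range(20)]
    )
    panel = BiomarkerPanel("d", frozenset({"bio"}))
    assert score_roc(pairs, panel, "intensity") == pytest.approx(1.0)
    const = pairs.assign(intensity=1.0)
    assert score_roc(const, panel, "intensity") == pytest.approx(0.5)


def test_roc_matches_u_statistic_oracle():
    rng = np.random.default_rng(31)
    rows = []
    for i in range(50):
        is_bio = i < 12
        rows.append(
            (f"f{i}", "bio" if is_bio else f"m{i}",
             float(rng.lognormal(10 + is_bio, 1)),
             float(rng.lognormal(is_bio * 1.0, 0.5)),
             float(rng.uniform(0, 0.05)))
        )
    pairs = _pairs(rows)
    panel = BiomarkerPanel("d", frozenset({"bio"}))
    labels = [m == "bio" for m in pairs["metabolite_id"]]
    assert score_roc(pairs, panel, "intensity") == pytest.approx(
        auc_from_u(labels, list(pairs["intensity"]))
    )
    assert score_roc(pairs, panel, "p_value") == pytest.approx(
        auc_from_u(labels, list(-pairs["raw_p"]))
    )
    assert score_roc(pairs, panel, "abs_fold_change") == pytest.approx(
        auc_from_u(labels, list(np.abs(np.log2(pairs["fold_change"]))))
    )


def test_pathway_sorting_beats_intensity_with_confounders():
    """Spike-in plus high-intensity non-pathway confounders: the
    pathway-sorted biomarker rank improves on the intensity-only rank
    (median over seeds)."""
    from msea.synthetic_data import simulate_reference, simulate_run, spike_in_spec
    from msea.workflow import run_pipeline

    feature_ranks, pathway_ranks = [], []
    for seed in range(15):
        spec = spike_in_spec(seed=seed, n_confounders=30)
        refs = simulate_reference(spec)
        run, _ = simulate_run(spec, refs)
        res = run_pipeline(run, refs.metabolites, refs.pathways)
        pairs = build_aberrant_pairs(run, res.calls, res.annotations)
        fr = feature_rank(pairs, refs.panel).best
        pr = pathway_sorted_rank(pairs, res.significant, refs.panel).best
        if fr is not None and pr is not None:
            feature_ranks.append(fr)
            pathway_ranks.append(pr)
    assert len(feature_ranks) >= 12
    assert np.median(pathway_ranks) <= np.median(feature_ranks)
    # Wilcoxon signed-rank confirms the direction on paired ranks
    if np.any(np.array(feature_ranks) != np.array(pathway_ranks)):
        w = stats.wilcoxon(pathway_ranks, feature_ranks, alternative="less")
        assert w.pvalue < 0.1
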