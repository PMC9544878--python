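"""One-sided Fisher enrichment, Holm correction and run-level MSEA."""

import dataclasses

import numpy as np
import pytest

from msea.msea_core import (
    ContingencyCounts,
    fisher_one_sided,
    holm_adjust,
    run_msea,
)
from msea.annotation import annotate_run, map_to_pathways
from msea.aberrant_detection import call_aberrant
from msea.reference_db import MetaboliteIndex, PathwayRecord, PathwaySource
from msea.synthetic_data import simulate_reference, simulate_run, spike_in_spec
from msea.workflow import run_pipeline

from ._oracles import fisher_tail_exact, holm_step_down


@pytest.mark.parametrize(
    "table, expected",
    [
        ((0, 7, 3, 11), 1.0),  # X >= 0 is certain
        ((1, 0, 0, 1), 0.5),   # two equiprobable tables
        # exact-rational tail sum computed independently
        ((5, 5, 95, 9895), 2.1901617709704862e-08),
    ],
)
def test_fisher_examples(table, expected):
    assert fisher_one_sided(ContingencyCounts(*table)) == pytest.approx(expected, rel=1e-9)


def test_fisher_matches_exact_oracle_on_random_tables():
    rng = np.random.default_rng(21)
    for _ in range(300):
        a, b, c, d = rng.integers(0, 40, size=4)
        got = fisher_one_sided(ContingencyCounts(int(a), int(b), int(c), int(d)))
        assert got == pytest.approx(float(fisher_tail_exact(a, b, c, d)), rel=1e-10)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyCounts(-1, 0, 0, 0)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ([0.001, 0.02, 0.04], [0.003, 0.04, 0.04]),
        ([0.5], [0.5]),
    ],
)
def test_holm_small_examples(raw, expected):
    assert holm_adjust(raw) == pytest.approx(expected)


def test_holm_matches_textbook_oracle_elementwise():
    rng = np.random.default_rng(11)
    p = rng.uniform(0, 1, size=100)
    assert holm_adjust(p) == pytest.approx(holm_step_down(list(p)), abs=1e-12)
    with pytest.raises(ValueError):
        holm_adjust([1.5])


def test_holm_monotone_and_dominates_raw():
    rng = np.random.default_rng(3)
    p = rng.uniform(0, 1, size=40)
    adj = holm_adjust(p)
    assert np.all(adj >= p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_no_aberrant_features_yields_empty_result(demo):
    """A run whose patient tracks the controls has no enrichment."""
    from msea.feature_io import SampleRun

    quiet = SampleRun(
        "quiet", [f for f in demo.run.features if f.patient_intensity <= 200.0]
    )
    res = run_pipeline(quiet, demo.metabolites, demo.pathways)
    assert res.enrichment == []


def test_spiked_pathway_recovered(spike_result):
    sig = spike_result.significant
    assert any(r.pathway_id == "SMP00001" for r in sig)
    top = sig[0]
    assert top.pathway_id == "SMP00001"
    assert top.counts.a >= 14  # 15 perturbed members, near-complete detection
    assert top.counts.total == len(spike_result.run)


def test_pathways_with_single_aberrant_association_not_tested(demo):
    """A pathway with exactly one aberrant feature is absent from output
    and from the Holm family."""
    # add a singleton pathway holding one aberrant metabolite only
    extra = PathwayRecord("hsa09901", "singleton", PathwaySource.KEGG,
                          "Metabolism", frozenset({"C10020"}))
    res = run_pipeline(demo.run, demo.metabolites, demo.pathways + [extra])
    ids = [r.pathway_id for r in res.enrichment]
    assert "hsa09901" not in ids
    assert len(ids) == 27  # family unchanged
    base = run_pipeline(demo.run, demo.metabolites, demo.pathways)
    assert [r.holm_p for r in res.enrichment] == [r.holm_p for r in base.enrichment]


def test_removing_decoy_pathway_changes_only_holm(demo):
    """Dropping one tested pathway leaves others' raw p intact and only
    rescales their Holm-adjusted values."""
    res_all = run_pipeline(demo.run, demo.metabolites, demo.pathways)
    keep = [p for p in demo.pathways if p.pathway_id != "hsa01101"]
    res_less = run_pipeline(demo.run, demo.metabolites, keep)
    raw_all = {r.pathway_id: r.raw_p for r in res_all.enrichment if r.pathway_id != "hsa01101"}
    raw_less = {r.pathway_id: r.raw_p for r in res_less.enrichment}
    assert raw_less == raw_all
    holm_all = {r.pathway_id: r.holm_p for r in res_all.enrichment}
    holm_less = {r.pathway_id: r.holm_p for r in res_less.enrichment}
    assert all(holm_less[k] <= holm_all[k] + 1e-15 for k in holm_less)


def test_counts_are_feature_level(demo, demo_result):
    """A feature annotated to two members of one pathway counts once."""
    for r in demo_result.enrichment:
        members = next(p for p in demo.pathways if p.pathway_id == r.pathway_id)
        assert r.counts.a == len(r.aberrant_feature_ids)
        assert r.aberrant_metabolite_ids <= members.member_metabolite_ids


def test_type_one_error_rate_under_null():
    """No spiked pathway: the share of 200 null runs with any significant
    pathway stays below 0.05 + 2 SE."""
    hits = 0
    n_runs = 200
    for seed in range(n_runs):
        # smaller universe keeps the loop fast; geometry unchanged
        spec = dataclasses.replace(
            spike_in_spec(seed=seed, spiked=False),
            n_metabolites=120, n_features_decoy=200, n_pathways=4,
        )
        refs = simulate_reference(spec)
        run, _ = simulate_run(spec, refs)
        calls = call_aberrant(run)
        anns = annotate_run(run, MetaboliteIndex(refs.metabolites))
        assoc = map_to_pathways(anns, refs.pathways)
        results = run_msea(calls, assoc, refs.pathways, anns)
        hits += any(r.significant for r in results)
    rate = hits / n_runs
    se = np.sqrt(0.05 * 0.95 / n_runs)
    assert rate <= 0.05 + 2 * se
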