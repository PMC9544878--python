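"""Adduct correction, ppm matching and pathway mapping."""

import numpy as np
import pytest

from msea.annotation import (
    AdductLabel,
    annotate_run,
    map_to_pathways,
    match_metabolites,
    neutral_masses,
    RtStatus,
)
from msea.feature_io import Feature, IonMode, SampleRun
from msea.reference_db import (
    MetaboliteIndex,
    MetaboliteRecord,
    PathwayRecord,
    PathwaySource,
    Source,
)
from msea.synthetic_data import SimulationSpec, simulate_reference, simulate_run


def test_proton_mz_yields_no_candidates():
    # a bare proton: M+H neutral mass 0 (dropped), M+Na negative (dropped)
    assert neutral_masses(1.007276, IonMode.positive) == []


@pytest.mark.parametrize(
    "mz, mode, adduct, neutral",
    [
        # glucose [M+H]+ and methionine [M-H]-, masses from an independent
        # monoisotopic-mass calculation
        (181.070664, IonMode.positive, AdductLabel.M_plus_H, 180.063388),
        (148.043773, IonMode.negative, AdductLabel.M_minus_H, 149.051049),
    ],
)
def test_neutral_mass_recovers_known_compounds(mz, mode, adduct, neutral):
    by_label = dict(neutral_masses(mz, mode))
    assert by_label[adduct] == pytest.approx(neutral, abs=1e-9)


def test_mode_compatibility():
    pos = {label for label, _ in neutral_masses(500.0, IonMode.positive)}
    neg = {label for label, _ in neutral_masses(500.0, IonMode.negative)}
    assert pos == {AdductLabel.M_plus_H, AdductLabel.M_plus_Na}
    assert neg == {AdductLabel.M_minus_H, AdductLabel.M_plus_Cl}


@pytest.fixture(scope="module")
def met_index():
    return MetaboliteIndex(
        [MetaboliteRecord("C00073", "methionine-like", 149.051049, Source.KEGG)]
    )


@pytest.mark.parametrize(
    "observed, expect_hit, expect_ppm",
    [
        (149.051500, True, 3.0258),  # ~3.0 ppm, inside tolerance
        (149.052100, False, None),   # ~7.1 ppm, outside
        (149.051049, True, 0.0),     # exact
    ],
)
def test_ppm_window(met_index, observed, expect_hit, expect_ppm):
    hits = match_metabolites(observed, met_index, tol_ppm=5)
    assert bool(hits) == expect_hit
    if expect_hit:
        assert hits[0][2] == pytest.approx(expect_ppm, abs=1e-3)


def test_matching_boundary_uses_database_mass_denominator():
    """Against 1000 random (mass, offset) pairs, membership agrees with
    the direct ratio computed from the database mass."""
    rng = np.random.default_rng(99)
    for _ in range(1000):
        mass = rng.uniform(50, 1000)
        ppm_true = rng.uniform(-8, 8)
        observed = mass * (1 + ppm_true * 1e-6)
        idx = MetaboliteIndex([MetaboliteRecord("M", "m", mass, Source.HMDB)])
        hit = bool(match_metabolites(observed, idx, tol_ppm=5))
        assert hit == (abs(observed - mass) / mass * 1e6 <= 5)


def test_annotation_count_monotone_in_tolerance():
    rng = np.random.default_rng(4)
    masses = np.sort(rng.uniform(200, 200.02, size=50))  # dense deliberate collisions
    idx = MetaboliteIndex(
        [MetaboliteRecord(f"M{i}", "m", float(m), Source.HMDB) for i, m in enumerate(masses)]
    )
    observed = 200.01
    counts = [len(match_metabolites(observed, idx, tol_ppm=t)) for t in (1, 5, 20, 50)]
    assert counts == sorted(counts)


def test_generator_round_trip_recovers_every_metabolite():
    """Zero mass error: each feature's generating metabolite is among its
    annotations at ~0 ppm."""
    spec = SimulationSpec(n_metabolites=120, n_pathways=4, n_features_decoy=50,
                          mass_error_sd_ppm=0.0, seed=8)
    refs = simulate_reference(spec)
    run, truth = simulate_run(spec, refs)
    anns = annotate_run(run, MetaboliteIndex(refs.metabolites))
    by_feature = {}
    for a in anns:
        by_feature.setdefault(a.feature_id, {})[a.metabolite_id] = a
    for _, row in truth.iterrows():
        if not row.metabolite_id:
            assert row.feature_id not in by_feature  # decoys stay unannotated
            continue
        ann = by_feature[row.feature_id][row.metabolite_id]
        assert abs(ann.ppm_error) < 1e-6


def test_rt_inconsistent_annotation_kept_but_flagged():
    rec = MetaboliteRecord("C1", "m", 149.051049, Source.KEGG, known_rt=1.0)
    idx = MetaboliteIndex([rec])
    run = SampleRun(
        "s",
        [Feature("f1", 150.058325, 1.5, IonMode.positive, 10.0, (1.0, 1.0))],
    )
    anns = annotate_run(run, idx)
    assert len(anns) == 1
    assert anns[0].rt_status is RtStatus.inconsistent
    # within 0.1 min -> consistent
    run2 = SampleRun(
        "s", [Feature("f1", 150.058325, 1.05, IonMode.positive, 10.0, (1.0, 1.0))]
    )
    assert annotate_run(run2, idx)[0].rt_status is RtStatus.consistent


def _random_assoc_fixture(seed):
    rng = np.random.default_rng(seed)
    mets = [MetaboliteRecord(f"HMDB{i:07d}", "m", 100.0 + i, Source.HMDB) for i in range(20)]
    idx = MetaboliteIndex(mets)
    feats = [
        Feature(f"f{i}", mets[rng.integers(20)].monoisotopic_mass + 1.007276,
                1.0, IonMode.positive, 10.0, (1.0, 1.0))
        for i in range(30)
    ]
    run = SampleRun("s", feats)
    pathways = [
        PathwayRecord(
            f"P{j}", "p", PathwaySource.SMPDB, "Metabolic",
            frozenset(rng.choice([m.metabolite_id for m in mets],
                                 size=rng.integers(1, 8), replace=False)),
        )
        for j in range(10)
    ]
    return run, idx, pathways


def test_map_to_pathways_matches_triple_loop_oracle():
    run, idx, pathways = _random_assoc_fixture(12)
    anns = annotate_run(run, idx)
    df = map_to_pathways(anns, pathways)
    got = {(r.feature_id, r.pathway_id) for r in df.itertuples()}
    expected = set()
    for a in anns:
        for p in pathways:
            if a.metabolite_id in p.member_metabolite_ids:
                expected.add((a.feature_id, p.pathway_id))
    assert got == expected
    # binary per (feature, pathway): no duplicates by construction
    assert len(df) == len(got)
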