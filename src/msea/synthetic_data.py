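"""Ground-truth-labelled synthetic cohorts.

Real screening data of this kind is not publicly shareable, so every
stage of the workflow is exercised against a generator that emulates its
structure: a metabolite reference with well-separated monoisotopic masses
(HMDB-style and KEGG-style entries), pathways drawing members from one
source each, a biomarker panel, and per-run feature tables where each
metabolite emits a feature through a sampled electrospray adduct with
Gaussian relative mass error, control intensities are log-normal
(multiplicative MS noise) and the patient sample is an independent draw
times a chosen fold change for the perturbed metabolites.

Unannotatable decoy features (random masses kept clear of every
reference metabolite) pad the background universe, and optional
"confounder" features -- annotated, high-intensity, perturbed, but
attached to metabolites outside every pathway -- emulate diet/medication
signals that dominate intensity-sorted lists without enriching pathways.

Everything is driven by one integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ADDUCTS, AdductLabel
from .feature_io import Feature, IonMode, SampleRun, write_feature_table
from .reference_db import (
    BiomarkerPanel,
    MetaboliteRecord,
    PathwayRecord,
    PathwaySource,
    Source,
    write_biomarkers,
    write_metabolites,
    write_pathways,
)

__all__ = ["SpikeSpec", "SimulationSpec", "ReferenceSet", "simulate_reference",
           "simulate_run", "write_simulation", "spike_in_spec"]


@dataclass(frozen=True)
class SpikeSpec:
    """One perturbed pathway: its first n members (sorted by id) get the
    given multiplicative fold change in the patient sample."""

    pathway_id: str
    n_members_perturbed: int
    fold_change: float

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValueError("fold_change must be positive")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic patient-vs-controls experiment.

    Defaults emulate a plausible single-batch screening run: ~10 batch
    controls, log-normal intensities spanning roughly e^9 to e^13
    arbitrary units with 10-40% multiplicative noise, reference masses in
    50-1000 Da spaced > 2x the 5 ppm annotation tolerance so annotation
    is unambiguous, and 1 ppm mass error on emitted features.
    """

    n_metabolites: int = 200
    fraction_kegg: float = 0.5
    n_pathways: int = 6
    pathway_size_range: tuple[int, int] = (10, 20)
    pathway_overlap: float = 0.0  # fraction of members reused from the previous same-source pathway
    n_duplicate_pathways: int = 0  # pathways cloned with identical member sets
    n_features_decoy: int = 1500
    n_confounders: int = 0  # annotated high-intensity non-pathway perturbations
    confounder_fold: float = 50.0
    n_controls: int = 10
    control_log_mean_range: tuple[float, float] = (9.0, 13.0)  # ln(intensity)
    control_log_sd_range: tuple[float, float] = (0.1, 0.4)
    spiked_pathways: tuple[SpikeSpec, ...] = ()
    mass_error_sd_ppm: float = 1.0
    adduct_probabilities: dict[str, float] = field(
        default_factory=lambda: {"M+H": 0.4, "M-H": 0.4, "M+Na": 0.1, "M+Cl": 0.1}
    )
    mass_range: tuple[float, float] = (50.0, 1000.0)
    min_spacing_ppm: float = 12.0  # pairwise reference-mass spacing (> 2 x 5 ppm)
    rt_range: tuple[float, float] = (0.5, 12.0)
    n_biomarkers: int = 2
    disorder: str = "SIM_DISORDER"
    seed: int = 0


@dataclass(frozen=True)
class ReferenceSet:
    metabolites: list[MetaboliteRecord]
    pathways: list[PathwayRecord]
    panel: BiomarkerPanel


def _spaced_masses(rng: np.random.Generator, n: int, lo: float, hi: float,
                   spacing_ppm: float) -> np.ndarray:
    """n masses in [lo, hi] with pairwise relative spacing > spacing_ppm."""
    masses: list[float] = []
    rel = spacing_ppm * 1e-6
    for _ in range(200):
        cand = np.sort(rng.uniform(lo, hi, size=4 * n))
        masses = []
        last = -np.inf
        for m in cand:
            if m - last > rel * m:
                masses.append(m)
                last = m
            if len(masses) == n:
                break
        if len(masses) == n:
            break
    if len(masses) < n:
        raise ValueError("cannot place that many masses at the requested spacing")
    out = np.array(masses)
    rng.shuffle(out)
    return out


def simulate_reference(spec: SimulationSpec) -> ReferenceSet:
    """Metabolite table, pathway table and biomarker panel for a spec.

    Metabolites split between an HMDB-like and a KEGG-like source; each
    pathway samples members from one source without replacement, so with
    ``pathway_overlap`` 0 pathways are pairwise disjoint.  The biomarker
    panel holds the first ``n_biomarkers`` perturbed members of the first
    spiked pathway (or of the first pathway when nothing is spiked).
    """
    rng = np.random.default_rng([spec.seed, 0])
    n_kegg = int(round(spec.n_metabolites * spec.fraction_kegg))
    n_hmdb = spec.n_metabolites - n_kegg
    masses = _spaced_masses(rng, spec.n_metabolites, *spec.mass_range, spec.min_spacing_ppm)
    metabolites: list[MetaboliteRecord] = []
    for i in range(n_hmdb):
        metabolites.append(
            MetaboliteRecord(f"HMDB{i + 1:07d}", f"hmdb metabolite {i + 1}",
                             float(masses[i]), Source.HMDB)
        )
    for i in range(n_kegg):
        metabolites.append(
            MetaboliteRecord(f"C{i + 1:05d}", f"kegg compound {i + 1}",
                             float(masses[n_hmdb + i]), Source.KEGG)
        )

    by_source = {
        Source.HMDB: [m.metabolite_id for m in metabolites if m.source is Source.HMDB],
        Source.KEGG: [m.metabolite_id for m in metabolites if m.source is Source.KEGG],
    }
    available = {s: list(ids) for s, ids in by_source.items()}
    prev_members: dict[PathwaySource, list[str]] = {}
    pathways: list[PathwayRecord] = []
    for i in range(spec.n_pathways):
        psrc = PathwaySource.SMPDB if i % 2 == 0 else PathwaySource.KEGG
        msrc = Source.HMDB if psrc is PathwaySource.SMPDB else Source.KEGG
        size = int(rng.integers(spec.pathway_size_range[0], spec.pathway_size_range[1] + 1))
        n_shared = min(int(round(spec.pathway_overlap * size)),
                       len(prev_members.get(psrc, [])))
        members = list(rng.choice(prev_members[psrc], size=n_shared, replace=False)) if n_shared else []
        n_new = size - n_shared
        pool = available[msrc]
        if n_new > len(pool):
            raise ValueError("not enough metabolites to build disjoint pathways")
        idx = rng.choice(len(pool), size=n_new, replace=False)
        new = [pool[j] for j in sorted(idx)]
        for m in new:
            pool.remove(m)
        members += new
        pid = f"SMP{i + 1:05d}" if psrc is PathwaySource.SMPDB else f"hsa{i + 1:05d}"
        pathways.append(
            PathwayRecord(pid, f"simulated pathway {i + 1}", psrc,
                          "Metabolic" if psrc is PathwaySource.SMPDB else "Metabolism",
                          frozenset(members))
        )
        prev_members[psrc] = members
    for k in range(spec.n_duplicate_pathways):
        src_pw = pathways[k % len(pathways)]
        suffix = "X" if src_pw.source is PathwaySource.SMPDB else "x"
        pathways.append(
            PathwayRecord(f"{src_pw.pathway_id}{suffix}", src_pw.name + " (duplicate)",
                          src_pw.source, src_pw.category, src_pw.member_metabolite_ids)
        )

    by_id = {p.pathway_id: p for p in pathways}
    for spike in spec.spiked_pathways:
        if spike.pathway_id not in by_id:
            raise ValueError(f"spiked pathway {spike.pathway_id!r} does not exist")
        if spike.n_members_perturbed > len(by_id[spike.pathway_id].member_metabolite_ids):
            raise ValueError(
                f"cannot perturb {spike.n_members_perturbed} members of "
                f"{spike.pathway_id!r}: pathway has only "
                f"{len(by_id[spike.pathway_id].member_metabolite_ids)}"
            )

    panel_source = (
        by_id[spec.spiked_pathways[0].pathway_id]
        if spec.spiked_pathways
        else pathways[0]
    )
    if spec.spiked_pathways:
        perturbed = sorted(panel_source.member_metabolite_ids)[: spec.spiked_pathways[0].n_members_perturbed]
    else:
        perturbed = sorted(panel_source.member_metabolite_ids)
    panel = BiomarkerPanel(
        disorder=spec.disorder,
        biomarker_metabolite_ids=frozenset(perturbed[: spec.n_biomarkers]),
    )
    return ReferenceSet(metabolites, pathways, panel)


def perturbed_metabolites(spec: SimulationSpec, refs: ReferenceSet) -> dict[str, float]:
    """Metabolite id -> fold change for every spiked pathway member."""
    by_id = {p.pathway_id: p for p in refs.pathways}
    folds: dict[str, float] = {}
    for spike in spec.spiked_pathways:
        members = sorted(by_id[spike.pathway_id].member_metabolite_ids)
        if spike.n_members_perturbed > len(members):
            raise ValueError("cannot perturb more members than the pathway has")
        for mid in members[: spike.n_members_perturbed]:
            folds[mid] = spike.fold_change
    return folds


def simulate_run(spec: SimulationSpec, refs: ReferenceSet) -> tuple[SampleRun, pd.DataFrame]:
    """One patient-vs-controls feature table plus ground-truth labels.

    Every reference metabolite emits exactly one feature via a sampled
    adduct; m/z = mass*(1+eps) + adduct shift with eps ~ N(0, sd_ppm),
    so the observed neutral mass deviates from the reference by exactly
    eps.  Truth columns: feature_id, metabolite_id (empty for decoys),
    is_perturbed, fold_change.
    """
    rng = np.random.default_rng([spec.seed, 1])
    folds = perturbed_metabolites(spec, refs)
    pathway_members: set[str] = set()
    for p in refs.pathways:
        pathway_members |= p.member_metabolite_ids
    non_pathway = sorted(
        m.metabolite_id for m in refs.metabolites if m.metabolite_id not in pathway_members
    )
    if spec.n_confounders > len(non_pathway):
        raise ValueError("not enough non-pathway metabolites for the requested confounders")
    conf_ids = set(
        rng.choice(non_pathway, size=spec.n_confounders, replace=False)
    ) if spec.n_confounders else set()

    labels = list(spec.adduct_probabilities)
    probs = np.array([spec.adduct_probabilities[k] for k in labels], dtype=float)
    probs = probs / probs.sum()

    counters = {IonMode.positive: 0, IonMode.negative: 0}
    features: list[Feature] = []
    truth_rows: list[tuple[str, str, bool, float]] = []

    def emit(mz: float, fold: float, metabolite_id: str, mode: IonMode, high: bool) -> None:
        counters[mode] += 1
        fid = ("ESIpos_" if mode is IonMode.positive else "ESIneg_") + str(counters[mode])
        mu = (
            spec.control_log_mean_range[1]
            if high
            else rng.uniform(*spec.control_log_mean_range)
        )
        sigma = rng.uniform(*spec.control_log_sd_range)
        controls = tuple(rng.lognormal(mu, sigma, size=spec.n_controls))
        patient = rng.lognormal(mu, sigma) * fold
        features.append(
            Feature(fid, mz, float(rng.uniform(*spec.rt_range)), mode, patient, controls)
        )
        truth_rows.append((fid, metabolite_id, fold != 1.0, fold))

    sorted_mets = sorted(refs.metabolites, key=lambda m: m.metabolite_id)
    for met in sorted_mets:
        label = AdductLabel(labels[rng.choice(len(labels), p=probs)])
        adduct = ADDUCTS[label]
        eps = rng.normal(0.0, spec.mass_error_sd_ppm * 1e-6)
        mz = met.monoisotopic_mass * (1.0 + eps) + adduct.mass_shift
        high = met.metabolite_id in conf_ids
        fold = spec.confounder_fold if high else folds.get(met.metabolite_id, 1.0)
        emit(mz, fold, met.metabolite_id, adduct.ion_mode, high)

    # unannotatable decoys: every adduct interpretation of the decoy's m/z
    # must stay > 2x the reference-grid spacing away from every reference
    # mass, so decoys receive no annotation at the 5 ppm tolerance
    ref_masses = np.sort([m.monoisotopic_mass for m in refs.metabolites])

    def clear_of_references(neutral: float) -> bool:
        if neutral <= 0:
            return True
        j = int(np.searchsorted(ref_masses, neutral))
        near = [ref_masses[k] for k in (j - 1, j) if 0 <= k < len(ref_masses)]
        return all(abs(neutral - m) / m * 1e6 > 2 * spec.min_spacing_ppm for m in near)

    made = 0
    while made < spec.n_features_decoy:
        mass = rng.uniform(*spec.mass_range)
        label = AdductLabel(labels[rng.choice(len(labels), p=probs)])
        adduct = ADDUCTS[label]
        mz = mass + adduct.mass_shift
        alt_neutrals = [
            mz - a.mass_shift for a in ADDUCTS.values() if a.ion_mode is adduct.ion_mode
        ]
        if not all(clear_of_references(n) for n in alt_neutrals):
            continue
        emit(mz, 1.0, "", adduct.ion_mode, False)
        made += 1

    truth = pd.DataFrame(
        truth_rows, columns=["feature_id", "metabolite_id", "is_perturbed", "fold_change"]
    )
    run = SampleRun(
        sample_id=f"sim_{spec.seed}",
        features=features,
        batch_id="sim_batch",
        disorder=spec.disorder,
    )
    return run, truth


def write_simulation(spec: SimulationSpec, outdir) -> None:
    """Generate and write metabolites/pathways/biomarkers/features/truth
    TSVs into a directory."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = simulate_reference(spec)
    run, truth = simulate_run(spec, refs)
    write_metabolites(refs.metabolites, outdir / "metabolites.tsv")
    write_pathways(refs.pathways, outdir / "pathways.tsv")
    write_biomarkers([refs.panel], outdir / "biomarkers.tsv")
    write_feature_table(run, outdir / "features.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def spike_in_spec(
    seed: int,
    *,
    spiked: bool = True,
    fold_change: float = 20.0,
    n_confounders: int = 0,
) -> SimulationSpec:
    """The canonical spike-in design: six disjoint 20-member pathways,
    one (SMP00001) with 15 of 20 members perturbed at the given fold,
    1500 unannotatable decoys, 10 controls.  ``spiked=False`` keeps the
    same geometry with no perturbation (null runs)."""
    return SimulationSpec(
        n_metabolites=300,
        n_pathways=6,
        pathway_size_range=(20, 20),
        n_features_decoy=1500,
        n_confounders=n_confounders,
        spiked_pathways=(SpikeSpec("SMP00001", 15, fold_change),) if spiked else (),
        seed=seed,
    )
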