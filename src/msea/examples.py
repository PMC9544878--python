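"""A deterministic worked example with hand-computable structure.

``structured_demo`` builds a synthetic single-run dataset shaped like the
classic homocystinuria (CBS-deficiency) screening picture: a two-compound
biomarker panel (a methionine-like compound detected by two features, its
sulphoxide by one), 600 detected features of which 26 are aberrant, and a
KEGG-style pathway table engineered so the pipeline yields exactly

* 27 enriched pathways, all Holm-significant, of which 12 contain a
  panel biomarker;
* 11 pathway clusters under exact-overlap clustering, 3 of them
  biomarker clusters, with the best biomarker cluster (containing both
  biomarkers) at position 3 of the p-sorted cluster list;
* biomarker feature ranks 1 (methionine-like) and 9 (sulphoxide-like).

Every number is fixed by construction -- intensities, masses and member
sets are hard-coded -- so the example doubles as an end-to-end
regression fixture.  It is synthetic: no patient data is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

from .feature_io import Feature, IonMode, SampleRun
from .reference_db import (
    BiomarkerPanel,
    MetaboliteRecord,
    PathwayRecord,
    PathwaySource,
    Source,
)

__all__ = ["StructuredDemo", "structured_demo"]

_PROTON = 1.007276
_CONTROLS = (100.0, 101.0, 99.0, 102.0, 98.0, 100.0, 100.0, 101.0, 99.0, 100.0)

#: biomarker metabolite ids (methionine-like, methionine-sulphoxide-like)
MET = "C00073"
MSO = "C02989"


@dataclass
class StructuredDemo:
    run: SampleRun
    metabolites: list[MetaboliteRecord]
    pathways: list[PathwayRecord]
    panel: BiomarkerPanel


def _pathway_groups() -> list[tuple[str, list[str], frozenset[str]]]:
    """(cluster label, pathway ids, member/aberrant metabolite set)."""
    m = [f"C1{i:04d}" for i in range(1, 24)]  # C10001..C10023

    def ids(prefix: int, n: int) -> list[str]:
        return [f"hsa{prefix:03d}{k:02d}" for k in range(1, n + 1)]

    return [
        ("C1", ids(1, 3), frozenset({m[0], m[1], m[6], m[7], m[8]})),   # a=5
        ("C2", ids(2, 2), frozenset({m[2], m[3], m[9], m[10]})),        # a=4
        ("C3", ids(3, 5), frozenset({MET, MSO})),                       # a=3 (2+1 features)
        ("C4", ids(4, 4), frozenset({MET, m[4]})),                      # a=3
        ("C5", ids(5, 3), frozenset({MSO, m[5]})),                      # a=2
        ("C6", ids(6, 2), frozenset({m[11], m[12]})),
        ("C7", ids(7, 2), frozenset({m[13], m[14]})),
        ("C8", ids(8, 2), frozenset({m[15], m[16]})),
        ("C9", ids(9, 2), frozenset({m[17], m[18]})),
        ("C10", ids(10, 1), frozenset({m[19], m[20]})),
        ("C11", ids(11, 1), frozenset({m[21], m[22]})),
    ]


def structured_demo() -> StructuredDemo:
    masses = {MET: 149.051049, MSO: 165.045969}
    for i in range(1, 24):
        masses[f"C1{i:04d}"] = 200.0 + 5.0 * i
    metabolites = [
        MetaboliteRecord(mid, mid, mass, Source.KEGG) for mid, mass in sorted(masses.items())
    ]

    pathways = [
        PathwayRecord(pid, pid, PathwaySource.KEGG, "Metabolism", members)
        for _, pids, members in _pathway_groups()
        for pid in pids
    ]

    features: list[Feature] = []

    def add(fid: str, mode: IonMode, neutral: float, patient: float) -> None:
        shift = _PROTON if mode is IonMode.positive else -_PROTON
        features.append(Feature(fid, neutral + shift, 1.0, mode, patient, _CONTROLS))

    # biomarker features: methionine-like seen twice, sulphoxide once
    add("ESIpos_1", IonMode.positive, masses[MET], 1_000_000.0)
    add("ESIneg_2", IonMode.negative, masses[MET], 900_000.0)
    add("ESIpos_3", IonMode.positive, masses[MSO], 600_000.0)
    # the other 23 aberrant metabolites, one feature each; intensities
    # interleave so the sulphoxide feature lands at pair rank 9
    other_intensity = [950_000.0, 850_000.0, 800_000.0, 750_000.0, 700_000.0, 650_000.0] + [
        550_000.0 - 10_000.0 * k for k in range(17)
    ]
    for i in range(1, 24):
        add(f"ESIpos_{3 + i}", IonMode.positive, masses[f"C1{i:04d}"], other_intensity[i - 1])
    # 574 unannotatable, unremarkable decoys -> universe of 600 features
    for k in range(574):
        add(f"ESIpos_{27 + k}", IonMode.positive, 1200.0 + 0.5 * k, 100.0)

    run = SampleRun(sample_id="structured_demo", features=features, batch_id="demo")
    panel = BiomarkerPanel(disorder="CBS-like (demo)", biomarker_metabolite_ids=frozenset({MET, MSO}))
    return StructuredDemo(run=run, metabolites=metabolites, pathways=pathways, panel=panel)
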