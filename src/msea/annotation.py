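"""Putative metabolite annotation of features and mapping to pathways.

A feature's m/z is corrected for the four electrospray adducts handled by
the workflow -- [M+H]+ and [M+Na]+ in positive mode, [M-H]- and [M+Cl]- in
negative mode -- giving one candidate neutral mass per mode-compatible
adduct.  Each candidate is searched against the metabolite reference
(HMDB and KEGG entries together) tolerating at most ``tol_ppm`` (default
5 ppm) relative deviation, the tolerance being defined against the
database (theoretical) monoisotopic mass.  A feature often receives
multiple putative annotations; all are kept.

When the reference records a known retention time for a matched
metabolite, the annotation carries an RT plausibility status: consistent
if |dRT| <= 0.1 min, inconsistent otherwise, unknown when no reference RT
exists.  RT-inconsistent annotations are retained but flagged; callers may
exclude them from pathway mapping via ``drop_rt_inconsistent``.

Pathway mapping is binary per (feature, pathway): a feature is associated
with a pathway iff at least one of its annotated metabolite ids is a
member of that pathway (matching source database), regardless of how many
annotations or adduct routes support the link.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .feature_io import IonMode, SampleRun
from .reference_db import (
    PATHWAY_METABOLITE_SOURCE,
    MetaboliteIndex,
    PathwayRecord,
    Source,
)

__all__ = [
    "AdductLabel",
    "Adduct",
    "ADDUCTS",
    "RtStatus",
    "Annotation",
    "neutral_masses",
    "match_metabolites",
    "annotate_run",
    "map_to_pathways",
]

#: Maximum |RT(feature) - RT(reference)| in minutes for a known-RT
#: annotation to be called consistent.
RT_TOLERANCE_MIN = 0.1

DEFAULT_TOL_PPM = 5.0


class AdductLabel(str, enum.Enum):
    M_plus_H = "M+H"
    M_plus_Na = "M+Na"
    M_minus_H = "M-H"
    M_plus_Cl = "M+Cl"


@dataclass(frozen=True)
class Adduct:
    label: AdductLabel
    ion_mode: IonMode
    mass_shift: float  # Da; neutral mass = mz - mass_shift


#: Ion-mass conventions including the electron mass: proton 1.007276 Da,
#: Na+ 22.989218 Da, Cl- 34.969402 Da.
ADDUCTS: dict[AdductLabel, Adduct] = {
    AdductLabel.M_plus_H: Adduct(AdductLabel.M_plus_H, IonMode.positive, +1.007276),
    AdductLabel.M_plus_Na: Adduct(AdductLabel.M_plus_Na, IonMode.positive, +22.989218),
    AdductLabel.M_minus_H: Adduct(AdductLabel.M_minus_H, IonMode.negative, -1.007276),
    AdductLabel.M_plus_Cl: Adduct(AdductLabel.M_plus_Cl, IonMode.negative, +34.969402),
}


class RtStatus(str, enum.Enum):
    consistent = "consistent"
    inconsistent = "inconsistent"
    unknown = "unknown"


@dataclass(frozen=True)
class Annotation:
    feature_id: str
    metabolite_id: str
    source: Source
    adduct: AdductLabel
    neutral_mass_obs: float  # Da
    ppm_error: float  # signed, observed vs database mass
    rt_status: RtStatus


def neutral_masses(mz: float, ion_mode: IonMode) -> list[tuple[AdductLabel, float]]:
    """Candidate neutral masses for every adduct compatible with the ion
    mode; candidates with non-positive neutral mass are dropped."""
    if not mz > 0:
        raise ValueError("mz must be positive")
    out = []
    for adduct in ADDUCTS.values():
        if adduct.ion_mode is not ion_mode:
            continue
        neutral = mz - adduct.mass_shift
        if neutral > 0:
            out.append((adduct.label, neutral))
    return out


def match_metabolites(
    neutral_mass: float, db: MetaboliteIndex, tol_ppm: float = DEFAULT_TOL_PPM
) -> list[tuple[str, Source, float]]:
    """Reference metabolites within tol_ppm of an observed neutral mass.

    Returns (metabolite_id, source, signed ppm error) triples; the ppm
    denominator is the database mass.
    """
    hits = []
    for rec in db.query_mass(neutral_mass, tol_ppm):
        ppm = (neutral_mass - rec.monoisotopic_mass) / rec.monoisotopic_mass * 1e6
        hits.append((rec.metabolite_id, rec.source, ppm))
    return hits


def annotate_run(
    run: SampleRun, db: MetaboliteIndex, tol_ppm: float = DEFAULT_TOL_PPM
) -> list[Annotation]:
    """All putative annotations of a run: features x compatible adducts x
    database sources, each (feature, metabolite, adduct) at most once."""
    annotations: list[Annotation] = []
    for f in run.features:
        for adduct_label, neutral in neutral_masses(f.mz, f.ion_mode):
            for met_id, source, ppm in match_metabolites(neutral, db, tol_ppm):
                rec = db.get(source, met_id)
                if rec.known_rt is None:
                    rt_status = RtStatus.unknown
                elif abs(f.rt - rec.known_rt) <= RT_TOLERANCE_MIN:
                    rt_status = RtStatus.consistent
                else:
                    rt_status = RtStatus.inconsistent
                annotations.append(
                    Annotation(
                        feature_id=f.feature_id,
                        metabolite_id=met_id,
                        source=source,
                        adduct=adduct_label,
                        neutral_mass_obs=neutral,
                        ppm_error=ppm,
                        rt_status=rt_status,
                    )
                )
    return annotations


def map_to_pathways(
    annotations: list[Annotation],
    pathways: list[PathwayRecord],
    *,
    drop_rt_inconsistent: bool = False,
) -> pd.DataFrame:
    """Binary feature-to-pathway association table.

    Columns: feature_id, pathway_id, source (pathway source); one row per
    associated (feature, pathway) pair.  RT-inconsistent annotations are
    excluded when ``drop_rt_inconsistent`` is set.
    """
    used = [
        a
        for a in annotations
        if not (drop_rt_inconsistent and a.rt_status is RtStatus.inconsistent)
    ]
    # metabolite id -> feature ids, per metabolite source
    by_source: dict[Source, dict[str, set[str]]] = {}
    for a in used:
        by_source.setdefault(a.source, {}).setdefault(a.metabolite_id, set()).add(a.feature_id)
    rows: set[tuple[str, str, str]] = set()
    for p in pathways:
        met_source = PATHWAY_METABOLITE_SOURCE[p.source]
        met_map = by_source.get(met_source, {})
        for mid in p.member_metabolite_ids:
            for fid in met_map.get(mid, ()):
                rows.add((fid, p.pathway_id, p.source.value))
    df = pd.DataFrame(sorted(rows), columns=["feature_id", "pathway_id", "source"])
    return df
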