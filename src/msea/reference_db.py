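"""Metabolite, pathway and biomarker reference tables.

The enrichment workflow needs three reference inputs, modelled on the
tab-separated exports a lab would derive from HMDB/KEGG (metabolites) and
SMPDB/KEGG (pathways):

* ``metabolites.tsv`` -- one row per metabolite: id, name, monoisotopic
  neutral mass in Da, source database, optional known retention time
  (minutes) on the local LC system.
* ``pathways.tsv`` -- one row per pathway: id, name, source, free-text
  category, semicolon-joined member metabolite ids (same source).
* ``biomarkers.tsv`` -- one row per (disorder, biomarker name, metabolite
  id, source).  A biomarker compound may appear once per source database
  because HMDB and KEGG identifiers are not reliably cross-linked; no id
  cross-mapping is attempted.

Metabolite lookup by mass is served by :class:`MetaboliteIndex`, a
mass-sorted array searched with :func:`numpy.searchsorted`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Source",
    "PathwaySource",
    "MetaboliteRecord",
    "PathwayRecord",
    "BiomarkerPanel",
    "MetaboliteIndex",
    "load_metabolites",
    "load_pathways",
    "load_biomarkers",
    "write_metabolites",
    "write_pathways",
    "write_biomarkers",
    "biomarker_pathways",
]

METABOLITE_COLUMNS = ["metabolite_id", "name", "monoisotopic_mass", "source", "known_rt"]
PATHWAY_COLUMNS = ["pathway_id", "name", "source", "category", "member_metabolite_ids"]
BIOMARKER_COLUMNS = ["disorder", "biomarker_name", "metabolite_id", "source"]

#: Pathway categories given preference during cluster representative
#: selection, per source database.
PREFERRED_CATEGORY = {"SMPDB": "Metabolic", "KEGG": "Metabolism"}


class Source(str, enum.Enum):
    """Metabolite reference database."""

    HMDB = "HMDB"
    KEGG = "KEGG"


class PathwaySource(str, enum.Enum):
    """Pathway reference database.

    SMPDB pathways reference HMDB metabolite ids, KEGG pathways reference
    KEGG compound ids.
    """

    SMPDB = "SMPDB"
    KEGG = "KEGG"


#: Which metabolite source a pathway source draws its member ids from.
PATHWAY_METABOLITE_SOURCE = {
    PathwaySource.SMPDB: Source.HMDB,
    PathwaySource.KEGG: Source.KEGG,
}


@dataclass(frozen=True)
class MetaboliteRecord:
    metabolite_id: str
    name: str
    monoisotopic_mass: float  # Da, neutral
    source: Source
    known_rt: float | None = None  # minutes, on the local LC system

    def __post_init__(self) -> None:
        if not self.monoisotopic_mass > 0:
            raise ValueError(
                f"metabolite {self.metabolite_id!r}: monoisotopic mass must be "
                f"positive, got {self.monoisotopic_mass}"
            )


@dataclass(frozen=True)
class PathwayRecord:
    pathway_id: str
    name: str
    source: PathwaySource
    category: str
    member_metabolite_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_metabolite_ids:
            raise ValueError(f"pathway {self.pathway_id!r} has an empty member set")


@dataclass(frozen=True)
class BiomarkerPanel:
    """Known biomarker metabolites for one disorder.

    ``biomarker_metabolite_ids`` may hold one id per source database for the
    same compound (separate rows in biomarkers.tsv sharing a biomarker name).
    An empty panel must be flagged explicitly with ``allow_empty``.
    """

    disorder: str
    biomarker_metabolite_ids: frozenset[str] = field(default_factory=frozenset)
    allow_empty: bool = False

    def __post_init__(self) -> None:
        if not self.biomarker_metabolite_ids and not self.allow_empty:
            raise ValueError(
                f"panel for {self.disorder!r} is empty; pass allow_empty=True "
                "if intentional"
            )


class MetaboliteIndex:
    """Mass-sorted metabolite index for ppm-window queries.

    Records from several sources may be combined; queries return records of
    every source unless restricted.
    """

    def __init__(self, records: list[MetaboliteRecord]):
        self.records = sorted(records, key=lambda r: (r.monoisotopic_mass, r.source.value, r.metabolite_id))
        self._masses = np.array([r.monoisotopic_mass for r in self.records])
        self._by_id: dict[tuple[Source, str], MetaboliteRecord] = {}
        for r in records:
            key = (r.source, r.metabolite_id)
            if key in self._by_id:
                raise ValueError(
                    f"duplicate metabolite id {r.metabolite_id!r} in source {r.source.value}"
                )
            self._by_id[key] = r

    def __len__(self) -> int:
        return len(self.records)

    def get(self, source: Source, metabolite_id: str) -> MetaboliteRecord:
        return self._by_id[(source, metabolite_id)]

    def query_mass(self, neutral_mass: float, tol_ppm: float) -> list[MetaboliteRecord]:
        """All records whose reference mass m satisfies
        1e6*|neutral_mass - m|/m <= tol_ppm.

        The tolerance window is defined relative to the reference (database)
        mass, so the search interval on observed mass is
        [m*(1-tol), m*(1+tol)] inverted for m.
        """
        if neutral_mass <= 0 or not self.records:
            return []
        tol = tol_ppm * 1e-6
        lo = neutral_mass / (1.0 + tol)
        hi = neutral_mass / (1.0 - tol) if tol < 1 else math.inf
        i = int(np.searchsorted(self._masses, lo, side="left"))
        j = int(np.searchsorted(self._masses, hi, side="right"))
        return [
            r
            for r in self.records[i:j]
            if abs(neutral_mass - r.monoisotopic_mass) / r.monoisotopic_mass * 1e6 <= tol_ppm
        ]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def load_metabolites(path, source: Source | None = None) -> list[MetaboliteRecord]:
    """Load metabolites.tsv; optionally restrict to one source database.

    Raises on duplicate ids within a source and on non-positive masses,
    naming the offending row.
    """
    df = _read_tsv(path, METABOLITE_COLUMNS[:4])
    records: list[MetaboliteRecord] = []
    seen: set[tuple[str, str]] = set()
    dups: list[str] = []
    for i, row in df.iterrows():
        src = Source(row["source"])
        if source is not None and src != source:
            continue
        try:
            mass = float(row["monoisotopic_mass"])
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: unparseable mass {row['monoisotopic_mass']!r}") from exc
        if not mass > 0:
            raise ValueError(
                f"{path} row {i}: non-positive mass {mass} for {row['metabolite_id']!r}"
            )
        key = (row["source"], row["metabolite_id"])
        if key in seen:
            dups.append(row["metabolite_id"])
            continue
        seen.add(key)
        rt_raw = str(row.get("known_rt", "") or "").strip()
        records.append(
            MetaboliteRecord(
                metabolite_id=row["metabolite_id"],
                name=row["name"],
                monoisotopic_mass=mass,
                source=src,
                known_rt=float(rt_raw) if rt_raw else None,
            )
        )
    if dups:
        raise ValueError(f"{path}: duplicate metabolite ids within source: {sorted(set(dups))}")
    return records


def load_pathways(path, source: PathwaySource | None = None) -> list[PathwayRecord]:
    df = _read_tsv(path, PATHWAY_COLUMNS)
    records: list[PathwayRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        src = PathwaySource(row["source"])
        if source is not None and src != source:
            continue
        key = (row["source"], row["pathway_id"])
        if key in seen:
            raise ValueError(f"{path} row {i}: duplicate pathway id {row['pathway_id']!r}")
        seen.add(key)
        members = frozenset(m for m in row["member_metabolite_ids"].split(";") if m)
        records.append(
            PathwayRecord(
                pathway_id=row["pathway_id"],
                name=row["name"],
                source=src,
                category=row["category"],
                member_metabolite_ids=members,
            )
        )
    return records


def load_biomarkers(path) -> list[BiomarkerPanel]:
    """Load biomarkers.tsv into one panel per disorder.

    Rows sharing a disorder are pooled; a compound listed under both HMDB and
    KEGG contributes both ids to the panel set.
    """
    df = _read_tsv(path, BIOMARKER_COLUMNS)
    panels = []
    for disorder, grp in df.groupby("disorder", sort=True):
        ids = frozenset(x for x in grp["metabolite_id"] if x)
        panels.append(BiomarkerPanel(disorder=str(disorder), biomarker_metabolite_ids=ids, allow_empty=not ids))
    return panels


def write_metabolites(records: list[MetaboliteRecord], path) -> None:
    df = pd.DataFrame(
        {
            "metabolite_id": [r.metabolite_id for r in records],
            "name": [r.name for r in records],
            "monoisotopic_mass": [repr(float(r.monoisotopic_mass)) for r in records],
            "source": [r.source.value for r in records],
            "known_rt": ["" if r.known_rt is None else repr(float(r.known_rt)) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_pathways(records: list[PathwayRecord], path) -> None:
    df = pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in records],
            "name": [r.name for r in records],
            "source": [r.source.value for r in records],
            "category": [r.category for r in records],
            "member_metabolite_ids": [";".join(sorted(r.member_metabolite_ids)) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_biomarkers(panels: list[BiomarkerPanel], path, *, names: dict[str, str] | None = None) -> None:
    rows = []
    for p in panels:
        for mid in sorted(p.biomarker_metabolite_ids):
            name = (names or {}).get(mid, mid)
            src = "HMDB" if mid.startswith("HMDB") else "KEGG"
            rows.append((p.disorder, name, mid, src))
    pd.DataFrame(rows, columns=BIOMARKER_COLUMNS).to_csv(path, sep="\t", index=False)


def biomarker_pathways(panel: BiomarkerPanel, pathways: list[PathwayRecord]) -> set[str]:
    """Pathways containing at least one of the panel's biomarker metabolites.

    A disorder with no such pathway simply yields the empty set; several
    disorders in the original screening context have no biomarker pathway in
    either database.
    """
    ids = panel.biomarker_metabolite_ids
    return {p.pathway_id for p in pathways if ids & p.member_metabolite_ids}
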