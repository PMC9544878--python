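"""Aligned LC-MS feature tables: one patient against its batch controls.

A feature table (``features.tsv``) is the unit of analysis: one row per
aligned feature with its m/z, retention time, ion mode, the patient
intensity and the intensities of the ~10 control samples run in the same
analytical batch.  Positive- and negative-mode features live in the same
table, distinguished by the ``ion_mode`` column.

Technical injection duplicates are assumed to be merged (or analysed as
separate runs) upstream; one table equals one patient-vs-controls
comparison.  Zero intensities are kept as observed values; no imputation
is performed.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["IonMode", "Feature", "SampleRun", "read_feature_table", "write_feature_table"]


class IonMode(str, enum.Enum):
    positive = "positive"
    negative = "negative"


@dataclass(frozen=True)
class Feature:
    feature_id: str
    mz: float  # Th
    rt: float  # minutes
    ion_mode: IonMode
    patient_intensity: float
    control_intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"feature {self.feature_id!r}: mz must be positive")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id!r}: negative retention time")
        if len(self.control_intensities) < 2:
            raise ValueError(f"feature {self.feature_id!r}: need >=2 control intensities")


@dataclass
class SampleRun:
    sample_id: str
    features: list[Feature]
    batch_id: str = ""
    disorder: str | None = None

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"run {self.sample_id!r}: duplicate feature ids {dup[:5]}")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n_controls(self) -> int:
        return len(self.features[0].control_intensities) if self.features else 0


def read_feature_table(path, sample_id: str | None = None, batch_id: str = "",
                       disorder: str | None = None) -> SampleRun:
    """Read features.tsv: feature_id, mz, rt_min, ion_mode, patient, ctrl_*.

    Control columns are every column whose name starts with ``ctrl``; fewer
    than two is a hard error.  Rows whose intensities fail to parse are
    dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["feature_id", "mz", "rt_min", "ion_mode", "patient"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ctrl_cols = [c for c in df.columns if c.startswith("ctrl")]
    if len(ctrl_cols) < 2:
        raise ValueError(f"{path}: need >=2 control columns, found {ctrl_cols}")

    features: list[Feature] = []
    n_dropped = 0
    seen: set[str] = set()
    for _, row in df.iterrows():
        fid = row["feature_id"]
        if fid in seen:
            raise ValueError(f"{path}: duplicate feature id {fid!r}")
        seen.add(fid)
        try:
            patient = float(row["patient"])
            controls = tuple(float(row[c]) for c in ctrl_cols)
            if not np.isfinite(patient) or not all(np.isfinite(c) for c in controls):
                raise ValueError
        except ValueError:
            n_dropped += 1
            continue
        features.append(
            Feature(
                feature_id=fid,
                mz=float(row["mz"]),
                rt=float(row["rt_min"]),
                ion_mode=IonMode(row["ion_mode"]),
                patient_intensity=patient,
                control_intensities=controls,
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d rows with unparseable intensities", path, n_dropped)
    if sample_id is None:
        sample_id = getattr(path, "stem", str(path))
    return SampleRun(sample_id=sample_id, features=features, batch_id=batch_id, disorder=disorder)


def write_feature_table(run: SampleRun, path) -> None:
    """Inverse of :func:`read_feature_table`; floats written with repr
    round-trip precision."""
    k = run.n_controls
    cols = {
        "feature_id": [f.feature_id for f in run.features],
        "mz": [repr(float(f.mz)) for f in run.features],
        "rt_min": [repr(float(f.rt)) for f in run.features],
        "ion_mode": [f.ion_mode.value for f in run.features],
        "patient": [repr(float(f.patient_intensity)) for f in run.features],
    }
    for j in range(k):
        cols[f"ctrl_{j + 1}"] = [repr(float(f.control_intensities[j])) for f in run.features]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
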