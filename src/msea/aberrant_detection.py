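"""Patient-vs-controls aberrant feature detection.

Each feature is tested for a patient intensity inconsistent with its batch
controls.  Intensities are moved to the log scale (``log1p``, tolerating
zeros) where multiplicative MS noise is approximately additive, and the
patient's deviation is studentized against the control mean and standard
deviation with the prediction-interval factor sqrt(1 + 1/n):

    T = (log1p(x_pat) - mean(log1p(x_ctrl))) / (s_ctrl * sqrt(1 + 1/n))

Under a log-normal null this statistic is exactly Student t with n-1
degrees of freedom, so two-sided p-values are calibrated even with the
~10 controls a typical analytical batch provides.  P-values are then
Benjamini-Hochberg adjusted across the whole run (both ion modes pooled)
and features with adjusted p below ``alpha`` (default 0.05) are flagged
aberrant.

Degenerate control spreads (all controls identical) yield p = 1 when the
patient equals the shared value and a smallest-representable p with a
degeneracy flag otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_io import Feature, SampleRun

__all__ = [
    "Direction",
    "AberrantCall",
    "feature_test",
    "benjamini_hochberg",
    "call_aberrant",
]

#: Surrogate p for a patient deviating from a zero-spread control set.
_P_FLOOR = 5e-324


class Direction(str, enum.Enum):
    up = "up"
    down = "down"


@dataclass(frozen=True)
class AberrantCall:
    feature_id: str
    statistic: float
    raw_p: float
    adjusted_p: float
    is_aberrant: bool
    direction: Direction
    degenerate: bool = False


def _test_arrays(patient: np.ndarray, controls: np.ndarray):
    """Vectorised studentized deviation test.

    patient: (m,) raw intensities; controls: (m, n) raw intensities.
    Returns (statistic, raw_p, degenerate) arrays.
    """
    n = controls.shape[1]
    lp = np.log1p(patient)
    lc = np.log1p(controls)
    mean = lc.mean(axis=1)
    sd = lc.std(axis=1, ddof=1)
    degenerate = sd == 0
    denom = np.where(degenerate, np.nan, sd) * np.sqrt(1.0 + 1.0 / n)
    stat = (lp - mean) / denom
    raw_p = 2.0 * stats.t.sf(np.abs(stat), df=n - 1)
    # zero-spread controls: exact match -> p=1, any deviation -> floor p
    exact = degenerate & (lp == mean)
    inf_stat = np.where(lp - mean > 0, np.inf, -np.inf)
    stat = np.where(degenerate, np.where(exact, 0.0, inf_stat), stat)
    raw_p = np.where(degenerate, np.where(exact, 1.0, _P_FLOOR), raw_p)
    return stat, np.clip(raw_p, 0.0, 1.0), degenerate


def feature_test(feature: Feature) -> tuple[float, float, Direction]:
    """Test a single feature; returns (statistic, raw two-sided p, direction)."""
    stat, p, _ = _test_arrays(
        np.array([feature.patient_intensity]),
        np.array([feature.control_intensities]),
    )
    direction = Direction.up if stat[0] >= 0 else Direction.down
    return float(stat[0]), float(p[0]), direction


def benjamini_hochberg(raw_ps) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(raw_ps, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_aberrant(run: SampleRun, alpha: float = 0.05) -> list[AberrantCall]:
    """Aberrant calls for a whole run: per-feature test + BH across all
    features of both ion modes, aberrant iff adjusted p < alpha."""
    if not run.features:
        return []
    patient = np.array([f.patient_intensity for f in run.features])
    controls = np.array([f.control_intensities for f in run.features])
    stat, raw_p, degenerate = _test_arrays(patient, controls)
    adj_p = benjamini_hochberg(raw_p)
    calls = []
    for i, f in enumerate(run.features):
        calls.append(
            AberrantCall(
                feature_id=f.feature_id,
                statistic=float(stat[i]),
                raw_p=float(raw_p[i]),
                adjusted_p=float(adj_p[i]),
                is_aberrant=bool(adj_p[i] < alpha),
                direction=Direction.up if stat[i] >= 0 else Direction.down,
                degenerate=bool(degenerate[i]),
            )
        )
    return calls
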