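"""Disease-activity labelling from clinical measurements.

Labels follow the clinical definitions used throughout this pipeline:

* **active**: fecal calprotectin (FC) > 250 ug/g — sufficient on its own;
* **remission**: HBI <= 4 together with serum CRP < 5 mg/l and FC < 100 ug/g;
* **indeterminate**: neither rule satisfied (e.g. FC in [100, 250] with quiet
  clinical scores) or a required measurement missing;
* **excluded**: sample collected within 30 days after a course of
  antibiotics; exclusion dominates every other label.

All inequalities are strict/non-strict exactly as written above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

ANTIBIOTIC_WASHOUT_DAYS = 30


class ActivityLabel(str, Enum):
    ACTIVE = "active"
    REMISSION = "remission"
    INDETERMINATE = "indeterminate"
    EXCLUDED = "excluded"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample clinical measurements needed for activity labelling."""

    subject_id: str
    sample_id: str
    hbi: Optional[float]
    crp: Optional[float]
    fc: Optional[float]
    days_since_antibiotics: Optional[float] = None


def _is_missing(x: Optional[float]) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def label_sample(rec: ClinicalRecord) -> ActivityLabel:
    """Pure function of (hbi, crp, fc); raises on negative values."""
    for name, val in (("hbi", rec.hbi), ("crp", rec.crp), ("fc", rec.fc)):
        if not _is_missing(val) and val < 0:  # type: ignore[operator]
            raise ValueError(
                f"sample {rec.sample_id!r}: negative {name} ({val}) — corrupt input"
            )
    if _is_missing(rec.fc):
        return ActivityLabel.INDETERMINATE
    if rec.fc > 250:  # type: ignore[operator]
        return ActivityLabel.ACTIVE
    if _is_missing(rec.hbi) or _is_missing(rec.crp):
        return ActivityLabel.INDETERMINATE
    if rec.hbi <= 4 and rec.crp < 5 and rec.fc < 100:  # type: ignore[operator]
        return ActivityLabel.REMISSION
    return ActivityLabel.INDETERMINATE


def apply_exclusions(
    records: Iterable[ClinicalRecord],
) -> list[tuple[str, ActivityLabel]]:
    """Label every sample, marking recent-antibiotic samples as excluded.

    Samples with ``days_since_antibiotics`` < 30 are excluded before any
    clinical labelling; an absent value never triggers exclusion.
    """
    out: list[tuple[str, ActivityLabel]] = []
    for rec in records:
        d = rec.days_since_antibiotics
        if not _is_missing(d) and d < ANTIBIOTIC_WASHOUT_DAYS:  # type: ignore[operator]
            out.append((rec.sample_id, ActivityLabel.EXCLUDED))
        else:
            out.append((rec.sample_id, label_sample(rec)))
    return out


def records_from_metadata(meta: pd.DataFrame) -> list[ClinicalRecord]:
    """Build ClinicalRecords from a validated metadata frame."""
    has_abx = "days_since_antibiotics" in meta.columns
    recs = []
    for row in meta.itertuples(index=False):
        recs.append(
            ClinicalRecord(
                subject_id=str(row.subject_id),
                sample_id=str(row.sample_id),
                hbi=float(row.hbi) if not pd.isna(row.hbi) else None,
                crp=float(row.crp) if not pd.isna(row.crp) else None,
                fc=float(row.fc) if not pd.isna(row.fc) else None,
                days_since_antibiotics=(
                    float(row.days_since_antibiotics)
                    if has_abx and not pd.isna(row.days_since_antibiotics)
                    else None
                ),
            )
        )
    return recs


def label_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Return a frame (sample_id, subject_id, label) for all samples."""
    labels = apply_exclusions(records_from_metadata(meta))
    lab = pd.DataFrame(labels, columns=["sample_id", "label"])
    lab["label"] = lab["label"].map(lambda v: v.value)
    return lab.merge(
        meta[["sample_id", "subject_id"]], on="sample_id", how="left"
    )[["sample_id", "subject_id", "label"]]
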