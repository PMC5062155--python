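"""Alpha-diversity estimators: Chao1 richness and Shannon entropy (nats).

Chao1 defaults to the bias-corrected form, which is defined when no
doubletons are observed; the classic form is available by flag.  Shannon uses
natural logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .tables import OtuTable


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    observed_otus: int
    f1: int  # OTUs seen exactly once in the sample
    f2: int  # OTUs seen exactly twice
    chao1: float
    shannon: float


def chao1(sample_counts: np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate for one sample's count vector.

    Bias-corrected: S_obs + F1*(F1-1)/(2*(F2+1)).
    Classic: S_obs + F1^2/(2*F2), undefined (inf) when F2 = 0 and F1 > 0.
    """
    x = np.asarray(sample_counts)
    if np.all(x <= 0):
        raise ValueError("chao1 undefined for an all-zero sample")
    s_obs = int(np.count_nonzero(x))
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return float("inf") if f1 > 0 else float(s_obs)
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(sample_counts: np.ndarray) -> float:
    """Shannon entropy -sum p ln p over OTUs with positive count (nats)."""
    x = np.asarray(sample_counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("shannon undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-np.sum(p * np.log(p)))


def sample_diversity(table: OtuTable) -> list[DiversityResult]:
    out = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        out.append(
            DiversityResult(
                sample_id=sid,
                observed_otus=int(np.count_nonzero(row)),
                f1=int(np.sum(row == 1)),
                f2=int(np.sum(row == 2)),
                chao1=chao1(row),
                shannon=shannon(row),
            )
        )
    return out


def diversity_frame(table: OtuTable) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in sample_diversity(table)])


def group_diversity_summary(
    table: OtuTable, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Median and IQR of each index per group plus a Mann-Whitney p-value.

    Quantiles use linear interpolation.  Returns one row per index with
    columns median/q1/q3 per group and ``p_mannwhitney``.
    """
    div = diversity_frame(table)
    div["label"] = div["sample_id"].map(labels)
    rows = []
    for index_name in ("chao1", "shannon"):
        rec: dict[str, object] = {"index": index_name}
        groups = {}
        for grp in ("active", "remission"):
            vals = div.loc[div["label"] == grp, index_name].to_numpy(float)
            if vals.size == 0:
                raise ValueError(f"group {grp!r} has no samples")
            groups[grp] = vals
            rec[f"{grp}_n"] = int(vals.size)
            rec[f"{grp}_median"] = float(np.median(vals))
            rec[f"{grp}_q1"] = float(np.quantile(vals, 0.25))
            rec[f"{grp}_q3"] = float(np.quantile(vals, 0.75))
        if np.ptp(np.concatenate(list(groups.values()))) == 0:
            p = 1.0  # identical constant groups: no evidence of difference
        else:
            p = float(
                stats.mannwhitneyu(
                    groups["active"], groups["remission"], alternative="two-sided"
                ).pvalue
            )
        rec["p_mannwhitney"] = p
        rows.append(rec)
    return pd.DataFrame(rows)
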