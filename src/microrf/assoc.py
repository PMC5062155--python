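"""Supporting association statistics.

Phylum presence/absence contrasts between disease states (Pearson chi-square
on 2x2 tables, Fisher's exact behind a flag), a Friedman-test confounder
screen with Benjamini-Hochberg FDR, and the correlation of the selected OTU
panel with fecal calprotectin (first canonical correlation of a multivariate
block against a univariate target, i.e. the multiple correlation, with a
permutation p-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import OtuTable


@dataclass(frozen=True)
class TwoByTwo:
    """Cell counts: rows = groups, columns = positive/negative."""

    a: int  # group 1 positive
    b: int  # group 1 negative
    c: int  # group 2 positive
    d: int  # group 2 negative

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


def two_by_two_test(t: TwoByTwo, method: str = "chi2") -> tuple[float, float]:
    """Association test for a 2x2 table.

    ``chi2``: Pearson chi-square without continuity correction, 1 df,
    chi2 = n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).  ``fisher``: two-sided
    Fisher's exact (returns (odds ratio, p)).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if method == "fisher":
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float(odds), float(p)
    if method != "chi2":
        raise ValueError("method must be 'chi2' or 'fisher'")
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("chi-square undefined: a margin is zero")
    chi2 = n * (a * d - b * c) ** 2 / margins
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def parse_rank(taxonomy: str, rank: str = "phylum") -> str:
    """Extract a rank from a Greengenes-style lineage; '' -> 'unclassified'."""
    prefixes = {
        "kingdom": "k__", "phylum": "p__", "class": "c__", "order": "o__",
        "family": "f__", "genus": "g__", "species": "s__",
    }
    try:
        prefix = prefixes[rank]
    except KeyError:
        raise ValueError(f"unknown rank {rank!r}")
    for part in taxonomy.split(";"):
        part = part.strip()
        if part.startswith(prefix) and len(part) > len(prefix):
            return part[len(prefix):]
    return "unclassified"


def phylum_prevalence(
    table: OtuTable,
    labels: Mapping[str, str],
    taxonomy_rank: str = "phylum",
) -> pd.DataFrame:
    """Per-taxon presence fraction per group with numerators/denominators.

    A taxon is present in a sample iff any OTU assigned to it has count > 0.
    Returns columns: taxon, active_positive, active_n, active_pct,
    remission_positive, remission_n, remission_pct.
    """
    taxa = np.array([parse_rank(t, taxonomy_rank) for t in table.taxonomy])
    lab = np.array([labels.get(s, "") for s in table.sample_ids])
    groups = {"active": lab == "active", "remission": lab == "remission"}
    rows = []
    for taxon in sorted(set(taxa)):
        cols = taxa == taxon
        present = (table.counts[:, cols] > 0).any(axis=1)
        rec: dict[str, object] = {"taxon": taxon}
        for g, rows_mask in groups.items():
            n = int(rows_mask.sum())
            pos = int((present & rows_mask).sum())
            rec[f"{g}_positive"] = pos
            rec[f"{g}_n"] = n
            rec[f"{g}_pct"] = prevalence_percent(pos, n) if n else float("nan")
        rows.append(rec)
    return pd.DataFrame(rows)


def prevalence_percent(n_positive: int, n_total: int, ndigits: int = 1) -> float:
    """Presence percentage as reported: 100 * positive / total, rounded."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_positive / n_total, ndigits)


def prevalence_contrast(
    table: OtuTable,
    labels: Mapping[str, str],
    taxon: str,
    taxonomy_rank: str = "phylum",
    method: str = "chi2",
) -> dict[str, float]:
    """2x2 presence-by-state test for one taxon; returns counts, chi2/odds, p."""
    prev = phylum_prevalence(table, labels, taxonomy_rank)
    row = prev[prev["taxon"] == taxon]
    if row.empty:
        raise ValueError(f"taxon {taxon!r} not found at rank {taxonomy_rank!r}")
    r = row.iloc[0]
    t = TwoByTwo(
        a=int(r["active_positive"]),
        b=int(r["active_n"] - r["active_positive"]),
        c=int(r["remission_positive"]),
        d=int(r["remission_n"] - r["remission_positive"]),
    )
    statistic, p = two_by_two_test(t, method=method)
    return {
        "taxon": taxon, "statistic": statistic, "p": p,
        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
    }


# ---------------------------------------------------------------------------
# Friedman confounder screen
# ---------------------------------------------------------------------------

def friedman_statistic(block_by_level: np.ndarray) -> tuple[float, float]:
    """Friedman rank test over a complete blocks x levels matrix.

    Uses average ranks with the standard tie correction; a fully tied layout
    (every block constant) yields statistic 0 and p = 1.
    """
    m = np.asarray(block_by_level, dtype=float)
    n_blocks, k = m.shape
    if k < 2:
        raise ValueError("need >= 2 factor levels")
    if n_blocks < 2:
        raise ValueError("need >= 2 usable blocks")
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    rj = ranks.sum(axis=0)
    chi = 12.0 / (n_blocks * k * (k + 1)) * np.sum(rj**2) - 3 * n_blocks * (k + 1)
    # tie correction (Conover): divide by 1 - sum(t^3 - t)/(n k (k^2 - 1))
    tie_term = 0.0
    for i in range(n_blocks):
        _, cnt = np.unique(m[i], return_counts=True)
        tie_term += float(np.sum(cnt**3 - cnt))
    denom = 1.0 - tie_term / (n_blocks * k * (k**2 - 1))
    if denom <= 0:
        return 0.0, 1.0  # all observations tied within every block
    chi /= denom
    chi = max(chi, 0.0)
    return float(chi), float(stats.chi2.sf(chi, df=k - 1))


@dataclass
class ConfounderScreen:
    factor: str
    per_otu: pd.DataFrame  # otu_id, statistic, p, q
    n_blocks: int
    alpha: float
    no_confounding: bool


def friedman_screen(
    panel_features,
    factor: Mapping[str, str],
    subject_map: Mapping[str, str],
    factor_name: str = "factor",
    alpha: float = 0.05,
) -> ConfounderScreen:
    """Per-OTU Friedman screen of a within-subject factor, BH-corrected.

    For each subject (block) with at least one sample at every factor level,
    per-level values are averaged; OTUs are tested across levels within
    blocks.  Verdict is "no confounding" when no OTU passes q < alpha.
    """
    levels = sorted(set(factor.values()))
    if len(levels) < 2:
        raise ValueError("factor needs >= 2 levels")
    sample_ids = panel_features.sample_ids
    X = panel_features.values
    subjects = np.array([subject_map[s] for s in sample_ids])
    flevel = np.array([factor[s] for s in sample_ids])
    blocks = []
    for subj in np.unique(subjects):
        rows = subjects == subj
        if set(flevel[rows]) >= set(levels):
            blocks.append(subj)
    if len(blocks) < 2:
        raise ValueError(f"fewer than 2 complete blocks for {factor_name!r}")
    results = []
    for j, otu in enumerate(panel_features.otu_ids):
        mat = np.empty((len(blocks), len(levels)))
        for bi, subj in enumerate(blocks):
            for li, lev in enumerate(levels):
                rows = (subjects == subj) & (flevel == lev)
                mat[bi, li] = X[rows, j].mean()
        statistic, p = friedman_statistic(mat)
        results.append({"otu_id": otu, "statistic": statistic, "p": p})
    per_otu = pd.DataFrame(results)
    per_otu["q"] = multipletests(per_otu["p"], method="fdr_bh")[1]
    return ConfounderScreen(
        factor=factor_name,
        per_otu=per_otu,
        n_blocks=len(blocks),
        alpha=alpha,
        no_confounding=bool((per_otu["q"] >= alpha).all()),
    )


# ---------------------------------------------------------------------------
# panel vs fecal calprotectin
# ---------------------------------------------------------------------------

def multiple_correlation(X: np.ndarray, y: np.ndarray) -> float:
    """First canonical correlation of X with univariate y = multiple R."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("target is constant")
    Xc = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    fitted = Xc @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return float(np.sqrt(min(r2, 1.0)))


def panel_fc_correlation(
    panel_features,
    fc: Sequence[float],
    n_permutations: int = 999,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Canonical correlation of the panel with FC plus permutation p-value.

    p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations), permuting FC across
    samples.
    """
    fc = np.asarray(fc, dtype=float)
    if np.any(np.isnan(fc)):
        raise ValueError("FC must be non-missing for included samples")
    X = panel_features.values
    r_obs = multiple_correlation(X, fc)
    if rng is None:
        rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        r_perm = multiple_correlation(X, rng.permutation(fc))
        if r_perm >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return r_obs, float(p)
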