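"""Count-table preprocessing: singletons, rarefaction, prevalence filter,
asinh transform, per-subject centering.

The fixed pipeline order is::

    remove_singletons -> rarefy -> prevalence_filter -> asinh -> subject_center

Rarefaction subsamples reads without replacement (multivariate
hypergeometric); samples shallower than the target depth are dropped and
reported.  Prevalence is computed on the rarefied table.  Centering uses only
each subject's own samples, so it is independent of any later
train/validation split.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .tables import FeatureMatrix, OtuTable

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = 4930
DEFAULT_PREVALENCE_THRESHOLD = 0.20


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs whose total count across all samples equals exactly 1."""
    totals = table.counts.sum(axis=0)
    return table.select_otus(totals != 1)


def rarefy(
    table: OtuTable,
    depth: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[OtuTable, list[str]]:
    """Subsample each sample to exactly *depth* reads without replacement.

    Returns the rarefied table and the ids of samples dropped for having
    fewer than *depth* reads.  Deterministic under a fixed ``rng``/``seed``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    if rng is None:
        rng = np.random.default_rng(seed)
    sums = table.counts.sum(axis=1)
    keep = sums >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy: dropping %d sample(s) below depth %d: %s",
                    len(dropped), depth, dropped)
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    sub = table.select_samples(kept_ids)
    out = np.empty_like(sub.counts)
    for i in range(sub.n_samples):
        out[i] = rng.multivariate_hypergeometric(sub.counts[i], depth)
    rarefied = OtuTable(
        counts=out, sample_ids=sub.sample_ids, otu_ids=sub.otu_ids,
        taxonomy=sub.taxonomy,
    )
    return rarefied, dropped


def prevalence_filter(
    table: OtuTable,
    labels: Mapping[str, str],
    threshold: float = DEFAULT_PREVALENCE_THRESHOLD,
) -> OtuTable:
    """Keep OTUs detected in >= *threshold* of the samples of either group.

    *labels* maps sample id -> "active"/"remission"; every sample in the
    table must be labelled and both groups must be non-empty.  The
    comparison is inclusive (>=).
    """
    lab = np.array([labels[s] for s in table.sample_ids])
    active = lab == "active"
    remission = lab == "remission"
    unknown = ~(active | remission)
    if unknown.any():
        bad = [s for s, u in zip(table.sample_ids, unknown) if u]
        raise ValueError(f"samples without an active/remission label: {bad[:5]}")
    n_act, n_rem = int(active.sum()), int(remission.sum())
    if n_act == 0 or n_rem == 0:
        raise ValueError(
            f"prevalence filter needs both groups non-empty (active={n_act}, "
            f"remission={n_rem})"
        )
    present = table.counts > 0
    frac_act = present[active].sum(axis=0) / n_act
    frac_rem = present[remission].sum(axis=0) / n_rem
    keep = (frac_act >= threshold) | (frac_rem >= threshold)
    return table.select_otus(keep)


def asinh_transform(table: OtuTable) -> FeatureMatrix:
    """Elementwise inverse hyperbolic sine: y = ln(x + sqrt(x^2 + 1))."""
    return FeatureMatrix(
        values=np.arcsinh(table.counts.astype(float)),
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        transformed=True,
        centered=False,
    )


def subject_center(
    matrix: FeatureMatrix, subject_map: Mapping[str, str]
) -> FeatureMatrix:
    """Subtract each subject's per-column mean over that subject's samples.

    Subjects contributing a single sample become all-zero rows (they are
    retained, not dropped).
    """
    try:
        subjects = np.array([subject_map[s] for s in matrix.sample_ids])
    except KeyError as e:
        raise ValueError(f"sample with no subject mapping: {e.args[0]!r}")
    values = matrix.values.copy()
    for subj in np.unique(subjects):
        rows = subjects == subj
        values[rows] -= values[rows].mean(axis=0, keepdims=True)
    return FeatureMatrix(
        values=values,
        sample_ids=list(matrix.sample_ids),
        otu_ids=list(matrix.otu_ids),
        transformed=matrix.transformed,
        centered=True,
    )


def preprocess_pipeline(
    table: OtuTable,
    labels: Mapping[str, str],
    subject_map: Mapping[str, str],
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    prevalence_threshold: float = DEFAULT_PREVALENCE_THRESHOLD,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[FeatureMatrix, OtuTable, list[str]]:
    """Run the fixed preprocessing chain.

    Only samples present in *labels* (active/remission) are carried through
    the prevalence filter and beyond.  Returns the model-ready matrix, the
    rarefied table (for diversity/prevalence reporting), and the dropped
    shallow sample ids.
    """
    table = remove_singletons(table)
    rarefied, dropped = rarefy(table, depth, rng=rng, seed=seed)
    labelled_ids = [s for s in rarefied.sample_ids if s in labels]
    rarefied_labelled = rarefied.select_samples(labelled_ids)
    filtered = prevalence_filter(rarefied_labelled, labels, prevalence_threshold)
    fm = asinh_transform(filtered)
    fm = subject_center(fm, subject_map)
    return fm, rarefied_labelled, dropped
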