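"""Subject-blocked repeated-subset random-forest discrimination.

Stage 1 fits one forest per random subject-blocked 80/20 subset and averages
per-OTU variable importance across subsets to select a discriminatory panel.
Stage 2 refits forests on the panel over a fresh set of subsets and scores
each sample by its validation vote rate; hard labels use a strict >0.5
majority.  All samples of a subject fall on the same side of every split, so
no model is ever trained on part of a subject and evaluated on the rest.

Importance is mean decrease in impurity (Gini) by default; permutation
importance is available behind a flag.  Forest hyperparameters beyond tree
count follow library defaults (sqrt(p) features per split, unlimited depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from ._seeding import child_ints, stage_seed_sequence

POSITIVE_LABEL = "active"
NEGATIVE_LABEL = "remission"


@dataclass
class SplitPlan:
    """Subject-level train/validation partitions; subjects never straddle."""

    subsets: list[tuple[frozenset[str], frozenset[str]]]
    train_fraction: float
    seed: int

    def __len__(self) -> int:
        return len(self.subsets)


@dataclass
class PanelResult:
    importance: dict[str, float]  # OTU id -> mean importance across subsets
    panel: list[str]  # top panel_size, importance-descending
    n_subsets_used: int
    n_trees: int


@dataclass
class PredictionReport:
    sample_ids: list[str]
    vote_rate: np.ndarray  # NaN for never-validated samples
    n_models_voting: np.ndarray
    hard_label: list[str]  # active / remission / indeterminate
    never_validated: list[str]
    roc_points: np.ndarray  # (threshold, FPR, TPR) rows
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    confusion: dict[str, int] = field(default_factory=dict)
    proximity: Optional[np.ndarray] = None


def make_subject_splits(
    subjects: Sequence[str],
    samples_per_subject: Mapping[str, int],
    n_subsets: int,
    train_fraction: float = 0.8,
    seed: int = 0,
    max_attempts_per_subset: int = 1000,
) -> SplitPlan:
    """Draw *n_subsets* distinct subject-blocked train/validation splits.

    Per subset, subjects are shuffled and assigned to the training side until
    the cumulative sample count first reaches ``train_fraction`` of all
    samples; the remainder form the validation side.  Duplicate subsets are
    re-drawn.
    """
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("cannot split fewer than 2 subjects")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    sizes = np.array([samples_per_subject[s] for s in subjects], dtype=float)
    target = train_fraction * sizes.sum()
    rng = np.random.default_rng(seed)
    seen: set[frozenset[str]] = set()
    subsets: list[tuple[frozenset[str], frozenset[str]]] = []
    for _ in range(n_subsets):
        for _attempt in range(max_attempts_per_subset):
            order = rng.permutation(len(subjects))
            cum = np.cumsum(sizes[order])
            cut = int(np.searchsorted(cum, target)) + 1  # first index reaching >= target
            if cut >= len(subjects):  # empty validation side: invalid draw
                continue
            train = frozenset(subjects[i] for i in order[:cut])
            if train in seen:
                continue
            seen.add(train)
            valid = frozenset(subjects[i] for i in order[cut:])
            subsets.append((train, valid))
            break
        else:
            raise RuntimeError(
                f"could not draw {n_subsets} distinct valid splits "
                f"({len(subsets)} found); too few subjects?"
            )
    return SplitPlan(subsets=subsets, train_fraction=train_fraction, seed=seed)


def _encode_labels(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray(labels)
    bad = set(y) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if bad:
        raise ValueError(f"labels must be active/remission, got extras: {bad}")
    return (y == POSITIVE_LABEL).astype(int)


def stage1_select_panel(
    features,
    labels: Mapping[str, str],
    subject_map: Mapping[str, str],
    plan: SplitPlan,
    n_trees: int = 700,
    panel_size: int = 50,
    seed: int = 0,
    importance: str = "impurity",
) -> PanelResult:
    """Average per-OTU importance over the plan's training fits; pick top OTUs.

    Ties in mean importance are broken by lexicographic OTU id.  Raises if
    any training side contains a single class.
    """
    if importance not in ("impurity", "permutation"):
        raise ValueError("importance must be 'impurity' or 'permutation'")
    X = features.values
    sample_subjects = np.array([subject_map[s] for s in features.sample_ids])
    y = _encode_labels([labels[s] for s in features.sample_ids])
    rstates = child_ints(stage_seed_sequence(seed, "forest_stage1"), len(plan))
    total = np.zeros(X.shape[1])
    for (train_subj, _valid_subj), rs in zip(plan.subsets, rstates):
        rows = np.isin(sample_subjects, list(train_subj))
        if len(np.unique(y[rows])) < 2:
            raise ValueError("a training side contains a single class")
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=rs, n_jobs=1
        )
        clf.fit(X[rows], y[rows])
        if importance == "impurity":
            total += clf.feature_importances_
        else:
            pi = permutation_importance(
                clf, X[rows], y[rows], n_repeats=5, random_state=rs, n_jobs=1
            )
            total += pi.importances_mean
    mean_imp = total / len(plan)
    order = sorted(
        range(len(features.otu_ids)),
        key=lambda j: (-mean_imp[j], features.otu_ids[j]),
    )
    panel = [features.otu_ids[j] for j in order[:panel_size]]
    return PanelResult(
        importance={features.otu_ids[j]: float(mean_imp[j]) for j in order},
        panel=panel,
        n_subsets_used=len(plan),
        n_trees=n_trees,
    )


def performance_from_rates(
    sensitivity: float, specificity: float, n_active: int, n_remission: int
) -> dict[str, float]:
    """PPV/NPV implied by sensitivity, specificity and class composition."""
    tp = sensitivity * n_active
    fn = n_active - tp
    tn = specificity * n_remission
    fp = n_remission - tn
    return {
        "ppv": tp / (tp + fp),
        "npv": tn / (tn + fn),
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def stage2_evaluate(
    features,
    labels: Mapping[str, str],
    subject_map: Mapping[str, str],
    plan: SplitPlan,
    n_trees: int = 700,
    seed: int = 0,
    vote_threshold: float = 0.5,
    compute_proximity: bool = False,
) -> PredictionReport:
    """Majority-vote evaluation over the plan's validation predictions.

    Each forest votes on its validation samples only; a sample's vote rate is
    the fraction of active votes among the models that validated it.  ROC and
    trapezoid AUC are computed over pooled vote rates; sensitivity,
    specificity, PPV and NPV at the strict >threshold rule.  Samples at
    exactly the threshold are labelled indeterminate and counted as errors in
    the confusion matrix.  With ``compute_proximity`` the co-leaf proximity
    matrix (averaged over trees and models, all samples) is accumulated.
    """
    X = features.values
    if X.shape[1] == 0:
        raise ValueError("panel is empty")
    n = X.shape[0]
    sample_subjects = np.array([subject_map[s] for s in features.sample_ids])
    y = _encode_labels([labels[s] for s in features.sample_ids])
    rstates = child_ints(stage_seed_sequence(seed, "forest_stage2"), len(plan))
    votes_active = np.zeros(n)
    n_voting = np.zeros(n, dtype=int)
    prox_sum = np.zeros((n, n)) if compute_proximity else None
    for (train_subj, valid_subj), rs in zip(plan.subsets, rstates):
        tr = np.isin(sample_subjects, list(train_subj))
        va = np.isin(sample_subjects, list(valid_subj))
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training side contains a single class")
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=rs, n_jobs=1
        )
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[va])
        votes_active[va] += pred
        n_voting[va] += 1
        if prox_sum is not None:
            leaves = clf.apply(X)
            prox_sum += _proximity_from_leaves(leaves)
    with np.errstate(invalid="ignore", divide="ignore"):
        vote_rate = np.where(n_voting > 0, votes_active / np.maximum(n_voting, 1), np.nan)
    never = [s for s, m in zip(features.sample_ids, n_voting) if m == 0]

    scored = n_voting > 0
    ys, vs = y[scored], vote_rate[scored]
    fpr, tpr, thresholds = roc_curve(ys, vs)
    auc_value = float(_trapezoid_auc(fpr, tpr))
    hard = []
    for s_ok, v in zip(scored, vote_rate):
        if not s_ok:
            hard.append("unscored")
        elif v > vote_threshold:
            hard.append(POSITIVE_LABEL)
        elif v < vote_threshold:
            hard.append(NEGATIVE_LABEL)
        else:
            hard.append("indeterminate")
    harr = np.array(hard, dtype=object)
    tp = int(np.sum((harr == POSITIVE_LABEL) & (y == 1) & scored))
    fn = int(np.sum((harr != POSITIVE_LABEL) & (y == 1) & scored))
    tn = int(np.sum((harr == NEGATIVE_LABEL) & (y == 0) & scored))
    fp = int(np.sum((harr != NEGATIVE_LABEL) & (y == 0) & scored))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    proximity = prox_sum / len(plan) if prox_sum is not None else None
    return PredictionReport(
        sample_ids=list(features.sample_ids),
        vote_rate=vote_rate,
        n_models_voting=n_voting,
        hard_label=hard,
        never_validated=never,
        roc_points=np.column_stack([thresholds, fpr, tpr]),
        auc=auc_value,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        proximity=proximity,
    )


def auc_mann_whitney(vote_rate: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic of vote rates (ties count half)."""
    y = np.asarray(labels)
    pos = vote_rate[y == 1]
    neg = vote_rate[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def _proximity_from_leaves(leaves: np.ndarray) -> np.ndarray:
    """Pairwise fraction of trees in which two samples share a terminal node."""
    n, n_trees = leaves.shape
    prox = np.zeros((n, n))
    for t in range(n_trees):
        col = leaves[:, t]
        prox += np.equal.outer(col, col)
    return prox / n_trees


def proximity_pca(proximity: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical MDS of the proximity-derived dissimilarity d = 1 - proximity.

    Double-centers the squared dissimilarity matrix and returns the leading
    principal coordinates (columns scaled by sqrt of eigenvalue).
    """
    p = np.asarray(proximity, dtype=float)
    if p.shape[0] != p.shape[1]:
        raise ValueError("proximity must be square")
    d2 = (1.0 - p) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:n_components]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)
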