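"""In-memory synthetic-cohort experiments.

Convenience wrapper running generate -> label -> preprocess -> stage 1 ->
stage 2 without file I/O, used for calibration and recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import forest, labeling, preprocess
from ._seeding import stage_rng
from .config import PipelineConfig
from .synthetic import CohortSpec, generate_cohort
from .tables import subject_map_from_metadata


@dataclass
class SyntheticRunResult:
    auc: float
    sensitivity: float
    specificity: float
    panel: list[str]
    truth: set[str]
    n_samples: int

    @property
    def panel_recovery(self) -> float:
        """Fraction of planted discriminatory OTUs recovered in the panel."""
        if not self.truth:
            return float("nan")
        return len(set(self.panel) & self.truth) / len(self.truth)


def run_synthetic_experiment(
    spec: CohortSpec, config: PipelineConfig
) -> SyntheticRunResult:
    """Full two-stage analysis of one synthetic cohort; seeds from config."""
    table, meta, truth = generate_cohort(spec)
    lab = labeling.label_metadata(meta)
    labels = dict(zip(lab["sample_id"], lab["label"]))
    subject_map = subject_map_from_metadata(meta)
    fm, _, _ = preprocess.preprocess_pipeline(
        table, labels, subject_map,
        depth=config.rarefaction_depth,
        prevalence_threshold=config.prevalence_threshold,
        rng=stage_rng(config.seed, "rarefy"),
    )
    labels = {s: labels[s] for s in fm.sample_ids}
    spp: dict[str, int] = {}
    for s in fm.sample_ids:
        spp[subject_map[s]] = spp.get(subject_map[s], 0) + 1
    subjects = sorted(spp)
    plan1 = forest.make_subject_splits(
        subjects, spp, config.stage1_subsets, config.train_fraction,
        seed=int(stage_rng(config.seed, "splits_stage1").integers(2**31)),
    )
    panel = forest.stage1_select_panel(
        fm, labels, subject_map, plan1,
        n_trees=config.n_trees, panel_size=config.panel_size, seed=config.seed,
    )
    plan2 = forest.make_subject_splits(
        subjects, spp, config.stage2_subsets, config.train_fraction,
        seed=int(stage_rng(config.seed, "splits_stage2").integers(2**31)),
    )
    report = forest.stage2_evaluate(
        fm.select_otus(panel.panel), labels, subject_map, plan2,
        n_trees=config.n_trees, seed=config.seed,
        vote_threshold=config.vote_threshold,
    )
    return SyntheticRunResult(
        auc=report.auc,
        sensitivity=report.sensitivity,
        specificity=report.specificity,
        panel=panel.panel,
        truth=truth,
        n_samples=len(fm.sample_ids),
    )
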