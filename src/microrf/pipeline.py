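"""End-to-end orchestration: label -> preprocess -> diversity -> stage 1 ->
stage 2 -> supporting statistics, with every artifact written to a report
directory and every exclusion logged with its reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import assoc, diversity, forest, labeling, preprocess
from ._seeding import stage_rng
from .config import PipelineConfig
from .tables import (
    OtuTable,
    read_metadata,
    read_otu_table,
    subject_map_from_metadata,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def run_pipeline(
    config: PipelineConfig,
    table_path: str | Path,
    meta_path: str | Path,
    out_dir: str | Path,
    compute_proximity: bool = True,
) -> dict:
    """Run the full analysis; returns the metrics dict written to metrics.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config_digest\t{config.digest()}",
                            f"seed\t{config.seed}"]

    table = read_otu_table(table_path)
    meta = read_metadata(meta_path)
    missing = set(table.sample_ids) - set(meta["sample_id"])
    if missing:
        raise PipelineError(f"samples without metadata: {sorted(missing)[:5]}")

    # --- labelling -------------------------------------------------------
    lab_frame = labeling.label_metadata(meta)
    lab_frame.to_csv(out / "labels.tsv", sep="\t", index=False)
    for row in lab_frame.itertuples(index=False):
        if row.label in ("excluded", "indeterminate"):
            log_lines.append(f"drop_sample\t{row.sample_id}\t{row.label}")
    labels = {
        r.sample_id: r.label
        for r in lab_frame.itertuples(index=False)
        if r.label in ("active", "remission")
    }
    labels = {s: l for s, l in labels.items() if s in set(table.sample_ids)}
    subject_map = subject_map_from_metadata(meta)
    for grp in ("active", "remission"):
        subj = {subject_map[s] for s, l in labels.items() if l == grp}
        if len(subj) < 2:
            raise PipelineError(
                f"fewer than 2 subjects with {grp} samples after exclusions"
            )

    # --- preprocessing ---------------------------------------------------
    fm, rarefied, dropped = preprocess.preprocess_pipeline(
        table.select_samples([s for s in table.sample_ids if s in labels]),
        labels,
        subject_map,
        depth=config.rarefaction_depth,
        prevalence_threshold=config.prevalence_threshold,
        rng=stage_rng(config.seed, "rarefy"),
    )
    for s in dropped:
        log_lines.append(f"drop_sample\t{s}\tbelow_rarefaction_depth")
    labels = {s: l for s, l in labels.items() if s in set(fm.sample_ids)}
    fm.to_dataframe().to_csv(out / "features.tsv", sep="\t")

    # --- diversity -------------------------------------------------------
    div = diversity.diversity_frame(rarefied)
    div["label"] = div["sample_id"].map(labels)
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    div_summary = diversity.group_diversity_summary(rarefied, labels)
    div_summary.to_csv(out / "diversity_summary.tsv", sep="\t", index=False)

    # --- stage 1: panel selection ---------------------------------------
    samples_per_subject = (
        pd.Series([subject_map[s] for s in fm.sample_ids]).value_counts().to_dict()
    )
    subjects = sorted(samples_per_subject)
    plan1 = forest.make_subject_splits(
        subjects,
        samples_per_subject,
        n_subsets=config.stage1_subsets,
        train_fraction=config.train_fraction,
        seed=int(stage_rng(config.seed, "splits_stage1").integers(2**31)),
    )
    panel_result = forest.stage1_select_panel(
        fm, labels, subject_map, plan1,
        n_trees=config.n_trees, panel_size=config.panel_size, seed=config.seed,
    )
    pd.DataFrame(
        [(o, panel_result.importance[o]) for o in panel_result.importance],
        columns=["otu_id", "importance"],
    ).to_csv(out / "panel.tsv", sep="\t", index=False)

    # --- stage 2: majority-vote evaluation ------------------------------
    plan2 = forest.make_subject_splits(
        subjects,
        samples_per_subject,
        n_subsets=config.stage2_subsets,
        train_fraction=config.train_fraction,
        seed=int(stage_rng(config.seed, "splits_stage2").integers(2**31)),
    )
    panel_fm = fm.select_otus(panel_result.panel)
    report = forest.stage2_evaluate(
        panel_fm, labels, subject_map, plan2,
        n_trees=config.n_trees, seed=config.seed,
        vote_threshold=config.vote_threshold,
        compute_proximity=compute_proximity,
    )
    pd.DataFrame(
        {
            "sample_id": report.sample_ids,
            "vote_rate": report.vote_rate,
            "n_models": report.n_models_voting,
            "label": report.hard_label,
        }
    ).to_csv(out / "votes.tsv", sep="\t", index=False)
    pd.DataFrame(
        report.roc_points, columns=["threshold", "fpr", "tpr"]
    ).to_csv(out / "roc.csv", index=False)
    for s in report.never_validated:
        log_lines.append(f"never_validated\t{s}\treport_only")
    if report.proximity is not None:
        coords = forest.proximity_pca(report.proximity)
        pd.DataFrame(
            {
                "sample_id": report.sample_ids,
                "pc1": coords[:, 0],
                "pc2": coords[:, 1],
                "label": [labels[s] for s in report.sample_ids],
            }
        ).to_csv(out / "pca.tsv", sep="\t", index=False)

    # --- supporting statistics ------------------------------------------
    prev = assoc.phylum_prevalence(rarefied, labels)
    prev.to_csv(out / "phylum_prevalence.tsv", sep="\t", index=False)
    fc = meta.set_index("sample_id").loc[panel_fm.sample_ids, "fc"].to_numpy(float)
    r_cca, p_cca = assoc.panel_fc_correlation(
        panel_fm, fc, n_permutations=199,
        rng=stage_rng(config.seed, "permutation"),
    )

    metrics = {
        "config_digest": config.digest(),
        "n_samples": len(fm.sample_ids),
        "n_subjects": len(subjects),
        "n_otus_model": len(fm.otu_ids),
        "panel_size": len(panel_result.panel),
        "auc": report.auc,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "ppv": report.ppv,
        "npv": report.npv,
        "confusion": report.confusion,
        "n_never_validated": len(report.never_validated),
        "cca_r": r_cca,
        "cca_p": p_cca,
    }
    with (out / "metrics.json").open("w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return metrics
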