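"""Shared fixtures: small synthetic cohorts and their processed forms."""

from __future__ import annotations

import numpy as np
import pytest

from microrf import forest, labeling, preprocess
from microrf.synthetic import CohortSpec, generate_cohort
from microrf.tables import OtuTable, subject_map_from_metadata

SMALL_SPEC = CohortSpec(
    n_subjects=30,
    samples_per_subject_range=(2, 4),
    n_otus=300,
    n_discriminatory=20,
    effect_size=6.0,
    subject_dispersion=200.0,
    depth_mean=2000.0,
    depth_sd=200.0,
    sparsity=0.3,
    active_fraction=0.5,
    seed=11,
    min_depth=1200,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with a strong planted signal."""
    table, meta, truth = generate_cohort(SMALL_SPEC)
    return table, meta, truth


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    """Labelled + preprocessed version of the small cohort."""
    table, meta, truth = small_cohort
    lab = labeling.label_metadata(meta)
    labels = dict(zip(lab["sample_id"], lab["label"]))
    subject_map = subject_map_from_metadata(meta)
    fm, rarefied, dropped = preprocess.preprocess_pipeline(
        table, labels, subject_map, depth=1000, seed=99
    )
    assert not dropped
    return {
        "features": fm,
        "rarefied": rarefied,
        "labels": labels,
        "subject_map": subject_map,
        "truth": truth,
        "meta": meta,
    }


@pytest.fixture(scope="session")
def small_stage2(small_processed):
    """Stage-1 panel + stage-2 report on the small cohort (reduced scale)."""
    fm = small_processed["features"]
    labels = small_processed["labels"]
    smap = small_processed["subject_map"]
    spp: dict[str, int] = {}
    for s in fm.sample_ids:
        spp[smap[s]] = spp.get(smap[s], 0) + 1
    subjects = sorted(spp)
    plan1 = forest.make_subject_splits(subjects, spp, 12, 0.8, seed=21)
    panel = forest.stage1_select_panel(
        fm, labels, smap, plan1, n_trees=50, panel_size=20, seed=22
    )
    plan2 = forest.make_subject_splits(subjects, spp, 25, 0.8, seed=23)
    report = forest.stage2_evaluate(
        fm.select_otus(panel.panel), labels, smap, plan2,
        n_trees=50, seed=24, compute_proximity=True,
    )
    return {"panel": panel, "report": report, "plan1": plan1, "plan2": plan2}


@pytest.fixture
def tiny_table():
    """A hand-built 4-sample x 5-OTU table."""
    counts = np.array(
        [
            [5, 0, 1, 10, 3],
            [2, 1, 0, 8, 0],
            [0, 0, 0, 12, 4],
            [7, 0, 2, 9, 1],
        ]
    )
    return OtuTable(
        counts=counts,
        sample_ids=["s1", "s2", "s3", "s4"],
        otu_ids=["o1", "o2", "o3", "o4", "o5"],
        taxonomy=[
            "k__Bacteria;p__Firmicutes;c__;o__;f__;g__;s__",
            "k__Bacteria;p__Fusobacteria;c__;o__;f__;g__;s__",
            "k__Bacteria;p__Bacteroidetes;c__;o__;f__;g__;s__",
            "k__Bacteria;p__Firmicutes;c__;o__;f__;g__;s__",
            "",
        ],
    )
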