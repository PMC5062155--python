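import numpy as np
import pytest

from microrf import forest
from microrf.forest import (
    SplitPlan,
    auc_mann_whitney,
    make_subject_splits,
    performance_from_rates,
    proximity_pca,
    stage1_select_panel,
    stage2_evaluate,
)
from microrf.tables import FeatureMatrix


def make_features(values, subjects):
    values = np.asarray(values, dtype=float)
    sids = [f"s{i}" for i in range(values.shape[0])]
    fm = FeatureMatrix(
        values=values,
        sample_ids=sids,
        otu_ids=[f"o{j}" for j in range(values.shape[1])],
        transformed=True,
        centered=True,
    )
    smap = {s: subj for s, subj in zip(sids, subjects)}
    return fm, smap


class TestMakeSubjectSplits:
    def test_exact_divisibility_eight_two(self):
        subjects = [f"p{i}" for i in range(10)]
        plan = make_subject_splits(subjects, {s: 1 for s in subjects}, 20, 0.8, seed=0)
        for train, valid in plan.subsets:
            assert len(train) == 8 and len(valid) == 2

    def test_partition_and_disjoint(self):
        subjects = [f"p{i}" for i in range(15)]
        sizes = {s: (i % 4) + 1 for i, s in enumerate(subjects)}
        plan = make_subject_splits(subjects, sizes, 30, 0.8, seed=1)
        for train, valid in plan.subsets:
            assert train | valid == set(subjects)
            assert not train & valid
            assert valid  # never empty

    def test_subsets_distinct(self):
        subjects = [f"p{i}" for i in range(12)]
        plan = make_subject_splits(subjects, {s: 2 for s in subjects}, 40, 0.8, seed=2)
        trains = {t for t, _ in plan.subsets}
        assert len(trains) == 40

    def test_deterministic(self):
        subjects = [f"p{i}" for i in range(12)]
        a = make_subject_splits(subjects, {s: 1 for s in subjects}, 10, 0.8, seed=3)
        b = make_subject_splits(subjects, {s: 1 for s in subjects}, 10, 0.8, seed=3)
        assert a.subsets == b.subsets

    def test_validation_sizes_concentrate_near_twenty_percent(self):
        # heterogeneous subject sizes: validation share stays near 1 - 0.8
        rng = np.random.default_rng(4)
        subjects = [f"p{i}" for i in range(71)]
        sizes = {s: int(rng.integers(1, 9)) for s in subjects}
        total = sum(sizes.values())
        plan = make_subject_splits(subjects, sizes, 100, 0.8, seed=5)
        valid_counts = [sum(sizes[s] for s in v) for _, v in plan.subsets]
        assert abs(np.mean(valid_counts) / total - 0.2) < 0.03

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            make_subject_splits(["only"], {"only": 4}, 5, 0.8, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_subject_splits(["a", "b"], {"a": 1, "b": 1}, 1, 1.0, seed=0)

    def test_exhausted_distinct_splits(self):
        with pytest.raises(RuntimeError):
            make_subject_splits(
                ["a", "b", "c"], {"a": 1, "b": 1, "c": 1}, 50, 0.67, seed=0,
                max_attempts_per_subset=50,
            )


class TestStage1:
    def test_perfect_separator_ranks_first(self):
        rng = np.random.default_rng(0)
        n = 40
        noise = rng.normal(size=(n, 9))
        y = np.array(["active", "remission"] * (n // 2))
        sep = np.where(y == "active", 1.0, -1.0) + rng.normal(scale=0.01, size=n)
        values = np.column_stack([noise[:, :4], sep, noise[:, 4:]])
        subjects = [f"p{i // 2}" for i in range(n)]
        fm, smap = make_features(values, subjects)
        labels = {s: l for s, l in zip(fm.sample_ids, y)}
        plan = make_subject_splits(
            sorted(set(subjects)), {p: 2 for p in set(subjects)}, 8, 0.8, seed=1
        )
        res = stage1_select_panel(fm, labels, smap, plan, n_trees=50, panel_size=3, seed=2)
        assert res.panel[0] == "o4"
        assert res.n_subsets_used == 8
        assert res.n_trees == 50

    def test_importance_tie_break_lexicographic(self):
        # constant features all get zero importance -> ordering by OTU id
        values = np.zeros((8, 4))
        values[:, 0] = [1, -1] * 4  # informative
        y = ["active", "remission"] * 4
        subjects = [f"p{i}" for i in range(8)]
        fm, smap = make_features(values, subjects)
        labels = dict(zip(fm.sample_ids, y))
        plan = make_subject_splits(subjects, {p: 1 for p in subjects}, 4, 0.8, seed=3)
        res = stage1_select_panel(fm, labels, smap, plan, n_trees=20, panel_size=3, seed=4)
        assert res.panel == ["o0", "o1", "o2"]

    def test_single_class_training_side_rejected(self):
        values = np.random.default_rng(1).normal(size=(4, 3))
        subjects = ["p0", "p1", "p2", "p3"]
        fm, smap = make_features(values, subjects)
        labels = dict(zip(fm.sample_ids, ["active"] * 4))
        plan = SplitPlan(
            subsets=[(frozenset(["p0", "p1", "p2"]), frozenset(["p3"]))],
            train_fraction=0.75, seed=0,
        )
        with pytest.raises(ValueError, match="single class"):
            stage1_select_panel(fm, labels, smap, plan, n_trees=10, panel_size=2, seed=0)

    def test_reproducible_under_seed(self, small_processed):
        fm = small_processed["features"]
        labels = small_processed["labels"]
        smap = small_processed["subject_map"]
        spp: dict[str, int] = {}
        for s in fm.sample_ids:
            spp[smap[s]] = spp.get(smap[s], 0) + 1
        plan = make_subject_splits(sorted(spp), spp, 5, 0.8, seed=6)
        r1 = stage1_select_panel(fm, labels, smap, plan, n_trees=30, panel_size=10, seed=7)
        r2 = stage1_select_panel(fm, labels, smap, plan, n_trees=30, panel_size=10, seed=7)
        assert r1.panel == r2.panel
        assert r1.importance == r2.importance


class TestStage2:
    def test_no_leakage_all_models(self, small_processed, small_stage2):
        smap = small_processed["subject_map"]
        for plan in (small_stage2["plan1"], small_stage2["plan2"]):
            for train, valid in plan.subsets:
                assert not train & valid

    def test_vote_conservation(self, small_stage2):
        report = small_stage2["report"]
        # vote_rate * n_models = active votes, an integer; remission votes fill the rest
        scored = report.n_models_voting > 0
        votes_active = report.vote_rate[scored] * report.n_models_voting[scored]
        assert np.allclose(votes_active, np.round(votes_active), atol=1e-9)
        assert np.all(votes_active <= report.n_models_voting[scored])

    def test_auc_equals_mann_whitney(self, small_processed, small_stage2):
        report = small_stage2["report"]
        labels = small_processed["labels"]
        scored = report.n_models_voting > 0
        y = np.array([1 if labels[s] == "active" else 0 for s in report.sample_ids])
        mw = auc_mann_whitney(report.vote_rate[scored], y[scored])
        assert abs(report.auc - mw) < 1e-10

    def test_strong_signal_auc_high(self, small_stage2):
        assert small_stage2["report"].auc > 0.75

    def test_hard_labels_threshold(self, small_stage2):
        report = small_stage2["report"]
        for v, m, h in zip(report.vote_rate, report.n_models_voting, report.hard_label):
            if m == 0:
                assert h == "unscored"
            elif v > 0.5:
                assert h == "active"
            elif v < 0.5:
                assert h == "remission"
            else:
                assert h == "indeterminate"

    def test_perfect_votes_trivial_metrics(self):
        # degenerate check through the metric formulas
        perf = performance_from_rates(1.0, 1.0, 10, 10)
        assert perf["ppv"] == 1.0 and perf["npv"] == 1.0

    def test_ppv_npv_from_printed_rates(self):
        # sens .79 / spec .73 on 97 active + 88 remission validation samples
        perf = performance_from_rates(0.79, 0.73, 97, 88)
        assert round(perf["ppv"], 2) == 0.76
        assert round(perf["npv"], 2) == 0.76

    def test_empty_panel_rejected(self, small_processed):
        fm = small_processed["features"].select_otus([])
        with pytest.raises(ValueError, match="panel is empty"):
            stage2_evaluate(
                fm, small_processed["labels"], small_processed["subject_map"],
                SplitPlan(subsets=[], train_fraction=0.8, seed=0), n_trees=5, seed=0,
            )

    def test_reproducible(self, small_processed, small_stage2):
        fm = small_processed["features"]
        panel = small_stage2["panel"].panel
        rep1 = stage2_evaluate(
            fm.select_otus(panel), small_processed["labels"],
            small_processed["subject_map"], small_stage2["plan2"],
            n_trees=50, seed=24,
        )
        rep2 = small_stage2["report"]
        assert np.allclose(rep1.vote_rate, rep2.vote_rate, equal_nan=True)
        assert rep1.auc == rep2.auc


class TestProximity:
    def test_properties(self, small_stage2):
        prox = small_stage2["report"].proximity
        assert prox is not None
        assert np.allclose(np.diag(prox), 1.0)
        assert np.allclose(prox, prox.T)
        assert prox.min() >= 0.0 and prox.max() <= 1.0 + 1e-12

    def test_within_class_closer_than_between(self, small_processed, small_stage2):
        prox = small_stage2["report"].proximity
        labels = small_processed["labels"]
        y = np.array([labels[s] == "active" for s in small_stage2["report"].sample_ids])
        same = np.equal.outer(y, y)
        off_diag = ~np.eye(len(y), dtype=bool)
        assert prox[same & off_diag].mean() > prox[~same].mean()

    def test_pca_shape_and_separation(self, small_processed, small_stage2):
        prox = small_stage2["report"].proximity
        coords = proximity_pca(prox)
        assert coords.shape == (prox.shape[0], 2)
        labels = small_processed["labels"]
        y = np.array([labels[s] == "active" for s in small_stage2["report"].sample_ids])
        # the planted effect separates classes along the leading coordinates
        centroid_dist = np.linalg.norm(coords[y].mean(axis=0) - coords[~y].mean(axis=0))
        spread = coords.std()
        assert centroid_dist > 0.5 * spread

    def test_pca_rejects_non_square(self):
        with pytest.raises(ValueError):
            proximity_pca(np.zeros((3, 2)))
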