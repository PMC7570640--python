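import numpy as np
import pandas as pd
import pytest

from lstmecoc.evaluation import (
    EvalConfig,
    PipelineSettings,
    bootstrap_sample,
    compute_metrics,
    cross_validate,
    run_bootstrap_evaluation,
    sweep,
)
from lstmecoc.lstm import TrainConfig
from lstmecoc.recording import class_index

from conftest import toy_sequences

FAST = PipelineSettings(hidden_units=4,
                        train=TrainConfig(epochs=2, mini_batch=4))


class TestBootstrapSample:
    def test_sample_size_equals_original_with_replacement(self, rng):
        seqs = toy_sequences(n_per_class=4)
        sample = bootstrap_sample(seqs, rng)
        assert len(sample) == len(seqs)
        ids = [s.id for s in sample]
        assert len(set(ids)) < len(ids)  # duplicates are expected at n=12

    def test_stratified_sample_preserves_class_counts(self, rng):
        seqs = toy_sequences(n_per_class=4)
        sample = bootstrap_sample(seqs, rng, stratified=True)
        labels = [s.label for s in sample]
        assert all(labels.count(c) == 4 for c in ("healthy", "mild", "moderate"))

    def test_single_item_dataset_repeats_it(self, rng):
        seqs = toy_sequences(n_per_class=1)[:1]
        sample = bootstrap_sample(seqs, rng)
        assert [s.id for s in sample] == [seqs[0].id]

    def test_empty_dataset_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            bootstrap_sample([], rng)

    def test_expected_distinct_fraction_matches_closed_form(self):
        """Over many draws of a 12-item class the distinct fraction
        approaches 1 - (1 - 1/12)^12 ~ 0.6480."""
        rng = np.random.default_rng(0)
        seqs = toy_sequences(n_per_class=12)
        per_class = [s for s in seqs if s.label == "healthy"]
        fracs = []
        for _ in range(1000):
            sample = bootstrap_sample(per_class, rng, stratified=True)
            fracs.append(len({s.id for s in sample}) / 12)
        expected = 1 - (1 - 1 / 12) ** 12
        assert np.mean(fracs) == pytest.approx(expected, rel=0.02)


class TestMetrics:
    def test_perfect_classifier_scores_100_everywhere(self):
        m = compute_metrics(np.diag([4, 4, 4]))
        assert all(v == pytest.approx(100.0) for v in m.values())

    def test_worked_three_class_example(self):
        """One-vs-rest collapse of [[4,0,0],[1,3,0],[0,1,3]], checked by hand."""
        m = compute_metrics(np.array([[4, 0, 0], [1, 3, 0], [0, 1, 3]]))
        assert m["accuracy"] == pytest.approx(83.33, abs=0.01)
        assert m["sensitivity"] == pytest.approx(83.33, abs=0.01)
        assert m["specificity"] == pytest.approx(91.67, abs=0.01)
        assert m["precision"] == pytest.approx(85.00, abs=0.01)

    def test_macro_averages_invariant_under_class_permutation(self, rng):
        cm = rng.integers(0, 10, (3, 3))
        cm[np.diag_indices(3)] += 5
        perm = [2, 0, 1]
        permuted = cm[np.ix_(perm, perm)]
        a, b = compute_metrics(cm), compute_metrics(permuted)
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_zero_predicted_positives_warns_and_counts_zero(self):
        cm = np.array([[4, 0, 0], [4, 0, 0], [0, 0, 4]])
        with pytest.warns(UserWarning, match="zero predicted"):
            m = compute_metrics(cm)
        assert m["precision"] == pytest.approx(100.0 * (0.5 + 0 + 1) / 3)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            compute_metrics(np.zeros((3, 3)))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_metrics(np.array([[1, -1, 0], [0, 1, 0], [0, 0, 1]]))


class TestCrossValidate:
    def test_duplicates_never_split_across_folds(self, rng):
        """All bootstrap copies of one original stay in one fold, so a
        tested duplicate can never have a twin in the training folds."""
        from lstmecoc.evaluation import _grouped_stratified_folds

        seqs = toy_sequences(n_per_class=12)
        sample = bootstrap_sample(seqs, rng)
        folds = _grouped_stratified_folds(sample, 3, rng)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(len(sample)))
        for gid in {s.id for s in sample}:
            holding = [f for f, idx in enumerate(folds)
                       if any(sample[i].id == gid for i in idx)]
            assert len(holding) == 1, gid

    def test_duplicate_free_sample_splits_into_equal_folds(self, rng):
        from lstmecoc.evaluation import _grouped_stratified_folds

        seqs = toy_sequences(n_per_class=12)
        folds = _grouped_stratified_folds(seqs, 3, rng)
        labels = np.array([class_index(s.label) for s in seqs])
        for idx in folds:
            assert len(idx) == 12
            assert [list(labels[idx]).count(c) for c in range(3)] == [4, 4, 4]

    def test_each_item_tested_exactly_once(self, rng):
        seqs = toy_sequences(n_per_class=4, seed=0)
        cm = cross_validate(seqs, 3, FAST, rng)
        assert cm.sum() == len(seqs)

    def test_separable_toys_give_diagonal_confusion(self, rng):
        seqs = toy_sequences(n_per_class=4, offset=5.0, noise=0.1, seed=1)
        cm = cross_validate(seqs, 3, FAST, rng)
        assert np.all(cm == np.diag(np.diag(cm))), cm

    def test_fold_assignment_deterministic_given_rng_state(self):
        seqs = toy_sequences(n_per_class=4, seed=2)
        cm1 = cross_validate(seqs, 3, FAST, np.random.default_rng(5))
        cm2 = cross_validate(seqs, 3, FAST, np.random.default_rng(5))
        assert np.array_equal(cm1, cm2)


class TestBootstrapEvaluation:
    def test_single_replicate_report_with_zero_sd_convention(self):
        seqs = toy_sequences(n_per_class=4, offset=5.0, noise=0.1)
        cfg = EvalConfig(n_bootstrap=1, seed=3, settings=FAST)
        report = run_bootstrap_evaluation(seqs, cfg)
        assert len(report.replicates) == 1
        assert report.summary.loc["accuracy", "sd"] == 0.0
        assert report.summary.loc["accuracy", "mean"] == pytest.approx(
            report.replicates["accuracy"].iloc[0]
        )

    def test_seeded_end_to_end_determinism(self):
        seqs = toy_sequences(n_per_class=4, seed=4)
        cfg = EvalConfig(n_bootstrap=3, seed=17, settings=FAST)
        r1 = run_bootstrap_evaluation(seqs, cfg)
        r2 = run_bootstrap_evaluation(seqs, cfg)
        pd.testing.assert_frame_equal(r1.replicates, r2.replicates)

    def test_metrics_bounded_and_ci_ordered(self):
        seqs = toy_sequences(n_per_class=4, seed=5, offset=1.0, noise=1.0)
        cfg = EvalConfig(n_bootstrap=4, seed=1, settings=FAST)
        report = run_bootstrap_evaluation(seqs, cfg)
        vals = report.replicates.to_numpy()
        assert np.all((vals >= 0) & (vals <= 100))
        s = report.summary
        for m in s.index:
            assert s.loc[m, "ci_low"] <= s.loc[m, "ci_high"]
            assert vals.min() <= s.loc[m, "ci_low"]
            assert s.loc[m, "ci_high"] <= vals.max()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EvalConfig(n_bootstrap=0).validate()
        with pytest.raises(ValueError):
            EvalConfig(k_folds=1).validate()


class TestSweep:
    def test_one_point_grid_yields_single_row(self):
        seqs = toy_sequences(n_per_class=4, offset=5.0, noise=0.1)
        cfg = EvalConfig(n_bootstrap=1, seed=2, settings=FAST)
        table, best = sweep(seqs, cfg, {"learning_rate": [0.001]})
        assert len(table) == 1
        assert best.train.learning_rate == 0.001

    def test_hill_climb_fixes_each_axis_at_its_best(self, monkeypatch):
        """Selection logic: with a synthetic monotone objective the sweep
        must pick the top of each grid before moving on."""
        import lstmecoc.evaluation as ev

        def fake_eval(dataset, config):
            s = config.settings
            acc = s.hidden_units + 100 * s.train.learning_rate
            reps = pd.DataFrame([{m: acc for m in ev.METRIC_NAMES}] * 2)
            return ev.BootstrapReport(replicates=reps, config=config)

        monkeypatch.setattr(ev, "run_bootstrap_evaluation", fake_eval)
        grid = {"learning_rate": [0.0001, 0.001], "hidden_units": [8, 16, 32]}
        table, best = ev.sweep([], EvalConfig(settings=FAST), grid)
        assert len(table) == 5
        assert best.train.learning_rate == 0.001
        assert best.hidden_units == 32

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            sweep([], EvalConfig(settings=FAST), {"learning_rate": []})
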