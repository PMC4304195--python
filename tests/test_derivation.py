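"""Training matrix, weighted SVM training, fold assignment, derivation."""

import numpy as np
import pytest

from idphydro.derivation import (
    DerivedScale,
    assign_folds,
    build_training_matrix,
    derive_scale,
    optimize_threshold_for_f,
    refit_whole_protein_boundary,
    train_weighted_linear,
)
from idphydro.features import SequenceRecord, chop_windows
from idphydro.io import DISORDERED, ORDERED
from idphydro.scales import CANONICAL_RESIDUES


def corpus_windows(dataset, limit=None):
    wins, labs = [], []
    records = dataset.records[:limit] if limit else dataset.records
    labels = dataset.labels[:limit] if limit else dataset.labels
    for rec, lab in zip(records, labels):
        ws = chop_windows(rec)
        wins.extend(ws)
        labs.extend([lab] * len(ws))
    return wins, labs


class TestBuildTrainingMatrix:
    def test_shape_and_targets(self):
        wins = [SequenceRecord(f"p{i}|w0-41", "K" * 41) for i in range(3)]
        labels = [DISORDERED, ORDERED, DISORDERED]
        tm = build_training_matrix(wins, labels)
        assert tm.X.shape == (3, 21)
        assert list(tm.Y) == [-1, 1, -1]

    def test_poly_k_row(self):
        tm = build_training_matrix(
            [SequenceRecord("p|w0-41", "K" * 41)], [DISORDERED])
        k_col = CANONICAL_RESIDUES.index("K")
        assert tm.X[0, k_col] == 1.0
        assert tm.X[0, 20] == 1.0  # signed net charge of poly-K
        assert tm.Y[0] == -1

    def test_abs_charge_option(self):
        tm = build_training_matrix(
            [SequenceRecord("p|w0-41", "E" * 41)], [DISORDERED],
            charge_feature="abs")
        assert tm.X[0, 20] == 1.0  # |-1|

    def test_provenance_tracks_protein_ids(self):
        wins = chop_windows(SequenceRecord("prot1", "A" * 123))
        tm = build_training_matrix(wins, [ORDERED] * len(wins))
        assert all(pid == "prot1" for pid, _ in tm.provenance)

    def test_empty_and_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            build_training_matrix([], [])
        with pytest.raises(ValueError):
            build_training_matrix(
                [SequenceRecord("p", "A" * 41)], ["maybe"])


def separable_toy(n_per_class=20):
    """Composition rows concentrated on distinct residues per class."""
    X = np.zeros((2 * n_per_class, 21))
    y = np.empty(2 * n_per_class, dtype=int)
    ile, lys = CANONICAL_RESIDUES.index("I"), CANONICAL_RESIDUES.index("K")
    for i in range(n_per_class):
        X[i, ile] = 0.9
        X[i, (ile + 1 + i) % 20] = 0.1
        y[i] = 1
        j = n_per_class + i
        X[j, lys] = 0.9
        X[j, (lys + 1 + i) % 20] = 0.1
        X[j, 20] = 0.9
        y[j] = -1
    return X, y


class TestTrainWeightedLinear:
    def test_separable_toy_training_accuracy(self):
        X, y = separable_toy()
        model = train_weighted_linear(X, y, seed=0)
        assert np.all(np.sign(model.decision(X)) == y)

    def test_sign_convention_positive_means_ordered(self):
        X, y = separable_toy()
        model = train_weighted_linear(X, y, seed=0)
        labels = model.predict_labels(X)
        assert labels[0] == ORDERED and labels[-1] == DISORDERED

    def test_duplication_leaves_direction_stable(self, small_corpus):
        """Duplicating every row (weights recomputed) rescales the
        effective cost but barely moves the max-margin direction."""
        wins, labs = corpus_windows(small_corpus)
        tm = build_training_matrix(wins, labs)
        m1 = train_weighted_linear(tm.X, tm.Y, seed=1)
        m2 = train_weighted_linear(
            np.vstack([tm.X, tm.X]), np.concatenate([tm.Y, tm.Y]), seed=1)
        u1 = m1.w / np.linalg.norm(m1.w)
        u2 = m2.w / np.linalg.norm(m2.w)
        assert float(u1 @ u2) > 0.99

    def test_label_flip_antisymmetry(self):
        X, y = separable_toy()
        m1 = train_weighted_linear(X, y, seed=0)
        m2 = train_weighted_linear(X, -y, seed=0)
        u1 = m1.w / np.linalg.norm(m1.w)
        u2 = m2.w / np.linalg.norm(m2.w)
        assert float(u1 @ u2) <= -0.99

    def test_single_class_rejected(self):
        X, y = separable_toy()
        with pytest.raises(ValueError):
            train_weighted_linear(X, np.ones_like(y), seed=0)


class TestAssignFolds:
    def test_equal_proteins_perfectly_balanced(self):
        labels = [DISORDERED] * 10 + [ORDERED] * 10
        counts = [4] * 20
        folds = assign_folds(labels, counts, k=10, seed=0)
        per_fold = np.bincount(folds, minlength=10)
        assert np.all(per_fold == 2)
        for f in range(10):
            fold_labels = {labels[i] for i in np.where(folds == f)[0]}
            assert fold_labels == {DISORDERED, ORDERED}

    def test_balance_bound_over_random_mixes(self):
        """Fold window totals stay within one max-protein of each other."""
        rng = np.random.default_rng(123)
        for trial in range(100):
            n_dis = int(rng.integers(10, 40))
            n_ord = int(rng.integers(10, 60))
            labels = [DISORDERED] * n_dis + [ORDERED] * n_ord
            counts = [int(c) for c in rng.integers(1, 12, size=len(labels))]
            folds = assign_folds(labels, counts, k=10, seed=trial)
            totals = np.zeros(10)
            for i, f in enumerate(folds):
                totals[f] += counts[i]
            assert totals.max() - totals.min() <= max(counts)
            for f in range(10):
                assert {labels[i] for i in np.where(folds == f)[0]} == {
                    DISORDERED, ORDERED}

    def test_deterministic_per_seed(self):
        labels = [DISORDERED] * 15 + [ORDERED] * 25
        counts = list(range(1, 41))
        a = assign_folds(labels, counts, k=10, seed=5)
        b = assign_folds(labels, counts, k=10, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_too_few_proteins_rejected(self):
        labels = [DISORDERED] * 5 + [ORDERED] * 20
        with pytest.raises(ValueError, match="at least k"):
            assign_folds(labels, [1] * 25, k=10)


class TestDeriveScale:
    def test_small_run_average_verifiable(self, small_corpus):
        derived = derive_scale(
            small_corpus.records, list(small_corpus.labels),
            k=2, repeats=1, seed=3)
        assert len(derived.fold_models) == 2
        W = np.stack([m.w for m in derived.fold_models])
        np.testing.assert_allclose(
            derived.residue_weights, W[:, :20].mean(axis=0))
        assert derived.charge_weight == pytest.approx(W[:, 20].mean())
        assert derived.bias == pytest.approx(
            np.mean([m.b for m in derived.fold_models]))

    def test_same_seed_bitwise_identical(self, small_corpus):
        kwargs = dict(k=3, repeats=2, seed=11)
        a = derive_scale(small_corpus.records, list(small_corpus.labels), **kwargs)
        b = derive_scale(small_corpus.records, list(small_corpus.labels), **kwargs)
        np.testing.assert_array_equal(a.residue_weights, b.residue_weights)
        assert a.charge_weight == b.charge_weight
        assert a.fold_assignments == b.fold_assignments

    def test_disorder_promoting_residues_get_negative_weights(self, small_corpus):
        """Sign convention: weights negative for residues enriched in the
        disordered class (here planted: P, K, E, S, ... low scale values)."""
        derived = derive_scale(
            small_corpus.records, list(small_corpus.labels),
            k=5, repeats=1, seed=3)
        from idphydro.synthetic import planted_scale

        truth = planted_scale(small_corpus.truth)
        centered = truth.as_array() - truth.as_array().mean()
        agree = np.sign(derived.residue_weights) == np.sign(centered)
        assert agree.sum() >= 16

    def test_cv_report_carries_metrics(self, small_corpus):
        derived = derive_scale(
            small_corpus.records, list(small_corpus.labels),
            k=3, repeats=1, seed=3)
        summary = derived.cv_summary()
        assert summary["n_models"] == 3
        assert summary["pooled"]["bal_acc"] is not None
        assert 0 <= summary["pooled"]["auc"] <= 1


class TestRefitWholeProteinBoundary:
    def test_boundary_slope_positive_and_heldout_reported(self, small_corpus):
        derived = derive_scale(
            small_corpus.records, list(small_corpus.labels),
            k=5, repeats=1, seed=3)
        boundary, report = refit_whole_protein_boundary(
            derived, small_corpus.records, list(small_corpus.labels))
        # disordered class has lower H and higher R by construction
        assert boundary.a > 0
        assert report.balanced_acc is not None
        assert report.auc > 0.8

    def test_single_fold_equals_direct_fit(self, small_corpus):
        """With one stored split the averaged boundary is just the mean of
        k per-fold fits; with k folds of identical content it matches."""
        from idphydro.chplot import fit_boundary, ch_point

        derived = derive_scale(
            small_corpus.records, list(small_corpus.labels),
            k=2, repeats=1, seed=3)
        boundary, _ = refit_whole_protein_boundary(
            derived, small_corpus.records, list(small_corpus.labels))
        scale = derived.to_normalized_scale()
        pts = [ch_point(r, scale, label=l)
               for r, l in zip(small_corpus.records, small_corpus.labels)]
        fold_of = np.asarray(derived.fold_assignments[0])
        manual = []
        for f in (0, 1):
            sub = [p for p, g in zip(pts, fold_of) if g != f]
            manual.append(fit_boundary(sub, seed=derived.seed))
        assert boundary.a == pytest.approx(np.mean([m.a for m in manual]))
        assert boundary.b == pytest.approx(np.mean([m.b for m in manual]))


class TestOptimizeThresholdForF:
    def test_separable_midpoint(self):
        t = optimize_threshold_for_f(
            [0.1, 0.2, 0.8, 0.9],
            [ORDERED, ORDERED, DISORDERED, DISORDERED])
        assert t == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold_for_f([1, 2], [DISORDERED, DISORDERED])

    def test_brute_force_oracle(self, rng):
        """Exhaustive sweep over all cut positions agrees on random data."""

        def oracle(scores, labels):
            best_f, best_t = -1.0, None
            order = np.argsort(scores)
            s = np.asarray(scores)[order]
            candidates = np.concatenate(
                [[s[0] - 1], (s[:-1] + s[1:]) / 2, [s[-1] + 1]])
            for t in np.unique(candidates):
                tp = sum(1 for sc, l in zip(scores, labels)
                         if sc > t and l == DISORDERED)
                fp = sum(1 for sc, l in zip(scores, labels)
                         if sc > t and l == ORDERED)
                fn = sum(1 for sc, l in zip(scores, labels)
                         if sc <= t and l == DISORDERED)
                if tp + fp == 0 or tp + fn == 0:
                    continue
                prec, rec_ = tp / (tp + fp), tp / (tp + fn)
                f = 0.0 if prec + rec_ == 0 else 2 * prec * rec_ / (prec + rec_)
                if f >= best_f:  # ties toward higher threshold
                    best_f, best_t = f, t
            return best_t, best_f

        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.normal(size=n), 1)
            labels = list(rng.choice([DISORDERED, ORDERED], size=n))
            if len(set(labels)) < 2:
                continue
            t = optimize_threshold_for_f(scores, labels)
            t_oracle, f_oracle = oracle(scores, labels)
            assert t == pytest.approx(t_oracle)
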