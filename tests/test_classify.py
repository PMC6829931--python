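"""k-NN, SVM, standardisation and subject-grouped CV invariants."""

import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import KNeighborsClassifier

from seatsense.classify import (
    KNNModel,
    SVMModel,
    Standardizer,
    cross_validate,
    euclidean_distances,
    make_subject_folds,
    select_k,
    svm_train,
)
from seatsense.features import FEATURE_NAMES


# ---------------------------------------------------------------- standardise
def test_standardizer_two_point_example():
    std = Standardizer.fit(np.array([[1.0], [3.0]]))
    np.testing.assert_allclose(std.transform(np.array([[1.0], [3.0]])), [[-1.0], [1.0]])


def test_standardizer_idempotent_on_z_scores(rng):
    X = rng.normal(size=(50, 5))
    Z = Standardizer.fit(X).transform(X)
    Z2 = Standardizer.fit(Z).transform(Z)
    np.testing.assert_allclose(Z, Z2, atol=1e-9)
    np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-9)
    np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-9)


def test_standardizer_moments_match_direct_recomputation(rng):
    X = rng.uniform(-5, 5, size=(50, 5))
    std = Standardizer.fit(X, FEATURE_NAMES)
    np.testing.assert_allclose(std.mean_, [np.mean(X[:, j]) for j in range(5)], rtol=1e-12)
    np.testing.assert_allclose(std.scale_, [np.std(X[:, j]) for j in range(5)], rtol=1e-12)


def test_standardizer_zero_variance_names_feature():
    X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
    with pytest.raises(ValueError, match="column 1"):
        Standardizer.fit(X)
    with pytest.raises(ValueError, match="sd_lat_cop"):
        Standardizer.fit(X, ("asv", "sd_lat_cop"))


# ----------------------------------------------------------------------- k-NN
def test_euclidean_three_four_five():
    assert euclidean_distances(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))[0, 0] == 5.0


def test_knn_nearest_neighbour_wins_at_k1():
    model = KNNModel(1, np.array([[0.0], [10.0]]), np.array(["A", "B"]))
    assert model.predict([[1.0]])[0] == "A"


def test_knn_matches_exhaustive_sort_oracle(rng):
    X = rng.normal(size=(6, 2))
    y = np.array(["A", "A", "B", "B", "C", "C"])
    model = KNNModel(3, X, y)
    for _ in range(20):
        q = rng.normal(size=(1, 2))
        dists = sorted(
            (np.sqrt(((X[i] - q[0]) ** 2).sum()), i) for i in range(6)
        )
        top = [y[i] for _, i in dists[:3]]
        counts = {c: top.count(c) for c in set(top)}
        best = max(counts.values())
        expect = next(c for c in top if counts[c] == best)
        assert model.predict(q)[0] == expect


def test_knn_agrees_with_sklearn_on_tie_free_data(rng):
    X = rng.normal(size=(40, 5))
    y = rng.choice(["A", "B"], size=40)
    Xq = rng.normal(size=(15, 5))
    ours = KNNModel(5, X, y).predict(Xq)
    ref = KNeighborsClassifier(n_neighbors=5).fit(X, y).predict(Xq)
    # ties are measure-zero on continuous data, so the two must agree
    np.testing.assert_array_equal(ours, ref)


def test_knn_vote_tie_broken_by_nearest_neighbour():
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    y = np.array(["A", "B", "B", "A"])
    # query at 0: neighbours 1(A), 2(B), 3(B), 4(A); k=4 -> 2 votes each,
    # nearest neighbour has class A
    assert KNNModel(4, X, y).predict([[0.0]])[0] == "A"


def test_knn_k1_training_accuracy_is_perfect(rng):
    X = rng.normal(size=(30, 3))
    y = rng.choice(["A", "B", "C"], size=30)
    model = KNNModel(1, X, y)
    np.testing.assert_array_equal(model.predict(X), y)


def test_knn_k_out_of_range():
    with pytest.raises(ValueError, match="k="):
        KNNModel(5, np.zeros((3, 2)), np.array(["A", "B", "A"]))


# ------------------------------------------------------------------- select_k
def _blob_set(rng, sep, n_subj=4, per=6):
    X, y, subj = [], [], []
    for s in range(n_subj):
        for c, center in (("A", -sep / 2), ("B", sep / 2)):
            pts = rng.normal(center, 1.0, size=(per, 2))
            X.append(pts)
            y += [c] * per
            subj += [f"S{s}"] * per
    return np.vstack(X), np.array(y), np.array(subj)


def test_select_k_single_candidate():
    rng = np.random.default_rng(0)
    X, y, subj = _blob_set(rng, sep=6.0)
    assert select_k(X, y, subj, candidates=[3]) == 3


def test_select_k_perfect_separation_returns_smallest():
    rng = np.random.default_rng(1)
    X, y, subj = _blob_set(rng, sep=50.0)
    assert select_k(X, y, subj, candidates=[1, 3, 5]) == 1


def test_select_k_matches_exhaustive_candidate_sweep(rng):
    from seatsense.classify import _grouped_splits
    from seatsense.metrics import confusion, precision_recall_f1

    X, y, subj = _blob_set(rng, sep=1.5)
    candidates = [1, 3, 5, 7]
    chosen = select_k(X, y, subj, candidates=candidates, n_inner=3)
    # independent sweep using sklearn k-NN on the same grouped splits
    scores = {}
    for k in candidates:
        pooled = None
        for tr, te in _grouped_splits(subj, 3):
            pred = KNeighborsClassifier(n_neighbors=k).fit(X[tr], y[tr]).predict(X[te])
            cm = confusion(y[te], pred, ("A", "B"))
            pooled = cm if pooled is None else pooled + cm
        scores[k] = precision_recall_f1(pooled).macro_f1
    best = max(scores.values())
    expect = min(k for k in candidates if scores[k] == best)
    assert chosen == expect


def test_select_k_no_candidate_fits():
    rng = np.random.default_rng(2)
    X, y, subj = _blob_set(rng, sep=5.0, n_subj=2, per=2)
    with pytest.raises(ValueError, match="no candidate"):
        select_k(X, y, subj, candidates=[99])


# ------------------------------------------------------------------------ SVM
def test_svm_1d_hard_margin_analytic():
    X = np.array([[-1.0], [1.0]] * 10)
    y = np.array(["neg", "pos"] * 10)
    model = svm_train(X, y, C=1e6)
    w, b = model.weights[0, 0], model.biases[0]
    # optimal separator: boundary at 0 with margin 1 at x = +-1
    assert abs(w) == pytest.approx(1.0, abs=1e-4)
    assert b == pytest.approx(0.0, abs=1e-4)


def test_svm_margin_constraints_on_separable_blobs(rng):
    X = np.vstack([rng.normal(-3, 0.5, size=(20, 2)), rng.normal(3, 0.5, size=(20, 2))])
    y = np.array(["a"] * 20 + ["b"] * 20)
    model = svm_train(X, y, C=1e6, tol=1e-8)
    sign = np.where(y == "b", 1.0, -1.0)  # sklearn: positive = larger class label
    margins = sign * model.decision_values(X)[:, 0]
    assert np.all(margins >= 1 - 1e-6)
    np.testing.assert_array_equal(model.predict(X), y)


def test_svm_invariant_to_duplicated_training_set(rng):
    X = rng.normal(size=(30, 3))
    y = rng.choice(["a", "b"], size=30)
    Xq = rng.normal(size=(10, 3))
    m1 = svm_train(X, y, C=1.0)
    m2 = svm_train(np.vstack([X, X]), np.concatenate([y, y]), C=0.5)
    np.testing.assert_array_equal(m1.predict(Xq), m2.predict(Xq))


def test_svm_single_class_errors():
    with pytest.raises(ValueError, match="single class"):
        svm_train(np.zeros((4, 2)), np.array(["a"] * 4))


def test_svm_multiclass_separable_blobs_zero_training_error(rng):
    centers = {"a": (-6, 0), "b": (6, 0), "c": (0, 6), "d": (0, -6)}
    X = np.vstack([rng.normal(c, 0.5, size=(15, 2)) for c in centers.values()])
    y = np.repeat(list(centers), 15)
    for scheme in ("ovr", "ovo"):
        model = svm_train(X, y, C=100.0, scheme=scheme)
        np.testing.assert_array_equal(model.predict(X), y)


# ------------------------------------------------------------ folds & full CV
def test_subject_folds_partition_properties():
    subjects = [f"S{i}" for i in range(8)]
    folds = make_subject_folds(subjects, n_folds=4, seed=3)
    test_sets = [folds.test_subjects(f) for f in range(4)]
    assert all(len(ts) == 2 for ts in test_sets)
    assert set().union(*test_sets) == set(subjects)
    for i in range(4):
        for j in range(i + 1, 4):
            assert not (test_sets[i] & test_sets[j])
        assert not (folds.train_subjects(i) & folds.test_subjects(i))


def test_subject_folds_deterministic_per_seed():
    subjects = [f"S{i}" for i in range(8)]
    assert make_subject_folds(subjects, seed=5).fold_of == make_subject_folds(subjects, seed=5).fold_of
    assert make_subject_folds(subjects, seed=5).fold_of != make_subject_folds(subjects, seed=6).fold_of


def test_subject_folds_indivisible_errors():
    with pytest.raises(ValueError, match="divisible"):
        make_subject_folds(["a", "b", "c"], n_folds=2)


def _cv_table(rng, n_subj=4, per=10, shift=0.0, shift_subject=None):
    rows = []
    for s in range(n_subj):
        subj = f"S{s}"
        for c, center in (("NC", -2.0), ("C", 2.0)):
            pts = rng.normal(center, 1.0, size=(per, len(FEATURE_NAMES)))
            if subj == shift_subject:
                pts = pts + shift
            for p in pts:
                rows.append({"subject": subj, "label": c, **dict(zip(FEATURE_NAMES, p))})
    return pd.DataFrame(rows)


def test_cv_each_trial_tested_exactly_once(rng):
    table = _cv_table(rng)
    folds = make_subject_folds(table["subject"], n_folds=4, seed=0)
    report = cross_validate(table, "knn", folds, class_order=("NC", "C"), k_grid=(1, 3))
    assert sorted(report.predictions["row"]) == list(range(len(table)))
    merged = report.predictions.merge(
        table.reset_index().rename(columns={"index": "row"}), on="row"
    )
    for fold in range(4):
        fold_subjects = set(merged[merged.fold == fold].subject_x)
        assert fold_subjects == folds.test_subjects(fold)


def test_cv_test_subject_cannot_leak_into_training(rng):
    """Perturbing one test subject's features leaves every co-tested
    subject's predictions unchanged in that fold (nothing it contributes
    reaches training or standardisation there)."""
    seed_rng = np.random.default_rng(11)
    base = _cv_table(seed_rng)
    folds = make_subject_folds(base["subject"], n_folds=2, seed=0)
    target_fold = 0
    s_perturb = sorted(folds.test_subjects(target_fold))[0]
    s_other = sorted(folds.test_subjects(target_fold))[1]
    shifted = base.copy()
    mask = shifted.subject == s_perturb
    shifted.loc[mask, list(FEATURE_NAMES)] += 100.0
    r1 = cross_validate(base, "knn", folds, class_order=("NC", "C"), k_grid=(3,))
    r2 = cross_validate(shifted, "knn", folds, class_order=("NC", "C"), k_grid=(3,))
    p1 = r1.predictions.query("fold == @target_fold and subject == @s_other")
    p2 = r2.predictions.query("fold == @target_fold and subject == @s_other")
    np.testing.assert_array_equal(p1["pred"].to_numpy(), p2["pred"].to_numpy())


def test_cv_majority_classifier_is_chance_level(rng):
    """A degenerate feature set where one class dominates: accuracy of
    always predicting it on a balanced 4-class set is ~= 0.25."""
    rows = []
    for s in range(4):
        for c in ("NC", "TLF", "TR", "SE"):
            for _ in range(10):
                rows.append(
                    {"subject": f"S{s}", "label": c,
                     **dict(zip(FEATURE_NAMES, rng.normal(size=5)))}
                )
    table = pd.DataFrame(rows)
    folds = make_subject_folds(table["subject"], n_folds=4, seed=1)
    report = cross_validate(table, "knn", folds, k_grid=(15,))
    assert report.pooled.accuracy == pytest.approx(0.25, abs=0.12)


def test_cv_predictions_invariant_to_common_rescaling(rng):
    table = _cv_table(rng)
    folds = make_subject_folds(table["subject"], n_folds=2, seed=0)
    scaled = table.copy()
    scaled[list(FEATURE_NAMES)] *= 1000.0
    for clf in ("knn", "svm"):
        r1 = cross_validate(table, clf, folds, class_order=("NC", "C"), k_grid=(3,))
        r2 = cross_validate(scaled, clf, folds, class_order=("NC", "C"), k_grid=(3,))
        np.testing.assert_array_equal(
            r1.predictions["pred"].to_numpy(), r2.predictions["pred"].to_numpy()
        )


def test_cv_missing_class_in_training_fold_errors(rng):
    table = _cv_table(rng, n_subj=2)
    # subject S0 holds every C row -> the fold testing on S0 lacks class C
    table.loc[(table.subject == "S1") & (table.label == "C"), "label"] = "NC"
    folds = make_subject_folds(table["subject"], n_folds=2, seed=0)
    with pytest.raises(ValueError, match="lacks class"):
        cross_validate(table, "knn", folds, class_order=("NC", "C"), k_grid=(1,))


def test_model_json_round_trip(tmp_path, rng):
    X = rng.normal(size=(12, 5))
    y = rng.choice(["a", "b"], size=12)
    knn = KNNModel(3, X, y)
    knn.to_json(tmp_path / "knn.json")
    back = KNNModel.from_json(tmp_path / "knn.json")
    Xq = rng.normal(size=(5, 5))
    np.testing.assert_array_equal(knn.predict(Xq), back.predict(Xq))
    svm = svm_train(X, y, C=1.0)
    svm.to_json(tmp_path / "svm.json")
    back = SVMModel.from_json(tmp_path / "svm.json")
    np.testing.assert_array_equal(svm.predict(Xq), back.predict(Xq))
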