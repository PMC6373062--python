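import numpy as np
import pytest

from papscreen import (CellClass, ContractError, FCMClassifier,
                       FCMClassifierConfig, FCMModel, binary_label,
                       choose_cluster_count, defuzz_fit, fcm_fit, membership,
                       predict_posteriors, screen_slide, table_to_xy)
from papscreen.synthetic_data import gen_feature_table
from papscreen.feature_selection import REFERENCE_SELECTED_FEATURES


def two_blobs(rng, n=50, sep=5.0):
    return np.vstack([rng.normal(0, 0.3, (n, 2)),
                      rng.normal(sep, 0.3, (n, 2))])


# ---------------------------------------------------------------------------
# clustering core

def test_two_blob_center_recovery(rng):
    X = two_blobs(rng)
    model = fcm_fit(X, c=2, q=2.0, seed=1, n_restarts=3)
    centers = model.centers[np.argsort(model.centers[:, 0])]
    assert np.abs(centers[0] - 0.0).max() <= 0.1
    assert np.abs(centers[1] - 5.0).max() <= 0.1


def test_objective_non_increasing(rng):
    X = two_blobs(rng)
    model = fcm_fit(X, c=3, q=1.5, seed=0)
    trace = np.array(model.objective_trace)
    assert np.all(np.diff(trace) <= 1e-8 * max(trace[0], 1.0))


def test_membership_normalization_and_range(rng):
    X = rng.normal(0, 1, (40, 3))
    model = fcm_fit(X, c=4, q=1.0930, seed=2)
    m = membership(rng.normal(0, 1, (25, 3)), model)
    assert np.abs(m.sum(axis=1) - 1).max() <= 1e-9
    assert m.min() >= 0 and m.max() <= 1


def test_equidistant_point_has_equal_memberships():
    model = FCMModel(centers=np.array([[0.0, 0.0], [4.0, 0.0]]), fuzzifier=2.0)
    m = membership(np.array([2.0, 1.0]), model)
    assert m == pytest.approx([0.5, 0.5])


def test_point_on_center_gets_full_membership():
    model = FCMModel(centers=np.array([[0.0, 0.0], [4.0, 0.0]]), fuzzifier=2.0)
    m = membership(np.array([4.0, 0.0]), model)
    assert m == pytest.approx([0.0, 1.0])


def test_membership_matches_direct_formula(rng):
    """Independent evaluation of the membership formula for c = 3."""
    centers = rng.normal(0, 2, (3, 4))
    q = 1.7
    model = FCMModel(centers=centers, fuzzifier=q)
    x = rng.normal(0, 2, 4)
    d = np.linalg.norm(centers - x, axis=1)
    expected = np.array([
        1.0 / sum((d[i] / d[j]) ** (2 / (q - 1)) for j in range(3))
        for i in range(3)
    ])
    assert membership(x, model) == pytest.approx(expected, rel=1e-9)


def test_near_one_fuzzifier_approaches_hard_assignment(rng):
    X = two_blobs(rng)
    model = fcm_fit(X, c=2, q=1.01, seed=0)
    m = membership(X, model)
    assert m.max(axis=1).min() >= 0.999


def test_contract_errors(rng):
    X = rng.normal(0, 1, (5, 2))
    with pytest.raises(ContractError):
        fcm_fit(X, c=5, q=2.0)          # n <= c
    with pytest.raises(ContractError):
        fcm_fit(X, c=2, q=1.0)          # q must exceed 1
    from papscreen import DataError
    bad = X.copy()
    bad[0, 0] = np.nan
    with pytest.raises(DataError):
        fcm_fit(bad, c=2, q=2.0)
    model = fcm_fit(X, c=2, q=2.0)
    with pytest.raises(ContractError):
        membership(np.zeros(5), model)  # dimension mismatch


# ---------------------------------------------------------------------------
# defuzzification

def test_pure_clusters_give_one_hot_posteriors(rng):
    X = two_blobs(rng, n=20)
    y = np.array([0] * 20 + [1] * 20)
    model = fcm_fit(X, c=2, q=1.5, seed=0)
    dz = defuzz_fit(model, X, y, smoothing=0.0)
    for j in range(2):
        col = dz.posteriors[:, j]
        assert col.max() == pytest.approx(1.0)
        assert col.sum() == pytest.approx(1.0)


def test_uniform_mix_posterior_equals_priors():
    # both clusters see the identical class mix -> posterior collapses to
    # the priors
    model = FCMModel(centers=np.array([[0.0], [10.0]]), fuzzifier=2.0)
    X = np.concatenate([np.zeros(30), np.full(30, 10.0)])[:, None]
    y = np.array(([0] * 10 + [1] * 10 + [2] * 10) * 2)
    dz = defuzz_fit(model, X, y, smoothing=0.0)
    for j in range(2):
        assert dz.posteriors[:, j] == pytest.approx(dz.priors)


def test_hand_computed_bayes_table():
    """3 clusters, two classes with counts A:(10,0,5), B:(0,10,5), alpha=0."""
    centers = np.array([[0.0], [10.0], [20.0]])
    model = FCMModel(centers=centers, fuzzifier=2.0)
    X = np.concatenate([np.full(10, 0.0), np.full(5, 20.0),
                        np.full(10, 10.0), np.full(5, 20.0)])[:, None]
    y = np.array(["A"] * 15 + ["B"] * 15)
    dz = defuzz_fit(model, X, y, smoothing=0.0)
    # likelihoods: P(B_j|A) = (10/15, 0, 5/15); P(B_j|B) = (0, 10/15, 5/15)
    assert dz.conditionals[0] == pytest.approx([10 / 15, 0.0, 5 / 15])
    assert dz.conditionals[1] == pytest.approx([0.0, 10 / 15, 5 / 15])
    # posteriors: cluster 0 -> pure A, cluster 1 -> pure B, cluster 2 -> 50/50
    assert dz.posteriors[:, 0] == pytest.approx([1.0, 0.0])
    assert dz.posteriors[:, 1] == pytest.approx([0.0, 1.0])
    assert dz.posteriors[:, 2] == pytest.approx([0.5, 0.5])


def test_defuzz_missing_class_rejected(rng):
    X = rng.normal(0, 1, (10, 2))
    model = fcm_fit(X, c=2, q=2.0, seed=0)
    with pytest.raises(ContractError):
        defuzz_fit(model, X, np.zeros(10), classes=np.array([0, 1]))


def test_posteriors_normalized_and_pure_center_confident(rng):
    X = two_blobs(rng, n=30)
    y = np.array([0] * 30 + [1] * 30)
    model = fcm_fit(X, c=2, q=1.5, seed=0)
    dz = defuzz_fit(model, X, y, smoothing=0.0)
    post = predict_posteriors(model.centers, model, dz)
    assert np.abs(post.sum(axis=1) - 1).max() <= 1e-9
    assert post.max() >= 0.99


# ---------------------------------------------------------------------------
# classifier on reference-statistics tables

def test_binary_accuracy_on_reference_tables(herlev_table, herlev_table_test):
    Xtr, ytr, _ = table_to_xy(herlev_table, subset=REFERENCE_SELECTED_FEATURES)
    Xte, yte, _ = table_to_xy(herlev_table_test,
                              subset=REFERENCE_SELECTED_FEATURES)
    clf = FCMClassifier(FCMClassifierConfig(n_restarts=5), seed=0)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    acc = np.mean([binary_label(CellClass(a)) == binary_label(CellClass(p))
                   for a, p in zip(yte, pred)])
    assert acc >= 0.95


def test_classifier_persistence_round_trip(tmp_path, herlev_table):
    Xtr, ytr, names = table_to_xy(herlev_table,
                                  subset=REFERENCE_SELECTED_FEATURES)
    clf = FCMClassifier(FCMClassifierConfig(n_clusters=5, n_restarts=2),
                        seed=0, feature_names=names)
    clf.fit(Xtr, ytr)
    path = tmp_path / "model.joblib"
    clf.save(path)
    back = FCMClassifier.load(path)
    assert np.array_equal(back.predict(Xtr[:20]), clf.predict(Xtr[:20]))


# ---------------------------------------------------------------------------
# cluster-count selection and slide screening

def test_choose_cluster_count_on_separated_classes(rng):
    import pandas as pd
    n = 30
    X = np.vstack([rng.normal(0, 0.5, (n, 2)), rng.normal(6, 0.5, (n, 2)),
                   rng.normal([0, 8], 0.5, (n, 2))])
    df = pd.DataFrame(X, columns=["f0", "f1"])
    df["label"] = ["A"] * n + ["B"] * n + ["C"] * n
    cfg = FCMClassifierConfig(n_restarts=2, max_iter=100)
    rep = choose_cluster_count(df, candidates=list(range(2, 9)), k=3, seed=0,
                               subset=["f0", "f1"], base_config=cfg)
    assert rep.chosen >= 3
    assert rep.cv_errors[rep.candidates.index(rep.chosen)] <= rep.cv_errors[0]
    rep2 = choose_cluster_count(df, candidates=list(range(2, 9)), k=3, seed=0,
                                subset=["f0", "f1"], base_config=cfg)
    assert rep2.cv_errors == rep.cv_errors and rep2.chosen == rep.chosen


def test_choose_cluster_count_single_candidate(herlev_table):
    cfg = FCMClassifierConfig(n_clusters=4, n_restarts=1, max_iter=50)
    rep = choose_cluster_count(herlev_table, candidates=[4], k=3, seed=0,
                               subset=["nucleus_area", "nc_ratio"],
                               base_config=cfg)
    assert rep.chosen == 4


def test_screen_slide_thresholds():
    all_normal = [CellClass.SUPERFICIAL] * 10
    assert screen_slide(all_normal).label == "NEGATIVE"
    one_bad = all_normal + [CellClass.SEVERE]
    assert screen_slide(one_bad).label == "POSITIVE"
    two_bad = all_normal + [CellClass.SEVERE, CellClass.MILD]
    assert screen_slide(two_bad, min_abnormal=3).label == "NEGATIVE"
    assert screen_slide(two_bad).class_counts["SEVERE"] == 1
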