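"""QSAR metrics, oversampling geometry and cross-validation contracts."""

import numpy as np
import pytest

from molrl import fixtures as fx
from molrl.predictors import (AffinityConfig, BBBConfig, OversampleSpec,
                              classification_metrics, crossvalidate,
                              oversample, regression_metrics, train_affinity,
                              train_bbb)

# ----------------------------------------------------------------- metrics


def test_regression_metrics_perfect_prediction():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    m = regression_metrics(y, y)
    assert m["MSE"] == 0.0
    assert m["Q2"] == 1.0
    assert m["CCC"] == pytest.approx(1.0)


def test_regression_metrics_hand_computed():
    y = np.array([1.0, 2.0, 3.0])
    p = np.array([2.0, 2.0, 2.0])  # constant prediction
    m = regression_metrics(y, p)
    assert m["MSE"] == pytest.approx(2 / 3)
    assert m["Q2"] == pytest.approx(0.0)
    assert m["CCC"] == pytest.approx(0.0)  # zero covariance


@pytest.mark.parametrize("p,expected_auc", [
    ((0.9, 0.8, 0.2, 0.1), 1.0),
    ((0.9, 0.2, 0.8, 0.1), 0.75),
])
def test_auc_matches_pair_enumeration(p, expected_auc):
    y = np.array([1, 1, 0, 0])
    m = classification_metrics(y, np.array(p))
    assert m["AUC"] == pytest.approx(expected_auc)


def test_classification_metrics_perfect_confusion():
    y = np.array([1, 1, 0, 0])
    p = np.array([0.9, 0.8, 0.2, 0.1])
    m = classification_metrics(y, p)
    assert m["ACC"] == 1.0
    assert m["MCC"] == pytest.approx(1.0)
    assert m["Sen"] == 1.0
    assert m["Spe"] == 1.0


def test_classification_metrics_hand_computed_confusion():
    # TP=1 FN=1 TN=1 FP=1 -> ACC 0.5, Sen 0.5, Spe 0.5, MCC 0
    y = np.array([1, 1, 0, 0])
    p = np.array([0.9, 0.1, 0.8, 0.2])
    m = classification_metrics(y, p)
    assert m["ACC"] == 0.5
    assert m["Sen"] == 0.5
    assert m["Spe"] == 0.5
    assert m["MCC"] == pytest.approx(0.0)


def test_single_class_labels_give_nan_with_warning():
    y = np.ones(4, dtype=int)
    p = np.array([0.9, 0.8, 0.7, 0.6])
    with pytest.warns(UserWarning):
        m = classification_metrics(y, p)
    assert np.isnan(m["AUC"])
    assert np.isnan(m["MCC"])


# -------------------------------------------------------------- oversampling


def _imbalanced_fixture(n=400, frac=0.2, seed=0, dim=32):
    rng = np.random.default_rng(seed)
    n_min = int(n * frac)
    X_maj = (rng.random((n - n_min, dim)) < 0.3).astype(float)
    X_min = (rng.random((n_min, dim)) < 0.7).astype(float)
    X = np.vstack([X_maj, X_min])
    y = np.concatenate([np.zeros(n - n_min, int), np.ones(n_min, int)])
    return X, y


@pytest.mark.parametrize("method", ["smote", "adasyn"])
def test_oversample_balances_within_one_sample(method):
    X, y = _imbalanced_fixture()
    Xo, yo = oversample(X, y, OversampleSpec(method, seed=1))
    counts = np.bincount(yo)
    assert abs(counts[0] - counts[1]) <= 1
    # originals preserved verbatim, synthetics appended
    assert np.array_equal(Xo[:len(X)], X)
    assert np.array_equal(yo[:len(y)], y)


def _segment_endpoints(s, minority_rows):
    """Reconstruct the two binary endpoints of a SMOTE segment, if any."""
    frac = s - np.floor(s)
    frac_vals = np.unique(np.round(frac[(frac > 1e-12) & (frac < 1 - 1e-12)], 9))
    rows = {r.tobytes() for r in minority_rows}
    if len(frac_vals) == 0:  # degenerate: synthetic equals a minority point
        r = s.round()
        return (r, r) if r.tobytes() in rows else None
    for lam in (frac_vals[0], 1.0 - frac_vals[0]):
        x = np.where(np.abs(frac) < 1e-9, s, np.where(
            np.abs(frac - lam) < 1e-9, 0.0, 1.0))
        yv = np.where(np.abs(frac) < 1e-9, s, 1.0 - x)
        if x.tobytes() in rows and yv.tobytes() in rows:
            return x, yv
    return None


def test_smote_synthetics_lie_on_minority_segments():
    X, y = _imbalanced_fixture()
    spec = OversampleSpec("smote", seed=3)
    Xo, yo = oversample(X, y, spec)
    minority = X[y == 1]
    synth = Xo[len(X):]
    assert len(synth) > 0
    for s in synth:
        endpoints = _segment_endpoints(s, minority)
        assert endpoints is not None, "synthetic off every minority segment"
        x, yv = endpoints
        assert np.all(np.minimum(x, yv) - 1e-9 <= s)
        assert np.all(s <= np.maximum(x, yv) + 1e-9)


def test_oversample_noop_when_balanced():
    X, y = _imbalanced_fixture(n=100, frac=0.5)
    Xo, yo = oversample(X, y, OversampleSpec("smote", seed=0))
    assert np.array_equal(Xo, X)
    assert np.array_equal(yo, y)


def test_oversample_rejects_single_class_and_big_k():
    X, y = _imbalanced_fixture()
    with pytest.raises(ValueError):
        oversample(X, np.zeros(len(y), int), OversampleSpec("smote"))
    with pytest.raises(ValueError):
        oversample(X[:30], y[:30], OversampleSpec("smote", k_neighbors=40))


def test_adasyn_allocates_more_synthetics_near_majority():
    """Minority points surrounded by majority get more synthetic neighbours."""
    rng = np.random.default_rng(5)
    # cluster A: isolated minority; cluster B: minority inside majority cloud
    A = rng.normal(0, 0.1, (10, 4))
    B = rng.normal(5, 0.1, (10, 4))
    maj = rng.normal(5, 0.5, (80, 4))
    X = np.vstack([A, B, maj])
    y = np.array([1] * 20 + [0] * 80)
    Xo, yo = oversample(X, y, OversampleSpec("adasyn", k_neighbors=5, seed=2))
    synth = Xo[len(X):]
    near_b = np.abs(synth - 5).max(axis=1) < 2
    assert near_b.mean() > 0.8


# ----------------------------------------------------------- cross-validation


def _linear_trainer(X_tr, y_tr, seed):
    from sklearn.linear_model import Ridge
    model = Ridge().fit(np.asarray(X_tr), y_tr)
    return model.predict


def test_crossvalidate_partitions_and_determinism():
    rng = np.random.default_rng(0)
    X = rng.random((100, 5))
    y = X @ np.arange(5) + 0.01 * rng.standard_normal(100)
    rep1 = crossvalidate(_linear_trainer, X, y, regression_metrics,
                         folds=5, seed=4)
    rep2 = crossvalidate(_linear_trainer, X, y, regression_metrics,
                         folds=5, seed=4)
    all_val = np.concatenate(rep1.fold_indices)
    assert len(all_val) == len(set(all_val)) == rep1.n_dev  # exact partition
    assert rep1.n_dev + rep1.n_test == 100
    assert [list(f) for f in rep1.fold_indices] == \
        [list(f) for f in rep2.fold_indices]
    assert rep1.per_fold == rep2.per_fold
    # easy task: fold-to-fold variance is small
    q2 = [f["Q2"] for f in rep1.per_fold]
    assert np.var(q2) < 0.05


def test_crossvalidate_rejects_too_many_folds():
    with pytest.raises(ValueError):
        crossvalidate(_linear_trainer, np.zeros((3, 2)), np.zeros(3),
                      regression_metrics, folds=10)


# ------------------------------------------------------------- QSAR training


def test_affinity_constant_labels():
    corpus = fx.make_corpus(fx.FixtureSpec(60, seed=2))
    model = train_affinity(corpus, np.full(len(corpus), 7.25),
                           AffinityConfig(max_epochs=150), seed=0)
    preds = model.predict(corpus[:10])
    assert np.all(np.abs(preds - 7.25) < 0.1)


def test_affinity_requires_min_examples():
    with pytest.raises(ValueError, match=">= 20"):
        train_affinity(["CCO"] * 5, np.ones(5))


def test_affinity_prediction_deterministic_and_finite(fixture_corpus):
    corpus = fixture_corpus[:200]
    y = np.array([fx.mock_affinity_oracle(s) for s in corpus])
    model = train_affinity(corpus, y, AffinityConfig(max_epochs=60), seed=1)
    a = model.predict("c1ccccc1CCO")
    b = model.predict("c1ccccc1CCO")
    assert a == b
    assert np.isfinite(a)


def test_bbb_rejects_single_class():
    X = np.zeros((30, 16))
    with pytest.raises(ValueError):
        train_bbb(X, np.zeros(30, int), OversampleSpec("smote"))


def test_bbb_probability_range_and_fp_invariance(fixture_corpus):
    sm, X, y, _ = fx.make_imbalanced_dataset(600, 0.25, seed=9)
    cfg = BBBConfig(hidden_layers=(32,), max_epochs=40)
    model = train_bbb(X, y, OversampleSpec("smote", seed=0), cfg, seed=0)
    p = model.predict_proba_fp(X[:200])
    assert np.all((p >= 0) & (p <= 1))
    # permuted-atom SMILES of the same molecule predict identically
    from rdkit import Chem
    s = fixture_corpus[0]
    alt = Chem.MolToSmiles(Chem.MolFromSmiles(s), doRandom=True)
    assert model.predict(s) == pytest.approx(model.predict(alt), abs=1e-12)


def test_no_synthetic_points_reach_validation_folds():
    """Oversampling inside the trainer leaves fold data binary originals."""
    sm, X, y, _ = fx.make_imbalanced_dataset(400, 0.25, seed=4)
    original_rows = {r.tobytes() for r in X.astype(np.float64)}
    seen_val_rows = []

    def trainer(X_tr, y_tr, seed):
        Xo, yo = oversample(np.asarray(X_tr, float), y_tr,
                            OversampleSpec("smote", seed=seed))
        from sklearn.linear_model import LogisticRegression
        model = LogisticRegression(max_iter=200).fit(Xo, yo)

        def predict(X_va):
            seen_val_rows.extend(np.asarray(X_va, float))
            return model.predict_proba(X_va)[:, 1]
        return predict

    crossvalidate(trainer, X, y, classification_metrics, folds=4, seed=0,
                  stratify=True)
    assert len(seen_val_rows) > 0
    for row in seen_val_rows:
        assert row.tobytes() in original_rows
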