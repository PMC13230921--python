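"""Metric oracles: confusion tables, Mann–Whitney AUC, FID closed forms,
overlap coefficient, subgroup tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentmix.classify import PredictionSet
from latentmix.errors import ValidationError
from latentmix.evaluate import (
    RandomProjectionFeatures,
    confusion_metrics,
    embed_features,
    frechet_distance,
    latent_overlap,
    pooled_auc,
    roc_auc,
    subgroup_metrics,
)


# -- confusion metrics ------------------------------------------------------


def test_confusion_perfect_predictions():
    cm, m = confusion_metrics([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
    assert m["accuracy"] == m["recall"] == m["specificity"] == 1.0
    assert cm.tolist() == [[2, 0], [0, 2]]


def test_confusion_hand_counted_case():
    """labels (1,1,0,0), preds (1,0,0,0): recall .5, spec 1, prec 1, F1 2/3."""
    cm, m = confusion_metrics([1, 1, 0, 0], [0.9, 0.1, 0.2, 0.3])
    assert m["recall"] == pytest.approx(0.5)
    assert m["specificity"] == pytest.approx(1.0)
    assert m["precision"] == pytest.approx(1.0)
    assert m["F1"] == pytest.approx(2 / 3)


def test_confusion_all_negative_precision_missing():
    _, m = confusion_metrics([1, 0, 0], [0.1, 0.2, 0.3])
    assert m["precision"] is None
    assert m["specificity"] == 1.0


def test_confusion_multiclass_macro():
    scores = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8], [0.8, 0.1, 0.1]])
    truth = ["a", "b", "c", "b"]
    cm, m = confusion_metrics(truth, scores, classes=("a", "b", "c"))
    assert m["accuracy"] == pytest.approx(0.75)
    assert cm.sum() == 4


# -- ROC AUC ----------------------------------------------------------------


def brute_force_auc(labels, scores):
    """Independent Mann–Whitney pair count with half-weight ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def test_roc_auc_examples():
    assert roc_auc([1, 0], [0.9, 0.1]) == 1.0
    assert roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5
    assert roc_auc([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2]) == pytest.approx(0.75)
    with pytest.raises(ValidationError):
        roc_auc([1, 1], [0.5, 0.6])


def test_roc_auc_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(99)
    for _ in range(50):
        n = int(rng.integers(4, 31))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
        assert roc_auc(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores), abs=1e-12
        )


def test_roc_auc_complement_symmetry():
    rng = np.random.default_rng(7)
    labels = np.array([1, 0, 1, 0, 1, 0, 0, 1])
    scores = rng.uniform(size=8)  # continuous: no ties
    assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)


def test_pooled_auc_properties():
    rng = np.random.default_rng(5)
    folds = []
    for _ in range(5):
        labels = rng.integers(0, 2, 12)
        if labels.sum() in (0, 12):
            labels[0] = 1 - labels[0]
        folds.append((labels, rng.uniform(size=12)))
    pooled = pooled_auc(folds)
    all_labels = np.concatenate([f[0] for f in folds])
    all_scores = np.concatenate([f[1] for f in folds])
    assert pooled == pytest.approx(brute_force_auc(all_labels, all_scores), abs=1e-12)
    # single fold identity, duplication invariance, order invariance
    assert pooled_auc(folds[:1]) == pytest.approx(roc_auc(*folds[0]))
    assert pooled_auc([folds[0], folds[0]]) == pytest.approx(roc_auc(*folds[0]))
    assert pooled_auc(folds[::-1]) == pytest.approx(pooled)


# -- FID --------------------------------------------------------------------


def test_fid_identical_sets_zero():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(40, 6))
    assert abs(frechet_distance(x, x).fid) < 1e-6


def test_fid_one_dimensional_closed_forms():
    """(0,1) vs (1,1) -> 1; (0,1) vs (0,4) -> 1, at population parameters."""
    a = np.array([[-1.0], [1.0]])         # mean 0, population var 1
    b = np.array([[0.0], [2.0]])          # mean 1, population var 1
    c = np.array([[-2.0], [2.0]])         # mean 0, population var 4
    assert frechet_distance(a, b, population=True).fid == pytest.approx(1.0, abs=1e-6)
    assert frechet_distance(a, c, population=True).fid == pytest.approx(1.0, abs=1e-6)


def test_fid_symmetry_and_quadratic_scaling():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(60, 5))
    y = rng.normal(loc=0.5, size=(50, 5))
    fxy = frechet_distance(x, y).fid
    fyx = frechet_distance(y, x).fid
    assert fxy == pytest.approx(fyx, abs=1e-6)
    c = 3.0
    scaled = frechet_distance(c * x, c * y).fid
    assert scaled == pytest.approx(c**2 * fxy, rel=1e-6)
    assert fxy >= -1e-8


def test_fid_validation():
    with pytest.raises(ValidationError):
        frechet_distance(np.zeros((1, 3)), np.zeros((5, 3)))
    with pytest.raises(ValidationError):
        frechet_distance(np.zeros((5, 3)), np.zeros((5, 4)))
    bad = np.zeros((5, 3))
    bad[0, 0] = np.nan
    with pytest.raises(ValidationError):
        frechet_distance(bad, np.zeros((5, 3)))


def test_feature_extractor_deterministic(phantom_cohort):
    extractor = RandomProjectionFeatures(image_side=64, seed=1234)
    images = np.stack([r.image for r in phantom_cohort.records[:6]])
    f1 = embed_features(images, extractor)
    f2 = embed_features(images, RandomProjectionFeatures(image_side=64, seed=1234))
    assert f1.shape[0] == 6
    np.testing.assert_array_equal(f1, f2)
    np.testing.assert_array_equal(f1[0], embed_features(images[:1], extractor)[0])


# -- latent overlap ---------------------------------------------------------


def test_overlap_identity_and_disjoint():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(200, 4))
    assert latent_overlap(x, x).overlap == pytest.approx(1.0)
    y = x + 1000.0
    assert latent_overlap(x, y).overlap == pytest.approx(0.0)


def test_overlap_matches_brute_force_histogram():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(300, 3))
    y = rng.normal(loc=0.8, size=(250, 3))
    res = latent_overlap(x, y, n_bins=32)
    # independent recomputation: PCA axis via numpy SVD, histogram min-sum
    center = x.mean(axis=0)
    _, _, vt = np.linalg.svd(x - center, full_matrices=False)
    axis = vt[0]
    px, py = (x - center) @ axis, (y - center) @ axis
    # eigh and SVD may disagree on sign; overlap is sign-invariant
    lo, hi = min(px.min(), py.min()), max(px.max(), py.max())
    edges = np.linspace(lo, hi, 33)
    p, _ = np.histogram(px, bins=edges)
    q, _ = np.histogram(py, bins=edges)
    brute = np.minimum(p / p.sum(), q / q.sum()).sum()
    assert res.overlap == pytest.approx(brute, abs=1e-12)
    assert 0.0 <= res.overlap <= 1.0


def test_overlap_rejects_degenerate_real_set():
    with pytest.raises(ValidationError):
        latent_overlap(np.zeros((10, 3)), np.random.default_rng(0).normal(size=(10, 3)))


# -- subgroups --------------------------------------------------------------


def _predset(truth, pred_labels, classes=("autosomal", "x_linked")):
    scores = np.array(
        [[0.9, 0.1] if p == classes[0] else [0.1, 0.9] for p in pred_labels]
    )
    return PredictionSet(
        record_ids=[f"r{i}" for i in range(len(truth))],
        true_labels=list(truth),
        scores=scores,
        classes=classes,
        positive_class=classes[1],
    )


def test_subgroup_hand_counted_bin():
    """6 records in one bin with one false positive: precision from the 2x2 table."""
    truth = ["autosomal"] * 3 + ["x_linked"] * 3
    pred = ["autosomal", "autosomal", "x_linked", "x_linked", "x_linked", "x_linked"]
    ps = _predset(truth, pred)
    ages = {f"r{i}": 15.0 for i in range(6)}
    rows = subgroup_metrics(ps, ages, age_bins=((10, 20),))
    by_class = {r["class"]: r for r in rows}
    # x_linked: TP=3, FP=1 -> precision 0.75; F1 = 2*.75*1/(1.75)
    assert by_class["x_linked"]["precision"] == pytest.approx(0.75)
    assert by_class["x_linked"]["F1"] == pytest.approx(2 * 0.75 / 1.75)
    assert by_class["autosomal"]["precision"] == pytest.approx(1.0)
    assert not by_class["x_linked"]["single_class"]


def test_subgroup_single_class_bin_flagged_and_empty_omitted():
    truth = ["x_linked"] * 4
    ps = _predset(truth, truth)
    ages = {"r0": 12, "r1": 14, "r2": 15, "r3": 18}
    with pytest.warns(UserWarning):
        rows = subgroup_metrics(ps, ages, age_bins=((10, 20), (50, 60)))
    assert all(r["age_bin"] == [10, 20] for r in rows)
    assert all(r["single_class"] for r in rows)


def test_default_bins_match_study_ranges():
    from latentmix.evaluate import DEFAULT_AGE_BINS

    assert DEFAULT_AGE_BINS == ((10.0, 20.0), (50.0, 60.0))
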