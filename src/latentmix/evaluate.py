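"""Evaluation metrics: confusion-derived scores, per-fold and pooled ROC AUC,
Fréchet distance between feature distributions, latent-density overlap, and
age-binned subgroup tables.

Pooled AUC follows the protocol of concatenating all out-of-fold labels and
scores across resamples and computing a single ROC AUC on the pooled vector.
The default FID feature extractor is a fixed-seed random convolutional
projection: absolute values are not comparable across extractors (in
particular not to published ImageNet-feature FIDs) — only rankings within
one run are meaningful. Any object mapping an image batch to fixed-length
feature rows can be plugged in instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .errors import ValidationError
from .nn import Tensor

DEFAULT_AGE_BINS = ((10.0, 20.0), (50.0, 60.0))


@dataclass
class FIDResult:
    fid: float
    extractor_id: str
    n_real: int
    n_synthetic: int
    feature_dim: int


@dataclass
class OverlapResult:
    overlap: float  # in [0, 1]
    projection: str
    n_real: int
    n_synthetic: int
    n_bins: int


@dataclass
class MetricsReport:
    """Per-fold metrics, their mean ± SD, and the pooled AUC, for one arm."""

    arm: str
    positive_class: str
    per_fold: list[dict[str, float | None]] = field(default_factory=list)
    confusions: list[list[list[int]]] = field(default_factory=list)
    pooled_auc: float | None = None
    subgroups: list[dict] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)

    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        if not self.per_fold:
            return out
        for key in self.per_fold[0]:
            vals = [f[key] for f in self.per_fold if f[key] is not None]
            if vals:
                out[key] = (float(np.mean(vals)), float(np.std(vals, ddof=0)))
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        blob = {
            "arm": self.arm,
            "positive_class": self.positive_class,
            "per_fold": self.per_fold,
            "confusion_matrices": self.confusions,
            "summary": {k: {"mean": m, "sd": s} for k, (m, s) in self.summary().items()},
            "pooled_auc": self.pooled_auc,
            "subgroups": self.subgroups,
            "seeds": self.seeds,
        }
        text = json.dumps(blob, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def confusion_metrics(
    true_labels, scores, threshold: float = 0.5, classes: tuple[str, ...] | None = None
) -> tuple[np.ndarray, dict[str, float | None]]:
    """Confusion matrix plus accuracy/recall/specificity/precision/F1.

    Binary: ``scores`` is a vector of positive-class probabilities,
    thresholded at ``threshold``; labels are 0/1 with 1 = positive.
    Multiclass: ``scores`` is an (n, k) matrix, argmax rule, and recall/
    specificity/precision/F1 are macro-averaged one-vs-rest.
    Ratios with zero denominator are reported as None (missing), never 0.
    """
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true_labels)
    if scores.ndim == 1:
        if not (0.0 <= threshold <= 1.0):
            raise ValidationError("threshold must be in [0, 1]")
        pred = (scores >= threshold).astype(int)
        truth = true.astype(int)
        cm = _sk_confusion(truth, pred, labels=[0, 1])
        tn, fp, fn, tp = cm.ravel()
        metrics = {
            "accuracy": (tp + tn) / cm.sum(),
            "recall": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
            "precision": _ratio(tp, tp + fp),
        }
        metrics["F1"] = _f1(metrics["precision"], metrics["recall"])
        return cm, metrics
    if len(true) != scores.shape[0]:
        raise ValidationError("label/score length mismatch")
    k = scores.shape[1]
    label_set = list(classes) if classes is not None else sorted(set(true))
    idx = {c: i for i, c in enumerate(label_set)}
    truth = np.array([idx[t] for t in true])
    pred = scores.argmax(axis=1)
    cm = _sk_confusion(truth, pred, labels=list(range(k)))
    per_class = []
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = cm.sum() - tp - fn - fp
        rec, spec, prec = _ratio(tp, tp + fn), _ratio(tn, tn + fp), _ratio(tp, tp + fp)
        per_class.append({"recall": rec, "specificity": spec, "precision": prec, "F1": _f1(prec, rec)})
    metrics: dict[str, float | None] = {"accuracy": float(np.trace(cm) / cm.sum())}
    for key in ("recall", "specificity", "precision", "F1"):
        vals = [pc[key] for pc in per_class if pc[key] is not None]
        metrics[key] = float(np.mean(vals)) if vals else None
    return cm, metrics


def _ratio(num, den) -> float | None:
    return float(num / den) if den > 0 else None


def _f1(precision, recall) -> float | None:
    if precision is None or recall is None or (precision + recall) == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def roc_auc(true_labels, positive_scores) -> float:
    """ROC AUC = Mann–Whitney U / (n+ · n−), ties counted one half."""
    truth = np.asarray(true_labels).astype(int)
    if len(set(truth.tolist())) < 2:
        raise ValidationError("roc_auc requires both classes present")
    return float(roc_auc_score(truth, np.asarray(positive_scores, dtype=float)))


def pooled_auc(folds: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Concatenate out-of-fold (labels, scores) across folds, then one ROC AUC."""
    if not folds:
        raise ValidationError("pooled_auc needs at least one fold")
    labels = np.concatenate([np.asarray(lab) for lab, _ in folds])
    scores = np.concatenate([np.asarray(sc) for _, sc in folds])
    return roc_auc(labels, scores)


class RandomProjectionFeatures:
    """Fixed-seed random convolutional feature extractor for FID.

    An untrained strided conv stack with fixed Gaussian weights followed by
    spatial mean and SD pooling per channel. Deterministic given seed.
    """

    def __init__(self, image_side: int = 64, seed: int = 1234, widths=(8, 16, 32)):
        from .nn import Conv2d

        self.image_side = image_side
        self.seed = seed
        rng = np.random.default_rng(seed)
        chans = (3,) + tuple(widths)
        self.convs = [Conv2d(chans[i], chans[i + 1], rng, stride=2, pad=1) for i in range(len(widths))]
        self.extractor_id = f"random-conv-proj-s{seed}-w{'x'.join(map(str, widths))}"

    def __call__(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.shape[1] != self.image_side:
            raise ValidationError(
                f"extractor expects side {self.image_side}, got {images.shape[1]}"
            )
        h = Tensor(images)
        feats = []
        for conv in self.convs:
            h = conv(h).relu()
            feats.append(h.data.mean(axis=(1, 2)))
        feats.append(h.data.std(axis=(1, 2)))
        return np.concatenate(feats, axis=1)


def embed_features(images, extractor) -> np.ndarray:
    """Feature matrix (one row per image) under a pluggable extractor."""
    images = np.asarray(images, dtype=np.float64)
    out = []
    for start in range(0, len(images), 64):
        rows = extractor(images[start : start + 64])
        out.append(np.asarray(rows, dtype=np.float64))
    feats = np.concatenate(out, axis=0)
    if feats.ndim != 2 or feats.shape[0] != len(images):
        raise ValidationError("extractor must return one feature row per image")
    return feats


def _sqrtm_psd(mat: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition; eigenvalues floored at 0."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(
    features_real: np.ndarray,
    features_syn: np.ndarray,
    extractor_id: str = "custom",
    population: bool = False,
) -> FIDResult:
    """Fréchet distance between Gaussian fits of two feature sets.

    FID = ||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2}), with sample means
    and (n-1)-denominator covariances (``population=True`` switches to n, for
    analytic fixtures). The cross trace uses the symmetric reformulation
    Tr((S1^{1/2} S2 S1^{1/2})^{1/2}).
    """
    a = np.asarray(features_real, dtype=np.float64)
    b = np.asarray(features_syn, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValidationError("feature matrices must be 2-D with equal column count")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("need at least 2 rows per feature set")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("non-finite features")
    ddof = 0 if population else 1
    mu1, mu2 = a.mean(axis=0), b.mean(axis=0)
    s1 = np.cov(a, rowvar=False, ddof=ddof)
    s2 = np.cov(b, rowvar=False, ddof=ddof)
    s1 = np.atleast_2d(s1)
    s2 = np.atleast_2d(s2)
    root_s1 = _sqrtm_psd(s1)
    cross = _sqrtm_psd(root_s1 @ s2 @ root_s1)
    fid = float(np.sum((mu1 - mu2) ** 2) + np.trace(s1 + s2 - 2.0 * cross))
    return FIDResult(
        fid=fid,
        extractor_id=extractor_id,
        n_real=a.shape[0],
        n_synthetic=b.shape[0],
        feature_dim=a.shape[1],
    )


def latent_overlap(z_real: np.ndarray, z_syn: np.ndarray, n_bins: int = 32) -> OverlapResult:
    """Histogram overlap of both sets projected on the real set's first PC.

    Overlap coefficient = sum_i min(p_i, q_i) over shared bins spanning the
    pooled projected range; 1 for identical sets, 0 for disjoint supports.
    """
    zr = np.asarray(z_real, dtype=np.float64)
    zs = np.asarray(z_syn, dtype=np.float64)
    if zr.ndim != 2 or zs.ndim != 2 or zr.shape[1] != zs.shape[1]:
        raise ValidationError("latent matrices must share dimension")
    center = zr.mean(axis=0)
    xc = zr - center
    cov = xc.T @ xc
    if not np.any(cov):
        raise ValidationError("real latent set has zero variance")
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    pr = (zr - center) @ axis
    ps = (zs - center) @ axis
    lo = min(pr.min(), ps.min())
    hi = max(pr.max(), ps.max())
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(pr, bins=edges)
    q, _ = np.histogram(ps, bins=edges)
    overlap = float(np.minimum(p / p.sum(), q / q.sum()).sum())
    return OverlapResult(
        overlap=overlap,
        projection="first-principal-axis-of-real",
        n_real=zr.shape[0],
        n_synthetic=zs.shape[0],
        n_bins=n_bins,
    )


def subgroup_metrics(
    prediction_set, ages: dict[str, float | None], age_bins=DEFAULT_AGE_BINS
) -> list[dict]:
    """Per-class precision and F1 restricted to each age bin [lo, hi).

    Bins containing a single true class are flagged (``single_class=True``)
    rather than reported as silently perfect; empty bins are omitted with a
    warning.
    """
    rows = []
    truth = np.asarray(prediction_set.true_labels)
    pred_idx = np.asarray(prediction_set.scores).argmax(axis=1)
    pred = np.array([prediction_set.classes[i] for i in pred_idx])
    for lo, hi in age_bins:
        mask = np.array(
            [
                ages.get(rid) is not None and lo <= ages[rid] < hi
                for rid in prediction_set.record_ids
            ]
        )
        if not mask.any():
            warnings.warn(f"age bin [{lo}, {hi}) is empty; omitted", stacklevel=2)
            continue
        t, p = truth[mask], pred[mask]
        single = len(set(t.tolist())) < 2
        for cls in prediction_set.classes:
            tp = int(((t == cls) & (p == cls)).sum())
            fp = int(((t != cls) & (p == cls)).sum())
            fn = int(((t == cls) & (p != cls)).sum())
            prec = _ratio(tp, tp + fp)
            rec = _ratio(tp, tp + fn)
            rows.append(
                {
                    "age_bin": [lo, hi],
                    "class": cls,
                    "n": int((t == cls).sum()),
                    "precision": prec,
                    "F1": _f1(prec, rec),
                    "single_class": bool(single),
                }
            )
    return rows
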