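"""Experiment orchestration: arms × resamples with leakage-safe plumbing.

One experiment fixes a cohort (real or phantom), a label scheme, and a list
of arms (expansion scheme or none, classifier architecture). Per resample it

1. draws a patient-grouped stratified train/test split,
2. balances classes on the train side by patient-preserving undersampling,
3. trains the codec (VAE) on that resample's real training images only,
4. runs the arm's expansion and attaches synthetics to the train pool,
5. trains the classifier and scores the untouched real test images.

Metrics are aggregated per arm: per-fold confusion metrics and AUC, their
mean ± SD, and the pooled AUC over concatenated out-of-fold predictions.
Every stage draws its seed deterministically from the master seed, so a rerun
with the same config reproduces the report bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import ClassifierConfig, predict_scores, train_classifier
from .data_model import (
    Cohort,
    SplitPlan,
    balance_classes,
    load_cohort,
    map_labels,
    normalize_laterality,
    repeated_resampling_folds,
)
from .errors import ValidationError
from .evaluate import (
    MetricsReport,
    RandomProjectionFeatures,
    confusion_metrics,
    embed_features,
    frechet_distance,
    latent_overlap,
    pooled_auc,
    roc_auc,
    subgroup_metrics,
)
from .expansion import (
    ExpansionConfig,
    SyntheticProvenance,
    attach_synthetic,
    gen1_expand,
    gen2_expand,
)
from .phantom import PhantomConfig, generate_phantom_cohort
from .vae_core import GeneratorConfig, VAEConfig, sample_dcgan, train_dcgan, train_vae


def derive_seed(master: int, *tags) -> int:
    """Stable sub-seed < 2^31 from a master seed and a tag path."""
    key = f"{master}:" + "/".join(map(str, tags))
    return int(hashlib.sha256(key.encode()).hexdigest()[:8], 16) % (2**31 - 1)


@dataclass
class ExperimentConfig:
    phantom: PhantomConfig | None = None
    cohort_path: str | None = None
    label_scheme: str = "binary"
    arms: tuple[tuple[str | None, str], ...] = ((None, "conv_residual"), ("gen2", "conv_residual"))
    k: int = 5
    train_fraction: float = 0.8
    vae: VAEConfig = field(default_factory=VAEConfig)
    expansion: ExpansionConfig = field(default_factory=ExpansionConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    gan: GeneratorConfig = field(default_factory=GeneratorConfig)
    master_seed: int = 0

    def __post_init__(self):
        if self.phantom is None and self.cohort_path is None:
            raise ValidationError("need a phantom config or a cohort path")


def _arm_name(scheme: str | None, arch: str) -> str:
    return f"{scheme or 'base'}+{arch}"


def _load_experiment_cohort(config: ExperimentConfig) -> Cohort:
    if config.phantom is not None:
        cohort = generate_phantom_cohort(config.phantom)
    else:
        cohort = load_cohort(config.cohort_path, image_side=config.classifier.image_side)
    cohort = Cohort([normalize_laterality(r) for r in cohort.records], cohort.label_scheme)
    return map_labels(cohort, config.label_scheme)


def _restrict_plan(plan: SplitPlan, kept_train: set[str]) -> SplitPlan:
    assignments = {
        pid: side
        for pid, side in plan.assignments.items()
        if side == "test" or pid in kept_train
    }
    return SplitPlan(assignments, plan.seed, plan.train_fraction)


def _gan_synthetics(train_records, gan_config: GeneratorConfig, seed: int):
    """Per class: train a DCGAN on that class's reals and sample one synthetic
    per real image (two-fold expansion parity with gen1)."""
    from dataclasses import replace as _replace

    from .data_model import ImageRecord

    synthetics = []
    by_label: dict[str, list] = {}
    for rec in train_records:
        by_label.setdefault(rec.label, []).append(rec)
    for label in sorted(by_label):
        recs = by_label[label]
        if len(recs) < 2:
            warnings.warn(f"class {label} has n<2 reals; GAN arm skips it", stacklevel=2)
            continue
        cfg = _replace(gan_config, seed=derive_seed(seed, "gan", label))
        gen, _ = train_dcgan(recs, cfg)
        images = sample_dcgan(gen, len(recs), derive_seed(seed, "gan-sample", label))
        for i, img in enumerate(images):
            proto = recs[i % len(recs)]
            synthetics.append(
                ImageRecord(
                    image=np.clip(img, 0, 1),
                    patient_id=proto.patient_id,
                    eye=proto.eye,
                    label=label,
                    acquisition_date=proto.acquisition_date,
                    is_synthetic=True,
                    provenance=SyntheticProvenance(
                        scheme="gan", parent_ids=(), seed=cfg.seed
                    ),
                    record_id=f"gan_{label}_{i}",
                )
            )
    return synthetics


def _expand_for_arm(scheme, train_records, codec, config: ExperimentConfig, seed: int):
    if scheme is None:
        return []
    if scheme == "gen1":
        from dataclasses import replace as _replace

        return gen1_expand(
            train_records, codec, _replace(config.expansion, scheme="gen1"), seed
        )
    if scheme == "gen2":
        from dataclasses import replace as _replace

        return gen2_expand(
            train_records, codec, _replace(config.expansion, scheme="gen2"), seed
        )
    if scheme == "gan":
        return _gan_synthetics(train_records, config.gan, seed)
    raise ValidationError(f"unknown expansion scheme {scheme!r}")


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    keep_fold0_artifacts: bool = False,
) -> tuple[dict[str, MetricsReport], dict]:
    """Run every arm over k grouped resamples; return reports and a manifest.

    With ``keep_fold0_artifacts`` the manifest carries an in-memory
    ``_fold0`` entry (codec, balanced training records, synthetics per arm)
    so downstream analyses (e.g. latent-overlap comparisons) can reuse the
    first resample's models instead of retraining; the entry is stripped
    before the manifest is written to disk.
    """
    cohort = _load_experiment_cohort(config)
    plans = repeated_resampling_folds(
        cohort, config.k, config.train_fraction, derive_seed(config.master_seed, "split")
    )
    ages = {r.record_id: r.age_years for r in cohort.records}
    arm_folds: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    arm_reports: dict[str, MetricsReport] = {}
    arm_pooled_records: dict[str, list] = {}
    manifest: dict = {
        "master_seed": config.master_seed,
        "k": config.k,
        "arms": [_arm_name(s, a) for s, a in config.arms],
        "resamples": [],
    }
    from dataclasses import replace as _replace

    for fold_idx, plan in enumerate(plans):
        train_real = cohort.subset(plan.train_patients())
        balanced = balance_classes(
            train_real, derive_seed(config.master_seed, "balance", fold_idx)
        )
        plan_eff = _restrict_plan(plan, set(balanced.patients()))
        cohort_eff = Cohort(
            balanced.records + [r for r in cohort.records if plan.side(r.patient_id) == "test"],
            cohort.label_scheme,
        )
        vae_cfg = _replace(config.vae, seed=derive_seed(config.master_seed, "vae", fold_idx))
        codec, vae_trace = train_vae(balanced, vae_cfg)
        if keep_fold0_artifacts and fold_idx == 0:
            manifest["_fold0"] = {"codec": codec, "balanced": balanced, "synthetics": {}}
        fold_entry = {
            "fold": fold_idx,
            "n_train_real": len(balanced),
            "n_test": sum(1 for r in cohort.records if plan.side(r.patient_id) == "test"),
            "vae_final_loss": vae_trace.totals()[-1] if len(vae_trace) else None,
            "arms": {},
        }
        for scheme, arch in config.arms:
            name = _arm_name(scheme, arch)
            synthetics = _expand_for_arm(
                scheme,
                balanced.records,
                codec,
                config,
                derive_seed(config.master_seed, "expand", scheme or "none", fold_idx),
            )
            if keep_fold0_artifacts and fold_idx == 0:
                manifest["_fold0"]["synthetics"][name] = synthetics
            train_pool, test_pool = attach_synthetic(plan_eff, cohort_eff, synthetics)
            clf_cfg = _replace(
                config.classifier,
                arch=arch,
                seed=derive_seed(config.master_seed, "clf", name, fold_idx),
            )
            model, _ = train_classifier(train_pool, clf_cfg)
            preds = predict_scores(model, test_pool)
            if len(model.classes) == 2:
                truth = preds.binary_truth()
                pos = preds.positive_scores()
                cm, metrics = confusion_metrics(truth, pos, threshold=0.5)
                try:
                    metrics["AUC"] = roc_auc(truth, pos)
                except ValidationError:
                    metrics["AUC"] = None
                arm_folds.setdefault(name, []).append((truth, pos))
            else:
                cm, metrics = confusion_metrics(
                    preds.true_labels, preds.scores, classes=model.classes
                )
                onehot = np.array(
                    [
                        [1 if t == c else 0 for c in model.classes]
                        for t in preds.true_labels
                    ]
                )
                arm_folds.setdefault(name, []).append(
                    (onehot.ravel(), preds.scores.ravel())
                )
                try:
                    metrics["AUC"] = roc_auc(onehot.ravel(), preds.scores.ravel())
                except ValidationError:
                    metrics["AUC"] = None
            report = arm_reports.setdefault(
                name,
                MetricsReport(
                    arm=name,
                    positive_class=preds.positive_class,
                    seeds={"master_seed": config.master_seed},
                ),
            )
            report.per_fold.append(metrics)
            report.confusions.append(cm.tolist())
            arm_pooled_records.setdefault(name, []).append(preds)
            fold_entry["arms"][name] = {
                "n_synthetic": len(synthetics),
                "n_train_pool": len(train_pool),
                "classifier_seed": clf_cfg.seed,
            }
        manifest["resamples"].append(fold_entry)
    for name, report in arm_reports.items():
        report.pooled_auc = pooled_auc(arm_folds[name])
        pooled_ids = [rid for p in arm_pooled_records[name] for rid in p.record_ids]
        pooled_truth = [t for p in arm_pooled_records[name] for t in p.true_labels]
        pooled_scores = np.concatenate([p.scores for p in arm_pooled_records[name]])
        merged = type(arm_pooled_records[name][0])(
            record_ids=pooled_ids,
            true_labels=pooled_truth,
            scores=pooled_scores,
            classes=arm_pooled_records[name][0].classes,
            positive_class=report.positive_class,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report.subgroups = subgroup_metrics(merged, ages)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, report in arm_reports.items():
            report.to_json(out_dir / f"report_{name.replace('+', '_')}.json")
        on_disk = {k: v for k, v in manifest.items() if not k.startswith("_")}
        (out_dir / "manifest.json").write_text(json.dumps(on_disk, indent=2, sort_keys=True))
    return arm_reports, manifest


def compare_expansions(
    config: ExperimentConfig, schemes: tuple[str, ...] = ("gen1", "gen2", "gan")
) -> list[dict]:
    """FID and latent overlap per generation arm on one grouped split.

    Returns rows sorted by FID ascending (best-aligned synthetics first).
    """
    if len(schemes) < 2:
        raise ValidationError("need at least 2 generation arms to compare")
    cohort = _load_experiment_cohort(config)
    from .data_model import grouped_split

    plan = grouped_split(
        cohort, config.train_fraction, derive_seed(config.master_seed, "cmp-split")
    )
    train_real = cohort.subset(plan.train_patients())
    balanced = balance_classes(train_real, derive_seed(config.master_seed, "cmp-balance"))
    from dataclasses import replace as _replace

    vae_cfg = _replace(config.vae, seed=derive_seed(config.master_seed, "cmp-vae"))
    codec, _ = train_vae(balanced, vae_cfg)
    extractor = RandomProjectionFeatures(
        image_side=config.vae.image_side, seed=derive_seed(config.master_seed, "fid-extractor")
    )
    real_images = np.stack([r.image for r in balanced.records])
    real_features = embed_features(real_images, extractor)
    real_mu, _ = codec.encode_batch(balanced.records)
    rows = []
    for scheme in schemes:
        synthetics = _expand_for_arm(
            scheme, balanced.records, codec, config, derive_seed(config.master_seed, "cmp", scheme)
        )
        if not synthetics:
            warnings.warn(f"arm {scheme} produced no synthetics; omitted", stacklevel=2)
            continue
        syn_images = np.stack([r.image for r in synthetics])
        fid = frechet_distance(
            real_features,
            embed_features(syn_images, extractor),
            extractor_id=extractor.extractor_id,
        )
        # VAE schemes carry the latent they were decoded from; GAN samples
        # have no VAE-native code and are embedded through the encoder
        if all(s.provenance.latent is not None for s in synthetics):
            syn_mu = np.stack([s.provenance.latent for s in synthetics])
        else:
            syn_mu, _ = codec.encode_batch(synthetics)
        ov = latent_overlap(real_mu, syn_mu)
        rows.append(
            {
                "scheme": scheme,
                "n_synthetic": len(synthetics),
                "fid": fid.fid,
                "latent_overlap": ov.overlap,
                "extractor_id": extractor.extractor_id,
            }
        )
    rows.sort(key=lambda r: r["fid"])
    return rows
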