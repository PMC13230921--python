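"""The package's standard phantom benchmark.

A scaled-down analog of the full study: two classes (autosomal vs X-linked
appearance), 12 phantom patients per class at side 64, a tiny VAE codec, a
conv-residual classifier, and k=5 grouped 80/20 resamples per master seed.
Three arms are compared — no expansion, gen1 noise perturbation, gen2
pairwise mixing (one seeded ratio per pair) — plus a latent-overlap
comparison of gen2 synthetics against DCGAN samples.

Problem sizes here are deliberately small so that the full benchmark (five
master seeds) runs on a single CPU in minutes; they are the package's
reference conditions for direction-of-effect claims, not a reproduction of
any clinical dataset.
"""

from __future__ import annotations

import numpy as np

from .classify import ClassifierConfig
from .evaluate import latent_overlap
from .expansion import ExpansionConfig
from .phantom import PhantomConfig
from .pipeline import (
    ExperimentConfig,
    _gan_synthetics,
    compare_expansions,
    derive_seed,
    run_experiment,
)
from .vae_core import GeneratorConfig, VAEConfig

ARMS = ((None, "conv_residual"), ("gen1", "conv_residual"), ("gen2", "conv_residual"))


def benchmark_config(master_seed: int) -> ExperimentConfig:
    """The frozen benchmark conditions for one master seed."""
    return ExperimentConfig(
        phantom=PhantomConfig(
            n_patients_per_class=12,
            classes=("autosomal", "x_linked"),
            image_side=64,
            effect_size=1.0,
            seed=derive_seed(master_seed, "phantom"),
        ),
        label_scheme="binary",
        arms=ARMS,
        k=5,
        train_fraction=0.8,
        vae=VAEConfig(epochs=100),
        expansion=ExpansionConfig(pair_mode="one_ratio_per_pair"),
        classifier=ClassifierConfig(
            arch="conv_residual", conv_channels=(6, 12, 24), epochs=30,
            learning_rate=1e-3, batch_size=48, crop_scale=(0.9, 1.0),
        ),
        gan=GeneratorConfig(output_side=64, epochs=8),
        master_seed=master_seed,
    )


def run_benchmark(
    base_seed: int, n_master_seeds: int = 5, with_overlap: bool = True
) -> dict:
    """Run the benchmark over several master seeds.

    Returns per-seed pooled AUCs per arm and, optionally, the latent-overlap
    comparison (gen2 vs DCGAN) per seed, plus direction-of-effect tallies.
    The overlap comparison reuses each seed's first-resample codec and gen2
    synthetics; only the DCGAN is trained additionally.
    """
    results: dict = {"seeds": [], "pooled_auc": {}, "overlap": {}}
    arm_names = ["base+conv_residual", "gen1+conv_residual", "gen2+conv_residual"]
    for name in arm_names:
        results["pooled_auc"][name] = []
    for i in range(n_master_seeds):
        master = derive_seed(base_seed, "benchmark", i)
        results["seeds"].append(master)
        cfg = benchmark_config(master)
        reports, manifest = run_experiment(cfg, keep_fold0_artifacts=with_overlap)
        for name in arm_names:
            results["pooled_auc"][name].append(reports[name].pooled_auc)
        if with_overlap:
            fold0 = manifest["_fold0"]
            codec = fold0["codec"]
            balanced = fold0["balanced"]
            real_mu, _ = codec.encode_batch(balanced.records)
            gen2_syn = fold0["synthetics"]["gen2+conv_residual"]
            gen2_mu = np.stack([s.provenance.latent for s in gen2_syn])
            gan_syn = _gan_synthetics(
                balanced.records, cfg.gan, derive_seed(master, "cmp", "gan")
            )
            gan_mu, _ = codec.encode_batch(gan_syn)
            results["overlap"].setdefault("gen2", []).append(
                latent_overlap(real_mu, gen2_mu).overlap
            )
            results["overlap"].setdefault("gan", []).append(
                latent_overlap(real_mu, gan_mu).overlap
            )
    base = np.array(results["pooled_auc"]["base+conv_residual"])
    g1 = np.array(results["pooled_auc"]["gen1+conv_residual"])
    g2 = np.array(results["pooled_auc"]["gen2+conv_residual"])
    results["wins"] = {
        "gen2_vs_base": int((g2 >= base).sum()),
        "gen2_vs_gen1": int((g2 >= g1).sum()),
        "n_seeds": n_master_seeds,
    }
    if with_overlap:
        ov2 = np.array(results["overlap"]["gen2"])
        ovg = np.array(results["overlap"]["gan"])
        results["wins"]["overlap_gen2_vs_gan"] = int((ov2 > ovg).sum())
    return results
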