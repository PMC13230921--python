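"""Latent-space training-set expansion: noise perturbation and pairwise mixing.

Two schemes operate on a trained codec's latent space:

* **gen1** — for every real training image, encode to the posterior mean,
  add one random noise vector (kind drawn from {constant, gaussian, uniform,
  sinusoidal}, strength drawn from a configured range) and decode. One
  synthetic per real image: the training pool exactly doubles.

* **gen2** — within each label class, enumerate every unordered pair of
  training images, linearly mix their latent means ``r·zA + (1−r)·zB`` for
  each ratio in the configured ratio set (or one seeded ratio per pair), and
  decode. All-ratios mode yields ``|R|·C(n,2)`` synthetics per class;
  one-ratio-per-pair yields ``C(n,2)``.

Mixing and perturbation act on the posterior mean (not a sampled z) so that
synthesis is deterministic given the codec weights and the seed. Every
synthetic record carries full provenance back to its real parents, and
:func:`attach_synthetic` refuses — with a hard error — any synthetic whose
parent sits on the test side of a split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .data_model import Cohort, ImageRecord, SplitPlan
from .errors import LeakageError, ValidationError

NOISE_KINDS = ("constant", "gaussian", "uniform", "sinusoidal")
DEFAULT_RATIOS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class ExpansionConfig:
    scheme: str = "gen2"  # gen1 | gen2 | gan
    noise_kinds: tuple[str, ...] = NOISE_KINDS
    strength_range: tuple[float, float] = (0.05, 1.0)
    ratio_set: tuple[float, ...] = DEFAULT_RATIOS
    pair_mode: str = "all_ratios"  # all_ratios | one_ratio_per_pair
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("gen1", "gen2", "gan"):
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "gen1" and not self.noise_kinds:
            raise ValidationError("gen1 requires at least one noise kind")
        for kind in self.noise_kinds:
            if kind not in NOISE_KINDS:
                raise ValidationError(f"unknown noise kind {kind!r}")
        if self.strength_range[0] <= 0:
            raise ValidationError("strength range must be positive")
        if any(not (0 < r < 1) for r in self.ratio_set):
            raise ValidationError("ratios must lie strictly in (0, 1)")
        if self.pair_mode not in ("all_ratios", "one_ratio_per_pair"):
            raise ValidationError(f"unknown pair_mode {self.pair_mode!r}")


@dataclass
class SyntheticProvenance:
    scheme: str
    parent_ids: tuple[str, ...]  # 1 for gen1, 2 for gen2, 0 for gan
    codec_id: str = ""
    seed: int = 0
    noise_kind: str | None = None  # gen1
    strength: float | None = None  # gen1
    ratio: float | None = None  # gen2
    #: latent the image was decoded from (VAE schemes); excluded from equality
    latent: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        expected = {"gen1": 1, "gen2": 2, "gan": 0}[self.scheme]
        if len(self.parent_ids) != expected:
            raise ValidationError(
                f"{self.scheme} provenance needs {expected} parents, got {len(self.parent_ids)}"
            )


def make_noise_vector(kind: str, strength: float, dim: int, seed: int) -> np.ndarray:
    """One latent perturbation vector of the given kind and strength.

    constant: all components equal to ±strength (one shared sign);
    gaussian: strength · N(0, I); uniform: strength · U(−1, 1)^d;
    sinusoidal: component i = strength · sin(2π f i / d + φ) with seeded
    integer frequency f ∈ {1..4} and phase φ ∈ [0, 2π).
    """
    if kind not in NOISE_KINDS:
        raise ValidationError(f"unknown noise kind {kind!r}")
    if strength <= 0:
        raise ValidationError("strength must be > 0")
    rng = np.random.default_rng(seed)
    if kind == "constant":
        sign = rng.choice([-1.0, 1.0])
        return np.full(dim, strength * sign)
    if kind == "gaussian":
        return strength * rng.standard_normal(dim)
    if kind == "uniform":
        return strength * rng.uniform(-1.0, 1.0, size=dim)
    freq = rng.integers(1, 5)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(dim)
    return strength * np.sin(2.0 * np.pi * freq * i / dim + phase)


def _require_real(records) -> None:
    for r in records:
        if r.is_synthetic:
            raise ValidationError(f"record {r.record_id} is synthetic; expansion needs real inputs")


def _codec_id(codec) -> str:
    cfg = getattr(codec, "config", None)
    return f"{type(codec).__name__}-d{getattr(codec, 'latent_dim', '?')}-s{getattr(cfg, 'seed', '?')}"


def _synthetic_record(image: np.ndarray, parent: ImageRecord, provenance: SyntheticProvenance, rid: str) -> ImageRecord:
    return ImageRecord(
        image=np.clip(image, 0.0, 1.0),
        patient_id=parent.patient_id,
        eye=parent.eye,
        label=parent.label,
        acquisition_date=parent.acquisition_date,
        age_years=parent.age_years,
        symptom_duration_years=parent.symptom_duration_years,
        is_synthetic=True,
        provenance=provenance,
        record_id=rid,
    )


def gen1_expand(
    train_records: list[ImageRecord], codec, config: ExpansionConfig, seed: int
) -> list[ImageRecord]:
    """Noise-perturbation expansion: exactly one synthetic per real record."""
    _require_real(train_records)
    rng = np.random.default_rng(seed)
    mus, _ = codec.encode_batch(train_records)
    synthetics: list[ImageRecord] = []
    z_primes = []
    provs = []
    for i, rec in enumerate(train_records):
        kind = str(rng.choice(list(config.noise_kinds)))
        s = float(rng.uniform(*config.strength_range))
        noise_seed = int(rng.integers(0, 2**31 - 1))
        noise = make_noise_vector(kind, s, codec.latent_dim, noise_seed)
        z_prime = mus[i] + noise
        z_primes.append(z_prime)
        provs.append(
            SyntheticProvenance(
                scheme="gen1",
                parent_ids=(rec.record_id,),
                codec_id=_codec_id(codec),
                seed=noise_seed,
                noise_kind=kind,
                strength=s,
                latent=z_prime,
            )
        )
    images = codec.decode_batch(np.stack(z_primes))
    for i, rec in enumerate(train_records):
        synthetics.append(
            _synthetic_record(images[i], rec, provs[i], f"gen1_{rec.record_id}_{i}")
        )
    return synthetics


def enumerate_pairs(records_of_one_label: list[ImageRecord]) -> list[tuple[ImageRecord, ImageRecord]]:
    """All C(n, 2) unordered pairs of same-label real records, sorted by id."""
    _require_real(records_of_one_label)
    labels = {r.label for r in records_of_one_label}
    if len(labels) > 1:
        raise ValidationError(f"mixed labels in pair enumeration: {sorted(labels)}")
    ordered = sorted(records_of_one_label, key=lambda r: r.record_id)
    return list(combinations(ordered, 2))


def mix_latents(za: np.ndarray, zb: np.ndarray, ratio: float) -> np.ndarray:
    """Convex combination r·zA + (1−r)·zB of two latent vectors."""
    za = np.asarray(za, dtype=np.float64)
    zb = np.asarray(zb, dtype=np.float64)
    if za.shape != zb.shape:
        raise ValidationError(f"latent length mismatch: {za.shape} vs {zb.shape}")
    if not (0.0 <= ratio <= 1.0):
        raise ValidationError("ratio must be in [0, 1]")
    return ratio * za + (1.0 - ratio) * zb


def gen2_expand(
    train_records: list[ImageRecord], codec, config: ExpansionConfig, seed: int
) -> list[ImageRecord]:
    """Pairwise combinatorial expansion within each label class."""
    import warnings

    _require_real(train_records)
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[ImageRecord]] = {}
    for rec in train_records:
        by_label.setdefault(rec.label, []).append(rec)
    mus, _ = codec.encode_batch(train_records)
    mu_of = {rec.record_id: mus[i] for i, rec in enumerate(train_records)}
    synthetics: list[ImageRecord] = []
    zs: list[np.ndarray] = []
    meta: list[tuple[ImageRecord, SyntheticProvenance, str]] = []
    for label in sorted(by_label):
        recs = by_label[label]
        if len(recs) < 2:
            warnings.warn(f"class {label} has n<2 training images; skipped by gen2", stacklevel=2)
            continue
        for a, b in enumerate_pairs(recs):
            if config.pair_mode == "all_ratios":
                ratios = config.ratio_set
            else:
                ratios = (float(rng.choice(list(config.ratio_set))),)
            for r in ratios:
                z_mix = mix_latents(mu_of[a.record_id], mu_of[b.record_id], r)
                zs.append(z_mix)
                prov = SyntheticProvenance(
                    scheme="gen2",
                    parent_ids=(a.record_id, b.record_id),
                    codec_id=_codec_id(codec),
                    seed=seed,
                    ratio=float(r),
                    latent=z_mix,
                )
                rid = f"gen2_{a.record_id}+{b.record_id}_r{r:.2f}"
                meta.append((a, prov, rid))
    if zs:
        images = codec.decode_batch(np.stack(zs))
        for img, (parent, prov, rid) in zip(images, meta):
            synthetics.append(_synthetic_record(img, parent, prov, rid))
    return synthetics


def expansion_counts(n: int, ratio_set=DEFAULT_RATIOS) -> dict[str, int]:
    """Closed-form per-class synthetic counts for n real images.

    ``n_by_n`` (ordered incl. self-pairs) is reported alongside the unordered
    C(n,2) count because both conventions circulate for pairwise mixing;
    expansion itself uses unordered pairs without self-pairs.
    """
    pairs = n * (n - 1) // 2
    return {
        "gen1": n,
        "gen2_all_ratios": len(ratio_set) * pairs,
        "gen2_one_ratio_per_pair": pairs,
        "n_by_n": n * n,
    }


def attach_synthetic(
    plan: SplitPlan, cohort: Cohort, synthetics: list[ImageRecord]
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Assemble (train, test) record lists; synthetics join train only.

    Raises :class:`LeakageError` if any synthetic has a parent whose patient
    is on the test side of the plan (or an unresolvable parent).
    """
    record_by_id = {r.record_id: r for r in cohort.records}
    train = [r for r in cohort.records if plan.side(r.patient_id) == "train"]
    test = [r for r in cohort.records if plan.side(r.patient_id) == "test"]
    for syn in synthetics:
        if not syn.is_synthetic or syn.provenance is None:
            raise ValidationError(f"record {syn.record_id} is not a provenance-tracked synthetic")
        for pid in syn.provenance.parent_ids:
            parent = record_by_id.get(pid)
            if parent is None:
                raise LeakageError(f"synthetic {syn.record_id} has unknown parent {pid}")
            if plan.side(parent.patient_id) != "train":
                raise LeakageError(
                    f"synthetic {syn.record_id} derives from test-side patient {parent.patient_id}"
                )
    return train + list(synthetics), test
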