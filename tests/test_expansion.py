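"""Expansion schemes: noise vectors, pair enumeration, mixing algebra,
count laws, provenance and leakage rejection."""

from itertools import combinations

import numpy as np
import pytest

from latentmix.data_model import Cohort, grouped_split
from latentmix.errors import LeakageError, ValidationError
from latentmix.expansion import (
    DEFAULT_RATIOS,
    ExpansionConfig,
    SyntheticProvenance,
    attach_synthetic,
    enumerate_pairs,
    expansion_counts,
    gen1_expand,
    gen2_expand,
    make_noise_vector,
    mix_latents,
)

from conftest import make_record


# -- noise vectors ----------------------------------------------------------


def test_constant_noise_shared_sign():
    v = make_noise_vector("constant", 0.5, 4, seed=1)
    assert np.all(np.abs(v) == 0.5)
    assert len(set(np.sign(v))) == 1


def test_gaussian_noise_sd_matches_strength():
    d = 10_000
    v = make_noise_vector("gaussian", 1.0, d, seed=2)
    se = 1.0 / np.sqrt(2 * (d - 1))  # SE of the sample SD for a normal sample
    assert abs(v.std(ddof=1) - 1.0) < 3 * se


def test_uniform_and_sinusoidal_bounds():
    u = make_noise_vector("uniform", 0.7, 1000, seed=3)
    assert np.all(np.abs(u) <= 0.7)
    for seed in range(5):
        s = make_noise_vector("sinusoidal", 0.3, 64, seed=seed)
        assert np.all(np.abs(s) <= 0.3 + 1e-12)


def test_noise_validation():
    with pytest.raises(ValidationError):
        make_noise_vector("perlin", 1.0, 8, seed=0)
    with pytest.raises(ValidationError):
        make_noise_vector("gaussian", 0.0, 8, seed=0)


# -- gen1 -------------------------------------------------------------------


@pytest.mark.parametrize("n", list(range(2, 11)))
def test_gen1_doubles_training_pool(n, stub_codec):
    records = [make_record("AD", f"p{i}") for i in range(n)]
    cfg = ExpansionConfig(scheme="gen1")
    synthetics = gen1_expand(records, stub_codec, cfg, seed=5)
    assert len(synthetics) == n == expansion_counts(n)["gen1"]
    assert len(records) + len(synthetics) == 2 * n
    for syn in synthetics:
        assert syn.is_synthetic
        assert syn.provenance.scheme == "gen1"
        assert len(syn.provenance.parent_ids) == 1
        assert syn.provenance.noise_kind in cfg.noise_kinds
        assert cfg.strength_range[0] <= syn.provenance.strength <= cfg.strength_range[1]
        assert syn.label == "AD"
        assert syn.image.min() >= 0 and syn.image.max() <= 1


def test_gen1_determinism(stub_codec):
    records = [make_record("AD", f"p{i}", value=0.2 + 0.1 * i) for i in range(4)]
    cfg = ExpansionConfig(scheme="gen1")
    a = gen1_expand(records, stub_codec, cfg, seed=7)
    b = gen1_expand(records, stub_codec, cfg, seed=7)
    for ra, rb in zip(a, b):
        np.testing.assert_array_equal(ra.image, rb.image)
        assert ra.provenance == rb.provenance


def test_gen1_zero_noise_limit(trained_vae, phantom_cohort):
    """With vanishing constant noise the synthetic equals the reconstruction."""
    model, _ = trained_vae
    records = phantom_cohort.records[:3]
    cfg = ExpansionConfig(
        scheme="gen1", noise_kinds=("constant",), strength_range=(1e-6, 1e-6)
    )
    synthetics = gen1_expand(records, model, cfg, seed=1)
    mus, _ = model.encode_batch(records)
    recons = model.decode_batch(mus)
    for syn, recon in zip(synthetics, recons):
        assert np.max(np.abs(syn.image - recon)) < 1e-2


def test_gen1_rejects_synthetic_input(stub_codec):
    records = [make_record("AD", "p0")]
    syn = gen1_expand(records * 2, stub_codec, ExpansionConfig(scheme="gen1"), 0)[0]
    with pytest.raises(ValidationError):
        gen1_expand([syn], stub_codec, ExpansionConfig(scheme="gen1"), 0)


# -- pairs & mixing ---------------------------------------------------------


@pytest.mark.parametrize("n,expected", [(1, 0), (2, 1), (4, 6), (5, 10)])
def test_enumerate_pairs_counts(n, expected):
    records = [make_record("AR", f"p{i}") for i in range(n)]
    pairs = enumerate_pairs(records)
    assert len(pairs) == expected
    brute = set()
    for a, b in combinations([r.record_id for r in records], 2):
        brute.add(frozenset((a, b)))
    assert {frozenset((a.record_id, b.record_id)) for a, b in pairs} == brute
    assert all(a.record_id != b.record_id for a, b in pairs)


def test_enumerate_pairs_rejects_mixed_labels():
    with pytest.raises(ValidationError):
        enumerate_pairs([make_record("AD", "a"), make_record("XR", "b")])


def test_mix_latents_algebra():
    za, zb = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    np.testing.assert_allclose(mix_latents(za, zb, 0.5), [0.5, 0.5])
    np.testing.assert_array_equal(mix_latents(za, zb, 1.0), za)
    np.testing.assert_array_equal(mix_latents(za, zb, 0.0), zb)
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=16), rng.normal(size=16)
    for r in DEFAULT_RATIOS:
        np.testing.assert_allclose(mix_latents(x, y, r), mix_latents(y, x, 1 - r), rtol=1e-12)
    with pytest.raises(ValidationError):
        mix_latents(za, np.zeros(3), 0.5)


# -- gen2 -------------------------------------------------------------------


@pytest.mark.parametrize("n", list(range(2, 11)))
def test_gen2_count_laws(n, stub_codec):
    """|R|·C(n,2) synthetics per class (all_ratios) and C(n,2) (one ratio)."""
    records = [make_record("XR", f"p{i}", value=0.1 + 0.05 * i) for i in range(n)]
    pairs_brute = len(list(combinations(range(n), 2)))
    all_r = gen2_expand(records, stub_codec, ExpansionConfig(scheme="gen2"), seed=1)
    assert len(all_r) == 5 * pairs_brute == expansion_counts(n)["gen2_all_ratios"]
    one_r = gen2_expand(
        records, stub_codec, ExpansionConfig(scheme="gen2", pair_mode="one_ratio_per_pair"), seed=1
    )
    assert len(one_r) == pairs_brute == expansion_counts(n)["gen2_one_ratio_per_pair"]


def test_gen2_two_classes_parents_share_label(stub_codec):
    records = [make_record("AD", f"a{i}", value=0.3) for i in range(3)]
    records += [make_record("XR", f"x{i}", value=0.6) for i in range(3)]
    out = gen2_expand(records, stub_codec, ExpansionConfig(scheme="gen2"), seed=2)
    assert len(out) == 30  # 2 classes x C(3,2) x 5 ratios
    by_id = {r.record_id: r for r in records}
    for syn in out:
        pa, pb = (by_id[p] for p in syn.provenance.parent_ids)
        assert pa.label == pb.label == syn.label
        assert syn.provenance.ratio in DEFAULT_RATIOS


def test_gen2_skips_singleton_class(stub_codec):
    records = [make_record("AD", "a0"), make_record("AD", "a1"), make_record("XR", "x0")]
    with pytest.warns(UserWarning):
        out = gen2_expand(records, stub_codec, ExpansionConfig(scheme="gen2"), seed=0)
    assert all(s.label == "AD" for s in out)
    assert len(out) == 5


def test_gen2_no_self_pairs(stub_codec):
    records = [make_record("AD", f"p{i}") for i in range(4)]
    out = gen2_expand(records, stub_codec, ExpansionConfig(scheme="gen2"), seed=0)
    for syn in out:
        a, b = syn.provenance.parent_ids
        assert a != b


# -- attach / leakage -------------------------------------------------------


def _two_class_cohort(n_per_class=4):
    records = []
    for i in range(n_per_class):
        records.append(make_record("AD", f"a{i}"))
        records.append(make_record("XR", f"x{i}"))
    return Cohort(records)


def test_attach_synthetic_identity_and_invariant(stub_codec):
    cohort = _two_class_cohort()
    plan = grouped_split(cohort, 0.75, seed=0)
    train, test = attach_synthetic(plan, cohort, [])
    assert {r.record_id for r in train}.isdisjoint({r.record_id for r in test})
    assert len(train) + len(test) == len(cohort)
    train_records = [r for r in cohort if plan.side(r.patient_id) == "train"]
    synthetics = gen1_expand(train_records, stub_codec, ExpansionConfig(scheme="gen1"), 3)
    train2, test2 = attach_synthetic(plan, cohort, synthetics)
    assert len(train2) == 2 * len(train_records)
    assert all(not r.is_synthetic for r in test2)


def test_attach_synthetic_rejects_test_side_parent(stub_codec):
    cohort = _two_class_cohort()
    plan = grouped_split(cohort, 0.75, seed=0)
    test_rec = next(r for r in cohort if plan.side(r.patient_id) == "test")
    leaked = gen1_expand([test_rec], stub_codec, ExpansionConfig(scheme="gen1"), 1)
    with pytest.raises(LeakageError):
        attach_synthetic(plan, cohort, leaked)


def test_attach_synthetic_rejects_unknown_parent():
    cohort = _two_class_cohort()
    plan = grouped_split(cohort, 0.75, seed=0)
    orphan = make_record("AD", "a0")
    orphan.is_synthetic = True
    orphan.provenance = SyntheticProvenance(scheme="gen1", parent_ids=("ghost",))
    with pytest.raises(LeakageError):
        attach_synthetic(plan, cohort, [orphan])


def test_no_synthetic_ever_lands_in_test_over_many_seeds(stub_codec):
    """Split + expand + attach over 100 seeds: zero leakage, zero straddling."""
    cohort = _two_class_cohort(5)
    cfg = ExpansionConfig(scheme="gen2", pair_mode="one_ratio_per_pair")
    for seed in range(100):
        plan = grouped_split(cohort, 0.8, seed=seed)
        assert set(plan.train_patients()).isdisjoint(plan.test_patients())
        train_records = [r for r in cohort if plan.side(r.patient_id) == "train"]
        synthetics = gen2_expand(train_records, stub_codec, cfg, seed=seed)
        train, test = attach_synthetic(plan, cohort, synthetics)
        assert not any(r.is_synthetic for r in test)


def test_provenance_parent_count_enforced():
    with pytest.raises(ValidationError):
        SyntheticProvenance(scheme="gen2", parent_ids=("only-one",))
    with pytest.raises(ValidationError):
        SyntheticProvenance(scheme="gan", parent_ids=("a",))
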