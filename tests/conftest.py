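"""Shared fixtures: tiny phantom cohorts and a small trained VAE.

Expensive fixtures are session-scoped; everything is generated in memory or
under tmp paths — no stored test data.
"""

from __future__ import annotations

import numpy as np
import pytest

from latentmix.data_model import Cohort, ImageRecord, normalize_laterality
from latentmix.phantom import PhantomConfig, generate_phantom_cohort
from latentmix.vae_core import VAEConfig, train_vae


@pytest.fixture(scope="session")
def phantom_cohort() -> Cohort:
    """24 laterality-normalised images: 6 patients x 2 eyes x 2 classes, side 64."""
    cohort = generate_phantom_cohort(PhantomConfig(n_patients_per_class=6, seed=42))
    return Cohort([normalize_laterality(r) for r in cohort.records], cohort.label_scheme)


@pytest.fixture(scope="session")
def trained_vae(phantom_cohort):
    """A small VAE trained long enough to reconstruct phantoms recognisably."""
    cfg = VAEConfig(epochs=200, seed=7)
    model, trace = train_vae(phantom_cohort, cfg)
    return model, trace


class StubCodec:
    """Deterministic stand-in codec for count/provenance tests.

    Encodes an image to coarse block means; decodes a latent back to a flat
    image. Implements the same contract as the VAE (encode_batch /
    decode_batch / latent_dim) without any training.
    """

    latent_dim = 12
    image_side = 64

    def encode_batch(self, records):
        mus = []
        for rec in records:
            img = rec.image if hasattr(rec, "image") else np.asarray(rec)
            blocks = img.reshape(4, 16, 4, 16, 3).mean(axis=(1, 3))  # 4x4 block means
            mus.append(blocks.mean(axis=-1).reshape(-1)[: self.latent_dim])
        mus = np.stack(mus)
        return mus, np.zeros_like(mus)

    def decode_batch(self, zs):
        zs = np.asarray(zs)
        n = zs.shape[0]
        vals = 1.0 / (1.0 + np.exp(-zs.mean(axis=1)))
        return np.tile(vals[:, None, None, None], (1, self.image_side, self.image_side, 3))


@pytest.fixture()
def stub_codec() -> StubCodec:
    return StubCodec()


def make_record(
    label: str,
    patient: str,
    eye: str = "OS",
    value: float = 0.5,
    side: int = 64,
    date: str = "2024-01-01",
) -> ImageRecord:
    """Flat-colour record for metadata-level tests."""
    return ImageRecord(
        image=np.full((side, side, 3), value),
        patient_id=patient,
        eye=eye,
        label=label,
        acquisition_date=date,
        record_id=f"{patient}_{eye}_{date}",
    )
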