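"""Synthetic fundus-like cohorts with class-conditional morphology.

The phantom renderer emulates the gross anatomy of a colour fundus
photograph — circular field on black background, optic disc, macula,
branching vessels — plus two degeneration-like features whose class-
conditional distributions are shifted by a controllable effect size:

* peripheral dark speckle (a bone-spicule pigmentation analog), and
* mid-peripheral ring attenuation.

Fellow eyes of one patient share a patient-level latent vector, so their
feature values correlate with strength ``fellow_eye_correlation``. Simulated
ages are drawn class-conditionally (X-linked classes younger) so that
age-confound analyses are possible; age never influences the rendered pixels
except through the class label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import Cohort, ImageRecord, save_cohort
from .errors import ValidationError

#: class-conditional age distributions (mean, SD) in years
_AGE_PARAMS = {
    "AD": (53.0, 16.0),
    "AR": (49.0, 17.0),
    "XR": (26.0, 19.0),
    "XLC": (26.0, 19.0),
    "autosomal": (51.0, 16.0),
    "x_linked": (26.0, 19.0),
    "NORMAL": (40.0, 18.0),
}

_PATIENT_LATENT_DIM = 4


@dataclass
class PhantomConfig:
    n_patients_per_class: int = 10
    classes: tuple[str, ...] = ("autosomal", "x_linked")
    image_side: int = 64
    effect_size: float = 1.0  # separation of class feature means, in between-patient SDs
    illumination_range: tuple[float, float] = (0.85, 1.1)
    rotation_range: float = 0.5  # radians, vessel-pattern rotation jitter
    vignette_strength: float = 0.25
    fellow_eye_correlation: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.image_side < 32:
            raise ValidationError("image_side must be >= 32")
        if not (0 <= self.fellow_eye_correlation <= 1):
            raise ValidationError("fellow_eye_correlation must be in [0, 1]")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")


def _class_index(label: str, classes: tuple[str, ...]) -> int:
    return list(classes).index(label)


def _eye_features(
    class_idx: int, patient_latent: np.ndarray, config: PhantomConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Speckle density and ring attenuation for one eye.

    Each feature is ``class mean + between-patient term + within-patient
    (eye) term``; the patient term comes from the shared latent so fellow
    eyes correlate with weight sqrt(rho).
    """
    rho = config.fellow_eye_correlation
    shift = config.effect_size * class_idx
    eye_noise = rng.standard_normal(2)
    mix0 = np.sqrt(rho) * patient_latent[0] + np.sqrt(1 - rho) * eye_noise[0]
    mix1 = np.sqrt(rho) * patient_latent[1] + np.sqrt(1 - rho) * eye_noise[1]
    speckle = np.clip(1.5 + shift + mix0, 0.0, None)  # speckles per 100 px^2
    ring = np.clip(0.18 + 0.10 * shift + 0.08 * mix1, 0.0, 0.85)
    return float(speckle), float(ring)


def generate_phantom_image(
    class_label: str,
    patient_latent: np.ndarray,
    eye: str,
    config: PhantomConfig,
    seed: int,
) -> ImageRecord:
    """Render one phantom eye; deterministic given (seed, latent, class, eye).

    OD images are rendered pre-flip, i.e. with the optic disc mirrored
    relative to OS, so laterality normalisation has something to undo.
    """
    if class_label not in config.classes:
        raise ValidationError(f"{class_label!r} not in configured classes")
    rng = np.random.default_rng(seed)
    s = config.image_side
    yy, xx = np.mgrid[0:s, 0:s]
    cx = cy = (s - 1) / 2.0
    u = (xx - cx) / (s / 2.0)  # [-1, 1] horizontal
    v = (yy - cy) / (s / 2.0)
    r = np.sqrt(u**2 + v**2)
    field_mask = r <= 0.95

    speckle_density, ring_strength = _eye_features(
        _class_index(class_label, config.classes), patient_latent, config, rng
    )
    lo, hi = config.illumination_range
    illum = rng.uniform(lo, hi)
    theta = rng.uniform(-config.rotation_range, config.rotation_range)

    # base retinal colour with mild radial shading
    base = np.stack(
        [0.82 * np.ones_like(r), 0.42 * np.ones_like(r), 0.18 * np.ones_like(r)], axis=-1
    )
    img = base * illum * (1.0 - config.vignette_strength * r[..., None] ** 2)

    # optic disc: bright ellipse on the nasal side (mirrored for OD pre-flip)
    disc_x = -0.45 if eye == "OS" else 0.45
    dd = ((u - disc_x) / 0.16) ** 2 + (v / 0.20) ** 2
    disc = np.exp(-dd * 2.0)
    img += disc[..., None] * np.array([0.45, 0.5, 0.35])

    # macula: dark disc slightly temporal to centre
    mac_x = 0.15 if eye == "OS" else -0.15
    mm = ((u - mac_x) / 0.18) ** 2 + (v / 0.18) ** 2
    img *= 1.0 - 0.4 * np.exp(-mm * 2.0)[..., None]

    # vessel arcades: dark parametric curves leaving the disc
    sign = 1.0 if eye == "OS" else -1.0
    for arc_dir in (+1.0, -1.0):
        bend = rng.uniform(0.5, 0.9)
        t = np.linspace(0.0, 1.0, 4 * s)
        px = disc_x + sign * 1.6 * t * np.cos(theta) - 0.0 * t
        py = arc_dir * (0.25 * t + bend * t**2) + 1.6 * t * np.sin(theta) * 0.2
        ix = np.round((px * s / 2.0) + cx).astype(int)
        iy = np.round((py * s / 2.0) + cy).astype(int)
        ok = (ix >= 0) & (ix < s) & (iy >= 0) & (iy < s)
        for dx in (0, 1):
            jx = np.clip(ix[ok] + dx, 0, s - 1)
            img[iy[ok], jx] *= 0.45

    # mid-peripheral ring attenuation (class-dependent strength)
    ring_profile = np.exp(-(((r - 0.62) / 0.10) ** 2))
    img *= 1.0 - ring_strength * ring_profile[..., None]

    # peripheral dark speckle (class-dependent density)
    annulus_area = np.pi * (0.92**2 - 0.55**2) * (s / 2.0) ** 2
    n_speckles = rng.poisson(speckle_density * annulus_area / 100.0)
    for _ in range(int(n_speckles)):
        rr = rng.uniform(0.55, 0.92)
        aa = rng.uniform(0, 2 * np.pi)
        px, py = rr * np.cos(aa), rr * np.sin(aa)
        ix, iy = int(px * s / 2.0 + cx), int(py * s / 2.0 + cy)
        rad = rng.integers(1, 3)
        y0, y1 = max(iy - rad, 0), min(iy + rad + 1, s)
        x0, x1 = max(ix - rad, 0), min(ix + rad + 1, s)
        img[y0:y1, x0:x1] *= 0.35

    img *= field_mask[..., None]
    img = np.clip(img, 0.0, 1.0)
    return ImageRecord(
        image=img,
        patient_id="",  # filled by the cohort generator
        eye=eye,
        label=class_label,
        acquisition_date="2024-06-01",
        record_id=f"anon_{eye}_{seed}",
    )


def generate_phantom_cohort(
    config: PhantomConfig, out_dir: str | Path | None = None
) -> Cohort:
    """Generate a full phantom cohort: n patients per class, two eyes each.

    If ``out_dir`` is given, PNGs + metadata.csv + a seed manifest are written
    there (loadable with :func:`latentmix.data_model.load_cohort`).
    """
    master = np.random.default_rng(config.seed)
    records: list[ImageRecord] = []
    manifest: dict[str, dict] = {}
    pidx = 0
    for label in config.classes:
        mean_age, sd_age = _AGE_PARAMS.get(label, (45.0, 15.0))
        for _ in range(config.n_patients_per_class):
            pid = f"P{pidx:04d}"
            pidx += 1
            latent = master.standard_normal(_PATIENT_LATENT_DIM)
            age = float(np.clip(master.normal(mean_age, sd_age), 5.0, 95.0))
            duration = float(np.clip(master.normal(age * 0.45, 5.0), 0.0, age))
            eye_seeds = {}
            for eye in ("OD", "OS"):
                seed = int(master.integers(0, 2**31 - 1))
                eye_seeds[eye] = seed
                rec = generate_phantom_image(label, latent, eye, config, seed)
                rec.patient_id = pid
                rec.age_years = round(age, 1)
                rec.symptom_duration_years = round(duration, 1)
                rec.record_id = f"{pid}_{eye}_{rec.acquisition_date}"
                records.append(rec)
            manifest[pid] = {"label": label, "eye_seeds": eye_seeds, "age": round(age, 1)}
    class_set = set(config.classes)
    if class_set <= {"autosomal", "x_linked"}:
        scheme = "binary"
    elif class_set <= {"NORMAL", "autosomal", "x_linked"}:
        scheme = "three_class"
    else:
        scheme = "four_class"
    cohort = Cohort(records, label_scheme=scheme)
    if out_dir is not None:
        out_dir = Path(out_dir)
        save_cohort(cohort, out_dir)
        (out_dir / "manifest.json").write_text(
            json.dumps({"config_seed": config.seed, "patients": manifest}, indent=2)
        )
    return cohort


def mean_peripheral_darkness(record: ImageRecord) -> float:
    """Simple pixel statistic separating phantom classes: 1 - mean intensity
    in the peripheral annulus. Used by calibration tests, not by models."""
    s = record.image.shape[0]
    yy, xx = np.mgrid[0:s, 0:s]
    c = (s - 1) / 2.0
    r = np.sqrt(((xx - c) / (s / 2)) ** 2 + ((yy - c) / (s / 2)) ** 2)
    ann = (r >= 0.55) & (r <= 0.92)
    return float(1.0 - record.image[ann].mean())
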