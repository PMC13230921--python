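"""Cohort representation, metadata/image I/O, preprocessing and patient-grouped splitting.

A cohort is an ordered list of :class:`ImageRecord` — one fundus photograph each —
plus a label scheme. Patients contribute up to two real eyes (OD/OS); every
split operation in this module groups by patient so that fellow eyes never
straddle a train/test boundary.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

FOUR_CLASS = ("AD", "AR", "XR", "XLC", "NORMAL")
BINARY = ("autosomal", "x_linked")
THREE_CLASS = ("NORMAL", "autosomal", "x_linked")
LABEL_SCHEMES = ("four_class", "binary", "three_class")

#: merge of the four inheritance modes into autosomal vs X-linked
_BINARY_MAP = {"AD": "autosomal", "AR": "autosomal", "XR": "x_linked", "XLC": "x_linked"}

METADATA_COLUMNS = (
    "patient_id",
    "image_path",
    "eye",
    "label",
    "acquisition_date",
    "age_years",
    "symptom_duration_years",
)


@dataclass
class ImageRecord:
    """One photograph with its clinical metadata.

    ``image`` is an H×W×3 float array in [0, 1], square after preprocessing.
    Real records have ``is_synthetic=False`` and empty provenance; synthetic
    records carry a provenance object describing how they were generated.
    """

    image: np.ndarray
    patient_id: str
    eye: str  # "OD" | "OS"
    label: str
    acquisition_date: str  # ISO date
    age_years: float | None = None
    symptom_duration_years: float | None = None
    is_synthetic: bool = False
    provenance: object | None = None
    record_id: str = ""
    flipped: bool = False  # laterality normalisation applied

    def __post_init__(self):
        if not self.record_id:
            self.record_id = f"{self.patient_id}_{self.eye}_{self.acquisition_date}"
        if self.eye not in ("OD", "OS"):
            raise ValidationError(f"eye must be OD or OS, got {self.eye!r}")
        if not self.is_synthetic and self.provenance is not None:
            raise ValidationError("real records must have empty provenance")


@dataclass
class Cohort:
    records: list[ImageRecord] = field(default_factory=list)
    label_scheme: str = "four_class"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def patient_label(self, patient_id: str) -> str:
        for r in self.records:
            if r.patient_id == patient_id:
                return r.label
        raise KeyError(patient_id)

    def subset(self, patient_ids) -> "Cohort":
        keep = set(patient_ids)
        return Cohort(
            [r for r in self.records if r.patient_id in keep], self.label_scheme
        )


@dataclass
class SplitPlan:
    """Patient-keyed train/test assignment; images follow their patient."""

    assignments: dict[str, str]  # patient_id -> "train" | "test"
    seed: int
    train_fraction: float

    def side(self, patient_id: str) -> str:
        return self.assignments[patient_id]

    def train_patients(self) -> list[str]:
        return [p for p, s in self.assignments.items() if s == "train"]

    def test_patients(self) -> list[str]:
        return [p for p, s in self.assignments.items() if s == "test"]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "train_fraction": self.train_fraction,
                    "assignments": self.assignments,
                },
                indent=2,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        blob = json.loads(Path(path).read_text())
        return cls(blob["assignments"], blob["seed"], blob["train_fraction"])


def _load_image(path: Path, image_side: int) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise IOError(f"cannot read image file {path}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    img = arr.astype(np.float64) / 255.0
    if img.shape[0] != image_side or img.shape[1] != image_side:
        img = resize(img, (image_side, image_side), anti_aliasing=True, preserve_range=True)
    return np.clip(img, 0.0, 1.0)


def load_cohort(
    metadata_path: str | Path,
    image_dir: str | Path | None = None,
    image_side: int = 64,
) -> Cohort:
    """Load a cohort from a metadata CSV plus an image directory.

    Keeps, per patient, only the rows from that patient's most recent
    acquisition date (ties on the same date keep all files). Pixels are
    rescaled to [0, 1] and resized to ``image_side``.
    """
    metadata_path = Path(metadata_path)
    df = pd.read_csv(metadata_path, dtype={"patient_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata is missing required columns: {missing}")
    if df.empty:
        warnings.warn("metadata table is empty; returning empty cohort", stacklevel=2)
        return Cohort([])

    valid = set(FOUR_CLASS) | set(BINARY)
    bad = sorted(set(df["label"]) - valid)
    if bad:
        raise ValidationError(f"unknown label tokens: {bad}; expected one of {sorted(valid)}")

    # most-recent-date filter, per patient (ISO strings order correctly)
    latest = df.groupby("patient_id")["acquisition_date"].transform("max")
    dropped = int((df["acquisition_date"] != latest).sum())
    if dropped:
        logger.info("dropped %d records from non-latest acquisition dates", dropped)
    df = df[df["acquisition_date"] == latest]

    base = Path(image_dir) if image_dir is not None else metadata_path.parent
    records = []
    for _, row in df.iterrows():
        img_path = Path(row["image_path"])
        if not img_path.is_absolute():
            img_path = base / img_path
        records.append(
            ImageRecord(
                image=_load_image(img_path, image_side),
                patient_id=str(row["patient_id"]),
                eye=str(row["eye"]),
                label=str(row["label"]),
                acquisition_date=str(row["acquisition_date"]),
                age_years=None if pd.isna(row["age_years"]) else float(row["age_years"]),
                symptom_duration_years=(
                    None
                    if pd.isna(row["symptom_duration_years"])
                    else float(row["symptom_duration_years"])
                ),
            )
        )
    return Cohort(records)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write PNG images plus a metadata CSV; returns the metadata path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.records:
        rel = f"images/{rec.record_id}.png"
        iio.imwrite(
            out_dir / rel, (np.clip(rec.image, 0, 1) * 255).round().astype(np.uint8)
        )
        rows.append(
            {
                "patient_id": rec.patient_id,
                "image_path": rel,
                "eye": rec.eye,
                "label": rec.label,
                "acquisition_date": rec.acquisition_date,
                "age_years": rec.age_years,
                "symptom_duration_years": rec.symptom_duration_years,
            }
        )
    meta = out_dir / "metadata.csv"
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(meta, index=False)
    return meta


def normalize_laterality(record: ImageRecord) -> ImageRecord:
    """Mirror right-eye (OD) images horizontally so all eyes share OS orientation.

    Idempotent: a record already flagged as flipped is returned unchanged.
    """
    if record.eye == "OS" or record.flipped:
        return record
    return replace(record, image=record.image[:, ::-1].copy(), flipped=True)


def map_labels(cohort: Cohort, scheme: str) -> Cohort:
    """Re-express labels under ``four_class``, ``binary`` or ``three_class``.

    Binary merges AD/AR into ``autosomal`` and XR/XLC into ``x_linked`` and
    rejects NORMAL records; three-class keeps NORMAL as its own class.
    """
    if scheme not in LABEL_SCHEMES:
        raise ValidationError(f"unknown label scheme {scheme!r}")
    if scheme == "four_class":
        return Cohort(list(cohort.records), "four_class")
    records = []
    for rec in cohort.records:
        if rec.label == "NORMAL":
            if scheme == "binary":
                raise ValidationError(
                    "NORMAL records are not allowed under the binary scheme"
                )
            records.append(replace(rec, label="NORMAL"))
        elif rec.label in _BINARY_MAP:
            records.append(replace(rec, label=_BINARY_MAP[rec.label]))
        else:  # already merged labels pass through
            if rec.label not in BINARY:
                raise ValidationError(f"cannot map label {rec.label!r} under {scheme}")
            records.append(rec)
    return Cohort(records, scheme)


def _records_by_class(cohort: Cohort) -> dict[str, list[ImageRecord]]:
    out: dict[str, list[ImageRecord]] = {}
    for rec in cohort.records:
        out.setdefault(rec.label, []).append(rec)
    return out


def balance_classes(cohort: Cohort, seed: int) -> Cohort:
    """Patient-preserving undersampling of majority classes.

    Majority classes lose whole randomly-chosen patients until their image
    count is within one patient's worth of the minority class. Deterministic
    under a fixed seed; never splits a patient's eyes.
    """
    by_class = _records_by_class(cohort)
    for label, recs in by_class.items():
        if not recs:
            raise ValidationError(f"class {label} is empty")
    target = min(len(recs) for recs in by_class.values())
    rng = np.random.default_rng(seed)
    keep_ids: set[str] = set()
    for label in sorted(by_class):
        recs = by_class[label]
        patients: dict[str, int] = {}
        for r in recs:
            patients[r.patient_id] = patients.get(r.patient_id, 0) + 1
        order = sorted(patients)
        rng.shuffle(order)
        count = 0
        for pid in order:
            if count >= target:
                break
            keep_ids.add(pid)
            count += patients[pid]
    kept = [r for r in cohort.records if r.patient_id in keep_ids]
    return Cohort(kept, cohort.label_scheme)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def grouped_split(cohort: Cohort, train_fraction: float, seed: int) -> SplitPlan:
    """Patient-grouped, class-stratified single train/test split.

    Both eyes of a patient always land on the same side. Within each class the
    train patient count is round-half-up of ``train_fraction`` times the class
    patient count, capped so that classes with ≥2 patients keep at least one
    test patient; a single-patient class is forced to train with a warning.
    """
    if not (0 < train_fraction < 1):
        raise ValidationError("train_fraction must be in (0, 1)")
    patient_class: dict[str, str] = {}
    for rec in cohort.records:
        patient_class.setdefault(rec.patient_id, rec.label)
    if len(patient_class) < 2:
        raise ValidationError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    assignments: dict[str, str] = {}
    by_class: dict[str, list[str]] = {}
    for pid in patient_class:
        by_class.setdefault(patient_class[pid], []).append(pid)
    for label in sorted(by_class):
        pids = sorted(by_class[label])
        rng.shuffle(pids)
        n = len(pids)
        if n == 1:
            warnings.warn(
                f"class {label} has a single patient; forcing it to train",
                stacklevel=2,
            )
            assignments[pids[0]] = "train"
            continue
        n_train = min(_round_half_up(train_fraction * n), n - 1)
        n_train = max(n_train, 1)
        for i, pid in enumerate(pids):
            assignments[pid] = "train" if i < n_train else "test"
    return SplitPlan(assignments, seed=seed, train_fraction=train_fraction)


def repeated_resampling_folds(
    cohort: Cohort, k: int, train_fraction: float, seed: int
) -> list[SplitPlan]:
    """k independent grouped stratified splits with derived seeds seed+0..seed+k-1.

    This is repeated resampling, not a partition: test sets may overlap across
    resamples.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    return [grouped_split(cohort, train_fraction, seed + i) for i in range(k)]
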