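"""Data model and I/O for labeled, located camera-trap images.

A camera-trap study produces a pile of images, each tagged with a class
label (a species, a human activity, or "No Animal") and the camera
location it came from.  The :class:`Catalog` is the in-memory inventory
of such a study; it is the input to every downstream stage (splitting,
resampling, training, evaluation).

The module also ships a transcription of the per-species recall table
from a published 47,279-image Parks Canada study (55 classes, 36
locations) as a packaged CSV fixture, used by the recall-vs-data
analysis and by the example scripts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ImageRecord",
    "Catalog",
    "ClassRecallRow",
    "ManifestError",
    "FixtureIntegrityError",
    "MODEL_COLUMNS",
    "load_manifest",
    "save_manifest",
    "class_counts",
    "location_counts",
    "load_recall_table",
    "save_recall_table",
    "load_table1_fixture",
    "table1_fixture_path",
]

#: Model columns of the packaged recall table, in printed order.
MODEL_COLUMNS = (
    "DenseNet201",
    "Inception-ResNet-V2",
    "InceptionV3",
    "MobileNetV2",
    "Xception",
    "NASNetMobile",
    "Ensemble",
)

MANIFEST_REQUIRED = ("image_path", "class_label", "location_id")
MANIFEST_OPTIONAL = ("image_id", "sequence_id", "captured_at", "is_augmented")


class ManifestError(ValueError):
    """Raised for malformed manifest CSVs (missing columns, empty fields)."""


class FixtureIntegrityError(ValueError):
    """Raised when the packaged recall-table fixture fails its integrity checks."""


@dataclass(frozen=True)
class ImageRecord:
    """One labeled image from one camera location.

    ``is_augmented`` marks supplementation copies created by the
    pipeline itself; such records never come from a disk manifest scan
    of raw imagery and are excluded from test sets.
    """

    image_id: str
    path: str
    class_label: str
    location_id: str
    sequence_id: str | None = None
    captured_at: str | None = None
    is_augmented: bool = False

    def __post_init__(self) -> None:
        if not self.class_label:
            raise ValueError(f"record {self.image_id!r}: empty class_label")
        if not self.location_id:
            raise ValueError(f"record {self.image_id!r}: empty location_id")


@dataclass(frozen=True)
class Catalog:
    """Ordered inventory of :class:`ImageRecord` with deduplicated
    class and location vocabularies in first-appearance order.

    The location order matters: the location-blocked cross-validation
    protocol forms contiguous fold blocks over it, so it is fixed
    deterministically as first appearance in the manifest.
    """

    records: tuple[ImageRecord, ...]
    classes: tuple[str, ...] = field(init=False)
    locations: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        classes: list[str] = []
        locations: list[str] = []
        for rec in self.records:
            if rec.image_id in seen_ids:
                raise ValueError(f"duplicate image_id {rec.image_id!r}")
            seen_ids.add(rec.image_id)
            if rec.class_label not in classes:
                classes.append(rec.class_label)
            if rec.location_id not in locations:
                locations.append(rec.location_id)
        object.__setattr__(self, "classes", tuple(classes))
        object.__setattr__(self, "locations", tuple(locations))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, image_ids: Iterable[str]) -> "Catalog":
        """Catalog restricted to ``image_ids``, preserving record order."""
        wanted = set(image_ids)
        return Catalog(tuple(r for r in self.records if r.image_id in wanted))

    def by_id(self, image_id: str) -> ImageRecord:
        for r in self.records:
            if r.image_id == image_id:
                return r
        raise KeyError(image_id)


@dataclass(frozen=True)
class ClassRecallRow:
    """One row of a per-class recall report: training/testing counts and
    the recall each model achieved on that class."""

    class_label: str
    n_train: int
    n_test: int
    recall_by_model: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n_train < 0 or self.n_test < 0:
            raise ValueError(f"{self.class_label}: negative count")
        for model, rec in self.recall_by_model.items():
            if not 0.0 <= rec <= 1.0:
                raise ValueError(f"{self.class_label}/{model}: recall {rec} outside [0, 1]")


def _none_if_empty(value: str) -> str | None:
    return value if value else None


def load_manifest(path: str | Path) -> Catalog:
    """Read a manifest CSV into a :class:`Catalog`.

    Required columns: ``image_path``, ``class_label``, ``location_id``.
    Optional: ``image_id`` (defaults to ``image_path``), ``sequence_id``,
    ``captured_at``, ``is_augmented``.  Row order, and hence class and
    location first-appearance order, is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANIFEST_REQUIRED:
        if col not in df.columns:
            raise ManifestError(f"manifest {path}: missing required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        label = row["class_label"]
        loc = row["location_id"]
        if not label:
            raise ManifestError(f"manifest {path} line {i}: empty class_label")
        if not loc:
            raise ManifestError(f"manifest {path} line {i}: empty location_id")
        records.append(
            ImageRecord(
                image_id=row.get("image_id") or row["image_path"],
                path=row["image_path"],
                class_label=label,
                location_id=loc,
                sequence_id=_none_if_empty(row.get("sequence_id", "")),
                captured_at=_none_if_empty(row.get("captured_at", "")),
                is_augmented=str(row.get("is_augmented", "")).lower() in ("1", "true"),
            )
        )
    return Catalog(tuple(records))


def save_manifest(catalog: Catalog, path: str | Path) -> None:
    """Write ``catalog`` as a manifest CSV; ``load_manifest`` of the
    result reproduces the catalog field-for-field."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "image_path", "class_label", "location_id",
                    "sequence_id", "captured_at", "is_augmented"])
        for r in catalog:
            w.writerow([r.image_id, r.path, r.class_label, r.location_id,
                        r.sequence_id or "", r.captured_at or "",
                        "true" if r.is_augmented else ""])


def class_counts(catalog: Catalog, include_augmented: bool = True) -> dict[str, int]:
    """Per-class image tallies, in catalog class order."""
    counts = {c: 0 for c in catalog.classes}
    for r in catalog:
        if not include_augmented and r.is_augmented:
            continue
        counts[r.class_label] += 1
    return {c: n for c, n in counts.items() if n > 0 or include_augmented}


def location_counts(catalog: Catalog) -> dict[str, int]:
    counts = {loc: 0 for loc in catalog.locations}
    for r in catalog:
        counts[r.location_id] += 1
    return counts


# ---------------------------------------------------------------------------
# Per-class recall tables (the printed-table dialect)
# ---------------------------------------------------------------------------

def load_recall_table(path: str | Path) -> list[ClassRecallRow]:
    """Read a per-class recall CSV: ``species,n_train,n_test`` followed by
    one recall column per model."""
    df = pd.read_csv(path)
    for col in ("species", "n_train", "n_test"):
        if col not in df.columns:
            raise ManifestError(f"recall table {path}: missing column {col!r}")
    model_cols = [c for c in df.columns if c not in ("species", "n_train", "n_test")]
    rows = []
    for _, row in df.iterrows():
        rows.append(
            ClassRecallRow(
                class_label=str(row["species"]),
                n_train=int(row["n_train"]),
                n_test=int(row["n_test"]),
                recall_by_model={m: float(row[m]) for m in model_cols},
            )
        )
    return rows


def save_recall_table(rows: Sequence[ClassRecallRow], path: str | Path) -> None:
    models = list(rows[0].recall_by_model) if rows else []
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "n_train", "n_test", *models])
        for r in rows:
            w.writerow([r.class_label, r.n_train, r.n_test,
                        *[repr(float(r.recall_by_model[m])) for m in models]])


def table1_fixture_path() -> Path:
    """Filesystem path of the packaged 55-class Parks Canada recall table."""
    return Path(resources.files("wildtrap.data") / "table1_parks.csv")


def load_table1_fixture(path: str | Path | None = None) -> list[ClassRecallRow]:
    """Load the packaged 55-class recall-table transcription (or a file in
    the same dialect), enforcing its integrity: exactly 55 rows, all
    recalls in [0, 1]."""
    rows = load_recall_table(path if path is not None else table1_fixture_path())
    if len(rows) != 55:
        raise FixtureIntegrityError(f"recall fixture has {len(rows)} rows, expected 55")
    return rows
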