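"""Class-imbalance machinery: ratio-based rejection resampling and
fixed-augmentation supplementation.

Camera-trap inventories are heavily long-tailed.  Two remedies are
implemented here:

* **ratio resampling** — each class gets a ratio ``r_c = n_c / n_max``
  against the largest class.  The training stream repeatedly draws a
  record uniformly from the whole dataset and a uniform variate ``u``;
  when ``u > r_c`` for the drawn record's class, a fresh uniform draw
  *within that class* is emitted, otherwise the whole draw repeats.
  Rare classes (small ``r_c``) are accepted almost every time they are
  drawn, so they are strongly upweighted relative to raw proportion.
  Taken literally the loop can never accept the largest class (its
  ratio is exactly 1), so the loop is capped at ``max_redraws``
  iterations and the last drawn record is emitted on exhaustion —
  giving the majority class its representation through the cap path.
  The induced class distribution has the closed form

  ``P(c) = p_c (1 - r_c) (1 - q^M) / (1 - q) + q^{M-1} p_c r_c``

  with ``p_c = n_c / N``, ``q = sum_c p_c r_c`` and cap ``M``, which the
  test suite checks by independent enumeration.

* **supplementation** — classes below a per-class floor (100 images in
  the study this pipeline reproduces) are topped up with deterministic
  augmented copies of their own training images, flagged
  ``is_augmented`` so they can never enter a test set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterator, Mapping

import numpy as np

from .augment import AugmentationConfig, augment
from .catalog import Catalog, ImageRecord

__all__ = [
    "ClassRatioTable",
    "SamplerConfig",
    "compute_class_ratios",
    "rebalanced_stream",
    "supplement_to_minimum",
]


@dataclass(frozen=True)
class ClassRatioTable:
    """Per-class ratios ``r_c = n_c / n_max``; the largest class has
    ratio exactly 1."""

    ratios: Mapping[str, float]
    n_max: int

    def __post_init__(self) -> None:
        if not self.ratios:
            raise ValueError("empty ratio table")
        vals = list(self.ratios.values())
        if max(vals) != 1.0 or min(vals) <= 0.0:
            raise ValueError("ratios must lie in (0, 1] with max exactly 1")


@dataclass(frozen=True)
class SamplerConfig:
    """Rejection-loop parameters: iteration cap and stream seed."""

    max_redraws: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_redraws < 1:
            raise ValueError("max_redraws must be >= 1")


def compute_class_ratios(counts: Mapping[str, int]) -> ClassRatioTable:
    """Ratios of each class count to the largest class count.

    Scale-invariant: multiplying all counts by a positive constant
    leaves every ratio unchanged.
    """
    if not counts:
        raise ValueError("cannot compute ratios of an empty count table")
    if any(n < 1 for n in counts.values()):
        raise ValueError("all class counts must be >= 1")
    n_max = max(counts.values())
    return ClassRatioTable({c: n / n_max for c, n in counts.items()}, n_max=n_max)


def rebalanced_stream(catalog: Catalog, ratios: ClassRatioTable,
                      config: SamplerConfig = SamplerConfig()) -> Iterator[ImageRecord]:
    """Endless seeded stream of records, rebalanced by the rejection
    heuristic described in the module docstring.

    Per emission, up to ``config.max_redraws`` times: draw a record
    uniformly (class ``c``), draw ``u ~ U(0,1)``; if ``u > r_c`` emit a
    fresh uniform draw within class ``c`` and stop, else redraw.  On cap
    exhaustion the last drawn record itself is emitted.
    """
    records = catalog.records
    missing = [c for c in catalog.classes if c not in ratios.ratios]
    if missing:
        raise ValueError(f"ratio table does not cover classes: {missing}")
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_class.setdefault(r.class_label, []).append(i)
    r_of = dict(ratios.ratios)
    rng = np.random.default_rng(config.seed)
    n = len(records)
    while True:
        emitted = None
        for _ in range(config.max_redraws):
            i = int(rng.integers(n))
            rec = records[i]
            u = rng.random()
            if u > r_of[rec.class_label]:
                pool = by_class[rec.class_label]
                emitted = records[pool[int(rng.integers(len(pool)))]]
                break
            emitted = rec  # cap path: last drawn record
        yield emitted


def supplement_to_minimum(catalog: Catalog, min_count: int,
                          augment_config: AugmentationConfig,
                          seed: int = 0, *,
                          loader: Callable[[ImageRecord], np.ndarray] | None = None,
                          ) -> tuple[Catalog, dict[str, np.ndarray]]:
    """Top every under-represented class up to exactly ``min_count``
    training records by appending fixed augmented copies.

    Source images are cycled in catalog order; copy ``j`` of a class is
    augmented with a seed derived from ``(seed, class, j)``, so the
    result is fully deterministic.  Intended for *training* records only
    — the appended records carry ``is_augmented=True`` and the split
    protocols keep such records out of test sets.

    ``loader`` maps a record to its 8-bit RGB array (e.g. a synthetic
    world's in-memory store, or a disk reader); when omitted, images are
    read from ``record.path`` with Pillow.

    Returns the supplemented catalog and a dict of the new images keyed
    by their fresh image ids (``<source>_augN``).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if loader is None:
        from PIL import Image

        def loader(rec: ImageRecord) -> np.ndarray:  # noqa: F811
            return np.asarray(Image.open(rec.path).convert("RGB"))

    by_class: dict[str, list[ImageRecord]] = {}
    for r in catalog:
        if not r.is_augmented:
            by_class.setdefault(r.class_label, []).append(r)
    for c in sorted(set(r.class_label for r in catalog)):
        if c not in by_class:
            raise ValueError(f"class {c!r} has zero source (non-augmented) records")

    new_records = list(catalog.records)
    new_images: dict[str, np.ndarray] = {}
    for c, sources in by_class.items():
        deficit = min_count - len(sources)
        for j in range(max(0, deficit)):
            src = sources[j % len(sources)]
            aug_seed = np.random.SeedSequence(
                [seed, abs(hash_stable(c)), j]).generate_state(1)[0]
            img = augment(loader(src), augment_config, seed=int(aug_seed))
            new_id = f"{src.image_id}_aug{j}"
            new_images[new_id] = img
            new_records.append(replace(src, image_id=new_id,
                                       path=f"{new_id}.png", is_augmented=True))
    return Catalog(tuple(new_records)), new_images


def hash_stable(text: str) -> int:
    """crc32-based stable string hash (Python's ``hash`` is salted per
    interpreter run and would break determinism)."""
    import zlib

    return zlib.crc32(text.encode("utf-8"))
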