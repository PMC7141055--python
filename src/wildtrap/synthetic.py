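"""Synthetic camera-trap worlds.

Real camera-trap data could not be redistributed here, so this module
generates miniature worlds that reproduce the *statistical* structure the
evaluation pipeline cares about, at desk scale:

* each camera location has its own static procedural background
  (layered color gradient plus fixed "rocks/logs"), so images are
  location-identifiable — the property that makes location-blocked
  evaluation meaningfully harder than a random split;
* species are rendered as simple sprites with within-class visual
  consistency and per-image pose/scale/illumination jitter, including
  the messy cases (partial occlusion, animals cropped out of frame);
* class abundances follow a configurable long tail (geometric decay by
  default), plus a majority "No Animal" background-only class;
* a species×location occupancy matrix restricts where each species can
  appear, so blocked folds can contain classes never seen in training;
* optional day/night conditions and motion-triggered 5-image bursts.

Everything is a pure function of ``(config, seed)``: rerunning a
generation yields byte-identical images and manifests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from .catalog import Catalog, ImageRecord, save_manifest

__all__ = [
    "SpeciesDescriptor",
    "Pose",
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "OccupancyError",
    "geometric_abundance",
    "default_species",
    "default_world_config",
    "easy_world_config",
    "render_background",
    "render_sprite",
    "render_image",
    "generate_world",
]

NO_ANIMAL = "No Animal"

SHAPES = ("ellipse", "triangle", "compound")

#: Default species palette: colors spaced in luminance so classes remain
#: separable after grayscale downsampling, shapes cycled through the
#: vocabulary.  (name, shape, RGB)
_PALETTE = [
    ("deerlike", "ellipse", (205, 170, 110)),
    ("wolflike", "compound", (90, 90, 100)),
    ("bearlike", "blobby", (50, 35, 25)),  # shape normalized below
    ("birdlike", "triangle", (235, 235, 240)),
    ("catlike", "compound", (160, 120, 60)),
    ("harelike", "ellipse", (245, 245, 245)),
    ("bovid", "triangle", (120, 80, 50)),
    ("mustelid", "compound", (30, 30, 30)),
]


class OccupancyError(ValueError):
    """A species was placed (or configured) at a location it does not occupy."""


def _rng(*tokens) -> np.random.Generator:
    """Stable RNG keyed on a tuple of ints/strings (crc32, not ``hash``,
    so streams are reproducible across interpreter runs)."""
    ints = []
    for t in tokens:
        if isinstance(t, (int, np.integer)):
            ints.append(int(t) & 0xFFFFFFFF)
        else:
            ints.append(zlib.crc32(str(t).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass(frozen=True)
class SpeciesDescriptor:
    """Visual identity of one synthetic species: a base shape from a
    small vocabulary, a base color, and a texture seed.  Distinct
    species must differ in at least one of the three."""

    name: str
    base_shape: str = "ellipse"
    base_color: tuple[int, int, int] = (128, 128, 128)
    texture_seed: int = 0

    def __post_init__(self) -> None:
        if self.base_shape not in SHAPES:
            raise ValueError(f"unknown base_shape {self.base_shape!r}; choose from {SHAPES}")


@dataclass(frozen=True)
class Pose:
    """Placement jitter for one rendered animal.

    ``scale`` multiplies the base sprite size; ``position`` is the sprite
    center in fractional image coordinates; ``occlusion_fraction`` hides
    that fraction of the sprite behind a foreground occluder;
    ``crop_fraction`` slides the sprite off the frame edge (1.0 = fully
    out of frame while the label is retained — a deliberately messy case).
    """

    scale: float = 1.0
    position: tuple[float, float] = (0.5, 0.55)
    occlusion_fraction: float = 0.0
    crop_fraction: float = 0.0


@dataclass
class SyntheticWorldConfig:
    """Recipe for one synthetic camera-trap world.

    ``occupancy`` is a binary species×location matrix (1 = the species
    occurs at that location); ``abundance`` gives the exact number of
    images to generate per species.  ``no_animal_count`` adds that many
    background-only images labeled "No Animal".  ``shared_background``
    collapses all locations onto one background (an ablation switch for
    the domain-shift mechanism; location IDs are kept distinct).
    """

    n_locations: int = 6
    species: tuple[SpeciesDescriptor, ...] = ()
    occupancy: np.ndarray | None = None  # species × locations, 0/1
    abundance: tuple[int, ...] = ()
    image_size: tuple[int, int] = (64, 64)
    no_animal_count: int = 0
    night_fraction: float = 0.25
    noise_level: float = 4.0
    background_contrast: float = 1.0  # 0 = flat mid-gray scenes, 1 = full variation
    sprite_px: int = 28          # base sprite size before pose scaling
    scale_range: tuple[float, float] = (0.7, 1.3)
    position_jitter: float = 0.22  # sprite center drawn within ± this of mid-frame
    occlusion_prob: float = 0.2
    crop_prob: float = 0.1
    sequence_mode: bool = False
    shared_background: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.occupancy is not None:
            self.occupancy = np.asarray(self.occupancy, dtype=int)
        self.validate()

    @property
    def location_ids(self) -> tuple[str, ...]:
        return tuple(f"L{i + 1:02d}" for i in range(self.n_locations))

    def resolved_occupancy(self) -> np.ndarray:
        """Occupancy matrix, defaulting to a seeded draw where each
        species occurs at ~60% of locations (at least one)."""
        if self.occupancy is not None:
            return self.occupancy
        rng = _rng(self.seed, "occupancy")
        occ = (rng.random((len(self.species), self.n_locations)) < 0.6).astype(int)
        for s in range(len(self.species)):
            if occ[s].sum() == 0:
                occ[s, rng.integers(self.n_locations)] = 1
        return occ

    def validate(self) -> None:
        if not 0.0 <= self.night_fraction < 1.0:
            raise ValueError("night_fraction must be in [0, 1)")
        if self.abundance and len(self.abundance) != len(self.species):
            raise ValueError("abundance length must match species list")
        if any(a < 0 for a in self.abundance):
            raise ValueError("abundance counts must be >= 0")
        if self.occupancy is not None:
            if self.occupancy.shape != (len(self.species), self.n_locations):
                raise ValueError("occupancy must be species x locations")
            bad = [self.species[s].name for s in range(len(self.species))
                   if self.occupancy[s].sum() == 0 and (not self.abundance or self.abundance[s] > 0)]
            if bad:
                raise OccupancyError(f"species with positive abundance but no occupied location: {bad}")


def geometric_abundance(n_classes: int, n_max: int = 60, ratio: float = 0.85) -> tuple[int, ...]:
    """Long-tailed per-class counts: geometric decay from ``n_max`` with
    the given ratio, floored at 2 — a desk-scale analog of the heavy
    class imbalance typical of camera-trap inventories."""
    return tuple(max(2, round(n_max * ratio**i)) for i in range(n_classes))


def default_species(n: int) -> tuple[SpeciesDescriptor, ...]:
    if n > len(_PALETTE):
        raise ValueError(f"at most {len(_PALETTE)} default species available")
    out = []
    for i, (name, shape, color) in enumerate(_PALETTE[:n]):
        shape = shape if shape in SHAPES else "compound"
        out.append(SpeciesDescriptor(name=name, base_shape=shape, base_color=color, texture_seed=i))
    return tuple(out)


def default_world_config(n_locations: int = 6, n_species: int = 5, n_max: int = 70,
                         seed: int = 0, **kwargs) -> SyntheticWorldConfig:
    """Standard test-bed world: long-tailed abundances, ~60% occupancy,
    location-distinct backgrounds, a No-Animal majority class, moderate
    pose/illumination jitter including some night frames and messy
    (occluded / cropped-out) animals."""
    abundance = geometric_abundance(n_species, n_max=n_max)
    defaults = dict(
        background_contrast=0.8,
        noise_level=3.0,
        night_fraction=0.15,
        sprite_px=32,
        scale_range=(0.85, 1.25),
        position_jitter=0.15,
        occlusion_prob=0.15,
        crop_prob=0.05,
    )
    defaults.update(kwargs)
    return SyntheticWorldConfig(
        n_locations=n_locations,
        species=default_species(n_species),
        abundance=abundance,
        no_animal_count=int(round(1.2 * n_max)),
        seed=seed,
        **defaults,
    )


def easy_world_config(n_locations: int = 4, n_species: int = 4, n_max: int = 50,
                      seed: int = 0, **kwargs) -> SyntheticWorldConfig:
    """Deliberately separable world: full occupancy, balanced classes,
    species colors at extreme luminance spread, subdued backgrounds,
    low noise, no night frames, no occlusion or cropping."""
    if n_species > 4:
        raise ValueError("easy world supports at most 4 species")
    hi_contrast = [
        SpeciesDescriptor("dark-sp", "ellipse", (15, 15, 15), 0),
        SpeciesDescriptor("pale-sp", "compound", (245, 245, 245), 1),
        SpeciesDescriptor("amber-sp", "triangle", (230, 190, 40), 2),
        SpeciesDescriptor("dusk-sp", "ellipse", (70, 70, 200), 3),
    ]
    species = tuple(hi_contrast[:n_species])
    return SyntheticWorldConfig(
        n_locations=n_locations,
        species=species,
        occupancy=np.ones((n_species, n_locations), dtype=int),
        abundance=tuple([n_max] * n_species),
        no_animal_count=n_max,
        night_fraction=0.0,
        noise_level=1.5,
        background_contrast=0.45,
        sprite_px=34,
        scale_range=(1.0, 1.2),
        position_jitter=0.06,
        occlusion_prob=0.0,
        crop_prob=0.0,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _background_base(config: SyntheticWorldConfig, location_id: str) -> np.ndarray:
    """Static scene for one location (float array, no per-image noise):
    a vertical two-color gradient plus fixed elliptical rocks/logs."""
    if location_id not in config.location_ids:
        raise OccupancyError(f"unknown location {location_id!r}")
    key = "SHARED" if config.shared_background else location_id
    rng = _rng(config.seed, "background", key)
    h, w = config.image_size
    c = config.background_contrast
    shrink = lambda col: 120.0 + c * (col - 120.0)  # noqa: E731
    top = shrink(rng.uniform(60, 200, 3))
    bot = shrink(rng.uniform(40, 180, 3))
    t = np.linspace(0.0, 1.0, h)[:, None, None]
    img = top[None, None, :] * (1 - t) + bot[None, None, :] * t
    img = np.broadcast_to(img, (h, w, 3)).copy()
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(rng.integers(4, 8)):
        cy, cx = rng.uniform(0.15, 0.95) * h, rng.uniform(0.05, 0.95) * w
        ay, ax = rng.uniform(0.04, 0.16) * h, rng.uniform(0.06, 0.30) * w
        color = shrink(rng.uniform(30, 150, 3))
        mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        img[mask] = 0.35 * img[mask] + 0.65 * color
    return img


def _apply_conditions(img: np.ndarray, night: bool, noise_level: float,
                      rng: np.random.Generator) -> np.ndarray:
    if night:
        # darken and desaturate; strictly lowers mean luminance
        gray = img.mean(axis=2, keepdims=True)
        img = 0.35 * (0.4 * img + 0.6 * gray)
    if noise_level > 0:
        img = img + rng.normal(0.0, noise_level, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_background(config: SyntheticWorldConfig, location_id: str, *,
                      night: bool = False, noise_level: float | None = None,
                      seed: int = 0) -> np.ndarray:
    """8-bit RGB background for one location under given conditions.

    Deterministic in ``(config, location_id, night, noise_level, seed)``;
    the static scene depends only on the location (and world seed), the
    sensor noise only on ``seed``.
    """
    base = _background_base(config, location_id)
    nl = config.noise_level if noise_level is None else noise_level
    return _apply_conditions(base, night, nl, _rng(config.seed, "noise", location_id, night, seed))


def render_sprite(descriptor: SpeciesDescriptor, size_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a species sprite on a ``size_px`` square canvas.

    Returns ``(patch, mask)``: float RGB patch with per-species texture,
    boolean coverage mask.  Pure function of (descriptor, size_px).
    """
    n = max(2, int(size_px))
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2
    if descriptor.base_shape == "ellipse":
        mask = ((yy - cy) / (0.38 * n)) ** 2 + ((xx - cx) / (0.48 * n)) ** 2 <= 1.0
    elif descriptor.base_shape == "triangle":
        # upright isoceles triangle
        mask = (yy >= 0.15 * n) & (np.abs(xx - cx) <= 0.45 * (yy - 0.15 * n + 1)) & (yy <= 0.9 * n)
    else:  # compound: body ellipse + head disc
        body = ((yy - 0.6 * n) / (0.28 * n)) ** 2 + ((xx - 0.45 * n) / (0.40 * n)) ** 2 <= 1.0
        head = ((yy - 0.32 * n) / (0.16 * n)) ** 2 + ((xx - 0.78 * n) / (0.16 * n)) ** 2 <= 1.0
        mask = body | head
    rng = _rng("texture", descriptor.texture_seed)
    patch = np.empty((n, n, 3), dtype=float)
    patch[:] = np.asarray(descriptor.base_color, dtype=float)
    patch += rng.normal(0.0, 12.0, patch.shape)  # within-class texture
    return np.clip(patch, 0, 255), mask


def render_image(config: SyntheticWorldConfig, location_id: str,
                 species: SpeciesDescriptor | None, pose: Pose = Pose(), *,
                 night: bool = False, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Composite one camera-trap frame; returns ``(image, sprite_mask)``.

    ``species=None`` yields a background-only frame with an all-zero
    mask.  Raises :class:`OccupancyError` when the species does not
    occupy the location.
    """
    h, w = config.image_size
    base = _background_base(config, location_id)
    full_mask = np.zeros((h, w), dtype=bool)
    if species is not None:
        occ = config.resolved_occupancy()
        names = [s.name for s in config.species]
        if species.name in names and occ[names.index(species.name), config.location_ids.index(location_id)] == 0:
            raise OccupancyError(f"species {species.name!r} does not occupy {location_id!r}")
        size = max(2, int(round(config.sprite_px * pose.scale)))
        patch, mask = render_sprite(species, size)
        if pose.occlusion_fraction > 0:
            cut = int(round(pose.occlusion_fraction * size))
            mask = mask.copy()
            mask[:, :cut] = False  # foreground occluder hides leading columns
        cy = pose.position[0] * (h - 1)
        cx = pose.position[1] * (w - 1)
        # crop_fraction slides the sprite off the right edge; 1.0 = fully out
        cx = cx + pose.crop_fraction * (w - cx + size / 2)
        top = int(round(cy - size / 2))
        left = int(round(cx - size / 2))
        y0, y1 = max(0, top), min(h, top + size)
        x0, x1 = max(0, left), min(w, left + size)
        if y1 > y0 and x1 > x0:
            sub = mask[y0 - top:y1 - top, x0 - left:x1 - left]
            base[y0:y1, x0:x1][sub] = patch[y0 - top:y1 - top, x0 - left:x1 - left][sub]
            full_mask[y0:y1, x0:x1] = sub
    rng = _rng(config.seed, "noise", location_id, night, seed)
    img = _apply_conditions(base, night, config.noise_level, rng)
    return img, full_mask


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    """A generated world: catalog plus in-memory images (and masks'
    pixel counts, for diagnostics).  ``images`` maps image_id to an
    8-bit RGB array."""

    config: SyntheticWorldConfig
    catalog: Catalog
    images: dict[str, np.ndarray]
    mask_areas: dict[str, int]

    def image(self, image_id: str) -> np.ndarray:
        return self.images[image_id]

    def write(self, output_dir: str | Path) -> Path:
        """Write PNGs and a manifest CSV; returns the manifest path.
        Byte-identical across reruns of the same (config, seed)."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        records = []
        for rec in self.catalog:
            fname = f"{rec.image_id}.png"
            Image.fromarray(self.images[rec.image_id]).save(out / fname)
            records.append(ImageRecord(
                image_id=rec.image_id, path=fname, class_label=rec.class_label,
                location_id=rec.location_id, sequence_id=rec.sequence_id,
                captured_at=rec.captured_at, is_augmented=rec.is_augmented))
        manifest = out / "manifest.csv"
        save_manifest(Catalog(tuple(records)), manifest)
        return manifest


def _draw_pose(config: SyntheticWorldConfig, rng: np.random.Generator) -> Pose:
    occl = rng.uniform(0.1, 0.5) if rng.random() < config.occlusion_prob else 0.0
    crop = rng.uniform(0.2, 0.7) if rng.random() < config.crop_prob else 0.0
    j = config.position_jitter
    return Pose(
        scale=rng.uniform(*config.scale_range),
        position=(rng.uniform(0.52 - j, 0.52 + j), rng.uniform(0.5 - j, 0.5 + j)),
        occlusion_fraction=occl,
        crop_fraction=crop,
    )


def generate_world(config: SyntheticWorldConfig,
                   output_dir: str | Path | None = None) -> SyntheticWorld:
    """Generate a full world: per-class record counts equal the
    configured abundance exactly, every (species, location) pair
    respects occupancy, and No-Animal records have empty sprite masks.

    With ``output_dir`` given, PNGs and a manifest CSV are also written.
    The whole run is a pure function of ``(config, config.seed)``.
    """
    config.validate()
    occ = config.resolved_occupancy()
    names = [s.name for s in config.species]
    for s, name in enumerate(names):
        count = config.abundance[s] if config.abundance else 0
        if count > 0 and occ[s].sum() == 0:
            raise OccupancyError(f"species {name!r} has abundance {count} but no occupied location")

    rng = _rng(config.seed, "world")
    records: list[ImageRecord] = []
    images: dict[str, np.ndarray] = {}
    mask_areas: dict[str, int] = {}
    burst = 5 if config.sequence_mode else 1
    next_id = 0

    def emit(species_idx: int | None, n_images: int) -> None:
        nonlocal next_id
        label = NO_ANIMAL if species_idx is None else names[species_idx]
        if species_idx is None:
            allowed = np.arange(config.n_locations)
        else:
            allowed = np.flatnonzero(occ[species_idx])
        made = 0
        seq_counter = 0
        while made < n_images:
            loc_i = int(rng.choice(allowed))
            loc = config.location_ids[loc_i]
            night = bool(rng.random() < config.night_fraction)
            pose = None if species_idx is None else _draw_pose(config, rng)
            seq_id = None
            if config.sequence_mode:
                seq_id = f"seq{zlib.crc32(label.encode()) & 0xFFFF:04x}-{seq_counter:04d}"
                seq_counter += 1
            n_in_burst = min(burst, n_images - made)
            for j in range(n_in_burst):
                image_id = f"img{next_id:05d}"
                next_id += 1
                if species_idx is None:
                    img, mask = render_image(config, loc, None, night=night, seed=next_id)
                else:
                    # within a burst the animal drifts slightly
                    p = pose if j == 0 else Pose(
                        scale=pose.scale,
                        position=(min(0.9, pose.position[0] + 0.01 * j),
                                  min(0.9, pose.position[1] + 0.03 * j)),
                        occlusion_fraction=pose.occlusion_fraction,
                        crop_fraction=pose.crop_fraction)
                    img, mask = render_image(config, loc, config.species[species_idx],
                                             p, night=night, seed=next_id)
                images[image_id] = img
                mask_areas[image_id] = int(mask.sum())
                records.append(ImageRecord(
                    image_id=image_id,
                    path=f"{image_id}.png",
                    class_label=label,
                    location_id=loc,
                    sequence_id=seq_id,
                    captured_at=(f"2020-01-01T00:{made // 60:02d}:{made % 60:02d}"
                                 if config.sequence_mode else None),
                ))
                made += 1

    for s in range(len(names)):
        emit(s, config.abundance[s] if config.abundance else 0)
    if config.no_animal_count > 0:
        emit(None, config.no_animal_count)

    world = SyntheticWorld(config=config, catalog=Catalog(tuple(records)),
                           images=images, mask_areas=mask_areas)
    if output_dir is not None:
        world.write(output_dir)
    return world
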