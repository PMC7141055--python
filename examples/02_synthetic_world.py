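"""Generate a synthetic camera-trap world.

Builds a small world with location-distinct backgrounds, a long-tailed
species-abundance distribution, partial species-location occupancy and
a "No Animal" majority class, then prints its inventory.  Pass an
output directory to also write PNGs and a manifest CSV.
"""

import sys

import wildtrap as wt

config = wt.default_world_config(n_locations=6, n_species=5, seed=42)
world = wt.generate_world(config, sys.argv[1] if len(sys.argv) > 1 else None)

print(f"{len(world.catalog)} images, {len(world.catalog.classes)} classes, "
      f"{len(world.catalog.locations)} locations")
print("\nclass counts (long tail by construction):")
for cls, n in wt.class_counts(world.catalog).items():
    print(f"  {cls:>10}: {n}")

occ = config.resolved_occupancy()
print("\noccupancy (1 = species occurs at location):")
for sp, row in zip(config.species, occ):
    print(f"  {sp.name:>10}: {' '.join(map(str, row))}")
# Species absent from some locations make location-blocked folds
# realistically hard: a held-out site can contain classes the model
# never saw in training.
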