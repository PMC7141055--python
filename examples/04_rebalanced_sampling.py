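"""Ratio-based rebalancing of a long-tailed training stream.

Builds a 90/10 imbalanced catalog, streams records through the
rejection resampler, and compares emitted class frequencies with the
raw proportions and with the closed-form prediction.
"""

import itertools

import wildtrap as wt
from wildtrap.catalog import Catalog, ImageRecord

counts = {"deer": 90, "wolverine": 10}
labels = [c for c, n in counts.items() for _ in range(n)]
catalog = Catalog(tuple(
    ImageRecord(f"r{i}", f"r{i}.png", lab, "L1") for i, lab in enumerate(labels)))

ratios = wt.compute_class_ratios(counts)
print("class ratios r_c = n_c / n_max:",
      {c: round(r, 3) for c, r in ratios.ratios.items()})

stream = wt.rebalanced_stream(catalog, ratios, wt.SamplerConfig(max_redraws=10, seed=0))
n = 50_000
tally = {c: 0 for c in counts}
for rec in itertools.islice(stream, n):
    tally[rec.class_label] += 1

print(f"\nover {n:,} emissions:")
for c in counts:
    raw = counts[c] / sum(counts.values())
    print(f"  {c:>10}: raw share {raw:.2f} → emitted {tally[c] / n:.3f}")
# The rare class is drawn far above its raw share: records whose class
# ratio is small are accepted almost every time they are drawn.
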