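"""How much training data does a species need?

Loads the packaged 55-class recall table from a 47,279-image camera-trap
study, bins per-class recall by training-image count, fits the
logarithmic recall curve, and reads off a data-requirement guideline.
"""

import wildtrap as wt

rows = wt.load_table1_fixture()
print(f"{len(rows)} classes, {sum(r.n_train + r.n_test for r in rows):,} images total")

bins = wt.bin_recall(rows, "DenseNet201", edges=(500, 1000))
print("\nDenseNet201 recall by training-set size:")
for b in bins:
    print(f"  {b.label():>7}: {b.n_classes:2d} classes, "
          f"mean recall {b.mean_recall:.3f} ± {b.sd_recall:.3g} (population SD)")

fit = wt.recall_curve_fit(rows, "DenseNet201")
print(f"\nlog fit over 500-wide bins: recall = {fit.intercept:.3f} "
      f"+ {fit.slope:.4f}·ln(n_train), r² = {fit.r_squared:.3f}")

guide = wt.threshold_guideline(bins, target_recall=0.95)
print(f"smallest bin with mean recall ≥ 0.95: {guide:,}+ training images")
# Classes with 1,000+ images show high, stable recall; below ~500 images
# recall is poor and wildly variable — the practical data floor.
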