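"""Screen a synthetic cell-lineage track table and classify sister pairs.

Generates a depth-3 binary lineage with asymmetric c-di-GMP dynamics (one
daughter per division runs through a 20-min low-c-di-GMP trough) plus
injected tracking glitches, applies the three exclusion filters, labels the
retained sister pairs high/low by lifetime-mean intensity, and overlays the
low-state tracks on a minimum-anchored time axis.
"""
from cdgsensor import (
    FilterConfig,
    align_to_minimum,
    classify_high_low,
    filter_pairs,
    gen_lineage_tracks,
    pair_and_trim,
)

tracks, truth = gen_lineage_tracks(
    depth=3,
    error_rates={"jump_prob": 0.03, "length_noise_sd": 0.005,
                 "intensity_noise_sd": 0.10},
    seed=6)
labels = dict(zip(truth["cell_id"], truth["label"]))

pairs = pair_and_trim(tracks)
kept, rejected = filter_pairs(pairs, FilterConfig.caulobacter())
print(f"sister pairs: {len(pairs)} found, {len(kept)} retained, "
      f"{len(rejected)} rejected")
for pair, reasons in rejected:
    print(f"  rejected {pair.track_a.cell_id}/{pair.track_b.cell_id}: "
          f"{', '.join(reasons)}")

correct = 0
for pair in kept:
    out = classify_high_low(pair)
    ok = labels[out["high"]] == "high" and labels[out["low"]] == "low"
    correct += ok
    print(f"  {out['high']} high ({out['mean_high']:.0f}) / "
          f"{out['low']} low ({out['mean_low']:.0f})"
          + ("" if ok else "  <- misclassified"))
print(f"classification agrees with ground truth for {correct}/{len(kept)} pairs")

low_tracks = [t for t in tracks if labels[t.cell_id] == "low"]
_, summary = align_to_minimum(low_tracks)
trough = summary.loc[summary["mean"] < 650]
print(f"\naligned overlay: trough (mean < 650 a.u.) spans "
      f"{trough['rel_time_min'].min():.0f} to {trough['rel_time_min'].max():.0f} min "
      f"around the minimum")
print()
print("The filters remove tracking artifacts (length jumps, inconsistent")
print("divisions, short tracks); the overlay recovers the ~20-min trough the")
print("low daughters experience after division.")
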