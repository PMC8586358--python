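"""Dilation-ratio structure association with a randomized control.

The statistic is the LP density on a binarized structure divided by the
density over its 50x-dilated neighborhood (~500 nm reach at the 10 nm
grid): 1 under randomness, >1 for enrichment, <1 for avoidance (e.g. a
drug excluded from the labeled terminals it surrounds).
"""
import numpy as np

import pharmstorm as ps

roi = ps.PolygonROI.rectangle(0, 0, 4000, 4000)
masks = ps.generate_structure_masks(
    "disks", 3, {"radius_nm": 300.0}, shape=(400, 400), pixel_size=10.0, seed=1
)
mask = ps.union_masks(masks)

scenarios = {"enriched": (600.0, 100.0), "random": (150.0, 150.0), "avoiding": (30.0, 300.0)}
for label, (d_on, d_off) in scenarios.items():
    ratios, controls = [], []
    for s in range(12):  # 12 synthetic images, as in a per-animal experiment
        scene = ps.place_molecules(masks, roi, d_on, d_off, seed=10 * s + 1)
        t = ps.LocalizationTable.from_arrays(scene.molecules["x_nm"], scene.molecules["y_nm"])
        res = ps.structure_density_ratio(t, mask, seed=10 * s + 2)
        ratios.append(res.ratio)
        controls.append(res.randomized_ratio)
    p = ps.test_median_vs_one(ratios)
    p_ctrl = ps.test_median_vs_one(controls)
    print(
        f"{label:9s} median ratio {np.median(ratios):5.2f} (Wilcoxon vs 1: p={p:.4f}) | "
        f"randomized control {np.median(controls):5.2f} (p={p_ctrl:.4f})"
    )
print("The randomized control always sits at ~1: re-distributing the same LPs")
print("uniformly erases any structural association, validating the statistic.")
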