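"""Blink stoichiometry: one-fluorophore probes versus antibodies.

In a sparse acquisition, each molecule's blinks form one spatial cluster.
A pharmacoprobe carries a single fluorophore and mostly appears as a
single localization point; an antibody with several fluorophores appears
as an LP cluster.  The cluster scatter also estimates the lateral
localization precision.
"""
import pharmstorm as ps
from pharmstorm import ClusteringConfig

roi = ps.PolygonROI.rectangle(0, 0, 120_000, 120_000)  # sparse: ~0.7 molecules/um2
for name, model in [
    ("pharmacoprobe", ps.pharmacoprobe_blink_model()),
    ("antibody", ps.antibody_blink_model()),
]:
    scene = ps.place_molecules([], roi, 0.0, 10_000 / roi.area_um2, seed=1)
    table = ps.render_blinks(scene, model, seed=2)
    clusters = ps.cluster_blinks(table, ClusteringConfig(radius=60))
    frac = ps.single_fraction(clusters)
    print(f"{name:13s}: {len(clusters)} molecules, single-LP fraction {frac:.1%}")

# precision from clusters with many blinks
scene = ps.place_molecules([], roi, 0.0, 1_000 / roi.area_um2, seed=3)
table = ps.render_blinks(scene, ps.BlinkModel(sigma_xy=9.42, lp_count_dist={30: 1.0}), seed=4)
clusters = ps.cluster_blinks(table, ClusteringConfig(radius=60))
_, median = ps.localization_precision(clusters, min_lps=20)
print(f"median lateral localization precision: {median:.2f} nm (generator sigma 9.42 nm)")
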