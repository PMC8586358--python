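"""LP density in the centered inner camera window, with background correction.

The analysis window is the inner 64 x 64 pixels of a 256 x 256 px EMCCD
field at 160 nm/pixel (104.86 um2), which avoids the inhomogeneously
illuminated field edges.
"""
import pharmstorm as ps

geom = ps.CameraGeometry(pixel_size=160.0, sensor_width=256, sensor_height=256)
field = ps.PolygonROI.rectangle(0, 0, geom.field_width_nm, geom.field_height_nm)

# a specifically labeled field and a probe-free control field
signal = ps.render_blinks(
    ps.place_molecules([], field, 0.0, 6.0, seed=1),
    ps.BlinkModel(sigma_xy=9.42, lp_count_dist={1: 1.0}),
    background_rate=2.0, seed=2, geometry=geom,
)
control = ps.randomize_lps(int(2.0 * field.area_um2), field, seed=3)
control.geometry = geom

sig_crop, window = ps.crop_inner(signal, 64)
ctl_crop, _ = ps.crop_inner(control, 64)
res = ps.background_correct(ps.density(sig_crop, window), ps.density(ctl_crop, window))

print(f"window area: {window.area_um2:.2f} um2 (inner 64 x 64 px)")
print(f"raw density: {res.density_per_um2:.2f} LPs/um2")
print(f"background:  {res.background_density_per_um2:.2f} LPs/um2 (control field)")
print(f"corrected:   {res.corrected_density_per_um2:.2f} LPs/um2 (true signal was 6.0)")
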