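"""Generate one synthetic measurement and extract its 97-variable vector.

The generator injects a known red-chrominance shift into an elliptical
flush region; extraction recovers it as the irritated-minus-control
delta of the mean Cr.
"""

from niaflush import (
    FlushModel,
    SkinThresholds,
    calibrate_scale,
    extract_features,
    generate_photograph,
    relative_statistics,
)

model = FlushModel(noise_sd=2.0, delta_cr_max=15.0)
photo = generate_photograph(model, concentration=0.1, time_min=10, seed=42)
print(f"requested Cr shift: {photo.metadata['requested_delta_cr']:.3f}")
print(f"rendered  Cr shift: {photo.metadata['rendered_delta_cr']:.3f} "
      "(8-bit channel shifts quantize the request)")

scale = calibrate_scale(photo.ruler)
print(f"ruler calibration:  {scale.mm_per_pixel:.4f} mm/px")

features = extract_features(photo, scale, SkinThresholds.permissive())
deltas = relative_statistics(features)
print(f"\nfeature vector length: {len(features.to_series())}")
print(f"flush surface:         {features.area_mm2:.1f} mm^2")
for name in ("delta_Cr_mean", "delta_R_mean", "delta_G_mean", "delta_S_mean"):
    print(f"{name:>16}: {deltas[name]:+.3f}")
print("\ndelta_Cr_mean matches the rendered shift to within the pixel-noise "
      "error of the two area means (~0.05 units here).")
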