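"""Convert pixels between color spaces and test skin plausibility.

Flushed skin is brighter in red chrominance (Cr) than the surrounding
skin; the conversions below are the basis of every downstream statistic.
"""

import numpy as np

from niaflush import SkinThresholds, rgb_to_hsv, rgb_to_ycbcr, skin_plausible

pixels = {
    "neutral gray": [128, 128, 128],
    "light skin": [205, 160, 130],
    "flushed skin": [225, 140, 130],
    "pure blue": [0, 0, 255],
}

print(f"{'pixel':>14} {'H deg':>7} {'S':>6} {'V':>6} {'Y':>7} {'Cb':>7} {'Cr':>7}")
for name, rgb in pixels.items():
    h, s, v = rgb_to_hsv(rgb)
    y, cb, cr = rgb_to_ycbcr(rgb)
    print(f"{name:>14} {h:7.1f} {s:6.3f} {v:6.3f} {y:7.1f} {cb:7.1f} {cr:7.1f}")

# Flushing raises Cr: the flushed pixel sits ~13 Cr units above the base
# skin tone while the gray and blue pixels are nowhere near skin-like red.
stock = SkinThresholds.defaults()
wide = SkinThresholds(cr_min=130, cr_max=180, cb_min=90, cb_max=130)
print("\nskin-plausible under the stock Cr window [140,165] x Cb [140,195]:")
for name, rgb in pixels.items():
    print(f"  {name:>14}: stock={bool(skin_plausible(rgb, stock))}"
          f"  neutral-light window={bool(skin_plausible(rgb, wide))}")
print("\nThe stock Cb interval is calibrated to the original acquisition "
      "setup; under neutral illumination use a window like the second one.")
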