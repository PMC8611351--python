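"""Calibrated image to boundary contour, exercised on a rendered leaf.

A synthetic blade is rasterized at a known pixels-per-cm, then pushed
through the image path: global threshold, largest-component mask,
petiole removal by calibrated opening, sub-pixel boundary trace, and
equal-arc-length resampling into a contour in cm.
"""

import leafmorph as lm

leaf = lm.generate_leaf(
    lm.LeafParams(R=4.0, furrow_depth_frac=0.35, noise_sd=0.0), 400)
image = lm.rasterize_contour(leaf.contour, px_per_cm=50.0)
print(f"rendered {image.pixels.shape} image at "
      f"{image.effective_px_per_cm:.0f} px/cm")

mask = lm.segment_leaf(image)
mask = lm.remove_petiole(mask, image, max_stalk_width_cm=0.3)
contour = lm.extract_contour(mask, image, n_points=300)
contour = lm.locate_base_point(contour)

recovered = lm.polygon_area(contour)
print(f"true blade area  {leaf.truth_area:.3f} cm^2")
print(f"recovered area   {recovered:.3f} cm^2 "
      f"({100 * abs(recovered - leaf.truth_area) / leaf.truth_area:.2f}% "
      "error)")
# sub-2% area error at 50 px/cm; accuracy scales with calibration
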