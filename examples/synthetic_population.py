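"""Generate a synthetic leaf population and inspect its trait table.

The generator produces fan-shaped blades anchored at the blade/petiole
junction P = (0, 0), with known radius, furrow depth, crenulation and
exact model-derived area — the ground truth every later stage is checked
against.
"""

import leafmorph as lm

leaves, traits = lm.generate_population(
    50,
    {"R": (2.0, 7.0), "furrow_depth_frac": (0.0, 0.6)},
    seed=1,
)

print(traits[["R", "furrow_depth_frac", "area_cm2", "max_radius_cm"]]
      .describe().round(2))
leaf = leaves[0]
print(f"\nfirst leaf: R={leaf.params.R:.2f} cm, "
      f"f={leaf.params.furrow_depth_frac:.2f}, "
      f"truth area={leaf.truth_area:.2f} cm^2, "
      f"polygon area={lm.polygon_area(leaf.contour):.2f} cm^2")
# the polygon area approaches the exact polar-model area as the contour is
# sampled more densely; at 200 points they already agree to ~0.1%
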