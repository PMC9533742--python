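"""Build the PILATUS3 2M gap mask and inspect its structure.

The detector is tiled from 3 x 8 modules; the dead stripes between them
form 7 horizontal and 2 vertical gap bands.  The mask is rasterized at
native resolution, checked for the expected 24-module topology, and
rescaled to the 512 x 512 working resolution used by the inpainting
pipeline.
"""

from scattergap import PILATUS3_2M, build_full_mask, count_modules, rescale_mask

mask = build_full_mask(PILATUS3_2M)
print(f"native mask: {mask.height} x {mask.width}")
print(f"gap pixels: {int(mask.raster.sum())} ({mask.raster.mean():.2%} of the frame)")
print(f"connected detector modules: {count_modules(mask)}")

mask512 = rescale_mask(mask, 512, 512)
print("\nat 512 x 512 working resolution:")
for r0, r1, c0, c1 in mask512.horizontal_rectangles:
    print(f"  horizontal band rows [{r0}, {r1})  ({r1 - r0} px tall)")
for r0, r1, c0, c1 in mask512.vertical_rectangles:
    print(f"  vertical band cols  [{c0}, {c1})  ({c1 - c0} px wide)")

# The module count printed above should be 24: the band grid partitions the
# frame into exactly module_rows x module_cols connected regions.
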