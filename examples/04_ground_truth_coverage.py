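"""Reference weed coverage from a known crop-row centerline.

Places monocot crop leaves along a row and dicot weeds off the row,
builds the dilated crop-band mask around the row centerline, classifies
vegetation blobs by centroid, and counts weed pixels — the procedure
used to ground-truth camera-based estimates.
"""

import numpy as np

from modicovi.ground_truth import RowPath, classify_blobs, crop_band_mask, dilation_radius_mm
from modicovi.synthetic_scenes import Scene, make_dicot, make_monocot

canvas = np.zeros((400, 400), dtype=np.uint8)

# crop leaves near the vertical row at x = 200 (ribbons rotated upright)
for seed, y in ((1, 40), (2, 150), (3, 260)):
    sp = np.rot90(make_monocot(length_px=120, rng_seed=seed).mask)
    h, w = sp.shape
    canvas[y : y + h, 180 : 180 + w][sp] = 1

# weeds between the rows
for seed, (y, x) in ((4, (60, 40)), (5, (200, 310)), (6, (320, 60))):
    sp = make_dicot(radius_px=25, rng_seed=seed).mask
    h, w = sp.shape
    canvas[y : y + h, x : x + w][sp] = 2

scene = Scene(label_map=canvas)
row = RowPath([(200, 0), (205, 200), (200, 399)])
band = crop_band_mask([row], radius_px=60, shape=canvas.shape)
result = classify_blobs(scene.veg_mask, band)

print(f"band radius: 60 px ({60 / 2.4:.0f} mm at 2.4 px/mm; "
      f"the field procedure used 350 px = {dilation_radius_mm(350, 2.4):.0f} mm)")
print(f"blob classes: {result.blob_labels}")
print(f"weed pixels:  {result.weed_pixels}  (true dicot pixels: {scene.true_weed_pixels})")
print(f"crop pixels:  {result.crop_pixels}")
print(f"weed fraction of image: {result.weed_fraction_of_image:.4f}")
# Weed pixels counted by the band procedure should match the scene's
# true dicot pixels whenever no weed blob strays onto the crop row.
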