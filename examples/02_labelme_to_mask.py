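"""Rasterize LabelMe-style polygon annotations into a label mask.

Clinical ground truth arrives as polygon outlines (uterus and tumor) drawn
by a radiologist; area-ratio staging needs filled pixel masks.  The tumor
polygon is painted over the uterus polygon, mirroring how the tumor sits
inside the organ.
"""

from turstage import parse_labelme, rasterize
from turstage.staging import compute_tur

document = {
    "imageHeight": 64,
    "imageWidth": 64,
    "shapes": [
        {"label": "uterus", "points": [[10, 12], [52, 12], [52, 50], [10, 50]]},
        {"label": "tumor", "points": [[22, 20], [38, 20], [38, 34], [22, 34]]},
        {"label": "bladder", "points": [[2, 2], [6, 2], [4, 6]]},  # ignored class
    ],
}

result = parse_labelme(document)
print(f"parsed {len(result.annotations)} annotations; "
      f"excluded shapes: {list(result.excluded)}")

mask = rasterize(result.annotations, result.image_shape)
uterus_px = int((mask == 1).sum())
tumor_px = int((mask == 2).sum())
print(f"uterus pixels: {uterus_px}, tumor pixels: {tumor_px}")
print(f"TUR = tumor / (tumor + uterus) = {compute_tur(mask):.3f}")
print("\nA TUR this small would read as superficial (stage IA) invasion.")
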