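"""Compute the four texture feature classes on one synthetic slice.

Builds two synthetic trabecular slices that differ only in spatial
organisation (correlation length of the underlying random field) and
prints the feature vector for the tibial ROI of each.  Coarser, more
organised texture shows lower GLCM entropy, higher ASM and longer runs.
"""

from ostex.synthetic import TextureParams, make_trabecular_slice
from ostex.texture import roi_feature_vector

for label, ell in (("organised (ell=8 px)", 8.0), ("disorganised (ell=2 px)", 2.0)):
    params = TextureParams(image_size=128, slice_count=1, correlation_length=ell)
    image, masks = make_trabecular_slice(params, seed=0)
    feats = roi_feature_vector(image.pixels, masks["medial_tibia"].mask)
    print(f"\n{label}")
    for name in ("entropy", "asm", "contrast", "long_run_emphasis",
                 "gr_mean", "mean", "variance"):
        print(f"  {name:20s} {feats[name]:10.4f}")

print(
    "\nEntropy rises and ASM / long-run emphasis fall as the trabecular"
    "\npattern becomes less spatially organised - the contrast the"
    "\ncomposite texture score is built to detect."
)
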