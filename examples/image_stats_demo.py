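"""Gist and LGN statistics of the 12 synthetic stimulus images.

Computes a Gabor-energy gist descriptor and Weibull contrast statistics
(CE = contrast energy, SC = spatial coherence) per image, builds
Euclidean RDMs and compares mean within-people versus within-places
dissimilarity.  The generator plants more variability in the place set.
"""

import numpy as np

import imfusion as im
from imfusion.images import ImageDescriptor, lgn_stats
from imfusion.synth import GroundTruth

truth = GroundTruth(seed=8)
images = im.generate_images(truth, seed=9)

gist = [im.gist_descriptor(img, image_id=i) for i, img in enumerate(images)]
print(f"gist descriptor length: {len(gist[0].features)} (4 scales x 8 orient x 4x4 grid)")
people_g, places_g = im.within_category_dissimilarity(im.image_rdm(gist))
print(f"gist  within-people {people_g:.4f}  within-places {places_g:.4f}")

lgn = [
    ImageDescriptor(i, "lgn", np.array([s.ce, s.sc]))
    for i, s in enumerate(lgn_stats(img) for img in images)
]
people_l, places_l = im.within_category_dissimilarity(im.image_rdm(lgn))
print(f"LGN   within-people {people_l:.4f}  within-places {places_l:.4f}")
print(
    "-> under both descriptors the place images are more dissimilar to each\n"
    "   other than the people images, matching the planted variability."
)
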