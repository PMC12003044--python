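"""ROI univariate contrasts and pairwise decoding on synthetic betas.

Generates per-run beta patterns for a place-preferring and a face-
preferring region, prints the places-minus-people contrast (percent
signal change) and leave-one-run-out decoding accuracies, plus the dice
overlap of two node masks.
"""

import imfusion as im
from imfusion.synth import GroundTruth, make_roi_mask

truth = GroundTruth(seed=5).for_subject(0)

for roi in ("Places1", "FFA1"):
    lh = im.generate_roi_betas(truth, roi, "lh")
    rh = im.generate_roi_betas(truth, roi, "rh")
    contrast = im.roi.average_hemispheres(im.roi_contrast(lh), im.roi_contrast(rh))
    print(f"{roi}: places-people contrast = {contrast.contrast:+.3f} PSC")
    for level in ("category", "within_people", "within_places"):
        acc = im.roi.average_hemispheres(
            im.roi_decode(lh, level), im.roi_decode(rh, level)
        )
        print(f"  {level:15s} decoding = {acc.accuracy:5.1f}% (chance 50%)")

a = make_roi_mask(truth, "Places1", "lh")
b = make_roi_mask(truth, "Places2", "lh")
print(f"dice(Places1, Places1) = {im.dice(a, a):.2f}  (identical masks)")
print(f"dice(Places1, Places2) = {im.dice(a, b):.2f}  (independent masks)")
print(
    "-> positive contrasts mark place-preferring cortex, negative face-\n"
    "   preferring; decoding above 50% means node patterns distinguish stimuli."
)
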