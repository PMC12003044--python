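"""Bayes-factor t-tests and BH-FDR on simple simulated group data.

Shows the three-way evidence classification (BF10 > 3 alternative,
BF10 < 1/3 null) for a real and an absent effect, and the adjusted
threshold the Benjamini-Hochberg procedure reports for a small p-value
family.
"""

import numpy as np

import imfusion as im

rng = np.random.default_rng(0)

effect = rng.normal(1.2, 1.0, size=12)   # 12 subjects, standardized effect ~1.2
nothing = rng.normal(0.0, 1.0, size=12)

for name, sample in (("planted effect", effect), ("no effect", nothing)):
    bf = im.bf_ttest(sample, null_value=0.0, direction="greater")
    print(f"{name:15s}: BF10 = {bf:8.3f} -> {im.classify_evidence(bf)}")

pvals = np.array([0.001, 0.011, 0.02, 0.24, 0.5, 0.86])
fdr = im.bh_fdr(pvals, q=0.05)
print(f"p-values: {pvals.tolist()}")
print(f"significant after BH-FDR (q=0.05): {fdr.mask.tolist()}")
print(f"adjusted significance threshold: p <= {fdr.threshold}")
print(
    "-> the half-Cauchy prior (width 0.707) with a 0.5 null range makes the\n"
    "   Bayes factor sensitive to the absence of small effects as well."
)
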