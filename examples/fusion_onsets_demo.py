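"""EEG-fMRI fusion with planted, ROI-specific onset latencies.

Two regions share stimulus-identity geometry with the EEG, one from
700 ms and one from 1400 ms after cue onset.  Fusion (per-timepoint
Spearman correlation between EEG RDMs and each region's fMRI RDM) is
averaged over hemispheres, group evidence is computed with Bayesian
t-tests over 12 synthetic subjects, and onsets are read off the first
sustained cluster of BF10 > 3.
"""

import numpy as np

import imfusion as im
from imfusion.synth import BlockGeometry, GroundTruth, RoiSpec

geometry = BlockGeometry(people=1.0, places=1.0, cross=0.0)
rois = {
    "early_roi": RoiSpec(name="early_roi", geometry=geometry, contrast=0.0,
                         latency_ms=(700.0, 2500.0)),
    "late_roi": RoiSpec(name="late_roi", geometry=geometry, contrast=0.0,
                        latency_ms=(1400.0, 2500.0)),
}
truth = GroundTruth(category_effect_eeg=0.0, rois=rois, seed=42)

curves = {r: [] for r in rois}
for s in range(12):
    ts = truth.for_subject(s)
    design = im.make_design(4, 10, 12, seed=ts.seed)
    epochs = im.generate_eeg(design, ts, seed=ts.seed + 1)
    eeg_rdms = im.eeg_rdm_timeseries(epochs)
    for roi in rois:
        lh, rh = (
            im.fuse(eeg_rdms, im.fmri_rdm(im.generate_roi_betas(ts, roi, h)),
                    subject=s, roi=roi, hemisphere=h)
            for h in ("lh", "rh")
        )
        curves[roi].append(im.hemisphere_average(lh, rh).rho)

for roi, planted in (("early_roi", 700), ("late_roi", 1400)):
    evidence = im.evidence_timeseries(
        np.vstack(curves[roi]), epochs.time_ms, null_value=0.0, direction="greater"
    )
    onset = im.onset_latency(evidence)
    print(
        f"{roi}: planted {planted} ms -> recovered onset {onset.onset_ms:.0f} ms "
        f"({onset.onset_imagery_ms:+.0f} ms relative to imagery onset), "
        f"{len(onset.clusters)} evidence cluster(s)"
    )
print(
    "-> the fusion time course localises in time when each region's\n"
    "   representational geometry appears in the EEG signal."
)
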