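"""The whole pipeline from one declarative config, at a small scale.

Runs generation -> decoding -> ROI analysis -> fusion -> group statistics
for three synthetic subjects with a reduced design (24 channels, 64 Hz,
1.2 s epochs, 30-node ROIs) and prints what the result bundle contains.
"""

import dataclasses

import imfusion as im
from imfusion.pipeline import RunConfig, run_all, summarize
from imfusion.synth import GroundTruth, default_rois

rois = {
    name: dataclasses.replace(spec, n_nodes=30, latency_ms=(300.0, 1000.0))
    for name, spec in default_rois().items()
}
truth = GroundTruth(
    n_subjects=3, n_channels=24, srate=64.0, epoch_ms=(-200.0, 1000.0),
    category_latency_ms=(300.0, 1000.0), rois=rois, seed=1,
)
config = RunConfig(
    truth=truth, outdir="scratch/pipeline_demo", master_seed=3,
    eeg_runs=2, eeg_reps=5, fmri_runs=3,
    decode_iterations=2, decode_time_step=4,
    timegen_iterations=2, timegen_time_step=8,
    # at 64 Hz a single sample lasts 15.6 ms, so ask for >= 4-sample clusters
    min_cluster_ms=60.0,
)

manifest = run_all(config)
n_rdm = sum(1 for f in manifest["subjects"]["s00"] if f.startswith("rdm_"))
print(f"stages run: {manifest['stages']}, errors: {manifest['errors'] or 'none'}")
print(f"fMRI RDM files for subject 0: {n_rdm} (9 ROIs x 2 hemispheres)")

tables = summarize(config.outdir)
print("\ngroup contrast (places - people, PSC):")
print(tables["contrast"][["roi", "mean", "sem"]].to_string(index=False))
print("\nfusion onsets (BF10 > 3 clusters):")
print(tables["onsets"].to_string(index=False))
print(
    "\n-> every output TSV carries the config hash and master seed; rerunning\n"
    "   with the same config reproduces the bundle byte for byte."
)
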