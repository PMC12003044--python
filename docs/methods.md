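# Methods

This note documents the models, parameter choices and numerical decisions
behind `imfusion`, in the spirit of a package methods appendix.  Nothing
here states an empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## The analysis problem

Subjects imagine 6 personally familiar people and 6 personally familiar
places, repeatedly, in separate EEG and fMRI sessions.  The questions the
pipeline answers are (a) *what* can be decoded from each modality
(category, stimulus identity, where in cortex), and (b) *when* the
representational geometry measured in an fMRI region appears in the EEG —
the fusion question.  The package assumes preprocessed inputs: epoched EEG
(trials × channels × timepoints with condition labels) and ROI beta
patterns (nodes × 12 stimuli, optionally × runs, in percent signal
change).  Acquisition and preprocessing (filtering, ICA, motion
correction, deconvolution, surface projection) are out of scope; the beta
set and the epoch set are the interface.

## Synthetic-data generative model

The generator exists so that every downstream stage can be tested against
a known truth without any recorded data.

**Design.**  12 conditions, each repeated `reps_per_stim` times per run in
a random order (EEG: 4 runs × 10; fMRI: 6 runs × 2), 64 channels at
256 Hz, epochs −200…3000 ms around cue onset (820 samples; the first
sample sits at −200 ms).  Imagery is instructed at cue + 500 ms, and all
outputs carry time both cue-relative and imagery-relative.

**Identity geometry.**  Each ROI has a latent 12-point configuration:
`z_i = cross·u_cat(i) + s_cat(i)·e_i`, with orthogonal category axes
`u_people, u_places`, random unit directions `e_i`, and scales
`(people, places, cross)`.  Condition patterns in either modality are
`A · Z Q`, where `Q` has orthonormal, zero-sum rows.  Because such a
projection preserves inner products and forces zero feature means,
the Pearson correlation between noiseless condition patterns equals the
cosine similarity of the latents — the planted correlation-distance RDM is
realised *exactly*, in EEG channel space and in fMRI node space alike
(verified to 1e-6 in the tests).  EEG and fMRI draw from the same latents
per ROI; the EEG expression switches on at an ROI-specific latency
(boxcar with 20 ms linear ramps).  This shared-latent mechanism is what
makes fusion-onset recovery a well-posed, testable property.

**Category effects.**  In EEG, a fixed random topography is added with
opposite sign for people and place trials during the category latency
window; its per-channel RMS difference is `category_effect_eeg` × noise
SD.  In fMRI, a uniform offset of ±contrast/2 (PSC) is added so that the
places-minus-people node-mean difference equals the planted contrast
exactly in expectation.

**Noise.**  EEG: white Gaussian per channel and sample (SD 1.0), with
optional 1/f spectral shaping for more realistic temporal autocorrelation
(off by default; onset tests pass under both).  fMRI: independent
Gaussian node noise per run (SD 0.8 PSC); the all-runs betas are the
across-run mean.

**Defaults and their rationale.**  No published raw-unit effect sizes
exist for imagery signals of this kind, so amplitudes are package choices,
fixed once and documented: EEG identity topography per-channel RMS = 0.2 ×
noise SD (a condition-mean SNR of roughly 1.6 after averaging 40 trials),
EEG category effect 0.15, beta identity pattern SD 0.3 PSC against 0.8 PSC
run noise over 200 nodes, category contrasts ±0.5 PSC with the usual
preference signs (place-preferring positive, face-preferring negative, V1
none).  These values are deliberately on the generous side of realistic:
the generator's job is to make recovery failures attributable to the
pipeline, not to an under-powered simulation, and the null configuration
(all effects zero) covers the opposite regime.  Tests sweep effect sizes
where the distinction matters.  Synthetic ROIs default to 200 nodes.

**What the generator does not emulate.**  Raw continuous EEG, ocular or
muscle artifacts, BOLD timeseries and haemodynamics, spatial channel
correlations of volume conduction, cortical surfaces, or a visual evoked
response to the cue.  Passing tests therefore demonstrate the correctness
and calibration of the *analysis*, not robustness to every artifact of
real recordings.

## Decoding

Pseudotrials are means of `chunk_size` (default 5) randomly chunked
same-condition trials; leftovers are dropped and the allocation is
re-randomized every iteration (50 for timecourses, 10 for temporal
generalization — the latter is quadratically more expensive).  The moving
window (default 3 samples, centred, edge timepoints dropped) concatenates
samples as features, widening the feature set rather than smoothing.
Folds leave one pseudotrial per condition out; fold accuracies are
averaged per fold, then over folds, iterations, and (for the reported
levels) pair sets.  Features are mean-centred per fold with the training
mean only.  The classifier is a linear SVM with C = 1 and no further
scaling.

At full design scale this is ~5 × 10⁷ fits per cohort, so the inner loop
is a maximal-violating-pair SMO solver for the C-SVC dual, numba-compiled
and run entirely in Gram space (per-fold centring included, since centred
kernels are linear functions of the uncentred ones).  The solver is not a
re-derivation of the statistics — it is the same optimisation problem
libsvm solves, and the tests assert agreement of decision values with
`sklearn.svm.SVC` on randomized problems.  ROI decoding (hundreds of
fits, not millions) simply calls scikit-learn.

## Fusion and onsets

RDMs use 1 − Pearson r (conditions ordered people then places; lower
triangle vectorized in the pdist/squareform order, shared by both
modalities).  EEG condition means pool all trials regardless of run.
Fusion is Spearman's ρ with average-rank ties over the 66 pairs,
evaluated independently at each timepoint; a zero-variance pattern makes
its entries `nan`, such pairs are removed pairwise, and fewer than 5
valid pairs yields a missing value.  Hemispheres are averaged as plain
means (no Fisher z), after per-hemisphere fusion and before group
statistics.  Difference waves are per-subject subtractions
(anti-symmetric by construction).

Group evidence uses one-sided tests (ρ > 0, accuracy > 50%) for fusion
and decoding, two-sided for difference waves, with no correction across
timepoints.  Clusters are maximal runs of BF₁₀ > 3; a run of *n* samples
lasts *n*·dt ms, and the onset is the start of the first cluster lasting
at least `min_duration_ms` (default 12 ms, i.e. 4 samples at 256 Hz —
chosen so that isolated 3-sample blips do not qualify).  At coarser
grids the minimum should be scaled accordingly (a single 64 Hz sample
already lasts 15.6 ms).  "No onset" is a regular result, not an error.

## Bayesian t-tests

The alternative model places a Cauchy prior (width 0.707) on the
standardized effect δ, truncated to the tested half-line beyond
|δ| = 0.5; by default the null is the point δ = 0, which matches the
"interval" convention of the MATLAB bayesFactor toolbox this mirrors.
Because the text-book phrase "a range of 0.5" is ambiguous, the
composite reading — the excluded interval itself carrying the null's
prior mass — is available as `null_mode="interval"`.  BF₁₀ is the ratio
of marginal likelihoods of the observed t statistic (noncentral-t
likelihood, ncp = δ√n).

Integration runs in the Cauchy-CDF domain (which linearises the heavy
tail) with three 64-node Gauss–Legendre panels, the middle one centred on
the likelihood peak δ* = t/√n; the effective upper limit is
|δ*| + 60 σ(t).  The tests pin this against an independent dense-trapezoid
oracle to relative error < 10⁻⁴ for t ∈ [−10, 10] and n ∈ {5, 12, 30}.
Zero variance across subjects raises by default; the pipeline's group
stage may instead saturate such timepoints (ceiling accuracy in a small
synthetic cohort) at infinite evidence for the side the common value
falls on.

BH-FDR uses the statsmodels step-up implementation and additionally
reports the adjusted threshold (the largest significant p), as analysis
tables conventionally do.

## Image statistics

Gist: 4 scales × 8 orientations of complex Gabor kernels (frequency
0.25/2ˢ cycles/pixel, bandwidth 1), DC-removed so that constant images
and luminance offsets map to exactly zero; images are grayscaled and
resized to 256 × 256; response magnitudes are averaged on a 4 × 4 grid
(512 features).  Convolution pads symmetrically so borders of constant
regions contribute nothing.  LGN: local contrast is |difference of
Gaussians| (σ = 1 and 3); a two-parameter Weibull fit (location 0) gives
CE = scale (grows linearly with image contrast) and SC = shape (contrast-
invariant; low for one coherent figure on a flat ground, high for
full-field clutter).  The source models specify no exact filter
parameters, so these defaults are configurable and the tests assert
directional and ordinal behaviour only.

The synthetic stimulus images are smooth random fields — a centrally
concentrated prototype per category plus exemplar noise, with higher
planted variability for places than people — sufficient for the
descriptor-level contrasts the pipeline makes, and nothing more.

## Pipeline and reproducibility

`RunConfig` (YAML-serialisable) carries the design, the ground truth, and
every stage parameter.  Each stochastic stage derives its seed from the
master seed, stage name and subject index, so a rerun with the same
config is byte-identical; every TSV carries the config hash and master
seed in its header, and `manifest.json` records files, seeds and
per-subject errors (a failing subject is reported, not fatal).
Deliberately small demo scales (24 channels, 64 Hz, 30-node ROIs, 2–3
subjects) are used in the examples and pipeline tests; the
calibration and recovery tests in `tests/test_acceptance.py` run the full
64-channel, 256 Hz, 12-subject design.

## Known limitations

* The pseudotrial count is truncated to the minimum across conditions, so
  strongly unbalanced designs waste trials.
* Fold accuracies are averaged per fold (not pooled), one of two
  conventions in circulation; with balanced folds the difference is nil.
* Onset estimation inherits the grid resolution and the BF threshold; it
  reports the first *evidence* crossing, which for shallow ramps is later
  than the generative onset.
* The LGN CE/SC reading (Weibull scale/shape of DoG contrast) is one
  member of a family of published variants; only its scaling and ordering
  properties are asserted.
* Group inference treats subjects as exchangeable; there are no
  hierarchical or mixed-effects models in scope.
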