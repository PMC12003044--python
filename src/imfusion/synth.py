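"""Synthetic paired EEG / fMRI imagery datasets with planted structure.

The generator emulates the data a familiar-imagery experiment produces after
preprocessing: epoched EEG (trials x channels x timepoints, 12 imagery
conditions = 6 people + 6 places, 4 runs x 10 repetitions, 64 channels,
256 Hz, epochs -200..3000 ms around cue onset) and ROI beta patterns
(nodes x 12 stimuli, optionally per run, in percent-signal-change units),
plus 12 grayscale stimulus images.

Two planted effects make every downstream stage testable:

* a *category* signal - a fixed channel topography whose sign differs for
  people and place trials (EEG), and a uniform mean-beta offset (fMRI);
* an *identity* geometry - a latent 12-point configuration per ROI.  EEG
  channel topographies and fMRI node patterns for the 12 conditions are
  drawn from the same latent configuration through orthonormal, zero-mean
  bases, so the noiseless correlation-distance RDM of either modality
  equals the planted one exactly.  The EEG expression of each ROI's
  geometry switches on at an ROI-specific latency, which is what makes
  fusion-onset recovery a well-posed test.

Amplitudes are not quantities the motivating literature reports in raw
signal units; the defaults here are arbitrary-but-realistic choices
documented in ``docs/methods.md`` and are exercised across a range in the
test-suite.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ROI_NAMES",
    "BlockGeometry",
    "RoiSpec",
    "GroundTruth",
    "EpochedEEG",
    "RoiBetaSet",
    "RoiMask",
    "make_design",
    "generate_eeg",
    "generate_roi_betas",
    "generate_images",
    "derive_seed",
    "save_epochs",
    "load_epochs",
]

DEFAULT_ROI_NAMES = (
    "pPPA",
    "aPPA",
    "FFA1",
    "FFA2",
    "Places1",
    "Places2",
    "People1",
    "People2",
    "V1",
)

CATEGORY_PEOPLE = "people"
CATEGORY_PLACES = "places"


def derive_seed(seed: int, *tags) -> int:
    """Deterministically derive a 31-bit child seed from a seed and tags."""
    ints = [int(seed)] + [zlib.crc32(str(t).encode()) for t in tags]
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % (2**31))


def _rng_for(seed: int, *tags) -> np.random.Generator:
    ints = [int(seed)] + [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(ints))


def _zero_mean_orthobasis(rng: np.random.Generator, k: int, m: int) -> np.ndarray:
    """k orthonormal m-vectors, each summing to zero (requires k < m).

    Projecting patterns through such a basis preserves inner products and
    makes every pattern zero-mean across features, so Pearson correlation
    between patterns equals cosine similarity between latents.
    """
    if k >= m:
        raise ValueError(f"need latent dim k={k} < n_features m={m}")
    g = rng.standard_normal((m, k))
    g -= g.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(g)
    return q.T  # (k, m), orthonormal zero-sum rows


@dataclass(frozen=True)
class BlockGeometry:
    """Scales of a latent 12-condition dissimilarity structure.

    Latent vectors are ``z_i = cross * u_cat(i) + scale_cat(i) * e_i`` with
    ``u_people, u_places`` fixed orthogonal axes and ``e_i`` random unit
    directions, so ``cross`` controls the category-block separation and
    ``people``/``places`` the within-block spread.  All zeros means "no
    identity structure".
    """

    people: float = 1.0
    places: float = 1.0
    cross: float = 1.0
    latent_dim: int = 12

    def latents(
        self, rng: np.random.Generator, n_people: int = 6, n_places: int = 6
    ) -> np.ndarray:
        n = n_people + n_places
        k = self.latent_dim + 2
        e = rng.standard_normal((n, self.latent_dim))
        e /= np.maximum(np.linalg.norm(e, axis=1, keepdims=True), 1e-300)
        z = np.zeros((n, k))
        scales = np.r_[
            np.full(n_people, self.people), np.full(n_places, self.places)
        ]
        z[:, : self.latent_dim] = scales[:, None] * e
        z[:n_people, self.latent_dim] = self.cross
        z[n_people:, self.latent_dim + 1] = self.cross
        return z

    @property
    def is_null(self) -> bool:
        return self.people == 0.0 and self.places == 0.0 and self.cross == 0.0


def target_rdm(latents: np.ndarray) -> np.ndarray:
    """Planted RDM implied by latent vectors: 1 - cosine similarity."""
    norms = np.linalg.norm(latents, axis=1)
    if np.any(norms == 0):
        raise ValueError("target RDM undefined for zero latent vectors")
    zn = latents / norms[:, None]
    d = 1.0 - zn @ zn.T
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class RoiSpec:
    """Planted structure for one region of interest (both hemispheres).

    ``contrast`` is the planted mean beta difference (places - people) in
    percent signal change; ``latency_ms`` is the window (relative to cue
    onset) in which this ROI's identity geometry is expressed in the EEG;
    ``eeg_amplitude`` is the per-channel RMS of the identity topographies
    in units of the EEG noise SD; ``beta_amplitude`` is the per-node SD of
    the identity pattern in percent signal change.
    """

    name: str
    geometry: BlockGeometry = field(default_factory=BlockGeometry)
    contrast: float = 0.5
    latency_ms: tuple[float, float] = (600.0, 2500.0)
    n_nodes: int = 200
    eeg_amplitude: float = 0.2
    beta_amplitude: float = 0.3


def default_rois(
    contrast: float = 0.5, latency_ms: tuple[float, float] = (600.0, 2500.0)
) -> dict[str, RoiSpec]:
    """The nine canonical ROIs with their category-preference signs.

    Place-preferring regions (pPPA, aPPA, Places1, Places2) get a positive
    places-minus-people contrast, people-preferring regions (FFA1, FFA2,
    People1, People2) a negative one, and V1 none.
    """
    sign = {
        "pPPA": +1.0,
        "aPPA": +1.0,
        "FFA1": -1.0,
        "FFA2": -1.0,
        "Places1": +1.0,
        "Places2": +1.0,
        "People1": -1.0,
        "People2": -1.0,
        "V1": 0.0,
    }
    return {
        name: RoiSpec(name=name, contrast=sign[name] * contrast, latency_ms=latency_ms)
        for name in DEFAULT_ROI_NAMES
    }


@dataclass
class GroundTruth:
    """Design constants and planted effect sizes for one synthetic subject.

    The epoch grid, trial counts, channel count, and the 6 + 6 stimulus
    design follow the experimental paradigm being emulated; amplitudes and
    noise scales are package defaults (see module docstring).
    """

    n_subjects: int = 12
    n_people: int = 6
    n_places: int = 6
    n_channels: int = 64
    srate: float = 256.0
    epoch_ms: tuple[float, float] = (-200.0, 3000.0)
    category_effect_eeg: float = 0.15
    category_latency_ms: tuple[float, float] = (500.0, 3000.0)
    rois: dict[str, RoiSpec] = field(default_factory=default_rois)
    noise_sd_eeg: float = 1.0
    noise_sd_beta: float = 0.8
    pink_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_eeg <= 0 or self.noise_sd_beta <= 0:
            raise ValueError("noise scales must be > 0")
        if self.n_people < 1 or self.n_places < 1:
            raise ValueError("need at least one stimulus per category")
        for name, window in self._latency_windows().items():
            lo, hi = window
            if lo < self.epoch_ms[0] or hi > self.epoch_ms[1] or hi <= lo:
                raise ValueError(
                    f"latency window {window} for {name!r} outside epoch {self.epoch_ms}"
                )

    def _latency_windows(self) -> dict[str, tuple[float, float]]:
        out = {"category": self.category_latency_ms}
        for name, spec in self.rois.items():
            out[name] = spec.latency_ms
        return out

    @property
    def n_conditions(self) -> int:
        return self.n_people + self.n_places

    def time_ms(self) -> np.ndarray:
        dt = 1000.0 / self.srate
        n = int(np.floor((self.epoch_ms[1] - self.epoch_ms[0]) / dt)) + 1
        return self.epoch_ms[0] + dt * np.arange(n)

    def condition_category(self) -> np.ndarray:
        return np.array(
            [CATEGORY_PEOPLE] * self.n_people + [CATEGORY_PLACES] * self.n_places
        )

    def for_subject(self, subject: int) -> "GroundTruth":
        """A copy of this truth with a subject-specific seed.

        Subjects share effect sizes and design but have independent latent
        geometries and noise, mirroring subject-specific stimuli.
        """
        return dataclasses.replace(self, seed=derive_seed(self.seed, "subject", subject))

    def roi_latents(self, roi: str) -> np.ndarray:
        spec = self.rois[roi]
        rng = _rng_for(self.seed, "geometry", roi)
        return spec.geometry.latents(rng, self.n_people, self.n_places)

    def roi_target_rdm(self, roi: str) -> np.ndarray:
        return target_rdm(self.roi_latents(roi))


@dataclass
class EpochedEEG:
    """Epoched EEG: trials x channels x timepoints plus labels.

    ``labels`` is a trial table with columns ``run``, ``trial``,
    ``condition`` (1-based) and ``category``.
    """

    data: np.ndarray
    time_ms: np.ndarray
    srate: float
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("trial count must equal label count")
        if self.data.shape[2] != len(self.time_ms):
            raise ValueError("time axis must match time_ms")
        dt = np.diff(self.time_ms)
        if not (np.all(dt > 0) and np.allclose(dt, 1000.0 / self.srate)):
            raise ValueError("time_ms must increase uniformly at 1000/srate")

    @property
    def n_conditions(self) -> int:
        return int(self.labels["condition"].max())

    def condition_trials(self, condition: int) -> np.ndarray:
        return np.flatnonzero(self.labels["condition"].to_numpy() == condition)

    def condition_means(self) -> np.ndarray:
        """Per-condition trial-average, (n_conditions, channels, time)."""
        conds = np.arange(1, self.n_conditions + 1)
        return np.stack(
            [self.data[self.condition_trials(c)].mean(axis=0) for c in conds]
        )


@dataclass
class RoiBetaSet:
    """Per-ROI, per-hemisphere beta patterns in percent signal change.

    ``betas_by_run`` is ``(nodes, stimuli, runs)`` (the per-run model);
    ``betas`` is ``(nodes, stimuli)`` (the all-runs model, equal to the
    across-run mean).  Stimulus axis order is people then places.
    """

    roi: str
    hemisphere: str
    betas: np.ndarray
    betas_by_run: np.ndarray | None = None
    units: str = "percent_signal_change"
    n_people: int = 6

    def __post_init__(self) -> None:
        if self.betas.ndim != 2:
            raise ValueError("betas must be nodes x stimuli")
        if self.betas.shape[0] < 2:
            raise ValueError("an ROI needs at least 2 nodes")
        if self.betas_by_run is not None and self.betas_by_run.shape[:2] != self.betas.shape:
            raise ValueError("betas_by_run must be nodes x stimuli x runs")

    @property
    def n_nodes(self) -> int:
        return self.betas.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.betas.shape[1]

    def category_of(self) -> np.ndarray:
        n = self.n_stimuli
        return np.array(
            [CATEGORY_PEOPLE] * self.n_people + [CATEGORY_PLACES] * (n - self.n_people)
        )


@dataclass(frozen=True)
class RoiMask:
    """A set of surface-node indices for one ROI and hemisphere."""

    roi: str
    hemisphere: str
    nodes: frozenset[int]

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.nodes):
            raise ValueError("node indices must be non-negative")

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# design / EEG


def make_design(
    n_runs: int, reps_per_stim: int, n_stim: int = 12, seed: int = 0, n_people: int = 6
) -> pd.DataFrame:
    """Randomized, condition-balanced trial table.

    Every condition appears exactly ``reps_per_stim`` times per run in a
    random order (the EEG imagery design is 4 runs x 10 repetitions, the
    fMRI design 6 runs x 2 repetitions).
    """
    if n_runs < 1 or reps_per_stim < 1 or n_stim < 1:
        raise ValueError("counts must be >= 1")
    rng = _rng_for(seed, "design", n_runs, reps_per_stim, n_stim)
    rows = []
    for run in range(1, n_runs + 1):
        conditions = np.repeat(np.arange(1, n_stim + 1), reps_per_stim)
        rng.shuffle(conditions)
        for trial, cond in enumerate(conditions, start=1):
            rows.append((run, trial, int(cond)))
    out = pd.DataFrame(rows, columns=["run", "trial", "condition"])
    out["category"] = np.where(
        out["condition"] <= n_people, CATEGORY_PEOPLE, CATEGORY_PLACES
    )
    return out


def _envelope(time_ms: np.ndarray, onset: float, offset: float, ramp_ms: float = 20.0) -> np.ndarray:
    """Boxcar with linear on/off ramps of ``ramp_ms`` starting at onset."""
    ramp = max(ramp_ms, 1e-9)
    up = np.clip((time_ms - onset) / ramp, 0.0, 1.0)
    down = np.clip((offset - time_ms) / ramp, 0.0, 1.0)
    return up * down


def _pink_shape(noise: np.ndarray, srate: float, rng: np.random.Generator) -> np.ndarray:
    """Impose an approximate 1/f amplitude spectrum, preserving the SD."""
    nt = noise.shape[-1]
    freqs = np.fft.rfftfreq(nt, d=1.0 / srate)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = scale[1] if len(scale) > 1 else 1.0
    spec = np.fft.rfft(noise, axis=-1) * scale
    shaped = np.fft.irfft(spec, n=nt, axis=-1)
    sd = shaped.std()
    if sd > 0:
        shaped *= noise.std() / sd
    return shaped


def generate_eeg(
    design: pd.DataFrame, truth: GroundTruth, seed: int | None = None
) -> EpochedEEG:
    """Simulate epoched EEG for one subject.

    Each trial is channel noise plus (a) the category topography with a
    sign set by the trial's category, active during
    ``truth.category_latency_ms``, and (b) one identity topography per ROI
    in ``truth.rois``, drawn from that ROI's latent geometry and active
    during the ROI's latency window.  Latent geometries and topography
    bases depend only on ``truth.seed`` so that EEG and fMRI realisations
    of the same truth share structure; ``seed`` only re-randomises noise.
    """
    n_cond = truth.n_conditions
    if int(design["condition"].max()) != n_cond:
        raise ValueError("design and truth disagree on the number of conditions")
    if seed is None:
        seed = truth.seed
    time_ms = truth.time_ms()
    nt, nch = len(time_ms), truth.n_channels
    n_trials = len(design)

    rng_noise = _rng_for(seed, "eeg-noise")
    data = rng_noise.standard_normal((n_trials, nch, nt))
    if truth.pink_noise:
        data = _pink_shape(data, truth.srate, rng_noise)
    data *= truth.noise_sd_eeg

    cond = design["condition"].to_numpy()
    is_place = (cond > truth.n_people).astype(float)
    cat_sign = 2.0 * is_place - 1.0  # people -1, places +1

    # category signal: fixed random topography, difference RMS per channel
    # equals category_effect_eeg * noise SD
    if truth.category_effect_eeg != 0.0:
        g = _rng_for(truth.seed, "eeg-category-topo").standard_normal(nch)
        g /= np.linalg.norm(g)
        topo = truth.category_effect_eeg * truth.noise_sd_eeg * np.sqrt(nch) * g
        env = _envelope(time_ms, *truth.category_latency_ms)
        data += (cat_sign[:, None, None] * 0.5) * topo[None, :, None] * env[None, None, :]

    # identity signals, one latent geometry per ROI
    for name, spec in truth.rois.items():
        if spec.geometry.is_null or spec.eeg_amplitude == 0.0:
            continue
        z = truth.roi_latents(name)  # (n_cond, k)
        basis = _zero_mean_orthobasis(
            _rng_for(truth.seed, "eeg-basis", name), z.shape[1], nch
        )
        amp = spec.eeg_amplitude * truth.noise_sd_eeg * np.sqrt(nch)
        topos = amp * (z @ basis)  # (n_cond, nch)
        env = _envelope(time_ms, *spec.latency_ms)
        data += topos[cond - 1][:, :, None] * env[None, None, :]

    return EpochedEEG(data=data, time_ms=time_ms, srate=truth.srate, labels=design.copy())


# ---------------------------------------------------------------------------
# fMRI betas


def generate_roi_betas(
    truth: GroundTruth,
    roi: str,
    hemisphere: str = "lh",
    n_runs: int = 6,
    seed: int | None = None,
) -> RoiBetaSet:
    """Simulate per-run and all-runs beta patterns for one ROI/hemisphere.

    Node patterns realise the ROI's latent geometry exactly in the
    noiseless condition means (orthonormal zero-mean node basis), shifted
    by a uniform category offset of ``+-contrast/2``; per-run betas add
    independent node noise and the all-runs betas are their mean.
    """
    if roi not in truth.rois:
        raise KeyError(
            f"unknown ROI {roi!r}; known: {sorted(truth.rois)}"
        )
    if hemisphere not in ("lh", "rh"):
        raise ValueError("hemisphere must be 'lh' or 'rh'")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    spec = truth.rois[roi]
    if seed is None:
        seed = truth.seed
    n_cond = truth.n_conditions
    m = spec.n_nodes

    mean = np.zeros((m, n_cond))
    if not spec.geometry.is_null and spec.beta_amplitude != 0.0:
        z = truth.roi_latents(roi)
        basis = _zero_mean_orthobasis(
            _rng_for(truth.seed, "beta-basis", roi, hemisphere), z.shape[1], m
        )
        mean += (spec.beta_amplitude * np.sqrt(m) * (z @ basis)).T
    offset = np.where(truth.condition_category() == CATEGORY_PLACES, 0.5, -0.5)
    mean += spec.contrast * offset[None, :]

    rng = _rng_for(seed, "beta-noise", roi, hemisphere)
    noise = truth.noise_sd_beta * rng.standard_normal((m, n_cond, n_runs))
    by_run = mean[:, :, None] + noise
    return RoiBetaSet(
        roi=roi,
        hemisphere=hemisphere,
        betas=by_run.mean(axis=2),
        betas_by_run=by_run,
        n_people=truth.n_people,
    )


def make_roi_mask(
    truth: GroundTruth, roi: str, hemisphere: str = "lh", node_space: int = 200_000
) -> RoiMask:
    """A synthetic node-index mask for one ROI (deterministic per truth)."""
    if roi not in truth.rois:
        raise KeyError(f"unknown ROI {roi!r}")
    spec = truth.rois[roi]
    rng = _rng_for(truth.seed, "mask", roi, hemisphere)
    nodes = rng.choice(node_space, size=spec.n_nodes, replace=False)
    return RoiMask(roi=roi, hemisphere=hemisphere, nodes=frozenset(int(n) for n in nodes))


# ---------------------------------------------------------------------------
# stimulus images


def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.standard_normal((size, size)), sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_images(
    truth: GroundTruth,
    seed: int | None = None,
    size: int = 128,
    people_variability: float = 0.25,
    place_variability: float = 0.75,
) -> list[np.ndarray]:
    """12 grayscale stimulus images (people 1-6 then places 7-12).

    Each image is a category prototype (a smooth random field; the people
    prototype is concentrated centrally, the place prototype is full-field
    and finer-grained) plus exemplar-specific structure scaled by the
    per-category variability.  Variability 0 makes a category's exemplars
    identical.  Pixel values are in [0, 1].
    """
    if seed is None:
        seed = truth.seed
    rng = _rng_for(seed, "images")
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = ((yy - size / 2) ** 2 + (xx - size / 2) ** 2) / (size / 4) ** 2
    central = np.exp(-r2)

    protos = {
        CATEGORY_PEOPLE: _smooth_field(rng, size, size / 16) * central,
        CATEGORY_PLACES: _smooth_field(rng, size, size / 32),
    }
    variability = {
        CATEGORY_PEOPLE: people_variability,
        CATEGORY_PLACES: place_variability,
    }
    sigma = {CATEGORY_PEOPLE: size / 16, CATEGORY_PLACES: size / 32}
    images = []
    for cat in truth.condition_category():
        img = protos[cat] + variability[cat] * _smooth_field(rng, size, sigma[cat]) * (
            central if cat == CATEGORY_PEOPLE else 1.0
        )
        lo, hi = img.min(), img.max()
        images.append((img - lo) / (hi - lo) if hi > lo else np.full_like(img, 0.5))
    return images


# ---------------------------------------------------------------------------
# persistence (array container + JSON sidecar / TSV)


def save_epochs(epochs: EpochedEEG, path: str) -> None:
    """Write epochs as ``.npz`` plus a ``.json`` sidecar with the labels."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    np.savez_compressed(path, data=epochs.data, time_ms=epochs.time_ms)
    sidecar = {
        "srate": epochs.srate,
        "labels": epochs.labels.to_dict(orient="list"),
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_epochs(path: str) -> EpochedEEG:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    arrays = np.load(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    return EpochedEEG(
        data=arrays["data"],
        time_ms=arrays["time_ms"],
        srate=sidecar["srate"],
        labels=pd.DataFrame(sidecar["labels"]),
    )


def save_betas_tsv(betas: RoiBetaSet, path: str) -> None:
    """All-runs betas as TSV (nodes x stimuli) with a provenance header."""
    with open(path, "w") as fh:
        fh.write(
            f"# roi={betas.roi}\themisphere={betas.hemisphere}\tunits={betas.units}\n"
        )
        pd.DataFrame(
            betas.betas, columns=[f"stim{i+1:02d}" for i in range(betas.n_stimuli)]
        ).to_csv(fh, sep="\t", index=False)


def save_mask_tsv(mask: RoiMask, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("hemisphere\tnode\n")
        for n in sorted(mask.nodes):
            fh.write(f"{mask.hemisphere}\t{n}\n")
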