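"""EEG-fMRI representational fusion and onset extraction.

Fusion asks *when* the representational geometry of a set of imagined
stimuli in an fMRI region appears in the EEG: the 12 x 12 EEG RDM at each
timepoint (1 - Pearson over the sensor pattern of condition means) is
rank-correlated (Spearman, average ranks for ties) with the region's fMRI
RDM over the 66 condition pairs.  Per-subject fusion curves are averaged
across hemispheres (plain mean, no Fisher transform), optionally
subtracted between regions (difference waves), and group evidence over
subjects is summarised with per-timepoint Bayes factors; onsets are the
start of the first sufficiently long run of BF10 > 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import BF_UPPER, EvidenceSeries
from .rdm import RDM, correlation_rdm, lower_triangle
from .synth import EpochedEEG, RoiBetaSet

__all__ = [
    "EegRdmSeries",
    "FusionTimeseries",
    "FusionDifference",
    "OnsetResult",
    "fmri_rdm",
    "eeg_rdm_timeseries",
    "fuse",
    "hemisphere_average",
    "difference_wave",
    "onset_latency",
]

MIN_VALID_PAIRS = 5

#: offset between cue onset and the instructed start of imagery
IMAGERY_ONSET_MS = 500.0


@dataclass
class EegRdmSeries:
    """One 12 x 12 RDM per EEG timepoint (1 - Pearson over sensors)."""

    time_ms: np.ndarray
    values: np.ndarray  # (n_time, n_cond, n_cond)
    metric: str = "one_minus_pearson"

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[0] != len(self.time_ms):
            raise ValueError("values must be (n_time, n_cond, n_cond)")

    def __len__(self) -> int:
        return len(self.time_ms)

    def rdm_at(self, index: int) -> RDM:
        return RDM(values=self.values[index], metric=self.metric)


@dataclass
class FusionTimeseries:
    """Spearman rho between EEG RDMs and one ROI RDM, per timepoint."""

    time_ms: np.ndarray
    rho: np.ndarray
    subject: int | str | None = None
    roi: str | None = None
    hemisphere: str = "avg"

    def __post_init__(self) -> None:
        finite = self.rho[np.isfinite(self.rho)]
        if finite.size and (finite.min() < -1.0 - 1e-9 or finite.max() > 1.0 + 1e-9):
            raise ValueError("rho must lie in [-1, 1]")


@dataclass
class FusionDifference:
    """Per-subject difference of two fusion timeseries (a - b)."""

    time_ms: np.ndarray
    values: np.ndarray
    pair: str
    subject: int | str | None = None


@dataclass
class OnsetResult:
    """Evidence-defined onset plus the full cluster table.

    ``onset_ms`` is None when no cluster of BF10 > 3 lasts at least the
    minimum duration.  ``clusters`` has columns start_ms, end_ms,
    n_samples, duration_ms (duration = n_samples x sample period).
    ``onset_imagery_ms`` re-expresses the onset relative to the instructed
    imagery onset (cue + 500 ms).
    """

    onset_ms: float | None
    clusters: pd.DataFrame

    @property
    def onset_imagery_ms(self) -> float | None:
        return None if self.onset_ms is None else self.onset_ms - IMAGERY_ONSET_MS


def fmri_rdm(betas: RoiBetaSet) -> RDM:
    """12 x 12 correlation-distance RDM from all-runs node patterns."""
    if betas.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return RDM(values=correlation_rdm(betas.betas.T), metric="one_minus_pearson")


def eeg_rdm_timeseries(epochs: EpochedEEG) -> EegRdmSeries:
    """Per-timepoint RDMs from condition-mean sensor patterns.

    Trials are pooled over runs into one mean per condition; at each
    timepoint the entry (i, j) is 1 - Pearson across the channel vectors.
    Zero-variance channel vectors yield the nan sentinel.
    """
    if epochs.data.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    means = epochs.condition_means()  # (n_cond, n_ch, n_time)
    x = means.transpose(2, 0, 1)  # (n_time, n_cond, n_ch)
    xc = x - x.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(xc, axis=2)
    ok = norms > 0
    xn = xc / np.where(ok, norms, 1.0)[:, :, None]
    r = np.matmul(xn, xn.transpose(0, 2, 1))
    np.clip(r, -1.0, 1.0, out=r)
    d = 1.0 - r
    bad = ~ok
    if bad.any():
        d[np.broadcast_to(bad[:, :, None], d.shape)] = np.nan
        d[np.broadcast_to(bad[:, None, :], d.shape)] = np.nan
    idx = np.arange(x.shape[1])
    d[:, idx, idx] = 0.0
    return EegRdmSeries(time_ms=epochs.time_ms, values=d)


def _rank(v: np.ndarray, axis: int = -1) -> np.ndarray:
    return stats.rankdata(v, axis=axis)


def fuse(
    eeg_rdms: EegRdmSeries,
    roi_rdm: RDM,
    subject: int | str | None = None,
    roi: str | None = None,
    hemisphere: str = "lh",
) -> FusionTimeseries:
    """Spearman correlation of EEG RDMs with an fMRI RDM at each timepoint.

    Both RDMs are vectorized in the shared lower-triangle order; nan
    sentinel entries are removed pairwise, and timepoints with fewer than
    five valid pairs yield nan.
    """
    if eeg_rdms.values.shape[1] != roi_rdm.n_conditions:
        raise ValueError("condition order/count mismatch between modalities")
    v_roi = roi_rdm.vector()
    v_eeg = lower_triangle(eeg_rdms.values)  # (n_time, n_pairs)
    n_time = v_eeg.shape[0]
    rho = np.full(n_time, np.nan)
    nan_roi = ~np.isfinite(v_roi)
    nan_eeg = ~np.isfinite(v_eeg)
    clean = not nan_roi.any() and not nan_eeg.any()
    if clean:
        ra = _rank(v_eeg, axis=1)
        rb = _rank(v_roi)
        ra = ra - ra.mean(axis=1, keepdims=True)
        rb = rb - rb.mean()
        denom = np.linalg.norm(ra, axis=1) * np.linalg.norm(rb)
        num = ra @ rb
        valid = denom > 0
        rho[valid] = num[valid] / denom[valid]
    else:
        for ti in range(n_time):
            keep = ~(nan_roi | nan_eeg[ti])
            if keep.sum() < MIN_VALID_PAIRS:
                continue
            res = stats.spearmanr(v_eeg[ti, keep], v_roi[keep])
            rho[ti] = res.statistic
    return FusionTimeseries(
        time_ms=eeg_rdms.time_ms, rho=rho, subject=subject, roi=roi, hemisphere=hemisphere
    )


def hemisphere_average(lh: FusionTimeseries, rh: FusionTimeseries) -> FusionTimeseries:
    """Element-wise mean of the two hemispheres' fusion curves."""
    if lh.subject != rh.subject or lh.roi != rh.roi:
        raise ValueError("hemisphere averaging requires the same subject and ROI")
    if len(lh.time_ms) != len(rh.time_ms) or not np.allclose(lh.time_ms, rh.time_ms):
        raise ValueError("time grids differ between hemispheres")
    return FusionTimeseries(
        time_ms=lh.time_ms,
        rho=(lh.rho + rh.rho) / 2.0,
        subject=lh.subject,
        roi=lh.roi,
        hemisphere="avg",
    )


def difference_wave(a: FusionTimeseries, b: FusionTimeseries) -> FusionDifference:
    """Per-subject difference a - b between two ROIs' fusion curves."""
    if a.subject != b.subject:
        raise ValueError("difference waves are per-subject; subjects differ")
    if len(a.time_ms) != len(b.time_ms) or not np.allclose(a.time_ms, b.time_ms):
        raise ValueError("time grids differ")
    return FusionDifference(
        time_ms=a.time_ms,
        values=a.rho - b.rho,
        pair=f"{a.roi}-{b.roi}",
        subject=a.subject,
    )


def onset_latency(evidence: EvidenceSeries, min_duration_ms: float = 12.0) -> OnsetResult:
    """First sufficiently long cluster of BF10 > 3 in an evidence series.

    Clusters are maximal runs of consecutive timepoints with BF10 > 3 on a
    uniform grid; the duration of an n-sample run is n x dt.  Absence of a
    qualifying cluster is a regular "no onset" result.
    """
    time_ms = np.asarray(evidence.time_ms, dtype=float)
    if len(time_ms) < 2:
        raise ValueError("evidence series too short")
    dt = np.diff(time_ms)
    if not np.allclose(dt, dt[0]):
        raise ValueError("evidence series must be on a uniform grid")
    dt = float(dt[0])
    above = evidence.bf10 > BF_UPPER
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above.size and above[0]:
        starts.insert(0, 0)
    if above.size and above[-1]:
        ends.append(len(above) - 1)
    rows = []
    for s, e in zip(starts, ends):
        n = e - s + 1
        rows.append((time_ms[s], time_ms[e], n, n * dt))
    clusters = pd.DataFrame(rows, columns=["start_ms", "end_ms", "n_samples", "duration_ms"])
    onset = None
    qualifying = clusters[clusters["duration_ms"] >= min_duration_ms]
    if len(qualifying):
        onset = float(qualifying.iloc[0]["start_ms"])
    return OnsetResult(onset_ms=onset, clusters=clusters)
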