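"""ROI-level fMRI analyses: univariate contrast, pairwise decoding, masks.

The univariate contrast is the node-mean beta for places minus people
(percent signal change; positive = place-preferring).  Decoding runs a
linear SVM (libsvm via scikit-learn) over every stimulus pair with
leave-one-run-out cross-validation on the per-run node patterns, then
averages pair accuracies within the requested level so chance is 50%.
Hemispheres are analysed separately and averaged afterwards, before any
group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .rdm import PAIR_ACROSS, PAIR_WITHIN_PEOPLE, PAIR_WITHIN_PLACES
from .synth import CATEGORY_PEOPLE, RoiBetaSet, RoiMask

__all__ = [
    "ContrastResult",
    "RoiDecodingResult",
    "roi_contrast",
    "roi_decode",
    "average_hemispheres",
    "dice",
    "v1_eccentricity_split",
]

_LEVEL_TO_KIND = {
    "category": PAIR_ACROSS,
    "within_people": PAIR_WITHIN_PEOPLE,
    "within_places": PAIR_WITHIN_PLACES,
}


@dataclass
class ContrastResult:
    roi: str
    hemisphere: str
    contrast: float  # mean place beta - mean people beta, PSC


@dataclass
class RoiDecodingResult:
    roi: str
    hemisphere: str
    level: str
    accuracy: float  # percent, chance 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 100.0:
            raise ValueError("accuracy must lie in [0, 100]%")


def roi_contrast(betas: RoiBetaSet) -> ContrastResult:
    """Places-minus-people mean beta within an ROI (one hemisphere)."""
    if betas.n_nodes == 0:
        raise ValueError("empty ROI")
    cats = betas.category_of()
    place = betas.betas[:, cats != CATEGORY_PEOPLE].mean()
    people = betas.betas[:, cats == CATEGORY_PEOPLE].mean()
    return ContrastResult(roi=betas.roi, hemisphere=betas.hemisphere, contrast=float(place - people))


def roi_decode(
    betas: RoiBetaSet, level: str, C: float = 1.0, min_runs: int = 3
) -> RoiDecodingResult:
    """Pairwise stimulus decoding with leave-one-run-out CV, one hemisphere.

    Every stimulus pair is decoded from the per-run node patterns (one
    sample per stimulus per run); pair accuracies are then averaged within
    ``level`` (``category`` = across-category pairs, ``within_people`` /
    ``within_places`` = pairs inside one category).
    """
    if level not in _LEVEL_TO_KIND:
        raise ValueError(f"unknown level {level!r}")
    if betas.betas_by_run is None:
        raise ValueError("roi_decode needs per-run betas")
    n_runs = betas.betas_by_run.shape[2]
    if n_runs < min_runs:
        raise ValueError(f"need >= {min_runs} runs, got {n_runs}")
    if np.allclose(np.std(betas.betas_by_run, axis=0), 0.0):
        raise ValueError("degenerate (constant) node patterns")
    cats = betas.category_of()
    n_stim = betas.n_stimuli
    iu, ju = np.triu_indices(n_stim, 1)
    kind_target = _LEVEL_TO_KIND[level]
    accs = []
    for i, j in zip(iu, ju):
        both_people = cats[i] == CATEGORY_PEOPLE and cats[j] == CATEGORY_PEOPLE
        both_places = cats[i] != CATEGORY_PEOPLE and cats[j] != CATEGORY_PEOPLE
        kind = (
            PAIR_WITHIN_PEOPLE if both_people else PAIR_WITHIN_PLACES if both_places else PAIR_ACROSS
        )
        if kind != kind_target:
            continue
        correct = 0
        total = 0
        for held in range(n_runs):
            train_runs = [r for r in range(n_runs) if r != held]
            x_tr = np.concatenate(
                [betas.betas_by_run[:, [i, j], r].T for r in train_runs]
            )
            y_tr = np.tile([0, 1], len(train_runs))
            x_te = betas.betas_by_run[:, [i, j], held].T
            clf = SVC(kernel="linear", C=C)
            clf.fit(x_tr, y_tr)
            pred = clf.predict(x_te)
            correct += int(pred[0] == 0) + int(pred[1] == 1)
            total += 2
        accs.append(correct / total)
    if not accs:
        raise ValueError(f"no pairs of kind {level!r}")
    return RoiDecodingResult(
        roi=betas.roi,
        hemisphere=betas.hemisphere,
        level=level,
        accuracy=100.0 * float(np.mean(accs)),
    )


def average_hemispheres(
    lh: RoiDecodingResult | ContrastResult, rh: RoiDecodingResult | ContrastResult
):
    """Average per-hemisphere results for one ROI (after decoding/contrast)."""
    if lh.roi != rh.roi or type(lh) is not type(rh):
        raise ValueError("hemisphere results must refer to the same ROI and measure")
    if isinstance(lh, ContrastResult):
        return ContrastResult(roi=lh.roi, hemisphere="avg", contrast=(lh.contrast + rh.contrast) / 2.0)
    if lh.level != rh.level:
        raise ValueError("levels differ between hemispheres")
    return RoiDecodingResult(
        roi=lh.roi,
        hemisphere="avg",
        level=lh.level,
        accuracy=(lh.accuracy + rh.accuracy) / 2.0,
    )


def dice(a: RoiMask, b: RoiMask) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|), 1 for identical masks."""
    if len(a) == 0 and len(b) == 0:
        raise ValueError("both masks are empty")
    overlap = len(a.nodes & b.nodes)
    return 2.0 * overlap / (len(a) + len(b))


def v1_eccentricity_split(
    mask: RoiMask, eccentricity: dict[int, float], threshold_deg: float = 4.0
) -> tuple[RoiMask, RoiMask]:
    """Partition V1 nodes into foveal (ecc <= threshold) and peripheral.

    A node exactly at the threshold counts as foveal ("up to" the
    threshold).  Every node must have an eccentricity value.
    """
    missing = [n for n in mask.nodes if n not in eccentricity]
    if missing:
        raise ValueError(f"missing eccentricities for nodes {sorted(missing)[:5]}...")
    foveal = frozenset(n for n in mask.nodes if eccentricity[n] <= threshold_deg)
    peripheral = frozenset(mask.nodes - foveal)
    return (
        RoiMask(roi=f"{mask.roi}_foveal", hemisphere=mask.hemisphere, nodes=foveal),
        RoiMask(roi=f"{mask.roi}_peripheral", hemisphere=mask.hemisphere, nodes=peripheral),
    )
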