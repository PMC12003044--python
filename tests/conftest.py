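import dataclasses

import numpy as np
import pandas as pd
import pytest

from imfusion.synth import (
    BlockGeometry,
    EpochedEEG,
    GroundTruth,
    RoiSpec,
    default_rois,
    make_design,
)


def small_truth(**overrides) -> GroundTruth:
    """A scaled-down truth (24 ch, 64 Hz, 1.2 s epochs, 30-node ROIs)."""
    rois = {
        name: dataclasses.replace(spec, n_nodes=30, latency_ms=(300.0, 1000.0))
        for name, spec in default_rois().items()
    }
    base = dict(
        n_subjects=3,
        n_channels=24,
        srate=64.0,
        epoch_ms=(-200.0, 1000.0),
        category_latency_ms=(300.0, 1000.0),
        rois=rois,
        seed=11,
    )
    base.update(overrides)
    return GroundTruth(**base)


@pytest.fixture
def tiny_truth() -> GroundTruth:
    return small_truth()


def epochs_from_array(data: np.ndarray, conditions: np.ndarray, srate: float = 100.0,
                      n_people: int | None = None) -> EpochedEEG:
    """Wrap a raw (trials, channels, time) array as EpochedEEG."""
    n_cond = int(conditions.max())
    if n_people is None:
        n_people = n_cond // 2
    labels = pd.DataFrame(
        {
            "run": 1,
            "trial": np.arange(1, len(conditions) + 1),
            "condition": conditions,
            "category": np.where(conditions <= n_people, "people", "places"),
        }
    )
    dt = 1000.0 / srate
    time_ms = dt * np.arange(data.shape[2])
    return EpochedEEG(data=data, time_ms=time_ms, srate=srate, labels=labels)
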