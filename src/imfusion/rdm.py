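"""Representational dissimilarity matrices (RDMs) and pair-index bookkeeping.

An RDM summarises the geometry of a set of condition-evoked activity
patterns as a symmetric matrix of pairwise dissimilarities.  Throughout the
package the canonical condition order is people exemplars first, then place
exemplars (6 + 6 = 12 under the default design), and the canonical
vectorization of the off-diagonal entries is the lower triangle in
column-major order, which coincides with the pair order used by
:func:`scipy.spatial.distance.pdist` (``(0,1), (0,2), ... (10,11)``).

Zero-variance patterns cannot enter a correlation distance; the affected
entries are set to ``nan`` (the documented sentinel) and are dropped
pairwise by downstream rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RDM",
    "correlation_rdm",
    "lower_triangle",
    "squareform_vector",
    "pair_table",
    "PAIR_ACROSS",
    "PAIR_WITHIN_PEOPLE",
    "PAIR_WITHIN_PLACES",
]

PAIR_ACROSS = "across"
PAIR_WITHIN_PEOPLE = "within_people"
PAIR_WITHIN_PLACES = "within_places"


@dataclass
class RDM:
    """A symmetric dissimilarity matrix with a metric tag.

    Parameters
    ----------
    values:
        ``(n, n)`` array, symmetric with a zero diagonal.  Off-diagonal
        entries may be ``nan`` where a pattern was degenerate.
    metric:
        ``"one_minus_pearson"`` or ``"euclidean"``.
    """

    values: np.ndarray
    metric: str = "one_minus_pearson"
    condition_order: str = "people_then_places"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"RDM must be square, got shape {v.shape}")
        if not np.allclose(np.diag(v), 0.0, equal_nan=False):
            raise ValueError("RDM diagonal must be zero")
        finite = np.isfinite(v)
        if not np.allclose(
            np.where(finite & finite.T, v, 0.0),
            np.where(finite & finite.T, v.T, 0.0),
            atol=1e-10,
        ):
            raise ValueError("RDM must be symmetric")
        self.values = v

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    def vector(self) -> np.ndarray:
        """Lower-triangle entries in the canonical (pdist) order."""
        return lower_triangle(self.values)


def lower_triangle(values: np.ndarray) -> np.ndarray:
    """Vectorize the strict lower triangle in column-major order.

    For a symmetric matrix this equals the row-major upper triangle, i.e.
    the pdist/squareform convention; both modalities use this single order
    so that fusion correlates matched condition pairs.
    """
    values = np.asarray(values)
    n = values.shape[-1]
    iu, ju = np.triu_indices(n, 1)
    return values[..., iu, ju]


def squareform_vector(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`lower_triangle` (zero diagonal)."""
    out = np.zeros((n, n), dtype=float)
    iu, ju = np.triu_indices(n, 1)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def correlation_rdm(patterns: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows of ``patterns``.

    Rows with zero variance across features yield ``nan`` off-diagonal
    entries (sentinel for "undefined"); the diagonal is always zero.
    """
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 2:
        raise ValueError("patterns must be 2-D (conditions x features)")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features per pattern")
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    ok = norms > 0
    denom = np.where(ok, norms, 1.0)
    xn = xc / denom[:, None]
    r = xn @ xn.T
    np.clip(r, -1.0, 1.0, out=r)
    d = 1.0 - r
    bad = ~ok
    d[bad, :] = np.nan
    d[:, bad] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def pair_table(n_people: int = 6, n_places: int = 6) -> pd.DataFrame:
    """All condition pairs in canonical order, labelled by pair kind.

    Returns a frame with columns ``i``, ``j`` (0-based condition indices,
    ``i < j``) and ``kind`` in {across, within_people, within_places}.
    With the default 6 + 6 design this is 36 + 15 + 15 = 66 pairs.
    """
    n = n_people + n_places
    iu, ju = np.triu_indices(n, 1)
    kind = np.where(
        (iu < n_people) & (ju < n_people),
        PAIR_WITHIN_PEOPLE,
        np.where((iu >= n_people) & (ju >= n_people), PAIR_WITHIN_PLACES, PAIR_ACROSS),
    )
    return pd.DataFrame({"i": iu, "j": ju, "kind": kind})
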