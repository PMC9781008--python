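"""Kennard-Stone selection of a representative calibration subset.

The classical max-min algorithm on Euclidean row distances: seed with
the most distant pair, then repeatedly add the sample farthest (in
min-distance) from everything already selected.  Fully deterministic;
ties break toward the lowest row index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist


@dataclass
class SplitResult:
    """Calibration ids in selection order plus the remaining test ids."""

    calibration_ids: list
    test_ids: list


def default_n_cal(n: int) -> int:
    """Calibration size at the study's 15:4 calibration:test ratio."""
    return max(2, round(n * 15 / 19))


def kennard_stone(X: np.ndarray, n_cal: int, ids: list | None = None) -> SplitResult:
    """Split rows of X into calibration/test by the Kennard-Stone rule.

    Parameters
    ----------
    X : array (n_samples, n_features)
        Preprocessed spectra (distances are Euclidean on rows).
    n_cal : int
        Number of calibration samples, 2 <= n_cal <= n_samples.
    ids : sequence, optional
        Sample identifiers; defaults to row indices.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 2 <= n_cal <= n:
        raise ValueError(f"n_cal must be in [2, {n}], got {n_cal}")
    if ids is None:
        ids = list(range(n))
    if len(ids) != n:
        raise ValueError("ids length must match number of rows")

    D = squareform(pdist(X))
    # seed pair: maximum pairwise distance, first occurrence in row-major
    # order => lowest indices on ties
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    while len(selected) < n_cal:
        mind = D[np.ix_(remaining, selected)].min(axis=1)
        k = int(np.argmax(mind))  # first max => lowest index tie-break
        selected.append(remaining.pop(k))
    return SplitResult(
        calibration_ids=[ids[k] for k in selected],
        test_ids=[ids[k] for k in range(n) if k not in selected],
    )
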