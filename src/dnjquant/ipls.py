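"""Stepwise-forward interval PLS over wavenumber windows.

Candidate windows are contiguous blocks of ``interval_size`` variables
placed every ``step`` variables (with a final window anchored at the
grid end so coverage is complete).  Forward selection greedily adds the
window whose union with the current selection minimizes LOO RMSE_CV,
stopping when the best addition no longer improves the error by more
than a relative threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pls_core

#: Fingerprint windows used for the final DNJ model: pyranose-ring
#: C-O/C-C stretches, C-H bending, and the N-H/aromatic region (cm^-1).
DNJ_INTERVALS = ((1101.0, 1196.0), (1333.0, 1427.0), (1603.0, 1697.0))


@dataclass
class IntervalSet:
    """Ordered wavenumber windows plus the resolved grid-column indices."""

    intervals: list
    variable_indices: np.ndarray

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("an IntervalSet needs at least one interval")
        for lo, hi in self.intervals:
            if lo >= hi:
                raise ValueError(f"invalid interval ({lo}, {hi}): start must be < end")
        self.variable_indices = np.unique(np.asarray(self.variable_indices, dtype=int))
        if self.variable_indices.size == 0:
            raise ValueError("an IntervalSet resolves to no variables")


def make_intervals(grid: np.ndarray, interval_size: int = 30, step: int = 10) -> list:
    """Candidate windows: starts 0, step, 2*step, ... plus an end-anchored
    window so every variable is covered.  ``interval_size >= n`` collapses
    to a single full-range window."""
    grid = np.asarray(grid, dtype=float)
    n = grid.size
    if interval_size < 2:
        raise ValueError("interval_size must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if interval_size >= n:
        return [IntervalSet([(grid[0], grid[-1])], np.arange(n))]
    starts = list(range(0, n - interval_size + 1, step))
    if starts[-1] + interval_size < n:
        starts.append(n - interval_size)
    out = []
    for s in starts:
        idx = np.arange(s, s + interval_size)
        out.append(IntervalSet([(grid[idx[0]], grid[idx[-1]])], idx))
    return out


def resolve_intervals(grid: np.ndarray, named: list) -> IntervalSet:
    """Resolve (start, end) cm^-1 ranges to grid indices (inclusive ends).

    Touching/overlapping ranges merge; indices are deduplicated.
    """
    grid = np.asarray(grid, dtype=float)
    if not named:
        raise ValueError("no intervals given")
    idx = []
    for lo, hi in named:
        if lo >= hi:
            raise ValueError(f"invalid interval ({lo}, {hi})")
        if hi < grid[0] or lo > grid[-1]:
            raise ValueError(f"interval ({lo}, {hi}) cm^-1 lies outside the grid")
        hit = np.flatnonzero((grid >= lo) & (grid <= hi))
        if hit.size == 0:
            raise ValueError(f"interval ({lo}, {hi}) cm^-1 contains no grid points")
        idx.append(hit)
    return IntervalSet([tuple(map(float, r)) for r in named], np.concatenate(idx))


def forward_ipls(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    candidates: list | None = None,
    max_intervals: int | None = None,
    n_lv: int | str = "auto",
    max_lv: int = 6,
    improve_tol: float = 0.005,
):
    """Greedy forward interval selection minimizing LOO RMSE_CV.

    Parameters
    ----------
    X, y : preprocessed (baseline + SNV) calibration spectra and response.
        Autoscaling is refitted inside every candidate evaluation.
    candidates : list of IntervalSet, optional
        Defaults to ``make_intervals(grid)`` with the standard 30/10
        window layout.
    max_intervals : int, optional
        Hard cap on accepted windows (None = "auto": stop when the best
        addition improves RMSE_CV by less than ``improve_tol`` relative).
    n_lv : int or "auto"
        Fixed LV count, or per-evaluation parsimonious selection up to
        ``max_lv``.

    Returns
    -------
    (IntervalSet, PLSModel, DataFrame) : the merged selection, the final
    model fitted on it, and the per-round audit history.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float)
    if candidates is None:
        candidates = make_intervals(grid)
    if not candidates:
        raise ValueError("no candidate intervals")
    n = X.shape[0]

    def eval_union(idx: np.ndarray):
        """(rmse_cv, k) for a variable union under the LV rule."""
        kcap = min(max_lv, n - 2, idx.size)
        curve = pls_core.loo_rmse_curve(X, y, kcap, variable_mask=idx)
        if isinstance(n_lv, int):
            k = min(n_lv, kcap)
            return float(curve[k - 1]), k
        thresh = curve.min() * 1.01
        k = int(np.flatnonzero(curve <= thresh)[0]) + 1
        return float(curve[k - 1]), k

    unused = list(range(len(candidates)))
    chosen: list[int] = []
    current_idx = np.array([], dtype=int)
    best_rmse = np.inf
    history = []
    cap = max_intervals if max_intervals is not None else len(candidates)
    while unused and len(chosen) < cap:
        round_best = None
        for ci in unused:
            union = np.union1d(current_idx, candidates[ci].variable_indices)
            rmse, k = eval_union(union)
            if round_best is None or rmse < round_best[0]:
                round_best = (rmse, ci, k, union)
        rmse, ci, k, union = round_best
        if chosen and not (best_rmse - rmse) / best_rmse > improve_tol:
            break
        chosen.append(ci)
        unused.remove(ci)
        current_idx = union
        best_rmse = rmse
        w = candidates[ci]
        history.append(
            {
                "round": len(chosen),
                "window_start_cm": w.intervals[0][0],
                "window_end_cm": w.intervals[0][1],
                "rmse_cv": rmse,
                "n_lv": k,
            }
        )

    final_rmse, final_k = eval_union(current_idx)
    model = pls_core.fit_pls(X, y, final_k, variable_mask=current_idx, wavenumbers=grid)
    intervals = [candidates[ci].intervals[0] for ci in chosen]
    selection = IntervalSet(intervals, current_idx)
    return selection, model, pd.DataFrame(history)
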