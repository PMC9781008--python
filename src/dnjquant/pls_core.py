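"""PLS1 regression engine (NIPALS) with metrics and LV selection.

The model encapsulates its own variable scaling: ``fit_pls`` receives
preprocessed but unscaled spectra, autoscales them (parameters stored on
the model), centers the response, and runs NIPALS with X-deflation.
Predictions are returned in the original response units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import AutoscaleParams, autoscale_apply, autoscale_fit


@dataclass
class Metrics:
    """Coefficient of determination and root-mean-square error."""

    r2: float
    rmse: float


@dataclass
class PLSModel:
    n_lv: int
    x_weights: np.ndarray      # (p, k), unit-norm deflated weights W
    x_loadings: np.ndarray     # (p, k) loadings P
    y_loadings: np.ndarray     # (k,) loadings q
    scores: np.ndarray         # (n, k) calibration scores T
    regression_vector: np.ndarray  # (p,) b on autoscaled variables
    autoscale_params: AutoscaleParams
    y_center: float
    variable_mask: np.ndarray | None = None
    provenance: list = field(default_factory=list)


def _nipals(Xs: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on scaled X / centered y.  Returns W, P, q, T."""
    n, p = Xs.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    Xd, yd = Xs.copy(), yc.copy()
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-13:  # response exhausted; truncate
            return W[:, :a], P[:, :a], q[:a], T[:, :a]
        w /= nw
        t = Xd @ w
        tt = t @ t
        p_a = Xd.T @ t / tt
        q_a = yd @ t / tt
        Xd -= np.outer(t, p_a)
        yd -= q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
    return W, P, q, T


def _regression_vectors(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """b_k = W_k (P_k^T W_k)^-1 q_k for every k = 1..K, as columns."""
    K = W.shape[1]
    B = np.zeros((W.shape[0], K))
    for k in range(1, K + 1):
        M = P[:, :k].T @ W[:, :k]
        B[:, k - 1] = W[:, :k] @ np.linalg.solve(M, q[:k])
    return B


def _apply_mask(X: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if mask is None:
        return X
    if X.shape[1] == mask.size:
        return X
    return X[:, mask]


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    variable_mask: np.ndarray | None = None,
    wavenumbers: np.ndarray | None = None,
) -> PLSModel:
    """Fit a PLS1 model with internal autoscaling and y-centering.

    ``variable_mask`` restricts the model to a column subset of X
    (interval selection); autoscaling is fitted on exactly the modelled
    columns.  ``n_lv`` must satisfy 1 <= n_lv <= min(n-1, p).
    """
    y = np.asarray(y, dtype=float).ravel()
    mask = None if variable_mask is None else np.asarray(variable_mask, dtype=int)
    Xm = _apply_mask(X, mask)
    n, p = Xm.shape
    if n != y.size:
        raise ValueError("X rows and y length differ")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    kmax = min(n - 1, p)
    if not 1 <= n_lv <= kmax:
        raise ValueError(f"n_lv must be in [1, {kmax}], got {n_lv}")
    wn = None
    if wavenumbers is not None:
        wn = np.asarray(wavenumbers, dtype=float)
        if mask is not None and wn.size != p:
            wn = wn[mask]
    params = autoscale_fit(Xm, wn)
    Xs = autoscale_apply(Xm, params)
    y_center = float(y.mean())
    W, P, q, T = _nipals(Xs, y - y_center, n_lv)
    b = _regression_vectors(W, P, q)[:, -1] if W.shape[1] else np.zeros(p)
    return PLSModel(
        n_lv=W.shape[1],
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        regression_vector=b,
        autoscale_params=params,
        y_center=y_center,
        variable_mask=mask,
    )


def transform(m: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Project new rows into the model's latent-score space."""
    Xs = autoscale_apply(_apply_mask(X_new, m.variable_mask), m.autoscale_params)
    R = m.x_weights @ np.linalg.inv(m.x_loadings.T @ m.x_weights)
    return Xs @ R


def predict(m: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted concentrations for new spectra (original y units)."""
    Xm = _apply_mask(X_new, m.variable_mask)
    if Xm.shape[1] != m.regression_vector.size:
        raise ValueError(
            f"grid mismatch: model has {m.regression_vector.size} variables, "
            f"input has {Xm.shape[1]}"
        )
    Xs = autoscale_apply(Xm, m.autoscale_params)
    return Xs @ m.regression_vector + m.y_center


def compute_metrics(y: np.ndarray, y_hat: np.ndarray) -> Metrics:
    """RMSE and R^2 of predictions against reference values."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 values")
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("R^2 undefined for a constant response")
    rss = np.sum((y - y_hat) ** 2)
    return Metrics(r2=float(1.0 - rss / tss), rmse=float(np.sqrt(rss / y.size)))


def loo_rmse_curve(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    variable_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Leave-one-out RMSE_CV for every LV count 1..max_lv in one pass.

    Each fold refits the full chain (autoscaling + NIPALS) on n-1 rows
    and predicts the held-out row at every truncation of the model.
    """
    y = np.asarray(y, dtype=float).ravel()
    Xm = _apply_mask(X, None if variable_mask is None else np.asarray(variable_mask, int))
    n = Xm.shape[0]
    if n < 3:
        raise ValueError("LOO needs at least 3 samples")
    kmax = min(n - 2, Xm.shape[1])
    if not 1 <= max_lv <= kmax:
        raise ValueError(f"max_lv must be in [1, {kmax}], got {max_lv}")
    press = np.zeros(max_lv)
    for i in range(n):
        keep = np.arange(n) != i
        params = autoscale_fit(Xm[keep])
        Xs = autoscale_apply(Xm[keep], params)
        yc = y[keep] - y[keep].mean()
        W, P, q, _ = _nipals(Xs, yc, max_lv)
        B = _regression_vectors(W, P, q)
        xs_i = autoscale_apply(Xm[i : i + 1], params)
        preds = (xs_i @ B).ravel() + y[keep].mean()
        if preds.size < max_lv:  # truncated fit: pad with last prediction
            preds = np.concatenate([preds, np.full(max_lv - preds.size, preds[-1] if preds.size else y[keep].mean())])
        press += (y[i] - preds) ** 2
    return np.sqrt(press / n)


def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    variable_mask: np.ndarray | None = None,
) -> Metrics:
    """Leave-one-out cross-validation metrics at a fixed LV count.

    R^2_CV is 1 - PRESS / TSS with TSS taken on the full response.
    """
    y = np.asarray(y, dtype=float).ravel()
    rmse = float(loo_rmse_curve(X, y, n_lv, variable_mask)[n_lv - 1])
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("R^2 undefined for a constant response")
    return Metrics(r2=float(1.0 - y.size * rmse**2 / tss), rmse=rmse)


def select_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    variable_mask: np.ndarray | None = None,
    rel_tol: float = 0.01,
) -> int:
    """Parsimonious near-minimum rule: the smallest LV count whose
    RMSE_CV is within ``rel_tol`` (relative) of the global minimum."""
    curve = loo_rmse_curve(X, y, max_lv, variable_mask)
    thresh = curve.min() * (1.0 + rel_tol)
    return int(np.flatnonzero(curve <= thresh)[0]) + 1
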