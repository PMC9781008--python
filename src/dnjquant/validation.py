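"""Model-quality battery: external-test metrics, Y-randomization,
Williams-plot applicability domain.

Y-randomization refits the whole calibration chain on permuted
responses and compares the real cross-validated R^2 against the
permuted population three ways: Wilcoxon signed-rank and sign test on
the paired differences, plus the empirical randomization p-value.
The applicability domain follows the conventional Williams-plot
cutoffs: warning leverage h* = 3(k+1)/n and |studentized residual| > 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import pls_core
from .pls_core import Metrics, PLSModel


@dataclass
class PermutationReport:
    n_permutations: int
    permuted_r2cv: np.ndarray
    real_r2cv: float
    p_wilcoxon: float
    p_sign: float
    p_randt: float
    passed: dict = field(default_factory=dict)


@dataclass
class ADReport:
    sample_ids: list
    leverages: np.ndarray
    studentized_residuals: np.ndarray
    outside_domain: np.ndarray
    warning_leverage: float
    is_calibration: np.ndarray


@dataclass
class ValidationReport:
    n_lv: int
    r2_cal: float
    rmse_cal: float
    r2_cv: float
    rmse_cv: float
    r2_pred: float | None = None
    rmse_pred: float | None = None
    permutation: PermutationReport | None = None
    ad: ADReport | None = None


def evaluate(
    model: PLSModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> ValidationReport:
    """Calibration, LOO cross-validation and (if a test set is given)
    external-prediction metrics for a fitted model."""
    cal = pls_core.compute_metrics(y_cal, pls_core.predict(model, X_cal))
    cv = pls_core.loo_cv(X_cal, y_cal, model.n_lv, model.variable_mask)
    rep = ValidationReport(
        n_lv=model.n_lv,
        r2_cal=cal.r2,
        rmse_cal=cal.rmse,
        r2_cv=cv.r2,
        rmse_cv=cv.rmse,
    )
    if X_test is not None and np.atleast_2d(X_test).shape[0] > 0:
        pred = pls_core.compute_metrics(y_test, pls_core.predict(model, X_test))
        rep.r2_pred, rep.rmse_pred = pred.r2, pred.rmse
    return rep


def y_randomization(
    X: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 100,
    n_lv: int = 6,
    seed: int = 0,
    variable_mask: np.ndarray | None = None,
    alpha: float = 0.05,
) -> PermutationReport:
    """Robustness test: does the real model beat chance?

    Each permutation shuffles y (multiset preserved), refits the full
    chain at fixed ``n_lv`` and records R^2_CV.  One-sided p-values test
    whether real R^2_CV exceeds the permuted population; the empirical
    randomization p is (1 + #{permuted >= real}) / (n + 1).
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.std(y) == 0:
        raise ValueError("constant response")
    if n_permutations < 20:
        raise ValueError("n_permutations must be >= 20")
    rng = np.random.default_rng(seed)
    real = pls_core.loo_cv(X, y, n_lv, variable_mask).r2
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm[i] = pls_core.loo_cv(X, rng.permutation(y), n_lv, variable_mask).r2
    d = real - perm
    p_wilcoxon = float(stats.wilcoxon(d, alternative="greater").pvalue)
    nz = d[d != 0]
    p_sign = float(stats.binomtest(int((nz > 0).sum()), nz.size, alternative="greater").pvalue)
    p_randt = float((1 + (perm >= real).sum()) / (n_permutations + 1))
    return PermutationReport(
        n_permutations=n_permutations,
        permuted_r2cv=perm,
        real_r2cv=float(real),
        p_wilcoxon=p_wilcoxon,
        p_sign=p_sign,
        p_randt=p_randt,
        passed={
            "wilcoxon": p_wilcoxon < alpha,
            "sign": p_sign < alpha,
            "randomization": p_randt < alpha,
        },
    )


def applicability_domain(
    model: PLSModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_query: np.ndarray | None = None,
    y_query: np.ndarray | None = None,
    query_ids: list | None = None,
    cal_ids: list | None = None,
) -> ADReport:
    """Williams-plot diagnostics in latent-score space.

    Leverage is h = 1/n + t^T (T^T T)^-1 t with T the calibration
    scores; query rows are projected through the model.  Calibration
    residuals are studentized with the (1 - h) correction; query
    residuals (when reference values are supplied) use residual/s only,
    since query leverage is not bounded by one.
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    T = model.scores
    n, k = T.shape
    G = T.T @ T
    if np.linalg.cond(G) > 1e12:
        raise np.linalg.LinAlgError("singular score covariance (T^T T)")
    Gi = np.linalg.inv(G)
    h_cal = 1.0 / n + np.einsum("ij,jk,ik->i", T, Gi, T)
    resid = y_cal - pls_core.predict(model, X_cal)
    dof = n - k - 1
    if dof <= 0:
        raise ValueError("too few calibration samples to studentize residuals")
    s = float(np.sqrt((resid**2).sum() / dof))
    with np.errstate(divide="ignore", invalid="ignore"):
        stud_cal = resid / (s * np.sqrt(np.clip(1.0 - h_cal, 1e-12, None)))

    hs, studs, is_cal = [h_cal], [stud_cal], [np.ones(n, bool)]
    ids = list(cal_ids) if cal_ids is not None else list(range(n))
    if X_query is not None and np.atleast_2d(X_query).shape[0] > 0:
        Tq = pls_core.transform(model, X_query)
        h_q = 1.0 / n + np.einsum("ij,jk,ik->i", Tq, Gi, Tq)
        m = Tq.shape[0]
        if y_query is not None:
            rq = np.asarray(y_query, dtype=float).ravel() - pls_core.predict(model, X_query)
            stud_q = rq / s
        else:
            stud_q = np.full(m, np.nan)
        hs.append(h_q)
        studs.append(stud_q)
        is_cal.append(np.zeros(m, bool))
        ids += list(query_ids) if query_ids is not None else [f"q{i}" for i in range(m)]

    h = np.concatenate(hs)
    stud = np.concatenate(studs)
    h_star = 3.0 * (k + 1) / n
    with np.errstate(invalid="ignore"):
        outside = (h > h_star) | (np.abs(stud) > 3.0)
    return ADReport(
        sample_ids=ids,
        leverages=h,
        studentized_residuals=stud,
        outside_domain=outside,
        warning_leverage=float(h_star),
        is_calibration=np.concatenate(is_cal),
    )


def williams_plot(ad: ADReport, path: str) -> None:
    """Render leverage vs studentized residual with h* and ±3 guides."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    cal = ad.is_calibration
    ax.scatter(ad.leverages[cal], ad.studentized_residuals[cal], label="calibration", marker="o")
    if (~cal).any():
        ax.scatter(ad.leverages[~cal], ad.studentized_residuals[~cal], label="test", marker="D")
    ax.axvline(ad.warning_leverage, ls="--", color="crimson", label="h*")
    for yv in (-3, 3):
        ax.axhline(yv, ls=":", color="gray")
    ax.set_xlabel("leverage")
    ax.set_ylabel("studentized residual")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
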