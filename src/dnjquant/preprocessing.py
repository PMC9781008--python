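"""Spectral preprocessing: WLS baseline removal, SNV, autoscaling.

The chain applied before modelling is: average replicates per product,
subtract an asymmetric weighted-least-squares polynomial baseline from
each spectrum, standard-normal-variate transform each spectrum, and
(at model-fit time, on calibration rows only) autoscale each variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SpectraDataset


@dataclass
class Spectrum:
    """A single spectrum: strictly ascending wavenumbers plus absorbance."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValueError("wavenumbers and absorbance must have equal length")
        if self.wavenumbers.size > 1 and np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        if np.any(~np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")


@dataclass
class AutoscaleParams:
    """Column means and (n-1) standard deviations fitted on calibration rows."""

    column_means: np.ndarray
    column_sds: np.ndarray


def _wls_baseline(y: np.ndarray, poly_order: int, max_iter: int, tol: float) -> np.ndarray:
    """Asymmetric IRLS polynomial baseline on an index grid mapped to [-1, 1].

    Points above the current baseline (positive residuals, i.e. peaks)
    are down-weighted by exp(-r/sigma) where sigma is the spread of the
    non-peak (non-positive) residuals, so that peak points cannot
    inflate their own tolerance; points on/below keep weight 1.
    Iteration stops when the weight vector is stable in relative L2 norm.
    """
    n = y.size
    x = np.linspace(-1.0, 1.0, n)
    V = np.vander(x, poly_order + 1, increasing=True)
    w = np.ones(n)
    baseline = np.zeros(n)
    for _ in range(max_iter):
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * sw[:, None], y * sw, rcond=None)
        baseline = V @ coef
        r = y - baseline
        pos = r > 0
        if not np.any(pos):
            break
        sigma = r[~pos].std() if np.any(~pos) else r[pos].std()
        if sigma <= 0:
            sigma = r[pos].std()
        if sigma <= 0:
            break
        w_new = np.where(pos, np.exp(-r / sigma), 1.0)
        delta = np.linalg.norm(w_new - w) / max(np.linalg.norm(w), 1e-300)
        w = w_new
        if delta < tol:
            break
    return baseline


def wls_baseline(
    s: Spectrum, poly_order: int = 2, max_iter: int = 100, tol: float = 1e-6
):
    """Weighted-least-squares baseline correction of one spectrum.

    Returns ``(baseline, corrected)`` where ``corrected = s - baseline``.
    """
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    if poly_order >= s.absorbance.size:
        raise ValueError(
            f"poly_order {poly_order} requires more than {s.absorbance.size} points"
        )
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    b = _wls_baseline(s.absorbance, poly_order, max_iter, tol)
    return Spectrum(s.wavenumbers, b), Spectrum(s.wavenumbers, s.absorbance - b)


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum (x - mean) / sd with n-1 sd.

    Removes additive offsets and multiplicative scatter; the output has
    mean 0 and sample standard deviation 1.
    """
    a = s.absorbance
    if a.size < 2:
        raise ValueError("SNV requires at least 2 points")
    sd = a.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a zero-variance spectrum")
    return Spectrum(s.wavenumbers, (a - a.mean()) / sd)


def autoscale_fit(X: np.ndarray, wavenumbers: np.ndarray | None = None) -> AutoscaleParams:
    """Fit per-variable mean/sd on calibration rows only."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("autoscale_fit needs at least 2 calibration rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        j = bad[0]
        where = (
            f"wavenumber {wavenumbers[j]:g} cm^-1"
            if wavenumbers is not None
            else f"column {j}"
        )
        raise ValueError(f"zero-variance variable at {where}")
    return AutoscaleParams(means, sds)


def autoscale_apply(X: np.ndarray, p: AutoscaleParams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X - p.column_means) / p.column_sds


def autoscale_invert(X: np.ndarray, p: AutoscaleParams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X * p.column_sds + p.column_means


def preprocess_pipeline(
    ds: SpectraDataset,
    poly_order: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
    average: bool = True,
) -> SpectraDataset:
    """Replicate averaging -> WLS baseline -> SNV, per spectrum.

    Autoscaling is deliberately deferred to model fitting so its
    parameters are estimated on calibration rows only.  The applied
    chain is appended to the dataset provenance.
    """
    work = ds.average_replicates() if average else ds
    out = np.empty_like(work.absorbance)
    for i in range(work.n_samples):
        s = Spectrum(work.wavenumbers, work.absorbance[i])
        _, corrected = wls_baseline(s, poly_order, max_iter, tol)
        out[i] = snv(corrected).absorbance
    return SpectraDataset(
        work.wavenumbers,
        out,
        work.metadata.copy(),
        list(work.provenance) + ["baseline", "snv"],
    )
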