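"""Wet-chemistry validation math: linear calibration with ICH Q2
LOD/LOQ, recovery, precision (%RSD), DPPH inhibition and EC50,
content conversion and RDI coverage.

Conventions: calibration levels in µg/mL, peak areas in arbitrary area
units, LOD/LOQ reported in ng/mL; sigma is the standard deviation of
the blank response (n >= 6 injections), not a regression residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

LOQ_LOD_RATIO = 10.0 / 3.3


@dataclass
class CalibrationCurve:
    slope: float          # area per (µg/mL)
    intercept: float      # area
    r2: float
    sigma: float          # sd of blank response (area)
    lod: float            # ng/mL
    loq: float            # ng/mL
    range_low: float      # µg/mL
    range_high: float     # µg/mL


@dataclass
class DoseResponseResult:
    ec50: float
    curve_points: np.ndarray  # (n, 2): concentration, inhibition%


def loq_from_lod(lod: float) -> float:
    """ICH Q2 ratio: LOQ = LOD * 10 / 3.3 (exact)."""
    return lod * LOQ_LOD_RATIO


def lod_from_blank(sigma: float, slope: float) -> float:
    """ICH Q2 detection limit, 3.3 sigma / S, in the calibration's
    concentration units."""
    if slope <= 0:
        raise ValueError("slope must be > 0")
    return 3.3 * sigma / slope


def loq_from_blank(sigma: float, slope: float) -> float:
    """ICH Q2 quantification limit, 10 sigma / S."""
    if slope <= 0:
        raise ValueError("slope must be > 0")
    return 10.0 * sigma / slope


def fit_calibration(levels, areas, blanks, unit_factor: float = 1000.0) -> CalibrationCurve:
    """OLS calibration line plus blank-based detection limits.

    LOD = 3.3 sigma / S and LOQ = 10 sigma / S, where sigma is the
    (n-1) standard deviation of >= 6 blank responses and S the slope.
    With levels in µg/mL the default ``unit_factor`` of 1000 reports the
    limits in ng/mL; pass 1 to stay in the level units.
    """
    levels = np.asarray(levels, dtype=float)
    areas = np.asarray(areas, dtype=float)
    blanks = np.asarray(blanks, dtype=float)
    if np.unique(levels).size < 3:
        raise ValueError("need at least 3 distinct calibration levels")
    if blanks.size < 6:
        raise ValueError("need at least 6 blank responses for sigma")
    fit = stats.linregress(levels, areas)
    if fit.slope <= 0:
        raise ValueError(f"invalid calibration: slope {fit.slope:g} is not positive")
    sigma = float(blanks.std(ddof=1))
    lod = lod_from_blank(sigma, fit.slope) * unit_factor
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        sigma=sigma,
        lod=lod,
        loq=loq_from_lod(lod),
        range_low=float(levels.min()),
        range_high=float(levels.max()),
    )


def recovery_percent(found_spiked: float, found_unspiked: float, added: float):
    """Spike recovery, 100 (found_spiked - found_unspiked) / added.

    Returns ``(percent, suspect)``; values above 120% or below 50% are
    flagged suspect (including negatives).
    """
    if added <= 0:
        raise ValueError("added amount must be > 0")
    pct = 100.0 * (found_spiked - found_unspiked) / added
    return pct, bool(pct > 120.0 or pct < 50.0)


def rsd_percent(values) -> float:
    """Relative standard deviation, 100 sd(n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicate values")
    m = v.mean()
    if m == 0:
        raise ValueError("%RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def dpph_inhibition(a_blank: float, a_sample: float):
    """Radical-scavenging percentage relative to the blank absorbance.

    Returns ``(percent, clipped)``; the value is clipped to [0, 100]
    and the flag records whether clipping occurred.
    """
    if a_blank <= 0:
        raise ValueError("blank absorbance must be > 0")
    raw = 100.0 * (a_blank - a_sample) / a_blank
    clipped = raw < 0.0 or raw > 100.0
    return float(min(max(raw, 0.0), 100.0)), bool(clipped)


def ec50_from_curve(points) -> DoseResponseResult:
    """EC50 by linear interpolation on an isotonic-regularized curve.

    ``points`` are (concentration, inhibition%) pairs.  The inhibition
    sequence is made monotone non-decreasing (isotonic regression in
    concentration order), then the two points bracketing 50% are
    interpolated linearly; an exact 50% point is returned as-is.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (concentration, inhibition) pairs")
    order = np.argsort(pts[:, 0])
    conc, inhib = pts[order, 0], pts[order, 1]
    from sklearn.isotonic import IsotonicRegression

    mono = IsotonicRegression(increasing=True).fit_transform(conc, inhib)
    exact = np.flatnonzero(mono == 50.0)
    if exact.size:
        ec50 = float(conc[exact[0]])
    else:
        above = np.flatnonzero(mono > 50.0)
        below = np.flatnonzero(mono < 50.0)
        if above.size == 0 or below.size == 0:
            raise ValueError("EC50 outside measured range")
        i, j = below[-1], above[0]
        frac = (50.0 - mono[i]) / (mono[j] - mono[i])
        ec50 = float(conc[i] + frac * (conc[j] - conc[i]))
    return DoseResponseResult(ec50=ec50, curve_points=np.column_stack([conc, mono]))


def content_per_gram(conc_extract: float, extract_volume: float = 15.0,
                     sample_mass: float = 0.5) -> float:
    """Analyte content per gram of dry material, µg/g.

    Defaults reflect the emulated extraction: 15 mL of extractant per
    ~500 mg of ground material.
    """
    if conc_extract < 0:
        raise ValueError("extract concentration must be >= 0")
    if extract_volume <= 0 or sample_mass <= 0:
        raise ValueError("volume and mass must be > 0")
    return conc_extract * extract_volume / sample_mass


def rdi_coverage(dnj_content: float, unit_mass: float, units_per_day: float,
                 rdi_mg: float = 30.0) -> float:
    """Percent of the recommended daily DNJ intake a product delivers.

    ``dnj_content`` in µg/g, ``unit_mass`` grams of raw material per
    tablet/capsule (or per daily tea portion), ``units_per_day`` the
    manufacturer's dosing; the 30 mg/day default reference intake comes
    from reported effective DNJ doses (6-18 mg three times daily).
    """
    if rdi_mg <= 0:
        raise ValueError("rdi_mg must be > 0")
    if dnj_content < 0 or unit_mass <= 0 or units_per_day <= 0:
        raise ValueError("content must be >= 0 and dosing positive")
    mg_per_day = dnj_content * unit_mass * units_per_day / 1000.0
    return 100.0 * mg_per_day / rdi_mg


def validation_summary(curves: dict) -> "pd.DataFrame":
    """Assemble a Table-1-style validation summary (one column per
    analyte) from fitted CalibrationCurve objects and optional
    recovery/%RSD entries: ``curves[name] = (curve, recovery, rsd)``."""
    import pandas as pd

    rows = {}
    for name, (curve, recovery, rsd) in curves.items():
        rows[name] = {
            "range_ug_mL": f"{curve.range_low:g}-{curve.range_high:g}",
            "equation": f"y = {curve.slope:.2f}x {curve.intercept:+.2f}",
            "r2": round(curve.r2, 4),
            "recovery_pct": recovery,
            "rsd_pct": rsd,
            "lod_ng_mL": round(curve.lod, 2),
            "loq_ng_mL": round(curve.loq, 2),
        }
    return pd.DataFrame(rows)
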