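"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates an ATR-FTIR study of powdered mulberry-leaf
products: a handful of chemical components, each a sum of Gaussian or
Lorentzian bands, mixed by Beer-Lambert superposition, then corrupted by
a smooth polynomial baseline, a per-replicate multiplicative scatter
factor and additive white noise.  It also fabricates HPLC calibration
tables and DPPH dose-response tables so the wet-chemistry math can be
exercised end to end without any instrument data.

All randomness flows through a single ``numpy`` Generator seeded from
the config, so identical configs give bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SpectraDataset

_LN2 = math.log(2.0)


@dataclass
class BandSpec:
    """One absorption band: center (cm^-1), half-width at half-maximum
    (cm^-1), peak height (a.u.) and line shape."""

    center: float
    width: float
    height: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band at {self.center} cm^-1: width must be > 0")
        if self.height < 0:
            raise ValueError(f"band at {self.center} cm^-1: height must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        d = grid - self.center
        if self.shape == "gaussian":
            return self.height * np.exp(-_LN2 * (d / self.width) ** 2)
        return self.height * self.width**2 / (d**2 + self.width**2)


@dataclass
class ComponentSpec:
    """A named chemical component: its bands and, optionally, the uniform
    concentration range it is drawn from per product.  ``conc_range=None``
    marks the analyte, whose range comes from the SimulationConfig."""

    name: str
    bands: list
    conc_range: tuple | None = None

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"component {self.name!r} has no bands")


@dataclass
class SimulationConfig:
    """Study-level knobs for the spectra generator.

    Defaults mirror the emulated study: 19 products measured in
    triplicate over 750-4000 cm^-1.  The grid spacing defaults to
    3.2 cm^-1 so that a ~95 cm^-1 fingerprint window resolves to ~30
    variables, consistent with the interval arithmetic used downstream.
    Concentrations are in µg/g of dry material, absorbances in a.u.
    """

    grid_start: float = 750.0
    grid_end: float = 4000.0
    grid_spacing: float = 3.2
    n_products: int = 19
    replicates_per_product: int = 3
    conc_low: float = 10.0
    conc_high: float = 1000.0
    noise_sd: float = 0.005
    baseline_poly_order: int = 2
    baseline_amplitude: float = 0.05
    scatter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_start >= self.grid_end:
            raise ValueError("grid_start must be < grid_end")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if self.conc_low >= self.conc_high:
            raise ValueError("conc_low must be < conc_high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates_per_product < 1:
            raise ValueError("replicates_per_product must be >= 1")
        if self.n_products < 1:
            raise ValueError("n_products must be >= 1")

    def grid(self) -> np.ndarray:
        n = int(math.floor((self.grid_end - self.grid_start) / self.grid_spacing)) + 1
        return self.grid_start + self.grid_spacing * np.arange(n)


def render_component(spec: ComponentSpec, grid: np.ndarray) -> np.ndarray:
    """Evaluate a pure-component spectrum (sum of its bands) on a grid.

    Raises if the grid is empty/non-monotone or a band center falls
    outside the grid range, naming the offending band.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavenumber grid")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("wavenumber grid must be strictly ascending")
    lo, hi = grid[0], grid[-1]
    out = np.zeros_like(grid)
    for band in spec.bands:
        if not (lo <= band.center <= hi):
            raise ValueError(
                f"component {spec.name!r}: band center {band.center} cm^-1 "
                f"outside grid range [{lo}, {hi}]"
            )
        out += band.profile(grid)
    return out


def default_components() -> list:
    """Component library emulating a dried-leaf matrix plus the analyte.

    The analyte (DNJ) carries bands at 1150, 1380 and 1650 cm^-1 —
    pyranose-ring C-O/C-C stretching, C-H bending and N-H bending
    regions.  The matrix is dominated by polysaccharide bands
    (1047/1205/935 cm^-1 plus C-H and O-H stretches), with protein amide
    bands (one of which, 1655 cm^-1, deliberately overlaps the analyte's
    N-H window) and a phenolic aromatic band as interferents.  Heights
    are absorbance per (µg/g), scaled so each component contributes on
    the order of 0.1-1 a.u. at a typical concentration.
    """
    return [
        ComponentSpec(
            "DNJ",
            bands=[
                BandSpec(1150.0, 20.0, 8.0e-4),
                BandSpec(1380.0, 18.0, 6.0e-4),
                BandSpec(1650.0, 22.0, 5.0e-4),
            ],
            conc_range=None,  # analyte: range set by the config
        ),
        ComponentSpec(
            "polysaccharide",
            bands=[
                BandSpec(1047.0, 30.0, 2.2e-6),
                BandSpec(1205.0, 25.0, 1.1e-6),
                BandSpec(935.0, 20.0, 8.0e-7),
                BandSpec(2920.0, 60.0, 1.3e-6),
                BandSpec(3350.0, 150.0, 1.8e-6),
            ],
            conc_range=(3.5e5, 4.5e5),
        ),
        ComponentSpec(
            "protein",
            bands=[
                BandSpec(1541.0, 25.0, 1.2e-6, shape="lorentzian"),
                BandSpec(1572.0, 20.0, 8.0e-7, shape="lorentzian"),
                BandSpec(1655.0, 30.0, 1.5e-6),
            ],
            conc_range=(1.5e5, 3.0e5),
        ),
        ComponentSpec(
            "phenolics",
            bands=[
                BandSpec(1600.0, 25.0, 4.0e-6),
                BandSpec(1280.0, 30.0, 2.0e-6),
            ],
            conc_range=(5.0e3, 5.0e4),
        ),
    ]


def generate_dataset(
    cfg: SimulationConfig,
    components: list | None = None,
    analyte: str = "DNJ",
) -> SpectraDataset:
    """Simulate a full product panel of replicate ATR-FTIR spectra.

    Per product, the analyte concentration is uniform on
    ``[conc_low, conc_high]`` and every other component is uniform on its
    own ``conc_range``.  Each replicate spectrum is the Beer-Lambert
    mixture plus a random polynomial baseline (coefficients
    Normal(0, baseline_amplitude) on a grid mapped to [-1, 1]), a
    multiplicative factor ``1 + Normal(0, scatter_sd)`` and additive
    Normal(0, noise_sd) noise.  Metadata records the true analyte
    concentration per product.
    """
    if components is None:
        components = default_components()
    if not components:
        raise ValueError("at least one component is required")
    names = [c.name for c in components]
    if analyte not in names:
        raise ValueError(f"analyte {analyte!r} not among components {names}")

    grid = cfg.grid()
    pure = np.vstack([render_component(c, grid) for c in components])
    rng = np.random.default_rng(cfg.seed)

    rows, meta = [], []
    width = len(str(cfg.n_products))
    for i in range(cfg.n_products):
        pid = f"P{i + 1:0{width}d}"
        concs = np.empty(len(components))
        for j, comp in enumerate(components):
            lo, hi = (
                (cfg.conc_low, cfg.conc_high)
                if comp.conc_range is None or comp.name == analyte
                else comp.conc_range
            )
            concs[j] = rng.uniform(lo, hi)
        mixture = concs @ pure
        true_conc = concs[names.index(analyte)]
        x_norm = np.linspace(-1.0, 1.0, grid.size)
        for r in range(cfg.replicates_per_product):
            coeffs = rng.normal(0.0, cfg.baseline_amplitude, cfg.baseline_poly_order + 1)
            baseline = np.polynomial.polynomial.polyval(x_norm, coeffs)
            scatter = 1.0 + rng.normal(0.0, cfg.scatter_sd)
            noise = rng.normal(0.0, cfg.noise_sd, grid.size)
            rows.append(scatter * mixture + baseline + noise)
            meta.append(
                {
                    "sample_id": f"{pid}_r{r + 1}",
                    "product_id": pid,
                    "replicate": r + 1,
                    "concentration": true_conc,
                }
            )
    return SpectraDataset(grid, np.asarray(rows), pd.DataFrame(meta), ["simulate"])


# -- wet-chemistry table generators ---------------------------------------

#: Printed DNJ calibration line of the emulated HPLC assay (area vs µg/mL).
DNJ_CALIBRATION_PRESET = {"slope": 88.68, "intercept": -0.06}


def generate_hplc_calibration(
    slope: float = DNJ_CALIBRATION_PRESET["slope"],
    intercept: float = DNJ_CALIBRATION_PRESET["intercept"],
    sigma_blank: float = 0.5,
    levels: list | None = None,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an HPLC calibration table plus n=6 blank injections.

    Returns a tidy frame (concentration, replicate, area); blanks are
    the rows with concentration 0.  Areas are ``slope*conc + intercept``
    with additive Normal(0, sigma_blank) noise.
    """
    if levels is None:
        levels = [3.14, 25.0, 50.0, 75.0, 100.0, 157.14]
    if len(levels) == 0:
        raise ValueError("at least one calibration level is required")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if sigma_blank < 0:
        raise ValueError("sigma_blank must be >= 0")
    rng = np.random.default_rng(seed)
    recs = []
    for conc in levels:
        for r in range(replicates):
            area = slope * conc + intercept + rng.normal(0.0, sigma_blank)
            recs.append({"concentration": float(conc), "replicate": r + 1, "area": area})
    for r in range(6):  # blank injections for the sigma estimate
        area = intercept + rng.normal(0.0, sigma_blank)
        recs.append({"concentration": 0.0, "replicate": r + 1, "area": area})
    return pd.DataFrame(recs)


def generate_dose_response(
    ec50_true: float = 2.0,
    hill: float = 1.0,
    conc_grid: list | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a DPPH dose-response table.

    Inhibition follows the logistic ``100 / (1 + (ec50/c)**hill)`` with
    additive Normal(0, noise_sd) noise, clipped to [0, 100].
    """
    if ec50_true <= 0:
        raise ValueError("ec50_true must be > 0")
    if conc_grid is None:
        conc_grid = np.linspace(0.5, 3.3, 8) * (ec50_true / 2.0)
    conc = np.asarray(conc_grid, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(np.diff(conc) < 0):
        raise ValueError("concentration grid must be sorted ascending")
    rng = np.random.default_rng(seed)
    inhib = 100.0 / (1.0 + (ec50_true / conc) ** hill)
    inhib = np.clip(inhib + rng.normal(0.0, noise_sd, conc.size), 0.0, 100.0)
    return pd.DataFrame({"concentration": conc, "inhibition": inhib})
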