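"""Container for wavenumber-indexed spectra with per-sample metadata.

A :class:`SpectraDataset` is the X/y of the calibration problem: an
``(n_samples, n_points)`` absorbance matrix on a shared, strictly
ascending wavenumber grid, plus a metadata table carrying sample id,
product id, replicate number and the reference analyte concentration
(µg per g of dry material).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_METADATA = ("sample_id", "product_id", "replicate", "concentration")


@dataclass
class SpectraDataset:
    """Absorbance spectra on a common grid with sample metadata.

    Parameters
    ----------
    wavenumbers : array, shape (n_points,)
        Strictly ascending grid in cm^-1.
    absorbance : array, shape (n_samples, n_points)
        One row per measured spectrum, absorbance units.
    metadata : DataFrame
        One row per spectrum; must contain the columns in
        ``REQUIRED_METADATA``. ``concentration`` is the reference
        analyte value (NaN when unknown).
    provenance : list of str
        Names of processing stages already applied, in order.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    metadata: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be one-dimensional")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"grid has {self.wavenumbers.size} points"
            )
        if len(self.metadata) != self.absorbance.shape[0]:
            raise ValueError("metadata rows must match spectra rows")
        missing = [c for c in REQUIRED_METADATA if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata is missing columns: {missing}")
        ids = self.metadata["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.metadata = self.metadata.reset_index(drop=True)

    # -- convenience views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def sample_ids(self) -> list:
        return list(self.metadata["sample_id"])

    @property
    def X(self) -> np.ndarray:
        return self.absorbance

    @property
    def y(self) -> np.ndarray:
        """Reference analyte concentrations, one per spectrum."""
        return self.metadata["concentration"].to_numpy(dtype=float)

    def select(self, sample_ids) -> "SpectraDataset":
        """Subset by sample id, preserving the requested order."""
        lookup = {s: i for i, s in enumerate(self.metadata["sample_id"])}
        try:
            rows = [lookup[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"unknown sample id: {exc.args[0]!r}") from None
        return SpectraDataset(
            self.wavenumbers,
            self.absorbance[rows],
            self.metadata.iloc[rows].reset_index(drop=True),
            list(self.provenance),
        )

    def average_replicates(self) -> "SpectraDataset":
        """Average replicate spectra per product into one row per product.

        The averaged row takes the product id as its sample id; the
        reference concentration is the (identical) per-product value.
        """
        groups = self.metadata.groupby("product_id", sort=False).indices
        rows, meta = [], []
        for pid, idx in groups.items():
            rows.append(self.absorbance[idx].mean(axis=0))
            meta.append(
                {
                    "sample_id": pid,
                    "product_id": pid,
                    "replicate": 0,
                    "concentration": float(
                        self.metadata.loc[idx, "concentration"].mean()
                    ),
                }
            )
        return SpectraDataset(
            self.wavenumbers,
            np.asarray(rows),
            pd.DataFrame(meta),
            list(self.provenance) + ["average_replicates"],
        )
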