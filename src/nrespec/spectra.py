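"""Tidy spectra tables: samples x wavelengths with organ/stage metadata.

The on-disk schema is a flat CSV with metadata columns first (sample_id,
organ, cultivar, treatment, stage, ...) followed by one reflectance column
per wavelength named ``wl_0375`` ... (zero-padded nm).  In memory the table
keeps the reflectance matrix, the wavelength grid and the metadata frame
separate, which is what the modelling code wants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import GridMismatchError, NrespecError

__all__ = ["ORGANS", "SpectrumTable", "wavelength_columns"]

# Nine-organ vocabulary for above-ground wheat at/after anthesis: top three
# leaves (TL1 = flag leaf), remaining leaves, top three internodes (TIN1 =
# peduncle), remaining internodes, and chaff (spike minus grain).
ORGANS = ("TL1", "TL2", "TL3", "RLs", "TIN1", "TIN2", "TIN3", "RINs", "Chaff")

_META_ORDER = ["sample_id", "organ", "cultivar", "treatment", "stage", "plot_id", "replicate"]

# plausibility bounds for organ N concentration, g N per kg dry mass
N_MASS_BOUNDS = (0.5, 60.0)


def wavelength_columns(wavelengths: np.ndarray) -> list[str]:
    """Column names for a wavelength grid: ``wl_0375`` style, zero-padded nm."""
    return [f"wl_{int(round(w)):04d}" for w in wavelengths]


@dataclass
class SpectrumTable:
    """Reflectance matrix with per-sample metadata.

    Parameters
    ----------
    X
        n x p reflectance matrix, no missing values.
    wavelengths
        Length-p strictly increasing grid in nm.
    meta
        Per-row metadata frame; must contain ``sample_id`` and ``organ``
        columns.  Organ labels come from the nine-organ vocabulary or
        ``"mixed"``.
    """

    X: np.ndarray
    wavelengths: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2:
            raise NrespecError("X must be 2-D (samples x wavelengths)")
        n, p = self.X.shape
        if p < 2:
            raise NrespecError("need at least two wavelengths")
        if self.wavelengths.shape != (p,):
            raise GridMismatchError("wavelength grid length does not match X columns")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise NrespecError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.X)):
            raise NrespecError("reflectance matrix contains missing/non-finite values")
        if self.meta.empty:
            self.meta = pd.DataFrame(
                {"sample_id": [f"s{i:04d}" for i in range(n)], "organ": "mixed"}
            )
        self.meta = self.meta.reset_index(drop=True)
        if len(self.meta) != n:
            raise NrespecError("metadata rows do not match X rows")
        if "sample_id" not in self.meta.columns:
            raise NrespecError("metadata must carry a sample_id column")
        if "organ" not in self.meta.columns:
            self.meta["organ"] = "mixed"
        bad = set(self.meta["organ"]) - set(ORGANS) - {"mixed"}
        if bad:
            raise NrespecError(f"unknown organ labels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, index: np.ndarray) -> "SpectrumTable":
        index = np.asarray(index)
        return SpectrumTable(self.X[index], self.wavelengths, self.meta.iloc[index])

    def subset_wavelengths(self, keep: np.ndarray) -> "SpectrumTable":
        keep = np.asarray(keep)
        return SpectrumTable(self.X[:, keep], self.wavelengths[keep], self.meta)

    def for_organ(self, organ: str) -> "SpectrumTable":
        idx = np.flatnonzero((self.meta["organ"] == organ).to_numpy())
        return self.subset_rows(idx)

    def sorted_by_sample_id(self) -> "SpectrumTable":
        order = np.argsort(self.meta["sample_id"].to_numpy(), kind="stable")
        return self.subset_rows(order)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the tidy CSV schema (metadata columns then wl_#### columns)."""
        meta_cols = [c for c in _META_ORDER if c in self.meta.columns]
        meta_cols += [c for c in self.meta.columns if c not in meta_cols]
        wl_cols = wavelength_columns(self.wavelengths)
        return pd.concat(
            [self.meta[meta_cols].reset_index(drop=True), pd.DataFrame(self.X, columns=wl_cols)],
            axis=1,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectrumTable":
        wl_cols = [c for c in df.columns if c.startswith("wl_")]
        if len(wl_cols) < 2:
            raise NrespecError("no wavelength (wl_####) columns found")
        wavelengths = np.array([float(c[3:]) for c in wl_cols])
        order = np.argsort(wavelengths)
        wl_cols = [wl_cols[i] for i in order]
        meta = df[[c for c in df.columns if not c.startswith("wl_")]]
        return cls(df[wl_cols].to_numpy(dtype=float), wavelengths[order], meta)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumTable":
        return cls.from_frame(pd.read_csv(path))


def match_response(table: SpectrumTable, y: pd.Series | pd.DataFrame) -> np.ndarray:
    """Align a sample_id-indexed N_mass response to the table's row order.

    Accepts a Series indexed by sample_id or a frame with ``sample_id`` and
    ``N_mass`` columns; validates plausibility bounds.
    """
    if isinstance(y, pd.DataFrame):
        y = y.set_index("sample_id")["N_mass"]
    aligned = y.reindex(table.meta["sample_id"])
    if aligned.isna().any():
        missing = table.meta["sample_id"][aligned.isna().to_numpy()].tolist()[:5]
        raise NrespecError(f"N_mass missing for samples {missing}")
    vals = aligned.to_numpy(dtype=float)
    lo, hi = N_MASS_BOUNDS
    if np.any(vals < lo) or np.any(vals > hi):
        raise NrespecError(f"N_mass outside plausibility bounds [{lo}, {hi}] g/kg")
    return vals
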