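"""Core in-memory containers for spectra and reference chemistry.

A :class:`SpectraSet` holds log(1/R) absorbance spectra on a common,
strictly increasing wavelength grid; a :class:`ReferenceTable` holds the
wet-chemistry reference values the spectra are calibrated against.  Both
are thin, validated wrappers around numpy arrays / pandas frames so that
every downstream stage can rely on aligned sample ids and a sane grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "ReferenceTable"]


@dataclass
class SpectraSet:
    """Absorbance spectra (samples x wavelengths) on a shared grid.

    Parameters
    ----------
    sample_ids : list of str
        One id per spectrum; order matches the rows of ``absorbance``.
    wavelengths : ndarray
        Strictly increasing wavelength grid in nm.
    absorbance : ndarray
        log(1/R) matrix of shape ``(n_samples, n_wavelengths)``.
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        n, p = self.absorbance.shape
        if p != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {p} columns but grid has {self.wavelengths.size} points"
            )
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} spectra"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    @property
    def grid_step(self) -> float:
        """Grid spacing in nm; raises if the grid is not uniform."""
        steps = np.diff(self.wavelengths)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("wavelength grid is not uniform")
        return float(steps[0])

    def select(self, sample_ids: list[str]) -> "SpectraSet":
        """Return the subset with the given ids, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return SpectraSet(list(sample_ids), self.wavelengths.copy(),
                          self.absorbance[rows].copy())

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: sample_id index, one column per wavelength."""
        cols = [f"{w:.1f}" for w in self.wavelengths]
        df = pd.DataFrame(self.absorbance, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectraSet":
        if "sample_id" not in df.columns:
            raise ValueError("spectra table must have a 'sample_id' column")
        ids = df["sample_id"].astype(str).tolist()
        wl_cols = [c for c in df.columns if c != "sample_id"]
        wavelengths = np.array([float(c) for c in wl_cols])
        return cls(ids, wavelengths, df[wl_cols].to_numpy(dtype=float))


@dataclass
class ReferenceTable:
    """Per-sample reference chemistry (one column per constituent)."""

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "sample_id" in self.data.columns:
            self.data = self.data.set_index(self.data["sample_id"].astype(str)).drop(
                columns="sample_id"
            )
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "sample_id"
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in reference table")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def constituents(self) -> list[str]:
        return self.data.columns.tolist()

    def values_for(self, constituent: str, sample_ids: list[str] | None = None) -> np.ndarray:
        if constituent not in self.data.columns:
            raise KeyError(f"unknown constituent {constituent!r}; "
                           f"have {self.constituents}")
        series = self.data[constituent]
        if sample_ids is not None:
            series = series.loc[sample_ids]
        return series.to_numpy(dtype=float)

    def select(self, sample_ids: list[str]) -> "ReferenceTable":
        return ReferenceTable(self.data.loc[sample_ids].copy(), dict(self.units))
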