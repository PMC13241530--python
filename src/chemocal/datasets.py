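"""Core in-memory containers shared by every stage of the workflow.

Two objects travel through the whole pipeline: a :class:`SpectraMatrix`
(samples x wavelengths absorbance block tied to its wavelength grid) and a
:class:`ConcentrationTable` (samples x analytes reference concentrations in
ug/mL).  Both round-trip losslessly through plain CSV so fitted models and
datasets can be inspected or reloaded from any language.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraMatrix",
    "ConcentrationTable",
    "ChemocalError",
    "ConfigurationError",
    "ValidationError",
]


class ChemocalError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(ChemocalError):
    """Invalid configuration (grids, band libraries, design parameters)."""


class ValidationError(ChemocalError):
    """Invalid data passed to an operation (shapes, signs, mismatched grids)."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced wavelength axis in nanometres.

    The default working window is 210-350 nm at 1 nm resolution, i.e. 141
    discrete variables -- the region where both analytes absorb while solvent
    background and baseline drift stay manageable.
    """

    start_nm: float = 210.0
    end_nm: float = 350.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ConfigurationError("wavelength step must be positive")
        if self.end_nm <= self.start_nm:
            raise ConfigurationError("end wavelength must exceed start wavelength")
        n = (self.end_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "wavelength range is not an integer multiple of the step"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def points(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    @classmethod
    def from_points(cls, points: Sequence[float]) -> "WavelengthGrid":
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ConfigurationError("need at least two wavelength points")
        steps = np.diff(pts)
        if np.any(steps <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ValidationError("wavelengths must be evenly spaced")
        return cls(float(pts[0]), float(pts[-1]), float(steps[0]))


@dataclass
class SpectraMatrix:
    """Absorbance block: one row per sample, one column per wavelength (AU)."""

    grid: WavelengthGrid
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("spectra must be a 2-D samples x wavelengths array")
        if self.values.shape[1] != self.grid.n_points:
            raise ValidationError(
                f"spectra have {self.values.shape[1]} columns but the grid has "
                f"{self.grid.n_points} points"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValidationError("sample_ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    def check_same_grid(self, other_grid: WavelengthGrid) -> None:
        if (
            self.grid.start_nm != other_grid.start_nm
            or self.grid.end_nm != other_grid.end_nm
            or self.grid.step_nm != other_grid.step_nm
        ):
            raise ValidationError(
                f"wavelength grid mismatch: data on {self.grid.start_nm}-"
                f"{self.grid.end_nm}/{self.grid.step_nm} nm vs expected "
                f"{other_grid.start_nm}-{other_grid.end_nm}/{other_grid.step_nm} nm"
            )

    # -- CSV dialect: first column `wavelength_nm`, one column per sample -----
    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values.T, index=self.grid.points, columns=self.sample_ids
        )
        df.index.name = "wavelength_nm"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SpectraMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "wavelength_nm":
            raise ValidationError(
                f"{path}: first column must be 'wavelength_nm', got {df.columns[0]!r}"
            )
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        if np.any(np.diff(wl) <= 0):
            bad = int(np.argmax(np.diff(wl) <= 0)) + 2
            raise ValidationError(
                f"{path}: wavelengths not strictly increasing near line {bad}"
            )
        grid = WavelengthGrid.from_points(wl)
        ids = [str(c) for c in df.columns[1:]]
        return cls(grid, df.iloc[:, 1:].to_numpy(dtype=float).T, ids)


@dataclass
class ConcentrationTable:
    """Reference or predicted concentrations, samples x analytes (ug/mL)."""

    analytes: list[str]
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.analytes):
            raise ValidationError("concentration columns do not match analyte names")
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValidationError("sample_ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, analyte: str) -> np.ndarray:
        return self.values[:, self.analytes.index(analyte)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.analytes)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationTable":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise ValidationError(
                f"{path}: first column must be 'sample_id', got {df.columns[0]!r}"
            )
        return cls(
            [str(c) for c in df.columns[1:]],
            df.iloc[:, 1:].to_numpy(dtype=float),
            [str(s) for s in df["sample_id"]],
        )
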