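"""Synthetic UV absorbance spectra for two-component Beer-Lambert mixtures.

The generator emulates the statistical structure of a cefepime (CFPM) /
tazobactam (TAZO) binary system measured by double-beam UV spectrophotometry:

* each pure component is a sum of Gaussian chromophoric bands on a shared
  wavelength grid -- TAZO dominated by a strong band near 211 nm, CFPM by
  bands around 257-280 nm -- so the two absorptivity profiles overlap
  severely below 250 nm and share support everywhere in the window;
* mixture spectra are additive (unit path length): A(i, lam) =
  sum_k c_ik * eps_k(lam), plus optional smooth baseline drift and
  homoscedastic Gaussian photometric noise;
* a plasma matrix scales each analyte's contribution by a per-analyte
  suppression factor (a percent-level matrix effect) and adds a small smooth
  background from residual plasma constituents.

Everything is seeded, so a (parameters, seed) pair reproduces a dataset
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import (
    ConcentrationTable,
    ConfigurationError,
    SpectraMatrix,
    ValidationError,
    WavelengthGrid,
)

__all__ = [
    "GaussianBand",
    "PureSpectrum",
    "NoiseModel",
    "MatrixEffectSpec",
    "DEFAULT_BAND_LIBRARY",
    "build_pure_spectra",
    "simulate_mixtures",
    "simulate_plasma_set",
]


@dataclass(frozen=True)
class GaussianBand:
    """One chromophoric band: Gaussian in wavelength.

    ``peak_absorptivity`` is the band height in AU per ug/mL at 1 cm path, so
    band shapes already absorb the fixed cuvette path length.
    """

    center_nm: float
    width_nm: float  # Gaussian sigma
    peak_absorptivity: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ConfigurationError("band width must be positive")
        if self.peak_absorptivity < 0:
            raise ConfigurationError("peak absorptivity must be non-negative")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        d = wavelengths - self.center_nm
        return self.peak_absorptivity * np.exp(-(d * d) / (2.0 * self.width_nm**2))


@dataclass
class PureSpectrum:
    """Unit-concentration absorptivity profile of one analyte on a grid."""

    analyte_name: str
    bands: list[GaussianBand]
    grid: WavelengthGrid
    epsilon: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError(
                f"analyte {self.analyte_name!r} needs at least one band"
            )
        wl = self.grid.points
        self.epsilon = np.sum([b.evaluate(wl) for b in self.bands], axis=0)


# Band library chosen so that (a) absorbance over the working ranges
# (CFPM 1-17, TAZO 1-9 ug/mL) stays within ~0.1-1.5 AU, and (b) the two
# profiles overlap severely below 250 nm with no interference-free wavelength
# anywhere in the 210-350 nm window.
DEFAULT_BAND_LIBRARY: dict[str, list[GaussianBand]] = {
    "CFPM": [
        GaussianBand(257.0, 12.0, 0.05),
        GaussianBand(275.0, 9.0, 0.07),
        GaussianBand(214.0, 10.0, 0.04),
    ],
    "TAZO": [
        GaussianBand(211.0, 8.0, 0.12),
        GaussianBand(280.0, 10.0, 0.02),
    ],
}


@dataclass(frozen=True)
class NoiseModel:
    """Homoscedastic photometric noise plus optional slow baseline drift.

    ``absorbance_sd`` is the per-cell Gaussian SD in AU (default 0.002 AU,
    typical double-beam photometric noise).  The baseline is a per-sample
    sinusoid of amplitude ``baseline_amplitude`` and period
    ``baseline_period_nm`` with a random phase; amplitude 0 disables it.
    """

    absorbance_sd: float = 0.002
    baseline_amplitude: float = 0.0
    baseline_period_nm: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.absorbance_sd < 0:
            raise ConfigurationError("absorbance SD must be non-negative")
        if self.baseline_amplitude < 0:
            raise ConfigurationError("baseline amplitude must be non-negative")


@dataclass(frozen=True)
class MatrixEffectSpec:
    """Plasma matrix behaviour: per-analyte signal suppression + background.

    ``suppression_fraction`` maps analyte name to the fractional signal loss
    (0.0235 means the analyte's contribution is scaled by 0.9765, i.e. a
    -2.35% matrix effect).  The background is a smooth exponential decay in
    wavelength mimicking residual protein/chromophore absorbance after
    precipitation; its default amplitude is small (<= 0.01 AU).
    ``variability_sd`` jitters the per-sample suppression around its nominal
    value.
    """

    suppression_fraction: dict[str, float] = field(default_factory=dict)
    background_amplitude: float = 0.005
    background_decay_nm: float = 30.0
    variability_sd: float = 0.0

    def __post_init__(self) -> None:
        for name, s in self.suppression_fraction.items():
            if not 0.0 <= s < 1.0:
                raise ValidationError(
                    f"suppression for {name!r} must be in [0, 1), got {s}"
                )
        if self.background_amplitude < 0:
            raise ConfigurationError("background amplitude must be non-negative")

    def background(self, grid: WavelengthGrid) -> np.ndarray:
        wl = grid.points
        return self.background_amplitude * np.exp(
            -(wl - wl[0]) / self.background_decay_nm
        )


def build_pure_spectra(
    band_library: dict[str, list[GaussianBand]] | None = None,
    grid: WavelengthGrid | None = None,
) -> dict[str, PureSpectrum]:
    """Evaluate per-analyte band libraries into pure spectra on a grid."""
    grid = grid or WavelengthGrid()
    band_library = band_library if band_library is not None else DEFAULT_BAND_LIBRARY
    if not band_library:
        raise ConfigurationError("band library is empty")
    return {
        name: PureSpectrum(name, bands, grid) for name, bands in band_library.items()
    }


def _epsilon_matrix(
    pure: dict[str, PureSpectrum], analytes: list[str]
) -> tuple[np.ndarray, WavelengthGrid]:
    missing = [a for a in analytes if a not in pure]
    if missing:
        raise ValidationError(f"no pure spectrum for analytes: {missing}")
    grid = next(iter(pure.values())).grid
    return np.stack([pure[a].epsilon for a in analytes]), grid


def _noise_terms(
    noise: NoiseModel, n_samples: int, grid: WavelengthGrid, seed_offset: int = 0
) -> np.ndarray:
    rng = np.random.default_rng(noise.seed + seed_offset)
    wl = grid.points
    total = np.zeros((n_samples, grid.n_points))
    if noise.baseline_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, size=n_samples)
        total += noise.baseline_amplitude * np.sin(
            2 * np.pi * wl[None, :] / noise.baseline_period_nm + phase[:, None]
        )
    if noise.absorbance_sd > 0:
        total += rng.normal(0.0, noise.absorbance_sd, size=total.shape)
    return total


def simulate_mixtures(
    pure: dict[str, PureSpectrum],
    conc: ConcentrationTable,
    noise: NoiseModel | None = None,
) -> SpectraMatrix:
    """Beer-Lambert mixture spectra: A = C @ E + baseline + noise."""
    noise = noise or NoiseModel(absorbance_sd=0.0)
    if np.any(conc.values < 0):
        raise ValidationError("concentrations must be non-negative")
    eps, grid = _epsilon_matrix(pure, conc.analytes)
    clean = conc.values @ eps
    values = clean + _noise_terms(noise, conc.n_samples, grid)
    return SpectraMatrix(grid, values, list(conc.sample_ids))


def simulate_plasma_set(
    pure: dict[str, PureSpectrum],
    conc: ConcentrationTable,
    noise: NoiseModel | None = None,
    matrix: MatrixEffectSpec | None = None,
) -> tuple[SpectraMatrix, dict[str, float]]:
    """Post-extraction spiked plasma spectra plus the true matrix factors.

    Each analyte's Beer-Lambert contribution is scaled by (1 - suppression)
    before the plasma background and photometric noise are added.  Returns the
    spectra and the nominal matrix factor MF = 1 - suppression per analyte.
    """
    noise = noise or NoiseModel(absorbance_sd=0.0)
    matrix = matrix or MatrixEffectSpec()
    if np.any(conc.values < 0):
        raise ValidationError("concentrations must be non-negative")
    eps, grid = _epsilon_matrix(pure, conc.analytes)
    mf = {a: 1.0 - matrix.suppression_fraction.get(a, 0.0) for a in conc.analytes}
    factors = np.array([mf[a] for a in conc.analytes])
    if matrix.variability_sd > 0:
        rng = np.random.default_rng(noise.seed + 7919)
        per_sample = factors[None, :] + rng.normal(
            0.0, matrix.variability_sd, size=(conc.n_samples, len(conc.analytes))
        )
        per_sample = np.clip(per_sample, 0.0, None)
    else:
        per_sample = np.broadcast_to(factors, (conc.n_samples, len(conc.analytes)))
    clean = (conc.values * per_sample) @ eps
    values = clean + matrix.background(grid)[None, :]
    values = values + _noise_terms(noise, conc.n_samples, grid, seed_offset=1)
    return SpectraMatrix(grid, values, list(conc.sample_ids)), mf
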