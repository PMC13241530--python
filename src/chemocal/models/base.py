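"""Shared preprocessing and the fit/predict contract."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..datasets import ConcentrationTable, SpectraMatrix, ValidationError

logger = logging.getLogger(__name__)

_SCALE_EPS = 1e-12


@dataclass
class Preprocessor:
    """Column-wise centering / autoscaling frozen on the calibration set.

    ``scale`` uses the sample standard deviation (ddof=1).  A constant
    wavelength column would give a zero scale; its scale is floored at a tiny
    epsilon and a warning is logged, so the column simply stays (numerically)
    inert instead of aborting the fit.
    """

    center: bool = True
    scale: bool = False
    mean_: np.ndarray | None = field(default=None, repr=False)
    scale_: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray) -> "Preprocessor":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            n_const = int(np.sum(sd <= _SCALE_EPS))
            if n_const:
                logger.warning(
                    "%d constant wavelength column(s); scale floored at epsilon",
                    n_const,
                )
            self.scale_ = np.where(sd <= _SCALE_EPS, _SCALE_EPS, sd)
        else:
            self.scale_ = np.ones(X.shape[1])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValidationError("preprocessor not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValidationError("preprocessor not fitted")
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def check_aligned(X: SpectraMatrix, Y: ConcentrationTable) -> None:
    if X.n_samples != Y.n_samples:
        raise ValidationError(
            f"spectra have {X.n_samples} samples but concentrations have "
            f"{Y.n_samples}"
        )


def prediction_table(
    yhat: np.ndarray, analytes: list[str], sample_ids: list[str]
) -> ConcentrationTable:
    return ConcentrationTable(list(analytes), np.atleast_2d(yhat), list(sample_ids))
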