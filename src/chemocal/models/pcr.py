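"""Principal component regression on (auto)scaled absorbance spectra.

Spectra are mean-centered and variance-scaled, compressed by singular value
decomposition, and the reference concentrations regressed on the leading
scores.  The retained dimensionality is picked by leave-one-out
cross-validation: the component count minimizing the prediction residual,
with an optional parsimony tie-break toward fewer components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datasets import ConcentrationTable, SpectraMatrix, ValidationError, WavelengthGrid
from .base import Preprocessor, check_aligned, prediction_table

__all__ = ["PcrModel", "fit_pcr"]


def _svd_regress(Xp: np.ndarray, Yc: np.ndarray, k: int) -> np.ndarray:
    """Regression coefficients of centered Y on the first k PCs of Xp."""
    U, s, Vt = np.linalg.svd(Xp, full_matrices=False)
    Uk, sk, Vk = U[:, :k], s[:k], Vt[:k].T
    # B maps preprocessed spectra to centered responses: B = V S^-1 U' Yc
    return Vk @ ((Uk.T @ Yc) / sk[:, None])


@dataclass
class PcrModel:
    grid: WavelengthGrid
    analytes: list[str]
    preprocessor: Preprocessor
    loadings: np.ndarray  # (p, k), orthonormal columns
    coef_: np.ndarray  # (p, n_analytes) in preprocessed-spectrum space
    y_mean_: np.ndarray  # (n_analytes,)
    k: int
    cv_curve: dict[int, float] = field(default_factory=dict)  # k -> RMSECV

    def predict(self, X: SpectraMatrix) -> ConcentrationTable:
        X.check_same_grid(self.grid)
        Xp = self.preprocessor.transform(X.values)
        yhat = Xp @ self.coef_ + self.y_mean_
        return prediction_table(yhat, self.analytes, X.sample_ids)


def fit_pcr(
    X: SpectraMatrix,
    Y: ConcentrationTable,
    max_k: int | None = None,
    center: bool = True,
    scale: bool = False,
    parsimony_tol: float = 0.0,
) -> PcrModel:
    """Fit PCR with leave-one-out selection of the component count.

    ``parsimony_tol`` > 0 retains the smallest k whose RMSECV is within
    (1 + tol) of the minimum; the default 0 takes the plain minimum.
    ``scale=True`` autoscales every wavelength to unit variance before the
    decomposition; the default keeps centering only, since unit-variance
    weighting hands information-free spectral channels the same influence
    as analytical bands and degrades prediction whenever such channels
    exist (see the methods note).
    """
    check_aligned(X, Y)
    n, p = X.values.shape
    if n < 3:
        raise ValidationError("need at least 3 calibration samples")
    k_cap = min(n - 1, p)
    max_k = k_cap if max_k is None else min(max_k, k_cap)

    cv_press = np.zeros(max_k)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        pre = Preprocessor(center=center, scale=scale)
        Xp = pre.fit_transform(X.values[mask])
        y_mean = Y.values[mask].mean(axis=0)
        Yc = Y.values[mask] - y_mean
        U, s, Vt = np.linalg.svd(Xp, full_matrices=False)
        xi = pre.transform(X.values[i : i + 1])
        for k in range(1, max_k + 1):
            B = Vt[:k].T @ ((U[:, :k].T @ Yc) / s[:k, None])
            resid = Y.values[i] - (xi @ B + y_mean)
            cv_press[k - 1] += float(np.sum(resid**2))
    rmsecv = np.sqrt(cv_press / (n * Y.values.shape[1]))
    best = float(rmsecv.min())
    # absolute floor absorbs floating-point dust among numerically exact fits
    ks = np.where(rmsecv <= best * (1.0 + parsimony_tol) + 1e-12)[0]
    k = int(ks[0]) + 1

    pre = Preprocessor(center=center, scale=scale)
    Xp = pre.fit_transform(X.values)
    y_mean = Y.values.mean(axis=0)
    Yc = Y.values - y_mean
    U, s, Vt = np.linalg.svd(Xp, full_matrices=False)
    coef = Vt[:k].T @ ((U[:, :k].T @ Yc) / s[:k, None])
    return PcrModel(
        grid=X.grid,
        analytes=list(Y.analytes),
        preprocessor=pre,
        loadings=Vt[:k].T,
        coef_=coef,
        y_mean_=y_mean,
        k=k,
        cv_curve={i + 1: float(v) for i, v in enumerate(rmsecv)},
    )
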