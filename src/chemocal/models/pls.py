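"""Partial least squares (NIPALS) and the firefly-assisted FA-PLS fit.

PLS is fit per analyte (PLS1) on mean-centered spectra restricted to a
wavelength mask; the latent dimensionality is chosen by leave-one-out
cross-validation.  :func:`fit_fapls` first runs the firefly wavelength
search for each analyte (the swarm parameters may differ per analyte) and
then fits the masked PLS model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datasets import ConcentrationTable, SpectraMatrix, ValidationError, WavelengthGrid
from .base import Preprocessor, check_aligned, prediction_table
from .firefly import FireflyParams, _nipals_coef, firefly_select_wavelengths

__all__ = ["PlsModel", "fit_pls", "fit_fapls"]


@dataclass
class _PlsSub:
    """Per-analyte PLS state: mask, frozen preprocessor, coefficients."""

    mask: np.ndarray
    preprocessor: Preprocessor
    coef: np.ndarray
    y_mean: float
    k: int
    cv_curve: dict[int, float] = field(default_factory=dict)
    firefly_history: list[float] = field(default_factory=list)


@dataclass
class PlsModel:
    grid: WavelengthGrid
    analytes: list[str]
    sub: dict[str, _PlsSub]

    @property
    def mask(self) -> np.ndarray:
        """Union of the per-analyte wavelength masks."""
        m = np.zeros(self.grid.n_points, bool)
        for s in self.sub.values():
            m |= s.mask
        return m

    def predict(self, X: SpectraMatrix) -> ConcentrationTable:
        X.check_same_grid(self.grid)
        cols = []
        for a in self.analytes:
            s = self.sub[a]
            Xm = s.preprocessor.transform(X.values[:, s.mask])
            cols.append(Xm @ s.coef + s.y_mean)
        return prediction_table(np.column_stack(cols), self.analytes, X.sample_ids)


def _loo_rmsecv(Xm: np.ndarray, y: np.ndarray, max_k: int) -> np.ndarray:
    n = Xm.shape[0]
    press = np.zeros(max_k)
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        pre = Preprocessor(center=True).fit(Xm[tr])
        Xc = pre.transform(Xm[tr])
        xi = pre.transform(Xm[i : i + 1])
        ym = y[tr].mean()
        yc = y[tr] - ym
        for k in range(1, max_k + 1):
            b = _nipals_coef(Xc, yc, k)
            press[k - 1] += (y[i] - (float(xi[0] @ b) + ym)) ** 2
    return np.sqrt(press / n)


def _fit_single(
    X: SpectraMatrix,
    y: np.ndarray,
    mask: np.ndarray,
    max_k: int | None,
) -> _PlsSub:
    Xm = X.values[:, mask]
    n, pm = Xm.shape
    k_cap = min(n - 1, pm)
    max_k = k_cap if max_k is None else min(max_k, k_cap)
    rmsecv = _loo_rmsecv(Xm, y, max_k)
    k = int(np.argmin(rmsecv)) + 1
    if pm < 2 * k:
        raise ValidationError("masked wavelength count below twice the latent rank")
    pre = Preprocessor(center=True).fit(Xm)
    ym = float(y.mean())
    coef = _nipals_coef(pre.transform(Xm), y - ym, k)
    return _PlsSub(
        mask=mask,
        preprocessor=pre,
        coef=coef,
        y_mean=ym,
        k=k,
        cv_curve={i + 1: float(v) for i, v in enumerate(rmsecv)},
    )


def fit_pls(
    X: SpectraMatrix,
    Y: ConcentrationTable,
    mask: np.ndarray | None = None,
    max_k: int | None = None,
) -> PlsModel:
    """Plain full-spectrum (or pre-masked) PLS1 per analyte."""
    check_aligned(X, Y)
    mask = np.ones(X.n_wavelengths, bool) if mask is None else np.asarray(mask, bool)
    sub = {
        a: _fit_single(X, Y.column(a), mask, max_k) for a in Y.analytes
    }
    return PlsModel(grid=X.grid, analytes=list(Y.analytes), sub=sub)


def fit_fapls(
    X: SpectraMatrix,
    Y: ConcentrationTable,
    params: dict[str, FireflyParams] | FireflyParams | None = None,
    max_k: int | None = None,
    inner_cv: int = 5,
    inner_components: int = 2,
    joint: bool = False,
) -> PlsModel:
    """Firefly wavelength selection followed by per-analyte PLS.

    ``params`` maps analyte name to its swarm parameters (a single
    FireflyParams is broadcast).  With ``joint=True`` one swarm is run on the
    pooled fitness of all analytes and the resulting mask shared.
    """
    check_aligned(X, Y)
    if params is None:
        params = FireflyParams()
    if isinstance(params, FireflyParams):
        params = {a: params for a in Y.analytes}
    sub: dict[str, _PlsSub] = {}
    if joint:
        first = params[Y.analytes[0]]
        mask, history = firefly_select_wavelengths(
            X.values, Y.values, first, inner_cv, inner_components
        )
        for a in Y.analytes:
            s = _fit_single(X, Y.column(a), mask, max_k)
            s.firefly_history = list(history)
            sub[a] = s
    else:
        for a in Y.analytes:
            mask, history = firefly_select_wavelengths(
                X.values, Y.column(a), params[a], inner_cv, inner_components
            )
            s = _fit_single(X, Y.column(a), mask, max_k)
            s.firefly_history = list(history)
            sub[a] = s
    return PlsModel(grid=X.grid, analytes=list(Y.analytes), sub=sub)
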