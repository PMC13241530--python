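"""Constrained MCR-ALS with evolving factor analysis rank estimation.

The absorbance block is decomposed bilinearly, X ~ C S', by alternating
non-negative least squares on the concentration profiles C and the pure
spectra S.  Evolving factor analysis (EFA) -- singular values of growing
forward and backward row windows -- estimates the chemical rank before the
resolution.  Constraints: non-negativity on C and S, closure (calibration
rows of C rescaled to their known concentration totals, which also anchors
C in ug/mL), optional unit-norm spectral normalization when closure is off,
and optional per-component zero windows (selectivity).  Resolved profiles
are mapped to analyte concentrations by per-analyte affine quantification
lines fitted against the calibration references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.optimize import linear_sum_assignment

from ..datasets import ConcentrationTable, SpectraMatrix, ValidationError, WavelengthGrid
from .base import check_aligned, prediction_table

__all__ = ["EfaResult", "efa_rank", "McrConstraints", "McrModel", "fit_mcrals"]


@dataclass
class EfaResult:
    forward: list[np.ndarray]  # singular values of X[:m], m = 1..n
    backward: list[np.ndarray]  # singular values of X[n-m:], m = 1..n
    threshold: float
    rank: int


def _default_threshold(s: np.ndarray, n: int, p: int, sigma: float | None) -> float:
    machine = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
    if sigma is not None:
        return max(machine, sigma * np.sqrt(n * p))
    # noise-floor estimate from the trailing half of the singular spectrum:
    # for an i.i.d. Gaussian noise matrix the mean squared singular value is
    # sigma^2 * n * p / min(n, p), and the trailing values sit below it.
    m = min(n, p)
    tail = s[m // 2 :]
    if tail.size == 0 or tail[0] == 0:
        return machine
    sigma_est = np.sqrt(np.mean(tail**2) * m / (n * p))
    return max(machine, sigma_est * np.sqrt(n * p))


def efa_rank(
    X: SpectraMatrix | np.ndarray,
    sigma: float | None = None,
    threshold: float | None = None,
) -> EfaResult:
    """Estimate chemical rank from forward/backward EFA eigenvalue traces.

    ``sigma`` (absorbance noise SD, AU) sharpens the default threshold
    sigma * sqrt(n*p); otherwise the noise floor is estimated from the
    trailing singular values.  The rank is the number of singular values of
    the full matrix above the threshold.
    """
    values = X.values if isinstance(X, SpectraMatrix) else np.asarray(X, float)
    n, p = values.shape
    if n < 3:
        raise ValidationError("need at least 3 samples for EFA")
    forward = [np.linalg.svd(values[: m + 1], compute_uv=False) for m in range(n)]
    backward = [np.linalg.svd(values[n - m - 1 :], compute_uv=False) for m in range(n)]
    s_full = forward[-1]
    thr = (
        threshold
        if threshold is not None
        else _default_threshold(s_full, n, p, sigma)
    )
    rank = max(1, int(np.sum(s_full > thr)))
    return EfaResult(forward=forward, backward=backward, threshold=float(thr), rank=rank)


@dataclass(frozen=True)
class McrConstraints:
    nonneg_c: bool = True
    nonneg_s: bool = True
    closure: bool = True
    normalize_s: bool = False  # unit-norm S columns; ignored while closure is on
    # selectivity: per-component wavelength windows forced to zero in S,
    # as {component_index: (lo_nm, hi_nm), ...}
    zero_windows: dict[int, tuple[float, float]] = field(default_factory=dict)


@dataclass
class McrModel:
    grid: WavelengthGrid
    analytes: list[str]
    rank: int
    C: np.ndarray  # (n_cal, rank), calibration concentration profiles
    S: np.ndarray  # (p, rank), resolved spectra
    constraints: McrConstraints
    lack_of_fit: float  # percent
    lof_history: list[float]
    component_of: dict[str, int]  # analyte -> resolved component index
    quant_maps: dict[str, tuple[float, float]]  # analyte -> (intercept, slope)

    def resolve(self, X: SpectraMatrix) -> np.ndarray:
        """Resolve new spectra against the frozen S (non-negative profiles)."""
        X.check_same_grid(self.grid)
        return _solve_c(X.values, self.S, nonneg=self.constraints.nonneg_c)

    def predict(self, X: SpectraMatrix) -> ConcentrationTable:
        C_new = self.resolve(X)
        cols = []
        for a in self.analytes:
            a0, b = self.quant_maps[a]
            cols.append(a0 + b * C_new[:, self.component_of[a]])
        return prediction_table(np.column_stack(cols), self.analytes, X.sample_ids)


def _solve_c(X: np.ndarray, S: np.ndarray, nonneg: bool) -> np.ndarray:
    if not nonneg:
        return np.linalg.lstsq(S, X.T, rcond=None)[0].T
    C = np.empty((X.shape[0], S.shape[1]))
    for i in range(X.shape[0]):
        C[i], _ = nnls(S, X[i])
    return C


def _solve_s(X: np.ndarray, C: np.ndarray, nonneg: bool) -> np.ndarray:
    if not nonneg:
        return np.linalg.lstsq(C, X, rcond=None)[0].T
    S = np.empty((X.shape[1], C.shape[1]))
    for j in range(X.shape[1]):
        S[j], _ = nnls(C, X[:, j])
    return S


def _lof(X: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    resid = X - C @ S.T
    return 100.0 * float(np.sqrt(np.sum(resid**2) / np.sum(X**2)))


def fit_mcrals(
    X: SpectraMatrix,
    Y_cal: ConcentrationTable,
    rank: int | None = None,
    constraints: McrConstraints | None = None,
    max_iter: int = 50,
    lof_tol: float = 1e-3,
    sigma: float | None = None,
) -> McrModel:
    """Resolve the calibration block and build the quantification maps.

    ``rank=None`` takes the EFA estimate.  ``lof_tol`` is the relative change
    in lack of fit that stops the alternation (default 0.1%).  Closure needs
    one resolved component per reference analyte; when the rank differs from
    the analyte count closure is disabled automatically and the quantification
    lines absorb the scale instead.
    """
    check_aligned(X, Y_cal)
    n, p = X.values.shape
    if rank is None:
        rank = efa_rank(X, sigma=sigma).rank
    if rank < 1 or rank > min(n, p):
        raise ValidationError(f"rank must lie in [1, {min(n, p)}], got {rank}")
    constraints = constraints or McrConstraints()
    closure = constraints.closure and rank == len(Y_cal.analytes)
    totals = Y_cal.values.sum(axis=1)

    Xv = X.values
    # initial concentration profiles: the reference concentrations when the
    # rank matches the analyte count, otherwise a non-negative SVD sketch
    if rank == len(Y_cal.analytes):
        C = Y_cal.values.astype(float).copy()
    else:
        U, s, _ = np.linalg.svd(Xv, full_matrices=False)
        C = np.abs(U[:, :rank] * s[:rank])

    zero_mask = np.zeros((p, rank), bool)
    wl = X.grid.points
    for comp, (lo, hi) in constraints.zero_windows.items():
        zero_mask[(wl >= lo) & (wl <= hi), comp] = True

    lof_history: list[float] = []
    S = _solve_s(Xv, C, constraints.nonneg_s)
    for _ in range(max_iter):
        S = _solve_s(Xv, C, constraints.nonneg_s)
        S[zero_mask] = 0.0
        if constraints.normalize_s and not closure:
            norms = np.linalg.norm(S, axis=0)
            norms[norms == 0] = 1.0
            S /= norms  # compensating scale moved into C below
            C *= norms
        C = _solve_c(Xv, S, constraints.nonneg_c)
        if closure:
            row_sums = C.sum(axis=1)
            scale = np.divide(
                totals, row_sums, out=np.ones_like(totals), where=row_sums > 0
            )
            C *= scale[:, None]
            S = _solve_s(Xv, C, constraints.nonneg_s)
            S[zero_mask] = 0.0
        lof = _lof(Xv, C, S)
        lof_history.append(lof)
        if len(lof_history) > 1:
            prev = lof_history[-2]
            if abs(prev - lof) <= lof_tol * max(prev, 1e-12):
                break

    # component-to-analyte assignment by maximal correlation between the
    # resolved calibration profiles and the reference concentrations
    n_a = len(Y_cal.analytes)
    corr = np.zeros((n_a, rank))
    for ia in range(n_a):
        y = Y_cal.values[:, ia]
        for ic in range(rank):
            c = C[:, ic]
            sy, sc = np.std(y), np.std(c)
            corr[ia, ic] = (
                0.0 if sy == 0 or sc == 0 else abs(np.corrcoef(y, c)[0, 1])
            )
    rows, cols = linear_sum_assignment(-corr)
    component_of = {Y_cal.analytes[r]: int(c) for r, c in zip(rows, cols)}

    quant_maps: dict[str, tuple[float, float]] = {}
    for a, ic in component_of.items():
        A = np.column_stack([np.ones(n), C[:, ic]])
        coef, *_ = np.linalg.lstsq(A, Y_cal.column(a), rcond=None)
        quant_maps[a] = (float(coef[0]), float(coef[1]))

    return McrModel(
        grid=X.grid,
        analytes=list(Y_cal.analytes),
        rank=rank,
        C=C,
        S=S,
        constraints=constraints,
        lack_of_fit=lof_history[-1],
        lof_history=lof_history,
        component_of=component_of,
        quant_maps=quant_maps,
    )
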