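"""Validation metrics, figures of merit and statistical comparisons.

Implements the full diagnostic suite for a multivariate calibration model:
the RMSE error family (RMSE/bias/SEC, relative and bias-corrected RMSEP),
net-analyte-signal sensitivity with its LOD/LOQ, recovery t-test against
100%, one-way ANOVA across models, the elliptical joint confidence region
(EJCR) of the predicted-vs-reference regression, and plasma matrix factors.

Two conventions exist in print for the relative RMSEP.  The standard form
divides the RMSE by the mean reference concentration; a variant typeset in
some sources divides the summed squared residual's square root by n rather
than sqrt(n), making it smaller by a factor sqrt(n).  Both are reported
(``rrmsep`` is the standard form, ``rrmsep_over_n`` the variant) so the
discrepancy is visible instead of silently hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import ValidationError

__all__ = [
    "PredictionSet",
    "MetricReport",
    "NasFiguresOfMerit",
    "EjcrResult",
    "MatrixEffectResult",
    "compute_metrics",
    "nas_figures_of_merit",
    "recovery_ttest",
    "oneway_anova",
    "ejcr",
    "matrix_effect",
]


@dataclass
class PredictionSet:
    """Paired reference (y) and predicted (y_hat) concentrations, ug/mL."""

    y: np.ndarray
    y_hat: np.ndarray
    analyte: str = ""
    role: str = "validation"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.y_hat = np.asarray(self.y_hat, dtype=float).ravel()
        if self.y.shape != self.y_hat.shape:
            raise ValidationError("reference and predicted vectors differ in length")
        if self.y.size < 2:
            raise ValidationError("need at least 2 samples")

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class MetricReport:
    rmse: float
    bias: float
    sec: float
    rrmsep: float  # standard form, %
    rrmsep_over_n: float  # typeset variant dividing by n instead of sqrt(n), %
    bcrmsep: float
    mean_recovery: float
    rsd: float
    n: int
    analyte: str = ""


def compute_metrics(pred: PredictionSet) -> MetricReport:
    """Error statistics of one prediction set.

    RMSE = sqrt(sum(y - y_hat)^2 / n); bias = mean(y - y_hat);
    SEC/BCRMSEP = sqrt(sum(y - y_hat - bias)^2 / (n - 1)) (bias-removed, the
    same expression plays both roles depending on the set it is computed on);
    RRMSEP% = RMSE / mean(y) * 100 in the standard form.
    """
    resid = pred.y - pred.y_hat
    n = pred.n
    rmse = float(np.sqrt(np.sum(resid**2) / n))
    bias = float(np.mean(resid))
    sec = float(np.sqrt(np.sum((resid - bias) ** 2) / (n - 1)))
    ybar = float(np.mean(pred.y))
    if ybar == 0:
        raise ValidationError("mean reference concentration is zero; "
                              "relative metrics undefined")
    with np.errstate(divide="ignore"):
        recoveries = np.where(pred.y != 0, pred.y_hat / pred.y * 100.0, np.nan)
    mean_rec = float(np.nanmean(recoveries))
    rec_sd = float(np.nanstd(recoveries, ddof=1))
    return MetricReport(
        rmse=rmse,
        bias=bias,
        sec=sec,
        rrmsep=rmse / ybar * 100.0,
        rrmsep_over_n=rmse / (ybar * np.sqrt(n)) * 100.0,
        bcrmsep=sec,
        mean_recovery=mean_rec,
        rsd=rec_sd / mean_rec * 100.0 if mean_rec else float("nan"),
        n=n,
        analyte=pred.analyte,
    )


@dataclass
class NasFiguresOfMerit:
    nas_vector: np.ndarray
    sensitivity: float  # AU * mL / ug
    noise_sd: float  # AU
    lod: float  # ug/mL
    loq: float  # ug/mL
    analyte: str = ""


def nas_figures_of_merit(
    spectra: np.ndarray,
    analyte_index: int,
    noise_sd: float,
    analyte: str = "",
) -> NasFiguresOfMerit:
    """Net-analyte-signal sensitivity and the LOD/LOQ it implies.

    ``spectra`` holds one unit-concentration spectrum per column (pure or
    resolved).  The NAS of analyte k is its spectrum projected onto the
    orthogonal complement of the space spanned by all other components; its
    norm is the multivariate sensitivity SEN, and LOD = 3.3 * noise_sd / SEN,
    LOQ = 10 * noise_sd / SEN (so LOQ/LOD = 10/3.3 identically).
    """
    S = np.atleast_2d(np.asarray(spectra, dtype=float))
    if S.shape[1] < 2:
        raise ValidationError("need at least 2 component spectra for a NAS")
    if noise_sd < 0:
        raise ValidationError("noise SD must be non-negative")
    k = analyte_index
    s_k = S[:, k]
    others = np.delete(S, k, axis=1)
    nas = s_k - others @ (np.linalg.pinv(others) @ s_k)
    sen = float(np.linalg.norm(nas))
    if sen <= 1e-12 * np.linalg.norm(s_k):
        raise ValidationError("no net analyte signal: spectra are collinear")
    return NasFiguresOfMerit(
        nas_vector=nas,
        sensitivity=sen,
        noise_sd=float(noise_sd),
        lod=3.3 * noise_sd / sen,
        loq=10.0 * noise_sd / sen,
        analyte=analyte,
    )


def recovery_ttest(
    recoveries: np.ndarray, reference: float = 100.0, alphas: tuple[float, ...] = (0.025, 0.01)
) -> dict:
    """One-sample t of mean recovery against the nominal value (default 100%).

    Returns the |t| statistic, its degrees of freedom, the two-sided p-value
    and the upper-tail critical values at each requested level.
    """
    r = np.asarray(recoveries, dtype=float).ravel()
    if r.size < 2:
        raise ValidationError("need at least 2 recoveries")
    n = r.size
    sd = float(np.std(r, ddof=1))
    mean = float(np.mean(r))
    if sd == 0:
        t = 0.0 if mean == reference else float("inf")
    else:
        t = abs(mean - reference) / (sd / np.sqrt(n))
    df = n - 1
    return {
        "t": t,
        "df": df,
        "mean": mean,
        "p_value": float(2 * stats.t.sf(t, df)) if np.isfinite(t) else 0.0,
        "critical": {a: float(stats.t.ppf(1 - a, df)) for a in alphas},
    }


def oneway_anova(groups: list[np.ndarray], alpha: float = 0.05) -> dict:
    """Classical one-way ANOVA: between/within decomposition, F and F_crit."""
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValidationError("need >= 2 groups with >= 2 observations each")
    N = sum(g.size for g in gs)
    k = len(gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    df_b, df_w = k - 1, N - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    F = 0.0 if ms_w == 0 and ms_b == 0 else ms_b / ms_w
    return {
        "F": float(F),
        "p_value": float(stats.f.sf(F, df_b, df_w)),
        "df": (df_b, df_w),
        "F_critical": float(stats.f.ppf(1 - alpha, df_b, df_w)),
        "ms_between": float(ms_b),
        "ms_within": float(ms_w),
    }


@dataclass
class EjcrResult:
    intercept: float
    slope: float
    xtx: np.ndarray  # 2x2 information matrix of [1, y]
    s2: float  # residual variance
    f_quantile: float
    threshold: float  # 2 * s2 * F
    center: tuple[float, float]  # (intercept, slope)
    semi_axes: tuple[float, float]
    angle_deg: float  # orientation of the major axis in (intercept, slope) plane
    area: float
    contains_ideal: bool
    zero_area: bool = False


def ejcr(pred: PredictionSet, alpha: float = 0.05) -> EjcrResult:
    """Elliptical joint confidence region of (intercept, slope).

    Predicted concentrations are regressed on the reference values,
    y_hat = a + b*y, and the (1 - alpha) region is
    {(a*, b*): (beta_hat - beta*)' X'X (beta_hat - beta*) <= 2 s^2 F(2, n-2)}.
    The method is judged unbiased when the region contains the ideality
    point (a, b) = (0, 1).  A perfect fit (s^2 = 0) degenerates to a point;
    it is reported with a zero-area flag instead of failing.
    """
    if pred.n < 3:
        raise ValidationError("EJCR needs at least 3 points")
    y = pred.y
    if np.allclose(y, y[0]):
        raise ValidationError("reference concentrations are all equal")
    X = np.column_stack([np.ones(pred.n), y])
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ pred.y_hat)
    resid = pred.y_hat - X @ beta
    s2 = float(resid @ resid) / (pred.n - 2)
    fq = float(stats.f.ppf(1 - alpha, 2, pred.n - 2))
    thr = 2.0 * s2 * fq

    # ellipse geometry: (beta - beta_hat)' XtX (beta - beta_hat) = thr
    # => axes along eigenvectors of XtX^-1, semi-axes sqrt(thr * eigval)
    evals, evecs = np.linalg.eigh(np.linalg.inv(xtx))
    semi = np.sqrt(thr * evals)
    order = np.argsort(semi)[::-1]
    semi = semi[order]
    major = evecs[:, order[0]]
    angle = float(np.degrees(np.arctan2(major[1], major[0])))
    area = float(np.pi * semi[0] * semi[1])

    d = beta - np.array([0.0, 1.0])
    q_ideal = float(d @ xtx @ d)
    zero_area = thr <= 0.0
    contains = q_ideal <= thr if not zero_area else bool(q_ideal <= 1e-18)
    return EjcrResult(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        xtx=xtx,
        s2=s2,
        f_quantile=fq,
        threshold=thr,
        center=(float(beta[0]), float(beta[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        angle_deg=angle,
        area=area,
        contains_ideal=bool(contains),
        zero_area=zero_area,
    )


@dataclass
class MatrixEffectResult:
    levels: np.ndarray  # nominal spike levels, ug/mL
    mf: np.ndarray  # matrix factors
    me_percent: np.ndarray  # (MF - 1) * 100
    analyte: str = ""


def matrix_effect(
    predicted_plasma: np.ndarray,
    predicted_neat: np.ndarray,
    levels: np.ndarray | None = None,
    analyte: str = "",
) -> MatrixEffectResult:
    """Matrix factor per spike level: plasma prediction over neat prediction."""
    pp = np.asarray(predicted_plasma, dtype=float).ravel()
    pn = np.asarray(predicted_neat, dtype=float).ravel()
    if pp.shape != pn.shape:
        raise ValidationError("plasma and neat predictions differ in length")
    if np.any(pn == 0):
        raise ValidationError("neat prediction of zero; matrix factor undefined")
    mf = pp / pn
    lv = np.arange(1, pp.size + 1, dtype=float) if levels is None else np.asarray(levels, float)
    return MatrixEffectResult(levels=lv, mf=mf, me_percent=(mf - 1.0) * 100.0, analyte=analyte)
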