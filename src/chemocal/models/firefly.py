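"""Firefly-algorithm wavelength selection for PLS calibration.

Each firefly carries a continuous position vector in [0, 1]^p; thresholding
at 0.5 turns it into a boolean wavelength mask.  Brightness is the (lower is
brighter) k-fold cross-validated RMSECV of a PLS model restricted to the
masked wavelengths.  Every firefly moves toward each brighter one with
attractiveness beta0 * exp(-gamma * r^2) plus a uniform random perturbation
of magnitude alpha, the global best being preserved unmodified (elitism).
Masks that fall below a minimum wavelength count are repaired by activating
the highest-position variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from ..datasets import ConfigurationError, ValidationError
from .base import Preprocessor

__all__ = ["FireflyParams", "firefly_select_wavelengths"]


@dataclass(frozen=True)
class FireflyParams:
    """Swarm control parameters.

    Defaults follow common practice for binary-relaxed firefly search:
    population 25, 100 generations, randomization alpha in [0, 1], initial
    attractiveness beta0 = 1 and absorption gamma just below 1.
    """

    population: int = 25
    generations: int = 100
    alpha: float = 0.25
    beta0: float = 1.0
    gamma: float = 0.9
    seed: int = 0
    min_wavelengths: int = 4

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ConfigurationError("population must be >= 2")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError("alpha must lie in [0, 1]")
        if self.beta0 <= 0 or self.gamma <= 0:
            raise ConfigurationError("beta0 and gamma must be positive")
        if self.min_wavelengths < 1:
            raise ConfigurationError("min_wavelengths must be >= 1")


def _nipals_coef(Xc: np.ndarray, yc: np.ndarray, k: int) -> np.ndarray:
    """PLS1 regression vector via NIPALS with deflation."""
    X = Xc.copy()
    y = yc.copy()
    W, P, q = [], [], []
    for _ in range(k):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        p = (X.T @ t) / tt
        q.append(float(y @ t) / tt)
        X -= np.outer(t, p)
        y = y - q[-1] * t
        W.append(w)
        P.append(p)
    if not W:
        return np.zeros(Xc.shape[1])
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    return Wm @ np.linalg.solve(Pm.T @ Wm, np.asarray(q))


def pls_rmsecv(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_splits: int = 5,
) -> float:
    """k-fold RMSECV of centered PLS1 models, pooled over response columns."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    n = X.shape[0]
    n_splits = min(n_splits, n)
    press = 0.0
    for train, test in KFold(n_splits=n_splits).split(X):
        pre = Preprocessor(center=True).fit(X[train])
        Xc = pre.transform(X[train])
        Xt = pre.transform(X[test])
        k = min(n_components, X.shape[1], len(train) - 1)
        for j in range(Y.shape[1]):
            ym = Y[train, j].mean()
            b = _nipals_coef(Xc, Y[train, j] - ym, k)
            press += float(np.sum((Y[test, j] - (Xt @ b + ym)) ** 2))
    return float(np.sqrt(press / Y.size))


def _repair(mask: np.ndarray, position: np.ndarray, min_count: int) -> np.ndarray:
    if mask.sum() >= min_count:
        return mask
    mask = mask.copy()
    mask[np.argsort(position)[::-1][:min_count]] = True
    return mask


def firefly_select_wavelengths(
    X: np.ndarray,
    Y: np.ndarray,
    params: FireflyParams,
    inner_cv: int = 5,
    n_components: int = 2,
    init_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Run the swarm; return the best mask and the best-so-far fitness trace.

    ``init_positions`` (population x p, values in [0, 1]) warm-starts the
    swarm, e.g. to seed one firefly with a known-good mask.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(params.seed)
    positions = rng.uniform(size=(params.population, p))
    if init_positions is not None:
        init_positions = np.asarray(init_positions, dtype=float)
        if init_positions.shape != positions.shape:
            raise ValidationError(
                f"init_positions must have shape {positions.shape}"
            )
        positions = np.clip(init_positions.copy(), 0.0, 1.0)

    cache: dict[bytes, float] = {}

    def fitness_of(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = pls_rmsecv(X[:, mask], Y, n_components, inner_cv)
        return cache[key]

    def mask_of(pos: np.ndarray) -> np.ndarray:
        m = _repair(pos > 0.5, pos, params.min_wavelengths)
        if not m.any():
            raise ValidationError("firefly produced an empty wavelength mask")
        return m

    best_mask: np.ndarray | None = None
    best_fit = np.inf
    history: list[float] = []

    for _ in range(params.generations):
        masks = [mask_of(positions[i]) for i in range(params.population)]
        fits = np.array([fitness_of(m) for m in masks])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_mask = masks[gen_best].copy()
        history.append(best_fit)

        order = np.argsort(fits, kind="stable")
        elite = order[0]
        for i in range(params.population):
            if i == elite:
                continue  # elitism: brightest firefly stays put
            for j in order:
                if fits[j] >= fits[i]:
                    break
                diff = positions[j] - positions[i]
                r2 = float(diff @ diff)
                beta = params.beta0 * np.exp(-params.gamma * r2)
                positions[i] = (
                    positions[i]
                    + beta * diff
                    + params.alpha * (rng.uniform(size=p) - 0.5)
                )
            np.clip(positions[i], 0.0, 1.0, out=positions[i])

    assert best_mask is not None
    return best_mask, history
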