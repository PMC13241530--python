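"""Calibration/validation design: multilevel grids and D-optimal selection.

The calibration set is a Brereton-style multilevel factorial: five coded
levels (-2, -1, 0, +1, +2) per analyte mapped affinely onto the working
concentration range, giving a 25-mixture grid for a binary system.  The
validation set is then chosen from a lattice of candidate mixtures (with
calibration coordinates excluded) by the Fedorov exchange algorithm, which
iteratively swaps design points against candidates to maximize the
determinant of the Fisher information matrix X'X of a response-surface
model -- the D-optimality criterion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .datasets import ConcentrationTable, ConfigurationError, ValidationError

__all__ = [
    "ConcentrationDomain",
    "DEFAULT_DOMAIN",
    "InformationModel",
    "DesignSet",
    "FedorovTrace",
    "generate_brereton",
    "enumerate_candidates",
    "fedorov_select",
    "leverage_diagnostics",
]


@dataclass(frozen=True)
class ConcentrationDomain:
    """Per-analyte working ranges (ug/mL), e.g. CFPM 1-17 and TAZO 1-9."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ConfigurationError(f"{name}: min must be below max")
            if lo <= 0:
                raise ConfigurationError(f"{name}: range must be positive")

    @property
    def analytes(self) -> list[str]:
        return list(self.ranges)

    def scale(self, points: np.ndarray) -> np.ndarray:
        """Affine map of each factor onto [-1, 1]."""
        lo = np.array([self.ranges[a][0] for a in self.analytes])
        hi = np.array([self.ranges[a][1] for a in self.analytes])
        return 2.0 * (np.asarray(points, dtype=float) - lo) / (hi - lo) - 1.0

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> bool:
        lo = np.array([self.ranges[a][0] for a in self.analytes])
        hi = np.array([self.ranges[a][1] for a in self.analytes])
        p = np.atleast_2d(points)
        return bool(np.all(p >= lo - atol) and np.all(p <= hi + atol))


DEFAULT_DOMAIN = ConcentrationDomain({"CFPM": (1.0, 17.0), "TAZO": (1.0, 9.0)})


@dataclass
class DesignSet:
    """A realized set of mixture coordinates with its provenance."""

    role: str  # "calibration" | "validation"
    analytes: list[str]
    points: np.ndarray  # (n, n_analytes) in ug/mL
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def to_concentration_table(self, prefix: str | None = None) -> ConcentrationTable:
        prefix = prefix or self.role[:3]
        ids = [f"{prefix}{i + 1}" for i in range(self.n_points)]
        return ConcentrationTable(list(self.analytes), self.points, ids)


@dataclass(frozen=True)
class InformationModel:
    """Feature expansion defining the Fisher information matrix X'X.

    ``quadratic`` (default) expands a 2-factor point into
    [1, x1, x2, x1*x2, x1^2, x2^2]; ``linear`` into [1, x1, x2].  When a
    domain is supplied, factors are first scaled onto [-1, 1] so the
    criterion is invariant to the concentration units.
    """

    model_order: str = "quadratic"
    domain: ConcentrationDomain | None = None

    def __post_init__(self) -> None:
        if self.model_order not in ("linear", "quadratic"):
            raise ConfigurationError(f"unknown model order {self.model_order!r}")

    def n_features(self, n_factors: int) -> int:
        if self.model_order == "linear":
            return 1 + n_factors
        return 1 + n_factors + n_factors * (n_factors + 1) // 2

    def expand(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.domain is not None:
            pts = self.domain.scale(pts)
        cols = [np.ones(pts.shape[0])]
        cols.extend(pts[:, j] for j in range(pts.shape[1]))
        if self.model_order == "quadratic":
            for j in range(pts.shape[1]):
                for k in range(j + 1, pts.shape[1]):
                    cols.append(pts[:, j] * pts[:, k])
            cols.extend(pts[:, j] ** 2 for j in range(pts.shape[1]))
        return np.column_stack(cols)


@dataclass
class FedorovTrace:
    """Per-swap log of one Fedorov run (best restart kept)."""

    seed: int
    restarts: int
    swaps: list[dict] = field(default_factory=list)
    final_log_det: float = -np.inf
    restart_log_dets: list[float] = field(default_factory=list)


def generate_brereton(
    domain: ConcentrationDomain = DEFAULT_DOMAIN, levels: int = 5
) -> DesignSet:
    """Full multilevel factorial calibration grid in cyclic-shift run order.

    With 5 levels and the default domain this is the 25-mixture calibration
    set: CFPM from {1, 5, 9, 13, 17} and TAZO from {1, 3, 5, 7, 9} ug/mL,
    level 0 sitting at the range centre (9 and 5 ug/mL).  Runs are ordered in
    blocks where the second factor's level sequence is a cyclic shift of the
    first's; the ordering is conventional and does not affect any model.
    """
    if levels % 2 == 0 or levels < 3:
        raise ConfigurationError("level count must be odd and >= 3")
    analytes = domain.analytes
    if len(analytes) != 2:
        raise ConfigurationError("the multilevel generator is defined for 2 analytes")
    coded = np.arange(levels) - levels // 2  # e.g. -2..+2
    level_values = {}
    for a in analytes:
        lo, hi = domain.ranges[a]
        step = (hi - lo) / (levels - 1)
        center = (hi + lo) / 2.0
        level_values[a] = center + coded * step
    points = []
    for shift in range(levels):
        for j in range(levels):
            points.append(
                (
                    level_values[analytes[0]][j],
                    level_values[analytes[1]][(j + shift) % levels],
                )
            )
    return DesignSet(
        "calibration",
        analytes,
        np.array(points),
        provenance={"generator": "brereton", "levels": levels},
    )


def enumerate_candidates(
    domain: ConcentrationDomain,
    grid_step: dict[str, float] | float = 1.0,
    exclude: DesignSet | None = None,
    atol: float = 1e-9,
) -> np.ndarray:
    """All lattice points of the domain minus any excluded design coordinates."""
    analytes = domain.analytes
    if np.isscalar(grid_step):
        grid_step = {a: float(grid_step) for a in analytes}
    axes = []
    for a in analytes:
        step = grid_step[a]
        if step <= 0:
            raise ConfigurationError("grid step must be positive")
        lo, hi = domain.ranges[a]
        n = int(np.floor((hi - lo) / step + atol)) + 1
        axes.append(lo + step * np.arange(n))
    pool = np.array(list(itertools.product(*axes)))
    if exclude is not None and exclude.n_points:
        dist = np.abs(pool[:, None, :] - exclude.points[None, :, :]).max(axis=2)
        pool = pool[~(dist.min(axis=1) <= atol)]
    if pool.shape[0] == 0:
        raise ValidationError("candidate pool is empty after exclusion")
    return pool


def _log_det(X: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(X.T @ X)
    return ld if sign > 0 else -np.inf


def fedorov_select(
    candidates: np.ndarray,
    n_select: int,
    model: InformationModel,
    seed: int = 0,
    restarts: int = 20,
    tol: float = 1e-9,
    max_passes: int = 200,
) -> tuple[DesignSet, FedorovTrace]:
    """D-optimal subset selection by the classic Fedorov exchange.

    Starting from a random ``n_select``-subset, every (design point,
    candidate) pair is scored with the variance-function delta

        delta = d(x_in) - d(x_out) - [d(x_in) d(x_out) - d(x_in, x_out)^2]

    where d(x) = x' (X'X)^-1 x, and the best improving swap is applied;
    det(X'X) grows by the factor (1 + delta) at each accepted swap, so the
    determinant is non-decreasing within a restart.  The best of ``restarts``
    random starts is returned.  Ties are broken toward the lowest candidate
    index for determinism.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    n_cand = candidates.shape[0]
    F = model.expand(candidates)
    p = F.shape[1]
    if n_select < p:
        raise ValidationError(
            f"need at least {p} points for a {model.model_order} model, "
            f"got n_select={n_select}"
        )
    if n_select > n_cand:
        raise ValidationError("n_select exceeds the candidate pool size")

    rng = np.random.default_rng(seed)
    best_idx: np.ndarray | None = None
    best_ld = -np.inf
    best_swaps: list[dict] = []
    restart_lds: list[float] = []

    for _ in range(max(1, restarts)):
        idx = np.sort(rng.choice(n_cand, size=n_select, replace=False))
        X = F[idx]
        ld = _log_det(X)
        attempts = 0
        while ld == -np.inf and attempts < 50:
            idx = np.sort(rng.choice(n_cand, size=n_select, replace=False))
            X = F[idx]
            ld = _log_det(X)
            attempts += 1
        if ld == -np.inf:
            restart_lds.append(ld)
            continue

        swaps: list[dict] = []
        selected = set(idx.tolist())
        for _ in range(max_passes):
            out_idx = np.array(sorted(n for n in range(n_cand) if n not in selected))
            if out_idx.size == 0:
                break
            in_idx = np.array(sorted(selected))
            X = F[in_idx]
            M_inv = np.linalg.inv(X.T @ X)
            A_in = F[in_idx] @ M_inv  # (n_sel, p)
            d_in = np.einsum("ij,ij->i", A_in, F[in_idx])
            d_out = np.einsum("ij,ij->i", F[out_idx] @ M_inv, F[out_idx])
            cross = A_in @ F[out_idx].T  # (n_sel, n_out)
            delta = (
                d_out[None, :]
                - d_in[:, None]
                - (d_in[:, None] * d_out[None, :] - cross**2)
            )
            i, j = np.unravel_index(np.argmax(delta), delta.shape)
            if delta[i, j] <= tol:
                break
            selected.discard(int(in_idx[i]))
            selected.add(int(out_idx[j]))
            ld += float(np.log1p(delta[i, j]))
            swaps.append(
                {
                    "out": int(in_idx[i]),
                    "in": int(out_idx[j]),
                    "log_det": float(ld),
                }
            )
        ld = _log_det(F[np.array(sorted(selected))])  # refresh against drift
        restart_lds.append(float(ld))
        if ld > best_ld + 1e-12:
            best_ld = float(ld)
            best_idx = np.array(sorted(selected))
            best_swaps = swaps

    if best_idx is None:
        raise ValidationError(
            "information matrix singular for every initialization; "
            "candidate pool cannot support the requested model"
        )

    analytes = model.domain.analytes if model.domain else [
        f"x{i + 1}" for i in range(candidates.shape[1])
    ]
    design = DesignSet(
        "validation",
        analytes,
        candidates[best_idx],
        provenance={
            "generator": "fedorov",
            "seed": seed,
            "restarts": restarts,
            "model_order": model.model_order,
            "log_det": best_ld,
        },
    )
    trace = FedorovTrace(
        seed=seed,
        restarts=restarts,
        swaps=best_swaps,
        final_log_det=best_ld,
        restart_log_dets=restart_lds,
    )
    return design, trace


def leverage_diagnostics(design: DesignSet, model: InformationModel) -> dict:
    """Hat-matrix leverages h_i = x_i' (X'X)^-1 x_i and spread summaries.

    Leverages sum to the number of model terms; near-duplicate points show up
    as shared low leverage, while a homogeneous spatial spread keeps the
    pairwise-distance summary balanced.
    """
    X = model.expand(design.points)
    M = X.T @ X
    if np.linalg.matrix_rank(M) < M.shape[0]:
        raise ValidationError("singular information matrix; design is degenerate")
    h = np.einsum("ij,ij->i", X @ np.linalg.inv(M), X)
    pts = design.points
    if design.n_points >= 2:
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        iu = np.triu_indices(design.n_points, k=1)
        pair = d[iu]
        spread = {
            "min_pairwise_distance": float(pair.min()),
            "max_pairwise_distance": float(pair.max()),
            "mean_pairwise_distance": float(pair.mean()),
        }
    else:
        spread = {}
    return {"leverages": h, "leverage_sum": float(h.sum()), **spread}
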