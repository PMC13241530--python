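"""End-to-end orchestration: simulate -> design -> fit x3 -> validate -> compare.

One :class:`RunConfig` drives the whole study: the multilevel calibration
grid and Fedorov-selected validation set are generated over the configured
concentration domain, synthetic mixture spectra are simulated for both sets,
the three calibration models are fitted and validated, and the per-model
metric / EJCR / NAS reports, cross-model ANOVA, and a plasma matrix-effect
study are collected into a :class:`ComparisonReport`.  Every stochastic
stage derives its seed from the pipeline seed by a fixed offset, so a config
reproduces its results bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import ConcentrationTable, SpectraMatrix
from .design import (
    ConcentrationDomain,
    DesignSet,
    InformationModel,
    enumerate_candidates,
    fedorov_select,
    generate_brereton,
)
from .io import save_model
from .models import (
    FireflyParams,
    McrModel,
    PcrModel,
    PlsModel,
    efa_rank,
    fit_fapls,
    fit_mcrals,
    fit_pcr,
)
from .models.mcr import McrConstraints
from .simulate import (
    DEFAULT_BAND_LIBRARY,
    GaussianBand,
    MatrixEffectSpec,
    NoiseModel,
    build_pure_spectra,
    simulate_mixtures,
    simulate_plasma_set,
)
from .validation import (
    PredictionSet,
    compute_metrics,
    ejcr,
    matrix_effect,
    nas_figures_of_merit,
    oneway_anova,
    recovery_ttest,
)

__all__ = ["RunConfig", "ComparisonReport", "run_pipeline"]

# fixed per-stage seed offsets from the pipeline seed
_SEED_DESIGN = 1
_SEED_CAL_NOISE = 2
_SEED_VAL_NOISE = 3
_SEED_PLASMA = 4
_SEED_FIREFLY = 10  # + analyte index


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (JSON round-trippable)."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CFPM": (1.0, 17.0), "TAZO": (1.0, 9.0)}
    )
    levels: int = 5
    n_validation: int = 13
    candidate_step: float = 1.0
    design_model_order: str = "quadratic"
    restarts: int = 20
    seed: int = 20260605
    noise_sd: float = 0.002
    baseline_amplitude: float = 0.0
    band_library: dict[str, list[tuple[float, float, float]]] | None = None
    max_k: int = 8
    firefly: dict[str, dict] = field(
        default_factory=lambda: {
            "CFPM": {"population": 25, "generations": 100, "alpha": 0.25,
                     "beta0": 1.0, "gamma": 0.9},
            "TAZO": {"population": 25, "generations": 100, "alpha": 0.20,
                     "beta0": 1.0, "gamma": 0.8},
        }
    )
    inner_cv: int = 5
    inner_components: int = 2
    mcr_max_iter: int = 50
    mcr_lof_tol: float = 1e-3
    alpha: float = 0.05
    matrix_suppression: dict[str, float] = field(
        default_factory=lambda: {"CFPM": 0.017, "TAZO": 0.020}
    )
    plasma_background: float = 0.005
    spike_levels: list[tuple[float, float]] = field(
        default_factory=lambda: [(5.0, 3.0), (10.0, 5.0), (15.0, 7.0)]
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def domain(self) -> ConcentrationDomain:
        return ConcentrationDomain({a: tuple(r) for a, r in self.ranges.items()})

    def bands(self) -> dict[str, list[GaussianBand]]:
        if self.band_library is None:
            return DEFAULT_BAND_LIBRARY
        return {
            a: [GaussianBand(*b) for b in bands]
            for a, bands in self.band_library.items()
        }


@dataclass
class ComparisonReport:
    config: RunConfig
    calibration: DesignSet
    validation: DesignSet
    models: dict[str, object]  # name -> fitted model
    predictions: dict[str, ConcentrationTable]
    metrics: dict[str, dict[str, object]]  # model -> analyte -> MetricReport
    ejcr: dict[str, dict[str, object]]
    nas: dict[str, dict[str, object]]
    ttests: dict[str, dict[str, dict]]
    anova: dict[str, dict]  # analyte -> ANOVA across models
    ranking: list[str]  # model names by mean validation RMSEP, best first
    matrix_effects: dict[str, object]  # analyte -> MatrixEffectResult (MCR model)
    efa_rank: int
    log: list[str] = field(default_factory=list)

    def rmsep(self, model: str, analyte: str) -> float:
        return self.metrics[model][analyte].rmse

    def max_rrmsep(self) -> float:
        return max(
            m.rrmsep for per in self.metrics.values() for m in per.values()
        )


def _spectral_noise_sd(model, X_cal: SpectraMatrix) -> float:
    """RMS spectral reconstruction residual of the fitted model (delta_r)."""
    V = X_cal.values
    if isinstance(model, McrModel):
        resid = V - model.C @ model.S.T
    elif isinstance(model, PcrModel):
        Xp = model.preprocessor.transform(V)
        recon = Xp @ model.loadings @ model.loadings.T
        resid = (Xp - recon) * model.preprocessor.scale_
    elif isinstance(model, PlsModel):
        # reconstruction on the union mask via an SVD basis of the same rank
        mask = model.mask
        k = max(s.k for s in model.sub.values())
        Vm = V[:, mask]
        mean = Vm.mean(axis=0)
        U, s, Vt = np.linalg.svd(Vm - mean, full_matrices=False)
        resid = (Vm - mean) - U[:, :k] * s[:k] @ Vt[:k]
    else:
        raise TypeError(type(model).__name__)
    return float(np.sqrt(np.mean(resid**2)))


def run_pipeline(config: RunConfig | None = None, out_dir=None) -> ComparisonReport:
    """Execute the full study described by ``config``; optionally write artifacts."""
    config = config or RunConfig()
    log: list[str] = []
    t0 = time.time()

    def note(msg: str) -> None:
        log.append(f"[{time.time() - t0:7.2f}s] {msg}")

    def stage(name: str):
        note(f"stage: {name}")

    domain = config.domain()
    analytes = domain.analytes

    stage("design")
    calib = generate_brereton(domain, config.levels)
    candidates = enumerate_candidates(domain, config.candidate_step, exclude=calib)
    info = InformationModel(config.design_model_order, domain)
    valid, trace = fedorov_select(
        candidates,
        config.n_validation,
        info,
        seed=config.seed + _SEED_DESIGN,
        restarts=config.restarts,
    )
    note(
        f"brereton {calib.n_points} points; fedorov picked {valid.n_points} "
        f"of {candidates.shape[0]} candidates, log det {trace.final_log_det:.4f}"
    )

    stage("simulate")
    pure = build_pure_spectra(config.bands())
    Y_cal = calib.to_concentration_table("cal")
    Y_val = valid.to_concentration_table("val")
    noise_cal = NoiseModel(
        config.noise_sd, config.baseline_amplitude, seed=config.seed + _SEED_CAL_NOISE
    )
    noise_val = NoiseModel(
        config.noise_sd, config.baseline_amplitude, seed=config.seed + _SEED_VAL_NOISE
    )
    X_cal = simulate_mixtures(pure, Y_cal, noise_cal)
    X_val = simulate_mixtures(pure, Y_val, noise_val)

    stage("fit")
    pcr = fit_pcr(X_cal, Y_cal, max_k=config.max_k)
    note(f"pcr retained k={pcr.k}")
    ff = {
        a: FireflyParams(seed=config.seed + _SEED_FIREFLY + i, **config.firefly[a])
        for i, a in enumerate(analytes)
    }
    fapls = fit_fapls(
        X_cal,
        Y_cal,
        params=ff,
        max_k=config.max_k,
        inner_cv=config.inner_cv,
        inner_components=config.inner_components,
    )
    note(
        "fa-pls masks: "
        + ", ".join(f"{a}={int(fapls.sub[a].mask.sum())} vars (k={fapls.sub[a].k})"
                    for a in analytes)
    )
    efa = efa_rank(X_cal)
    mcr = fit_mcrals(
        X_cal,
        Y_cal,
        rank=efa.rank,
        constraints=McrConstraints(),
        max_iter=config.mcr_max_iter,
        lof_tol=config.mcr_lof_tol,
    )
    note(f"efa rank {efa.rank}; mcr lack of fit {mcr.lack_of_fit:.4f}%")
    models: dict[str, object] = {"PCR": pcr, "FA-PLS": fapls, "MCR-ALS": mcr}

    stage("validate")
    predictions, metrics, ejcrs, nass, ttests = {}, {}, {}, {}, {}
    eps_matrix = np.column_stack([pure[a].epsilon for a in analytes])
    for name, model in models.items():
        pred = model.predict(X_val)
        predictions[name] = pred
        metrics[name], ejcrs[name], nass[name], ttests[name] = {}, {}, {}, {}
        delta_r = _spectral_noise_sd(model, X_cal)
        for ia, a in enumerate(analytes):
            ps = PredictionSet(Y_val.column(a), pred.column(a), analyte=a)
            metrics[name][a] = compute_metrics(ps)
            ejcrs[name][a] = ejcr(ps, alpha=config.alpha)
            if isinstance(model, McrModel):
                # resolved spectra rescaled to unit concentration via the
                # quantification slope, so SEN is in AU mL/ug
                S = np.column_stack(
                    [
                        mcr.S[:, mcr.component_of[an]] / mcr.quant_maps[an][1]
                        for an in analytes
                    ]
                )
            else:
                S = eps_matrix
            nass[name][a] = nas_figures_of_merit(S, ia, delta_r, analyte=a)
            rec = pred.column(a) / Y_val.column(a) * 100.0
            ttests[name][a] = recovery_ttest(rec)

    anova = {}
    for a in analytes:
        groups = [
            predictions[name].column(a) / Y_val.column(a) * 100.0 for name in models
        ]
        anova[a] = oneway_anova(groups, alpha=config.alpha)
    ranking = sorted(
        models, key=lambda name: np.mean([metrics[name][a].rmse for a in analytes])
    )
    note("ranking by mean RMSEP: " + " < ".join(ranking))

    stage("plasma")
    spikes = np.array(config.spike_levels, dtype=float)
    Y_spike = ConcentrationTable(list(analytes), spikes)
    noise_plasma = NoiseModel(config.noise_sd, seed=config.seed + _SEED_PLASMA)
    mx = MatrixEffectSpec(
        suppression_fraction=dict(config.matrix_suppression),
        background_amplitude=config.plasma_background,
    )
    X_plasma, true_mf = simulate_plasma_set(pure, Y_spike, noise_plasma, mx)
    X_neat = simulate_mixtures(pure, Y_spike, noise_plasma)
    pred_plasma = mcr.predict(X_plasma)
    pred_neat = mcr.predict(X_neat)
    matrix_effects = {
        a: matrix_effect(
            pred_plasma.column(a), pred_neat.column(a), spikes[:, ia], analyte=a
        )
        for ia, a in enumerate(analytes)
    }
    note(
        "true matrix factors: "
        + ", ".join(f"{a}={true_mf[a]:.4f}" for a in analytes)
    )

    report = ComparisonReport(
        config=config,
        calibration=calib,
        validation=valid,
        models=models,
        predictions=predictions,
        metrics=metrics,
        ejcr=ejcrs,
        nas=nass,
        ttests=ttests,
        anova=anova,
        ranking=ranking,
        matrix_effects=matrix_effects,
        efa_rank=efa.rank,
        log=log,
    )
    if out_dir is not None:
        _write_artifacts(report, X_cal, X_val, Path(out_dir))
    return report


def _report_json(report: ComparisonReport) -> dict:
    cfg = report.config

    def metric_dict(m):
        return {
            k: v for k, v in dataclasses.asdict(m).items() if not isinstance(v, np.ndarray)
        }

    out = {
        "config": json.loads(cfg.to_json()),
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "efa_rank": report.efa_rank,
        "ranking": report.ranking,
        "metrics": {
            name: {a: metric_dict(m) for a, m in per.items()}
            for name, per in report.metrics.items()
        },
        "ejcr": {
            name: {
                a: {
                    "intercept": e.intercept,
                    "slope": e.slope,
                    "semi_axes": list(e.semi_axes),
                    "angle_deg": e.angle_deg,
                    "area": e.area,
                    "contains_ideal": e.contains_ideal,
                    "zero_area": e.zero_area,
                }
                for a, e in per.items()
            }
            for name, per in report.ejcr.items()
        },
        "nas": {
            name: {
                a: {
                    "sensitivity": f.sensitivity,
                    "noise_sd": f.noise_sd,
                    "lod": f.lod,
                    "loq": f.loq,
                }
                for a, f in per.items()
            }
            for name, per in report.nas.items()
        },
        "ttests": report.ttests,
        "anova": report.anova,
        "matrix_effects": {
            a: {
                "levels": me.levels.tolist(),
                "mf": me.mf.tolist(),
                "me_percent": me.me_percent.tolist(),
            }
            for a, me in report.matrix_effects.items()
        },
        "log": report.log,
    }
    return out


def _write_artifacts(
    report: ComparisonReport, X_cal: SpectraMatrix, X_val: SpectraMatrix, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.calibration.to_concentration_table("cal").to_csv(out / "calibration_conc.csv")
    report.validation.to_concentration_table("val").to_csv(out / "validation_conc.csv")
    X_cal.to_csv(out / "calibration_spectra.csv")
    X_val.to_csv(out / "validation_spectra.csv")
    for name, model in report.models.items():
        save_model(model, out / f"model_{name.lower().replace('-', '_')}")
    for name, pred in report.predictions.items():
        pred.to_csv(out / f"predictions_{name.lower().replace('-', '_')}.csv")
    (out / "comparison.json").write_text(json.dumps(_report_json(report), indent=2))
    (out / "run.log").write_text("\n".join(report.log) + "\n")
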