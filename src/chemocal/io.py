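"""Model archives: JSON metadata plus companion CSV matrices.

A fitted model is written to a directory holding ``model.json`` (type,
scalars, structure) and one full-precision CSV per array, so the archive can
be reloaded from any language.  Round-tripping a model reproduces its
predictions to within 1e-12.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datasets import ValidationError, WavelengthGrid
from .models.base import Preprocessor
from .models.mcr import McrConstraints, McrModel
from .models.pcr import PcrModel
from .models.pls import PlsModel, _PlsSub

__all__ = ["save_model", "load_model"]

_FMT = "%.17g"


def _write_array(directory: Path, name: str, arr: np.ndarray) -> str:
    path = directory / f"{name}.csv"
    np.savetxt(path, np.atleast_1d(np.asarray(arr)), fmt=_FMT, delimiter=",")
    return path.name


def _read_array(directory: Path, name: str) -> np.ndarray:
    return np.loadtxt(directory / f"{name}.csv", delimiter=",")


def _grid_meta(grid: WavelengthGrid) -> dict:
    return {"start_nm": grid.start_nm, "end_nm": grid.end_nm, "step_nm": grid.step_nm}


def _pre_meta(pre: Preprocessor, directory: Path, prefix: str) -> dict:
    return {
        "center": pre.center,
        "scale": pre.scale,
        "mean": _write_array(directory, f"{prefix}_mean", pre.mean_),
        "scale_vec": _write_array(directory, f"{prefix}_scale", pre.scale_),
    }


def _pre_load(meta: dict, directory: Path) -> Preprocessor:
    pre = Preprocessor(center=meta["center"], scale=meta["scale"])
    pre.mean_ = np.atleast_1d(_read_array(directory, Path(meta["mean"]).stem))
    pre.scale_ = np.atleast_1d(_read_array(directory, Path(meta["scale_vec"]).stem))
    return pre


def save_model(model, path) -> Path:
    """Serialize a fitted PCR / PLS / MCR model into a directory archive."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    meta: dict = {"grid": _grid_meta(model.grid), "analytes": list(model.analytes)}
    if isinstance(model, PcrModel):
        meta["type"] = "pcr"
        meta["k"] = model.k
        meta["cv_curve"] = {str(k): v for k, v in model.cv_curve.items()}
        meta["preprocessor"] = _pre_meta(model.preprocessor, directory, "pre")
        meta["loadings"] = _write_array(directory, "loadings", model.loadings)
        meta["coef"] = _write_array(directory, "coef", model.coef_)
        meta["y_mean"] = _write_array(directory, "y_mean", model.y_mean_)
    elif isinstance(model, PlsModel):
        meta["type"] = "pls"
        meta["sub"] = {}
        for a, s in model.sub.items():
            meta["sub"][a] = {
                "k": s.k,
                "y_mean": s.y_mean,
                "cv_curve": {str(k): v for k, v in s.cv_curve.items()},
                "firefly_history": s.firefly_history,
                "preprocessor": _pre_meta(s.preprocessor, directory, f"{a}_pre"),
                "mask": _write_array(directory, f"{a}_mask", s.mask.astype(int)),
                "coef": _write_array(directory, f"{a}_coef", s.coef),
            }
    elif isinstance(model, McrModel):
        meta["type"] = "mcr"
        meta["rank"] = model.rank
        meta["lack_of_fit"] = model.lack_of_fit
        meta["lof_history"] = model.lof_history
        meta["component_of"] = model.component_of
        meta["quant_maps"] = {a: list(v) for a, v in model.quant_maps.items()}
        c = model.constraints
        meta["constraints"] = {
            "nonneg_c": c.nonneg_c,
            "nonneg_s": c.nonneg_s,
            "closure": c.closure,
            "normalize_s": c.normalize_s,
            "zero_windows": {str(k): list(v) for k, v in c.zero_windows.items()},
        }
        meta["C"] = _write_array(directory, "C", model.C)
        meta["S"] = _write_array(directory, "S", model.S)
    else:
        raise ValidationError(f"cannot archive model of type {type(model).__name__}")
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_model(path):
    """Reload a model archive written by :func:`save_model`."""
    directory = Path(path)
    meta = json.loads((directory / "model.json").read_text())
    grid = WavelengthGrid(**meta["grid"])
    analytes = list(meta["analytes"])
    kind = meta.get("type")
    if kind == "pcr":
        return PcrModel(
            grid=grid,
            analytes=analytes,
            preprocessor=_pre_load(meta["preprocessor"], directory),
            loadings=np.atleast_2d(_read_array(directory, "loadings")),
            coef_=np.atleast_2d(_read_array(directory, "coef")),
            y_mean_=np.atleast_1d(_read_array(directory, "y_mean")),
            k=int(meta["k"]),
            cv_curve={int(k): v for k, v in meta["cv_curve"].items()},
        )
    if kind == "pls":
        sub = {}
        for a, m in meta["sub"].items():
            sub[a] = _PlsSub(
                mask=np.atleast_1d(_read_array(directory, f"{a}_mask")).astype(bool),
                preprocessor=_pre_load(m["preprocessor"], directory),
                coef=np.atleast_1d(_read_array(directory, f"{a}_coef")),
                y_mean=float(m["y_mean"]),
                k=int(m["k"]),
                cv_curve={int(k): v for k, v in m["cv_curve"].items()},
                firefly_history=list(m["firefly_history"]),
            )
        return PlsModel(grid=grid, analytes=analytes, sub=sub)
    if kind == "mcr":
        c = meta["constraints"]
        constraints = McrConstraints(
            nonneg_c=c["nonneg_c"],
            nonneg_s=c["nonneg_s"],
            closure=c["closure"],
            normalize_s=c["normalize_s"],
            zero_windows={int(k): tuple(v) for k, v in c["zero_windows"].items()},
        )
        return McrModel(
            grid=grid,
            analytes=analytes,
            rank=int(meta["rank"]),
            C=np.atleast_2d(_read_array(directory, "C")),
            S=np.atleast_2d(_read_array(directory, "S")),
            constraints=constraints,
            lack_of_fit=float(meta["lack_of_fit"]),
            lof_history=list(meta["lof_history"]),
            component_of={a: int(v) for a, v in meta["component_of"].items()},
            quant_maps={a: (float(v[0]), float(v[1])) for a, v in meta["quant_maps"].items()},
        )
    raise ValidationError(f"unknown model archive type {kind!r}")
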