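"""Sustainability calculators: per-sample carbon footprint and score panels.

The carbon footprint of one analysis is a cradle-to-gate double sum

    CF = sum_i(P_i * t_i * EF_elec) + sum_j(m_j * EF_j)

over instrument energy draws (power P_i in kW for t_i hours, grid emission
factor EF_elec in kg CO2e/kWh) and consumables (mass m_j in kg with
cradle-to-gate emission factor EF_j in kg CO2e/kg).  Multi-color
sustainability panels (greenness / practicality / performance / innovation
sub-scores on a 0-100% scale) are aggregated into one overall "whiteness"
percentage by a weighted arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ValidationError

__all__ = [
    "EnergyItem",
    "ConsumableItem",
    "EXAMPLE_EMISSION_FACTORS",
    "carbon_footprint",
    "aggregate_scores",
]


@dataclass(frozen=True)
class EnergyItem:
    name: str
    power_kw: float
    hours: float

    def __post_init__(self) -> None:
        if self.power_kw < 0 or self.hours < 0:
            raise ValidationError(f"{self.name}: power and hours must be >= 0")


@dataclass(frozen=True)
class ConsumableItem:
    name: str
    mass_kg: float
    emission_factor: float  # kg CO2e per kg

    def __post_init__(self) -> None:
        if self.mass_kg < 0 or self.emission_factor < 0:
            raise ValidationError(f"{self.name}: mass and EF must be >= 0")


# Editable example cradle-to-gate emission factors (kg CO2e per kg); users
# supply their own inventory for any real assessment.
EXAMPLE_EMISSION_FACTORS: dict[str, float] = {
    "water_ultrapure": 0.001,
    "methanol": 2.0,
    "acetonitrile": 5.5,
    "glass": 1.2,
    "polypropylene": 2.3,
    "nitrile_gloves": 6.0,
}


def carbon_footprint(
    energy: list[EnergyItem],
    ef_elec: float,
    consumables: list[ConsumableItem] | None = None,
) -> float:
    """Per-sample carbon footprint in kg CO2e."""
    if ef_elec < 0:
        raise ValidationError("electricity emission factor must be >= 0")
    consumables = consumables or []
    cf = sum(e.power_kw * e.hours * ef_elec for e in energy)
    cf += sum(c.mass_kg * c.emission_factor for c in consumables)
    return float(cf)


def aggregate_scores(
    scores: dict[str, float],
    weights: dict[str, float] | None = None,
    decimals: int = 1,
) -> float:
    """Weighted mean of percentage sub-scores, rounded to ``decimals``.

    With no weights the plain arithmetic mean is used; weights must cover the
    same keys and are normalized to sum to one.
    """
    if not scores:
        raise ValidationError("score panel is empty")
    for name, v in scores.items():
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"score {name!r} outside [0, 100]: {v}")
    names = list(scores)
    vals = np.array([scores[n] for n in names], dtype=float)
    if weights is None:
        w = np.full(len(names), 1.0 / len(names))
    else:
        if set(weights) != set(names):
            raise ValidationError("weights do not match the score panel keys")
        w = np.array([weights[n] for n in names], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("weights must be non-negative with positive sum")
        w = w / w.sum()
    return float(np.round(float(vals @ w), decimals))
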