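"""Scenario results and solution audit structures shared by both engines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .constraints import ConstraintSystem
from .survey import DietSurvey, DietVector

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
ERROR = "error"


@dataclass
class DeviationSplit:
    """Split decision variables at a solution.

    ``q_plus[i] >= q0_i`` carries increases and ``q_minus[i] <= q0_i``
    carries decreases of category i (similarly ``Q_plus``/``Q_minus`` per
    group); the physical quantity is ``q = q_plus + q_minus - q0``.  At an
    optimum the deviation is one-sided: min(q_plus - q0, q0 - q_minus) = 0
    within tolerance.
    """

    q_plus: dict[str, float]
    q_minus: dict[str, float]
    Q_plus: dict[str, float]
    Q_minus: dict[str, float]


def diet_totals(diet: DietVector, survey: DietSurvey) -> dict[str, float]:
    """Energy (kJ), mass (g), GHGE (kg CO2e) and cost (EUR) of a diet."""
    q = diet.as_array(survey)
    ghge = 0.01 * np.array([c.ghge for c in survey.categories])
    price = 0.01 * np.array([c.price for c in survey.categories])
    energy = 0.01 * np.array(
        [c.nutrients.get(survey.energy_nutrient, 0.0)
         for c in survey.categories])
    return {
        "energy": float(energy @ q),
        "mass": float(q.sum()),
        "ghge": float(ghge @ q),
        "cost": float(price @ q),
    }


@dataclass
class ScenarioResult:
    """Outcome of one optimization scenario."""

    label: str
    status: str
    engine: str
    diet: DietVector | None = None
    objective: float | None = None
    totals: dict[str, float] = field(default_factory=dict)
    binding: list[tuple[str, str]] = field(default_factory=list)
    split: DeviationSplit | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def is_optimal(self) -> bool:
        return self.status == OPTIMAL

    def quantities_frame(self, survey: DietSurvey) -> pd.DataFrame:
        """Tidy per-category table: optimized vs baseline quantities."""
        if self.diet is None:
            raise ValueError(f"scenario {self.label!r} has no diet "
                             f"(status {self.status})")
        rows = []
        for c in survey.categories:
            q = self.diet.quantities[c.id]
            rows.append({
                "scenario": self.label, "category": c.id, "group": c.group_id,
                "quantity": q, "baseline": c.baseline_intake,
                "change": q - c.baseline_intake,
            })
        return pd.DataFrame(rows)


@dataclass
class AuditReport:
    """Independent feasibility/optimality check of a ScenarioResult."""

    violations: list[str] = field(default_factory=list)
    binding: list[tuple[str, str]] = field(default_factory=list)
    objective_recomputed: float | None = None
    objective_gap: float | None = None

    @property
    def ok(self) -> bool:
        return not self.violations


def binding_rows(system: ConstraintSystem, q: np.ndarray,
                 tol: float = 1e-6) -> list[tuple[str, str]]:
    """Rows satisfied with (near-)equality at ``q``: (name, family) pairs."""
    out = []
    for r in system.rows:
        v = r.value(q)
        scale = tol * max(1.0, float(np.linalg.norm(r.coeffs)))
        lo_hit = r.lower is not None and abs(v - r.lower) <= scale
        hi_hit = r.upper is not None and abs(v - r.upper) <= scale
        if lo_hit or hi_hit:
            out.append((r.name, r.family))
    return out
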