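"""Scenario engine: the NUTR diet and the stepwise GHGE-reduction ladder.

The optimization strategy proceeds in two stages:

1. **NUTR** — a nutritionally adequate diet is optimized under the
   nutritional, energy, feasible-consumption, new-food group-cap, fixed and
   total-mass constraints, with no GHGE cap.
2. **NUTR+GHGE-X%** — dietary GHGE is then reduced stepwise: each step caps
   diet GHGE at (1 - x) times the *NUTR diet's* GHGE while holding the new
   food's host-group total (e.g. meat plus the meat alternative) at its NUTR
   value, so that substitution happens *within* the group.  The ladder is
   truncated at the first infeasible step.

Runs for different population strata (e.g. male/female) are pure data
changes: the same code path runs on each stratum's survey and constraint
spec.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .constraints import ConstraintSystem, NutrientConstraintSpec, \
    build_constraints
from .lp import build_lp, solve_lp
from .qp import solve_qp
from .results import OPTIMAL, ScenarioResult
from .survey import DietSurvey
from .weights import PenaltyWeightSet, category_weights

#: default ladder: 5% to 60% GHGE reduction in 5% steps
DEFAULT_REDUCTIONS = tuple(np.round(np.arange(0.05, 0.601, 0.05), 2))

ENGINES = ("qp", "lp")


def _solve(survey: DietSurvey, weights: PenaltyWeightSet,
           system: ConstraintSystem, engine: str,
           label: str) -> ScenarioResult:
    if engine == "qp":
        return solve_qp(survey, weights, system, label=label)
    if engine == "lp":
        model = build_lp(survey, system, weights, label=label)
        return solve_lp(model)
    raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")


def run_nutr(survey: DietSurvey, nutrients: NutrientConstraintSpec,
             engine: str = "qp",
             weights: PenaltyWeightSet | None = None) -> ScenarioResult:
    """Optimize the nutritionally adequate (NUTR) diet — no GHGE cap."""
    if weights is None:
        weights = category_weights(survey)
    system = build_constraints(survey, nutrients)
    result = _solve(survey, weights, system, engine, "NUTR")
    result.meta["system"] = system
    return result


def run_ghge_ladder(survey: DietSurvey, nutrients: NutrientConstraintSpec,
                    nutr_result: ScenarioResult,
                    reductions: Sequence[float] = DEFAULT_REDUCTIONS,
                    engine: str = "qp",
                    weights: PenaltyWeightSet | None = None,
                    ) -> list[ScenarioResult]:
    """Stepwise GHGE reduction relative to the NUTR diet.

    Each step x caps diet GHGE at ``(1 - x) * GHGE(NUTR)`` and pins the new
    food's host-group total at its NUTR value.  Results are returned in
    order; the ladder stops after the first infeasible step (which is
    included, with its status).
    """
    if not nutr_result.is_optimal:
        raise ValueError("NUTR result must be optimal to anchor the ladder")
    reds = list(reductions)
    if any(not 0 <= x < 1 for x in reds):
        raise ValueError(f"reductions must lie in [0, 1), got {reds}")
    if any(b <= a for a, b in zip(reds, reds[1:])):
        raise ValueError("reductions must be strictly increasing")
    if weights is None:
        weights = category_weights(survey)
    ghge_base = nutr_result.totals["ghge"]
    host = survey.new_food.group_id
    group_total = nutr_result.diet.group_totals(survey)[host]

    results: list[ScenarioResult] = []
    for x in reds:
        label = f"NUTR+GHGE-{round(100 * x):g}%"
        system = build_constraints(
            survey, nutrients,
            ghge_cap=(1.0 - x) * ghge_base,
            fix_group_totals={host: group_total},
        )
        res = _solve(survey, weights, system, engine, label)
        res.meta.update(system=system, reduction=x,
                        ghge_cap=(1.0 - x) * ghge_base,
                        ghge_base=ghge_base, fixed_group=host,
                        fixed_group_total=group_total)
        results.append(res)
        if not res.is_optimal:
            break
    return results


def max_feasible_reduction(survey: DietSurvey,
                           nutrients: NutrientConstraintSpec,
                           nutr_result: ScenarioResult,
                           engine: str = "qp",
                           resolution: float = 0.01,
                           weights: PenaltyWeightSet | None = None) -> float:
    """Largest GHGE reduction fraction still solvable, by bisection.

    Returns the largest x (to within ``resolution``) for which the capped
    scenario has an optimal solution; 0.0 if even tiny reductions fail.
    """
    if not nutr_result.is_optimal:
        raise ValueError("NUTR result must be optimal")
    if weights is None:
        weights = category_weights(survey)
    ghge_base = nutr_result.totals["ghge"]
    host = survey.new_food.group_id
    group_total = nutr_result.diet.group_totals(survey)[host]

    # feasibility is engine-independent (both engines share the constraint
    # system), so probing uses the cheap LP phase only
    from .qp import _lp_feasible_point

    def feasible(x: float) -> bool:
        system = build_constraints(
            survey, nutrients, ghge_cap=(1.0 - x) * ghge_base,
            fix_group_totals={host: group_total})
        return _lp_feasible_point(system) is not None

    lo, hi = 0.0, 1.0 - 1e-9
    if not feasible(lo):
        return 0.0
    if feasible(hi):
        return hi
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo
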