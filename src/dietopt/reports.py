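"""Reporting layer: group shares, nutrient contributions, category breakdowns.

All shares are stored as fractions; formatting as percentages happens only
at the presentation edge.  Shares are computed on the optimized
(as-consumed) quantities, and metric totals are recomputed here
independently of the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .results import ScenarioResult, diet_totals
from .survey import DietSurvey

METRICS = ("mass", "energy", "ghge", "cost")


def _metric_coeff(survey: DietSurvey, cid: str, metric: str) -> float:
    c = survey.category(cid)
    if metric == "mass":
        return 1.0
    if metric == "energy":
        return 0.01 * c.nutrients.get(survey.energy_nutrient, 0.0)
    if metric == "ghge":
        return 0.01 * c.ghge
    if metric == "cost":
        return 0.01 * c.price
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def group_shares(result: ScenarioResult, survey: DietSurvey,
                 metric: str = "mass") -> dict[str, float]:
    """Per-group share of the diet total for one metric; shares sum to 1."""
    if not result.is_optimal:
        raise ValueError(f"result {result.label!r} is not optimal")
    per_group = {
        g.id: sum(result.diet.quantities[cid]
                  * _metric_coeff(survey, cid, metric)
                  for cid in g.member_ids)
        for g in survey.groups
    }
    total = sum(per_group.values())
    if total <= 0:
        raise ValueError(f"diet total for metric {metric!r} is zero")
    return {gid: v / total for gid, v in per_group.items()}


def nutrient_contributions(result: ScenarioResult, survey: DietSurvey,
                           threshold: float = 0.20) -> pd.DataFrame:
    """Share of each nutrient's intake supplied by each group.

    Long table with columns ``nutrient, group, share, defined, flagged``;
    ``flagged`` marks group contributions at or above ``threshold`` (e.g.
    the groups contributing more than 20% of a nutrient's intake).  A
    nutrient with zero total intake has undefined shares: ``defined`` is
    False and ``share`` is NaN.
    """
    if not result.is_optimal:
        raise ValueError(f"result {result.label!r} is not optimal")
    rows = []
    for nid in survey.nutrient_ids:
        totals = {
            g.id: sum(result.diet.quantities[cid]
                      * survey.category(cid).nutrients.get(nid, 0.0)
                      for cid in g.member_ids)
            for g in survey.groups
        }
        grand = sum(totals.values())
        for gid, v in totals.items():
            defined = grand > 0
            share = v / grand if defined else float("nan")
            rows.append({"nutrient": nid, "group": gid, "share": share,
                         "defined": defined,
                         "flagged": bool(defined and share >= threshold)})
    return pd.DataFrame(rows)


@dataclass
class CategoryBreakdown:
    """Within-group per-category metrics, plus the new-food mass share."""

    group_id: str
    frame: pd.DataFrame
    new_food_mass_share: float | None


def category_breakdown(result: ScenarioResult, survey: DietSurvey,
                       group_id: str) -> CategoryBreakdown:
    """Per-category mass, energy, GHGE and cost within one group."""
    if not result.is_optimal:
        raise ValueError(f"result {result.label!r} is not optimal")
    g = survey.group(group_id)  # raises KeyError for an unknown group
    rows = []
    for cid in g.member_ids:
        q = result.diet.quantities[cid]
        row = {"category": cid, "quantity": q,
               "is_new_food": survey.category(cid).is_new_food}
        for metric in METRICS:
            row[metric] = q * _metric_coeff(survey, cid, metric)
        rows.append(row)
    df = pd.DataFrame(rows)
    for metric in METRICS:
        total = df[metric].sum()
        df[f"{metric}_share"] = df[metric] / total if total > 0 \
            else float("nan")
    nf_share = None
    new_rows = df[df["is_new_food"]]
    if len(new_rows) and df["mass"].sum() > 0:
        nf_share = float(new_rows["mass"].sum() / df["mass"].sum())
    return CategoryBreakdown(group_id=group_id, frame=df,
                             new_food_mass_share=nf_share)


def scenario_summary(result: ScenarioResult, survey: DietSurvey) -> dict:
    """JSON-ready summary of one scenario's totals and binding families."""
    totals = diet_totals(result.diet, survey) if result.is_optimal else {}
    return {
        "label": result.label,
        "status": result.status,
        "engine": result.engine,
        "objective": result.objective,
        "totals": totals,
        "binding": [{"name": n, "family": f} for n, f in result.binding],
    }
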