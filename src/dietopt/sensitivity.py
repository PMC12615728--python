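"""Sensitivity analyses as reproducible variant runs.

Four variants probe the robustness of the simulated substitutions, each
changing exactly one input relative to a base configuration:

* ``profile_override`` — replace the new food's nutrient profile (e.g. a
  market-product profile instead of the pure ingredient);
* ``no_category_weights`` — remove all directional category penalty
  weights (set w+ = w- = 1); group weights z are left unchanged;
* ``ghge_scale`` — multiply only the new food's GHGE coefficient (e.g.
  0.5 and 1.5 for a +/-50% uncertainty band);
* ``engine_swap`` — rerun with the piecewise-linear engine instead of the
  quadratic one (or vice versa).

Everything else — survey, constraint spec, scenario ladder — is held
fixed, and each output carries the variant label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .constraints import ConstraintSystem, NutrientConstraintSpec
from .qp import _SplitProblem
from .results import ScenarioResult
from .scenarios import DEFAULT_REDUCTIONS, run_ghge_ladder, run_nutr
from .survey import DietSurvey
from .weights import PenaltyWeightSet, category_weights

VARIANTS = ("profile_override", "no_category_weights", "ghge_scale",
            "engine_swap")


@dataclass
class RunConfig:
    """A complete scenario-run configuration."""

    survey: DietSurvey
    nutrients: NutrientConstraintSpec
    reductions: tuple[float, ...] = DEFAULT_REDUCTIONS
    engine: str = "qp"
    use_category_weights: bool = True


@dataclass
class VariantRun:
    """Labelled results of one (variant of a) scenario run."""

    label: str
    variant: str | None
    params: dict[str, Any]
    nutr: ScenarioResult
    ladder: list[ScenarioResult]

    @property
    def results(self) -> list[ScenarioResult]:
        return [self.nutr, *self.ladder]

    def scenario_table(self, survey: DietSurvey) -> pd.DataFrame:
        """Tidy long table: one row per optimal scenario x category."""
        frames = [r.quantities_frame(survey) for r in self.results
                  if r.is_optimal]
        df = pd.concat(frames, ignore_index=True) if frames \
            else pd.DataFrame(columns=["scenario", "category", "group",
                                       "quantity", "baseline", "change"])
        df.insert(0, "variant", self.label)
        return df


def _weights_for(config: RunConfig) -> PenaltyWeightSet:
    w = category_weights(config.survey)
    return w if config.use_category_weights else w.without_category_weights()


def run_scenarios(config: RunConfig, label: str = "base") -> VariantRun:
    """Run NUTR plus the GHGE ladder for one configuration."""
    weights = _weights_for(config)
    nutr = run_nutr(config.survey, config.nutrients, config.engine, weights)
    ladder = run_ghge_ladder(
        config.survey, config.nutrients, nutr, config.reductions,
        config.engine, weights) if nutr.is_optimal else []
    return VariantRun(label=label, variant=None, params={},
                      nutr=nutr, ladder=ladder)


def run_variant(base_config: RunConfig, variant: str,
                params: Mapping[str, Any] | None = None) -> VariantRun:
    """Run one sensitivity variant; only its declared inputs change."""
    params = dict(params or {})
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of "
                         f"{VARIANTS}")
    config = base_config
    label = variant
    if variant == "profile_override":
        profile = params.get("profile")
        if profile is None:
            raise ValueError("profile_override requires a 'profile' mapping")
        survey = base_config.survey.copy()
        missing = [nid for nid in survey.nutrient_ids if nid not in profile]
        if missing:
            raise ValueError(
                f"override profile is missing nutrients: {missing}")
        survey.new_food.nutrients = {nid: float(profile[nid])
                                     for nid in survey.nutrient_ids}
        config = replace(base_config, survey=survey)
    elif variant == "no_category_weights":
        config = replace(base_config, use_category_weights=False)
    elif variant == "ghge_scale":
        scale = params.get("scale")
        if scale is None or scale <= 0:
            raise ValueError("ghge_scale requires a positive 'scale'")
        survey = base_config.survey.copy()
        survey.new_food.ghge *= float(scale)
        config = replace(base_config, survey=survey)
        label = f"ghge_scale:{scale:g}"
    elif variant == "engine_swap":
        other = "lp" if base_config.engine == "qp" else "qp"
        config = replace(base_config, engine=params.get("engine", other))
        label = f"engine:{config.engine}"
    run = run_scenarios(config, label=label)
    run.variant = variant
    run.params = params
    return run


def run_grid(base_config: RunConfig,
             grid: Sequence[Mapping[str, Any]]) -> list[VariantRun]:
    """Run the base plus a declarative list of variant specs.

    Each grid entry is ``{"variant": <name>, "params": {...}}``; the JSON
    form of this list is accepted by the command-line interface.
    """
    runs = [run_scenarios(base_config)]
    for entry in grid:
        runs.append(run_variant(base_config, entry["variant"],
                                entry.get("params")))
    return runs


def grid_table(runs: Sequence[VariantRun], survey: DietSurvey) -> pd.DataFrame:
    """One tidy long table over (variant, scenario, category)."""
    return pd.concat([r.scenario_table(survey) for r in runs],
                     ignore_index=True)


@dataclass
class RunComparison:
    """Per-category quantity differences plus new-food group-mass shares."""

    differences: pd.DataFrame      # scenario x category: q_a, q_b, diff
    new_food_share: pd.DataFrame   # scenario: share_a, share_b


def compare_runs(run_a: VariantRun, run_b: VariantRun,
                 survey: DietSurvey) -> RunComparison:
    """Compare two runs over the same survey and scenario grid."""
    labels_a = [r.label for r in run_a.results if r.is_optimal]
    labels_b = [r.label for r in run_b.results if r.is_optimal]
    common = [lab for lab in labels_a if lab in labels_b]
    if not common:
        raise ValueError("runs share no optimal scenarios to compare "
                         f"({labels_a} vs {labels_b})")
    res_a = {r.label: r for r in run_a.results}
    res_b = {r.label: r for r in run_b.results}
    nf = survey.new_food
    host = survey.group(nf.group_id)
    diff_rows, share_rows = [], []
    for lab in common:
        a, b = res_a[lab], res_b[lab]
        if set(a.diet.quantities) != set(b.diet.quantities):
            raise ValueError(f"scenario {lab!r}: category sets differ")
        for cid in survey.category_ids:
            qa = a.diet.quantities[cid]
            qb = b.diet.quantities[cid]
            diff_rows.append({"scenario": lab, "category": cid,
                              "q_a": qa, "q_b": qb, "diff": qb - qa})
        share_rows.append({
            "scenario": lab,
            "share_a": _group_mass_share(a, nf.id, host.member_ids),
            "share_b": _group_mass_share(b, nf.id, host.member_ids),
        })
    return RunComparison(pd.DataFrame(diff_rows), pd.DataFrame(share_rows))


def _group_mass_share(result: ScenarioResult, cid: str,
                      member_ids: Sequence[str]) -> float:
    total = sum(result.diet.quantities[m] for m in member_ids)
    return result.diet.quantities[cid] / total if total > 0 else float("nan")


def model_matrices(survey: DietSurvey, weights: PenaltyWeightSet,
                   system: ConstraintSystem) -> dict[str, np.ndarray]:
    """Assembled model arrays, for diffing between variants.

    Variant isolation means e.g. a GHGE rescaling of the new food changes
    exactly one coefficient of one constraint row and nothing else.
    """
    prob = _SplitProblem(survey, weights, system)
    return {
        "hessian_diag": 2.0 * prob.diag,
        "center": prob.center.copy(),
        "A": prob.A.copy(),
        "row_lower": prob.rlo.copy(),
        "row_upper": prob.rhi.copy(),
        "var_lower": prob.lb.copy(),
        "var_upper": prob.ub.copy(),
    }
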