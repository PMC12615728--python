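"""Synthetic dietary-survey generator.

Produces surveys with the structure of a national dietary survey aggregated
to food categories: by default 79 categories in 13 food groups, with
right-skewed positive baseline intakes, intake SDs proportional to the
baselines, 5th/95th percentile bounds bracketing the mean, per-100 g
nutrient profiles (including energy), GHGE and price coefficients, one
fixed water category, and exactly one zero-baseline new food (a
mycoprotein-like meat alternative) inside the meat group with an imputed
SD.  The generator emulates structure, not any country's actual intake
magnitudes.

The new food's coefficients follow the qualitative economics of mycoprotein:
GHGE well below the host-group mean, price near the group maximum, energy
density low, protein and fiber high.  These defaults make substitution
direction in downstream scenario runs meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constraints import ABSOLUTE, NutrientBound, NutrientConstraintSpec
from .survey import (ENERGY_NUTRIENT, DietSurvey, FoodCategory, FoodGroup,
                     impute_new_food_sd, validate_survey)

_GROUP_NAMES = ["meat", "dairy", "grains", "vegetables", "fruit", "fish",
                "drinks", "fats", "legumes", "starches", "sweets", "eggs",
                "misc"]

#: nutrient-id -> (low, high) per 100 g sampling range
_NUTRIENT_RANGES = {
    ENERGY_NUTRIENT: (80.0, 1600.0),   # kJ/100 g
    "protein": (0.5, 25.0),            # g/100 g
    "fat": (0.1, 20.0),
    "carbohydrate": (0.5, 60.0),
    "fiber": (0.0, 8.0),
    "iron": (0.05, 4.0),               # mg/100 g
    "calcium": (2.0, 150.0),
    "vitamin_b12": (0.0, 3.0),         # ug/100 g
    "sodium": (5.0, 600.0),            # mg/100 g
}

#: mycoprotein-like profile of the new food (per 100 g)
_NEW_FOOD_NUTRIENTS = {
    ENERGY_NUTRIENT: 355.6, "protein": 11.5, "fat": 2.9,
    "carbohydrate": 3.0, "fiber": 6.0, "iron": 0.5, "calcium": 40.0,
    "vitamin_b12": 0.1, "sodium": 5.0,
}


@dataclass
class GeneratorParams:
    """Tunable scales of the generator; defaults define the test conditions."""

    intake_scale: float = 40.0        # median category intake, g/day
    intake_sigma: float = 1.0         # lognormal shape (right skew)
    cv: float = 0.8                   # intake SD as fraction of baseline
    sd_floor: float = 1.0             # g/day, keeps SDs positive
    group_cv: float = 0.35            # group SD as fraction of group total
    p5_range: tuple[float, float] = (0.2, 0.6)    # x baseline
    p95_range: tuple[float, float] = (1.6, 3.0)   # x baseline
    group_p95_factor: float = 1.3     # group cap over group baseline
    water_intake: float = 1200.0      # g/day, fixed category
    host_group: str = "meat"
    new_food_ghge: float = 0.30       # kg CO2e/100 g, below meat-group mean
    new_food_price: float = 1.31      # EUR/100 g, near meat-group maximum
    meat_ghge_range: tuple[float, float] = (0.8, 4.0)
    other_ghge_range: tuple[float, float] = (0.02, 0.8)
    price_range: tuple[float, float] = (0.1, 1.4)


def generate_survey(n_categories: int = 79, m_groups: int = 13,
                    seed: int = 0,
                    params: GeneratorParams | None = None) -> DietSurvey:
    """Deterministically generate a survey with ``n`` categories, ``m`` groups.

    The host group always contains the single new food (zero baseline,
    imputed SD) and the drinks group (or the host group when m == 1) the
    fixed water category.
    """
    if n_categories < m_groups:
        raise ValueError(
            f"need at least one category per group: n={n_categories} < "
            f"m={m_groups}")
    if m_groups < 1:
        raise ValueError("m_groups must be >= 1")
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)

    group_names = [_GROUP_NAMES[j] if j < len(_GROUP_NAMES) else f"group{j+1}"
                   for j in range(m_groups)]
    if p.host_group in group_names:
        host = p.host_group
    else:
        host = group_names[0]
    water_group = "drinks" if "drinks" in group_names else host

    # spread categories over groups; host group large enough for the five
    # SD-reference categories plus the new food
    sizes = np.full(m_groups, n_categories // m_groups)
    sizes[: n_categories % m_groups] += 1
    host_j = group_names.index(host)
    want_host = min(n_categories, 6)
    while sizes[host_j] < want_host:
        donor = int(np.argmax(sizes))
        if donor == host_j or sizes[donor] <= 1:
            break
        sizes[donor] -= 1
        sizes[host_j] += 1

    categories: list[FoodCategory] = []
    per_group_scale = {
        g: float(p.intake_scale * rng.lognormal(0.0, 0.5))
        for g in group_names
    }
    k = 0
    new_food_done = False
    water_done = False
    for j, gname in enumerate(group_names):
        for slot in range(int(sizes[j])):
            cid = f"c{k:02d}_{gname}"
            k += 1
            if gname == host and not new_food_done and slot == sizes[j] - 1:
                categories.append(FoodCategory(
                    id="new_food", name="mycoprotein", group_id=gname,
                    baseline_intake=0.0, intake_sd=1.0,  # imputed below
                    p5=0.0, p95=0.0,
                    nutrients=dict(_NEW_FOOD_NUTRIENTS),
                    ghge=p.new_food_ghge, price=p.new_food_price,
                    is_new_food=True,
                ))
                new_food_done = True
                continue
            if gname == water_group and not water_done and slot == 0:
                categories.append(FoodCategory(
                    id="water", name="drinking water", group_id=gname,
                    baseline_intake=p.water_intake,
                    intake_sd=max(p.cv * p.water_intake, p.sd_floor),
                    p5=p.water_intake, p95=p.water_intake,
                    nutrients={nid: 0.0 for nid in _NUTRIENT_RANGES},
                    ghge=0.001, price=0.001, is_fixed=True,
                ))
                water_done = True
                continue
            base = float(per_group_scale[gname]
                         * rng.lognormal(0.0, p.intake_sigma))
            sd = max(p.cv * base, p.sd_floor)
            p5 = base * rng.uniform(*p.p5_range)
            p95 = base * rng.uniform(*p.p95_range)
            nutrients = {
                nid: float(rng.uniform(lo, hi))
                for nid, (lo, hi) in _NUTRIENT_RANGES.items()
            }
            if gname == host:
                # meat-like: protein-dense, B12-rich
                nutrients["protein"] = float(rng.uniform(15.0, 28.0))
                nutrients["vitamin_b12"] = float(rng.uniform(0.5, 3.0))
                nutrients[ENERGY_NUTRIENT] = float(rng.uniform(500.0, 1300.0))
                ghge = float(rng.uniform(*p.meat_ghge_range))
            else:
                ghge = float(rng.uniform(*p.other_ghge_range))
            categories.append(FoodCategory(
                id=cid, name=cid.replace("_", " "), group_id=gname,
                baseline_intake=base, intake_sd=sd, p5=p5, p95=p95,
                nutrients=nutrients, ghge=ghge,
                price=float(rng.uniform(*p.price_range)),
            ))

    groups = []
    for gname in group_names:
        members = tuple(c.id for c in categories if c.group_id == gname)
        total = sum(c.baseline_intake for c in categories
                    if c.group_id == gname)
        groups.append(FoodGroup(
            id=gname, name=gname, member_ids=members, baseline_total=total,
            group_sd=max(p.group_cv * total, p.sd_floor),
            group_weight=2.0, p95=p.group_p95_factor * total,
        ))

    survey = DietSurvey(f"synthetic-seed{seed}", categories, groups)
    impute_new_food_sd(survey)
    issues = validate_survey(survey)
    if issues:  # a generator bug, not a data problem
        raise AssertionError(f"generated survey is invalid: {issues}")
    return survey


def make_feasible_spec(survey: DietSurvey,
                       slack: float = 0.3) -> NutrientConstraintSpec:
    """Nutrient bounds at (1 +/- slack) of the baseline diet's intakes.

    The baseline diet satisfies every bound by construction, so scenario
    runs on the result always have a feasible starting point.
    """
    if slack < 0:
        raise ValueError(f"slack must be >= 0, got {slack}")
    baseline = survey.baseline_diet()
    bounds = []
    for nid in survey.nutrient_ids:
        total = survey.nutrient_total(baseline, nid)
        bounds.append(NutrientBound(
            nutrient_id=nid, lower=(1.0 - slack) * total,
            upper=(1.0 + slack) * total, basis=ABSOLUTE))
    return NutrientConstraintSpec(bounds)


def make_binding_spec(survey: DietSurvey, nutrient_id: str,
                      push: float = 0.1,
                      slack: float = 0.3) -> NutrientConstraintSpec:
    """A feasible spec with one nutrient's lower bound pushed above baseline.

    Raising the lower bound of ``nutrient_id`` to (1 + push) x its baseline
    intake forces that constraint to bind (when still feasible), inducing
    nontrivial substitutions.
    """
    if push < 0:
        raise ValueError(f"push must be >= 0, got {push}")
    if nutrient_id not in survey.nutrient_ids:
        raise KeyError(f"unknown nutrient {nutrient_id!r}")
    spec = make_feasible_spec(survey, slack)
    baseline = survey.baseline_diet()
    total = survey.nutrient_total(baseline, nutrient_id)
    bounds = []
    for b in spec:
        if b.nutrient_id == nutrient_id:
            upper = b.upper
            if upper is not None and upper < (1.0 + push) * total:
                upper = (1.0 + push) * total
            bounds.append(NutrientBound(
                nutrient_id=nutrient_id, lower=(1.0 + push) * total,
                upper=upper, basis=ABSOLUTE))
        else:
            bounds.append(b)
    return NutrientConstraintSpec(bounds)
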