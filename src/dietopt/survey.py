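"""Dietary-survey data model, validation, and data-preparation transforms.

The central container is :class:`DietSurvey`: a population stratum's observed
diet expressed as ``n`` food categories grouped into ``m`` food groups.  Each
category carries its mean daily intake (g/day), the population standard
deviation of that intake, the 5th/95th percentiles of observed consumption,
a per-100 g nutrient profile, and per-100 g greenhouse-gas (GHGE) and price
coefficients.  A *new food* (e.g. a mycoprotein meat alternative) is a
category with zero baseline intake placed inside a host group; a *fixed*
category (e.g. drinking water) is pinned at its observed intake.

Unit conventions, used consistently across the package:

* diet quantities: g/day
* nutrient, GHGE and price coefficients: per 100 g of food
* energy: kJ (the designated energy nutrient is stored per 100 g like any
  other nutrient)

The g/day-to-per-100 g conversion factor 0.01 is applied in exactly one
place, the constraint/objective assembly, never here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Default id of the designated energy entry in each category's nutrient map.
ENERGY_NUTRIENT = "energy_kj"

#: Columns of the category table that are not nutrient columns.
_CATEGORY_COLUMNS = [
    "id", "name", "group_id", "baseline_intake", "intake_sd",
    "p5", "p95", "is_new_food", "is_fixed", "ghge", "price",
]


@dataclass
class FoodCategory:
    """One food category of the survey.

    Parameters use the package's unit conventions: ``baseline_intake``,
    ``intake_sd``, ``p5`` and ``p95`` in g/day; ``nutrients`` per 100 g;
    ``ghge`` in kg CO2e per 100 g; ``price`` in EUR per 100 g.
    """

    id: str
    name: str
    group_id: str
    baseline_intake: float
    intake_sd: float
    p5: float
    p95: float
    nutrients: dict[str, float] = field(default_factory=dict)
    ghge: float = 0.0
    price: float = 0.0
    is_new_food: bool = False
    is_fixed: bool = False


@dataclass
class FoodGroup:
    """A named set of categories with group-level baseline and weight.

    ``p95`` is the 95th percentile of observed *group* consumption; it is
    required for the host group of a new food, where it caps the group total.
    """

    id: str
    name: str
    member_ids: tuple[str, ...]
    baseline_total: float
    group_sd: float
    group_weight: float = 2.0
    p95: float | None = None


@dataclass
class DietSurvey:
    """A population stratum's full category/group structure.

    ``energy_target`` (kJ/day) is the stratum's observed dietary energy
    intake; if omitted it is computed from the baseline diet and the
    designated energy nutrient.
    """

    stratum: str
    categories: list[FoodCategory]
    groups: list[FoodGroup]
    energy_target: float | None = None
    energy_nutrient: str = ENERGY_NUTRIENT

    def __post_init__(self) -> None:
        if self.energy_target is None:
            self.energy_target = 0.01 * sum(
                c.baseline_intake * c.nutrients.get(self.energy_nutrient, 0.0)
                for c in self.categories
            )

    # -- lookup helpers -------------------------------------------------
    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def category_ids(self) -> list[str]:
        return [c.id for c in self.categories]

    @property
    def group_ids(self) -> list[str]:
        return [g.id for g in self.groups]

    def category(self, cid: str) -> FoodCategory:
        for c in self.categories:
            if c.id == cid:
                return c
        raise KeyError(f"unknown category id {cid!r}")

    def group(self, gid: str) -> FoodGroup:
        for g in self.groups:
            if g.id == gid:
                return g
        raise KeyError(f"unknown group id {gid!r}")

    def group_members(self, gid: str) -> list[FoodCategory]:
        order = {cid: k for k, cid in enumerate(self.category_ids)}
        return sorted(
            (c for c in self.categories if c.group_id == gid),
            key=lambda c: order[c.id],
        )

    @property
    def nutrient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.categories:
            for nid in c.nutrients:
                seen.setdefault(nid)
        return list(seen)

    @property
    def new_foods(self) -> list[FoodCategory]:
        return [c for c in self.categories if c.is_new_food]

    @property
    def new_food(self) -> FoodCategory:
        nf = self.new_foods
        if len(nf) != 1:
            raise ValueError(f"expected exactly one new food, found {len(nf)}")
        return nf[0]

    def baseline_diet(self) -> "DietVector":
        return DietVector({c.id: c.baseline_intake for c in self.categories})

    def nutrient_total(self, diet: "DietVector", nutrient_id: str) -> float:
        """Daily intake of a nutrient under ``diet`` (per-day units)."""
        return 0.01 * sum(
            diet.quantities[c.id] * c.nutrients.get(nutrient_id, 0.0)
            for c in self.categories
        )

    def copy(self) -> "DietSurvey":
        cats = [replace(c, nutrients=dict(c.nutrients)) for c in self.categories]
        grps = [replace(g) for g in self.groups]
        return DietSurvey(self.stratum, cats, grps,
                          self.energy_target, self.energy_nutrient)


@dataclass
class DietVector:
    """A candidate diet: g/day per category, with derived group totals."""

    quantities: dict[str, float]

    def group_totals(self, survey: DietSurvey) -> dict[str, float]:
        return {
            g.id: sum(self.quantities[cid] for cid in g.member_ids)
            for g in survey.groups
        }

    def as_array(self, survey: DietSurvey) -> np.ndarray:
        return np.array([self.quantities[cid] for cid in survey.category_ids])

    @classmethod
    def from_array(cls, survey: DietSurvey, q: np.ndarray) -> "DietVector":
        return cls(dict(zip(survey.category_ids, (float(v) for v in q))))


# ---------------------------------------------------------------------------
# Data-preparation transforms
# ---------------------------------------------------------------------------

def apply_yield_factor(raw_quantity: float, factor: float,
                       category: str = "") -> float:
    """Convert a raw quantity to as-consumed mass (e.g. raw to cooked meat).

    Raises ``ValueError`` for a non-positive factor, naming the category.
    """
    if factor <= 0:
        raise ValueError(
            f"yield factor must be positive, got {factor} for category "
            f"{category or '<unnamed>'}"
        )
    if raw_quantity < 0:
        raise ValueError(f"raw quantity must be non-negative, got {raw_quantity}")
    return raw_quantity * factor


def aggregate_category_profile(
    item_intakes: Sequence[float],
    item_profiles: Sequence[Mapping[str, float]],
) -> dict[str, float]:
    """Intake-weighted average nutrient profile of the items in a category.

    Each nutrient of the aggregate equals
    ``sum(intake_k * profile_k) / sum(intake_k)``.  All item profiles must
    share the same nutrient keys; a zero total intake is an error rather
    than a silent fall-back to an unweighted mean.
    """
    if len(item_intakes) != len(item_profiles):
        raise ValueError("item_intakes and item_profiles differ in length")
    if not item_intakes:
        raise ValueError("cannot aggregate an empty item list")
    total = float(sum(item_intakes))
    if total <= 0:
        raise ValueError("total intake is zero; cannot form intake weights")
    keys = set(item_profiles[0])
    for k, prof in enumerate(item_profiles[1:], start=1):
        missing = keys.symmetric_difference(prof)
        if missing:
            raise ValueError(
                f"item {k} nutrient keys differ from item 0: "
                f"{sorted(missing)}"
            )
    return {
        nid: sum(w * prof[nid] for w, prof in zip(item_intakes, item_profiles))
        / total
        for nid in item_profiles[0]
    }


def rescale_ghge_electricity(coef: float, elec_share: float,
                             gwp_old: float, gwp_new: float) -> float:
    """Adapt a GHGE coefficient to a different electricity mix.

    The electricity-attributable share of the coefficient is rescaled by the
    ratio of the new to the old grid GWP (kg CO2e/kWh); the remainder is
    unchanged.
    """
    if not 0.0 <= elec_share <= 1.0:
        raise ValueError(f"electricity share must be in [0, 1], got {elec_share}")
    if gwp_old <= 0:
        raise ValueError(f"old electricity GWP must be positive, got {gwp_old}")
    return coef * (1.0 - elec_share) + coef * elec_share * (gwp_new / gwp_old)


def impute_new_food_sd(
    survey: DietSurvey,
    reference_ids: Sequence[str] | None = None,
    n_default_references: int = 5,
) -> float:
    """Impute the new food's intake SD as the mean SD of reference categories.

    A new food has zero baseline intake and therefore no observed SD.  By
    default the references are the ``n_default_references`` largest-intake
    non-new categories of the host group (emulating the use of the common
    meat categories as references for mycoprotein).  The imputed value is
    assigned to the new food's ``intake_sd`` and returned.
    """
    new = survey.new_food
    if reference_ids is None:
        peers = [c for c in survey.group_members(new.group_id)
                 if not c.is_new_food]
        peers.sort(key=lambda c: c.baseline_intake, reverse=True)
        refs = peers[:n_default_references]
        if not refs:
            raise ValueError(
                f"host group {new.group_id!r} has no reference categories"
            )
    else:
        if not reference_ids:
            raise ValueError("reference_ids is empty")
        refs = [survey.category(cid) for cid in reference_ids]
    for c in refs:
        if c.intake_sd <= 0:
            raise ValueError(f"reference category {c.id!r} has non-positive SD")
    sd = float(np.mean([c.intake_sd for c in refs]))
    new.intake_sd = sd
    return sd


def derive_price(expenditure: float, quantity_kg: float) -> float:
    """Price in EUR per 100 g from expenditure (EUR) and quantity (kg)."""
    if quantity_kg <= 0:
        raise ValueError(f"purchased quantity must be positive, got {quantity_kg}")
    return expenditure / quantity_kg / 10.0


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_survey(survey: DietSurvey) -> list[str]:
    """Check every structural invariant; return one message per violation.

    An empty list means the survey is well-formed.  This is a reporting
    operation: it never raises on bad data.
    """
    issues: list[str] = []
    cat_ids = survey.category_ids
    if len(set(cat_ids)) != len(cat_ids):
        issues.append("duplicate category ids")
    grp_ids = survey.group_ids
    if len(set(grp_ids)) != len(grp_ids):
        issues.append("duplicate group ids")
    if survey.n_categories < 1:
        issues.append("survey has no categories")
    if survey.n_groups < 1:
        issues.append("survey has no groups")
    if survey.energy_target is None or survey.energy_target <= 0:
        issues.append(f"energy target must be positive, got {survey.energy_target}")

    for c in survey.categories:
        if c.group_id not in grp_ids:
            issues.append(f"category {c.id!r}: unknown group {c.group_id!r}")
        if c.baseline_intake < 0:
            issues.append(f"category {c.id!r}: negative baseline intake")
        if c.intake_sd <= 0:
            issues.append(f"category {c.id!r}: intake SD must be > 0 "
                          "(impute it for a new food)")
        if not 0 <= c.p5 <= c.p95:
            issues.append(f"category {c.id!r}: requires 0 <= p5 <= p95, "
                          f"got p5={c.p5}, p95={c.p95}")
        if c.ghge < 0:
            issues.append(f"category {c.id!r}: negative GHGE coefficient")
        if c.price < 0:
            issues.append(f"category {c.id!r}: negative price")
        for nid, val in c.nutrients.items():
            if val < 0 or not math.isfinite(val):
                issues.append(f"category {c.id!r}: nutrient {nid!r} must be "
                              f"finite and >= 0, got {val}")
        if c.is_new_food and c.baseline_intake != 0:
            issues.append(f"new food {c.id!r} must have zero baseline intake")
        if c.is_fixed and not (c.p5 == c.p95 == c.baseline_intake):
            issues.append(f"fixed category {c.id!r} must have "
                          "p5 = p95 = baseline_intake")

    membership: dict[str, int] = {cid: 0 for cid in cat_ids}
    for g in survey.groups:
        for cid in g.member_ids:
            if cid not in membership:
                issues.append(f"group {g.id!r}: unknown member {cid!r}")
            else:
                membership[cid] += 1
        member_sum = sum(
            survey.category(cid).baseline_intake
            for cid in g.member_ids if cid in membership
        )
        if g.baseline_total > 0:
            rel = abs(g.baseline_total - member_sum) / max(abs(g.baseline_total), 1.0)
        else:
            rel = abs(g.baseline_total - member_sum)
        if rel > 1e-9:
            issues.append(f"group {g.id!r}: baseline_total {g.baseline_total} "
                          f"!= member sum {member_sum}")
        if g.group_sd <= 0:
            issues.append(f"group {g.id!r}: group SD must be > 0")
        if g.group_weight < 1:
            issues.append(f"group {g.id!r}: group weight must be >= 1")
        if g.p95 is not None and g.p95 < 0:
            issues.append(f"group {g.id!r}: negative p95")
    for cid, count in membership.items():
        if count != 1:
            issues.append(f"category {cid!r} belongs to {count} groups "
                          "(must be exactly 1)")
    if len(survey.new_foods) > 1:
        issues.append("more than one new food in the survey")
    return issues


# ---------------------------------------------------------------------------
# File I/O — delimited text and JSON with identical field names
# ---------------------------------------------------------------------------

def categories_to_frame(survey: DietSurvey) -> pd.DataFrame:
    nutrient_ids = survey.nutrient_ids
    rows = []
    for c in survey.categories:
        row = {
            "id": c.id, "name": c.name, "group_id": c.group_id,
            "baseline_intake": c.baseline_intake, "intake_sd": c.intake_sd,
            "p5": c.p5, "p95": c.p95,
            "is_new_food": int(c.is_new_food), "is_fixed": int(c.is_fixed),
            "ghge": c.ghge, "price": c.price,
        }
        for nid in nutrient_ids:
            row[nid] = c.nutrients.get(nid, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def groups_to_frame(survey: DietSurvey) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": g.id, "name": g.name, "group_sd": g.group_sd,
          "group_weight": g.group_weight,
          "p95": "" if g.p95 is None else g.p95}
         for g in survey.groups]
    )


def write_survey(survey: DietSurvey, categories_path: str | Path,
                 groups_path: str | Path) -> None:
    """Write the survey as two comma-separated tables."""
    categories_to_frame(survey).to_csv(categories_path, index=False)
    groups_to_frame(survey).to_csv(groups_path, index=False)


def read_survey(categories_path: str | Path, groups_path: str | Path,
                stratum: str = "stratum",
                energy_target: float | None = None) -> DietSurvey:
    """Read a survey from the two-table comma-separated format.

    The category table has one row per category with the fixed columns
    ``id, name, group_id, baseline_intake, intake_sd, p5, p95, is_new_food,
    is_fixed, ghge, price`` followed by one column per nutrient.  The group
    table has ``id, name, group_sd, group_weight`` and optionally ``p95``.
    """
    cat_df = pd.read_csv(categories_path, dtype={"id": str, "group_id": str})
    grp_df = pd.read_csv(groups_path, dtype={"id": str})
    nutrient_cols = [c for c in cat_df.columns if c not in _CATEGORY_COLUMNS]
    categories = [
        FoodCategory(
            id=str(r["id"]), name=str(r["name"]), group_id=str(r["group_id"]),
            baseline_intake=float(r["baseline_intake"]),
            intake_sd=float(r["intake_sd"]),
            p5=float(r["p5"]), p95=float(r["p95"]),
            nutrients={nid: float(r[nid]) for nid in nutrient_cols},
            ghge=float(r["ghge"]), price=float(r["price"]),
            is_new_food=bool(int(r["is_new_food"])),
            is_fixed=bool(int(r["is_fixed"])),
        )
        for _, r in cat_df.iterrows()
    ]
    groups = []
    for _, r in grp_df.iterrows():
        gid = str(r["id"])
        members = tuple(c.id for c in categories if c.group_id == gid)
        p95 = r.get("p95", None)
        p95 = None if p95 is None or (isinstance(p95, float) and math.isnan(p95)) \
            or p95 == "" else float(p95)
        groups.append(FoodGroup(
            id=gid, name=str(r["name"]), member_ids=members,
            baseline_total=sum(c.baseline_intake for c in categories
                               if c.group_id == gid),
            group_sd=float(r["group_sd"]),
            group_weight=float(r["group_weight"]),
            p95=p95,
        ))
    return DietSurvey(stratum, categories, groups, energy_target)


def survey_to_json(survey: DietSurvey) -> str:
    obj = {
        "stratum": survey.stratum,
        "energy_target": survey.energy_target,
        "energy_nutrient": survey.energy_nutrient,
        "categories": [
            {
                "id": c.id, "name": c.name, "group_id": c.group_id,
                "baseline_intake": c.baseline_intake, "intake_sd": c.intake_sd,
                "p5": c.p5, "p95": c.p95, "nutrients": c.nutrients,
                "ghge": c.ghge, "price": c.price,
                "is_new_food": c.is_new_food, "is_fixed": c.is_fixed,
            }
            for c in survey.categories
        ],
        "groups": [
            {
                "id": g.id, "name": g.name, "member_ids": list(g.member_ids),
                "baseline_total": g.baseline_total, "group_sd": g.group_sd,
                "group_weight": g.group_weight, "p95": g.p95,
            }
            for g in survey.groups
        ],
    }
    return json.dumps(obj, indent=2)


def survey_from_json(text: str) -> DietSurvey:
    obj = json.loads(text)
    categories = [FoodCategory(**c) for c in obj["categories"]]
    groups = [
        FoodGroup(
            id=g["id"], name=g["name"], member_ids=tuple(g["member_ids"]),
            baseline_total=g["baseline_total"], group_sd=g["group_sd"],
            group_weight=g.get("group_weight", 2.0), p95=g.get("p95"),
        )
        for g in obj["groups"]
    ]
    return DietSurvey(obj.get("stratum", "stratum"), categories, groups,
                      obj.get("energy_target"),
                      obj.get("energy_nutrient", ENERGY_NUTRIENT))
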