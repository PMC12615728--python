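"""Linear constraint system over the diet vector.

All constraint rows are linear in the per-category daily quantities
``q`` (g/day).  Every row carries a family tag from the closed set

    nutrition, energy, feasible-range, group-cap, fixed, mass, ghge,
    group-total

and a human-readable name, so solutions can be audited and binding
constraints reported family by family.

Nutrient bounds are either absolute per day (same per-day unit as the
nutrient coefficient times g/day/100) or a percentage of dietary energy.
Percent-of-energy bounds are linearized against the *fixed* energy target,
which is valid because dietary energy itself is held at its observed level
by an equality row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .survey import DietSurvey

FAMILIES = ("nutrition", "energy", "feasible-range", "group-cap",
            "fixed", "mass", "ghge", "group-total")

#: kJ per gram used to convert percent-of-energy bounds for common
#: energy-yielding nutrients (Atwater-style factors).
ENERGY_KJ_PER_G = {
    "protein": 17.0,
    "fat": 37.0,
    "carbohydrate": 17.0,
    "fiber": 8.0,
    "alcohol": 29.0,
    "sfa": 37.0,
    "pufa": 37.0,
    "mufa": 37.0,
}

ABSOLUTE = "absolute"
PERCENT_ENERGY = "percent_energy"


@dataclass(frozen=True)
class NutrientBound:
    """Bounds for one nutrient: absolute per day or percent of energy."""

    nutrient_id: str
    lower: float | None = None
    upper: float | None = None
    basis: str = ABSOLUTE
    kj_per_g: float | None = None  # required for percent_energy if not listed

    def __post_init__(self) -> None:
        if self.basis not in (ABSOLUTE, PERCENT_ENERGY):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.lower is not None and self.upper is not None \
                and self.lower > self.upper:
            raise ValueError(
                f"{self.nutrient_id}: lower bound {self.lower} exceeds "
                f"upper bound {self.upper}"
            )
        if self.basis == PERCENT_ENERGY:
            for b in (self.lower, self.upper):
                if b is not None and not 0 <= b <= 100:
                    raise ValueError(
                        f"{self.nutrient_id}: percent-of-energy bound {b} "
                        "outside [0, 100]"
                    )

    def energy_factor(self) -> float:
        if self.kj_per_g is not None:
            return self.kj_per_g
        try:
            return ENERGY_KJ_PER_G[self.nutrient_id]
        except KeyError:
            raise ValueError(
                f"no kJ/g factor known for {self.nutrient_id!r}; supply "
                "kj_per_g for percent-of-energy bounds"
            ) from None


@dataclass
class NutrientConstraintSpec:
    """An ordered list of nutrient bounds."""

    bounds: list[NutrientBound] = field(default_factory=list)

    def __iter__(self):
        return iter(self.bounds)

    def __len__(self) -> int:
        return len(self.bounds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"nutrient_id": b.nutrient_id,
              "lower": "" if b.lower is None else b.lower,
              "upper": "" if b.upper is None else b.upper,
              "basis": b.basis,
              "kj_per_g": "" if b.kj_per_g is None else b.kj_per_g}
             for b in self.bounds]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "NutrientConstraintSpec":
        df = pd.read_csv(path)

        def _opt(v):
            return None if v is None or (isinstance(v, float) and math.isnan(v)) \
                or v == "" else float(v)

        return cls([
            NutrientBound(
                nutrient_id=str(r["nutrient_id"]),
                lower=_opt(r.get("lower")), upper=_opt(r.get("upper")),
                basis=str(r.get("basis", ABSOLUTE)),
                kj_per_g=_opt(r.get("kj_per_g")),
            )
            for _, r in df.iterrows()
        ])


@dataclass
class ConstraintRow:
    """One linear row: lower <= coeffs . q <= upper (None = unbounded)."""

    name: str
    family: str
    coeffs: np.ndarray
    lower: float | None
    upper: float | None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown constraint family {self.family!r}")
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError(f"row {self.name!r} has non-finite coefficients")

    @property
    def is_equality(self) -> bool:
        return (self.lower is not None and self.upper is not None
                and self.lower == self.upper)

    def value(self, q: np.ndarray) -> float:
        return float(self.coeffs @ q)

    def violation(self, q: np.ndarray) -> float:
        """Signed magnitude by which q breaks the row (0 when satisfied)."""
        v = self.value(q)
        out = 0.0
        if self.lower is not None and v < self.lower:
            out = self.lower - v
        if self.upper is not None and v > self.upper:
            out = max(out, v - self.upper)
        return out


@dataclass
class ConstraintSystem:
    """All rows for one scenario, in the survey's category order."""

    category_ids: list[str]
    rows: list[ConstraintRow] = field(default_factory=list)

    def add(self, name: str, family: str, coeffs: np.ndarray,
            lower: float | None, upper: float | None) -> None:
        self.rows.append(ConstraintRow(name, family, coeffs, lower, upper))

    def by_family(self, family: str) -> list[ConstraintRow]:
        return [r for r in self.rows if r.family == family]

    @property
    def n_vars(self) -> int:
        return len(self.category_ids)

    def matrices(self):
        """(A, lb, ub) with +/-inf for missing bounds."""
        A = np.array([r.coeffs for r in self.rows], dtype=float) \
            if self.rows else np.zeros((0, self.n_vars))
        lb = np.array([-np.inf if r.lower is None else r.lower
                       for r in self.rows])
        ub = np.array([np.inf if r.upper is None else r.upper
                       for r in self.rows])
        return A, lb, ub


def build_constraints(
    survey: DietSurvey,
    nutrients: NutrientConstraintSpec,
    *,
    ghge_cap: float | None = None,
    fix_group_totals: Mapping[str, float] | None = None,
    mass_tolerance: float = 0.2,
) -> ConstraintSystem:
    """Assemble the full constraint system for one scenario.

    Families emitted:

    * ``nutrition`` — one row per nutrient bound; percent-of-energy bounds
      are converted to absolute per-day bounds via the fixed energy target.
    * ``energy`` — dietary energy pinned at the survey's observed target.
    * ``feasible-range`` — per-category box [p5, p95] for ordinary
      categories; a zero 95th percentile is replaced by the mean observed
      intake; a new food gets only non-negativity (its cap is group-level).
    * ``group-cap`` — the host group of each new food is capped at the
      group's observed 95th percentile.
    * ``fixed`` — fixed categories (e.g. water) pinned at baseline.
    * ``mass`` — total diet mass within +/- ``mass_tolerance`` of baseline
      (fixed categories included on both sides of the band).
    * ``ghge`` — optional cap on total diet GHGE (kg CO2e/day).
    * ``group-total`` — optional equality pinning named group totals.

    The 0.01 g/day-to-per-100 g conversion is applied here and only here.
    """
    ids = survey.category_ids
    idx = {cid: k for k, cid in enumerate(ids)}
    n = len(ids)
    system = ConstraintSystem(category_ids=list(ids))
    known_nutrients = set(survey.nutrient_ids)

    # (a) nutrient rows
    for b in nutrients:
        if b.nutrient_id not in known_nutrients:
            raise KeyError(f"unknown nutrient id {b.nutrient_id!r} in "
                           "constraint spec")
        coeffs = 0.01 * np.array(
            [c.nutrients.get(b.nutrient_id, 0.0) for c in survey.categories])
        lower, upper = b.lower, b.upper
        if b.basis == PERCENT_ENERGY:
            # bound% of energy_target, converted from grams via kJ/g
            factor = b.energy_factor()
            coeffs = coeffs * factor
            lower = None if lower is None else lower / 100.0 * survey.energy_target
            upper = None if upper is None else upper / 100.0 * survey.energy_target
        system.add(f"nutrient:{b.nutrient_id}", "nutrition", coeffs,
                   lower, upper)

    # (b) energy equality
    e_coeffs = 0.01 * np.array(
        [c.nutrients.get(survey.energy_nutrient, 0.0)
         for c in survey.categories])
    system.add("energy", "energy", e_coeffs,
               survey.energy_target, survey.energy_target)

    # (c) per-category feasible ranges
    for c in survey.categories:
        e = np.zeros(n)
        e[idx[c.id]] = 1.0
        if c.is_fixed:
            continue  # handled by the fixed family
        if c.is_new_food:
            # only non-negativity; the binding limit is the group cap
            system.add(f"nonneg:{c.id}", "feasible-range", e, 0.0, None)
            continue
        upper = c.p95
        if upper == 0.0 and c.baseline_intake > 0:
            upper = c.baseline_intake  # mean observed intake replaces zero p95
        system.add(f"box:{c.id}", "feasible-range", e,
                   max(c.p5, 0.0), upper)

    # (d) new-food host-group cap
    for nf in survey.new_foods:
        g = survey.group(nf.group_id)
        if g.p95 is None:
            raise ValueError(
                f"host group {g.id!r} of new food {nf.id!r} has no p95; "
                "the group-level cap requires it"
            )
        coeffs = np.zeros(n)
        for cid in g.member_ids:
            coeffs[idx[cid]] = 1.0
        system.add(f"group-cap:{g.id}", "group-cap", coeffs, None, g.p95)

    # (e) fixed categories
    for c in survey.categories:
        if c.is_fixed:
            e = np.zeros(n)
            e[idx[c.id]] = 1.0
            system.add(f"fixed:{c.id}", "fixed", e,
                       c.baseline_intake, c.baseline_intake)

    # (f) total mass band
    m0 = sum(c.baseline_intake for c in survey.categories)
    system.add("total-mass", "mass", np.ones(n),
               (1.0 - mass_tolerance) * m0, (1.0 + mass_tolerance) * m0)

    # (g) optional GHGE cap
    if ghge_cap is not None:
        if ghge_cap <= 0:
            raise ValueError(f"GHGE cap must be positive, got {ghge_cap}")
        coeffs = 0.01 * np.array([c.ghge for c in survey.categories])
        system.add("ghge-cap", "ghge", coeffs, None, ghge_cap)

    # (h) optional group-total equalities
    for gid, total in (fix_group_totals or {}).items():
        g = survey.group(gid)
        coeffs = np.zeros(n)
        for cid in g.member_ids:
            coeffs[idx[cid]] = 1.0
        system.add(f"group-total:{gid}", "group-total", coeffs, total, total)

    return system
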