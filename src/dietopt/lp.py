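"""Relative piecewise-linear comparator engine.

The linear model measures dietary change as the absolute relative deviation
|q_i - q0_i| / q0_i, split into non-negative up (u_i) and down (d_i)
deviations with q_i = q0_i + u_i - d_i.  Because the relative deviation is
undefined for a zero-baseline category (the new food), the imputed intake SD
serves as the denominator there, keeping the term dimensionless and on the
same scale as the SD-standardized quadratic model.  Group-level terms
(weights z_j, denominators Q0_j) mirror the two-level structure of the
quadratic objective and are on by default; the directional category weights
w+/w- can likewise be applied so that the "no penalty weights" sensitivity
variant is meaningful for both engines.

The LP is solved to an optimal vertex with HiGHS.  Vertex solutions make
few, large changes (most categories stay exactly at baseline) — the
characteristic contrast with the quadratic model's many small adjustments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .constraints import ConstraintSystem
from .results import (ERROR, INFEASIBLE, OPTIMAL, DeviationSplit,
                      ScenarioResult, binding_rows, diet_totals)
from .survey import DietSurvey, DietVector
from .weights import PenaltyWeightSet


@dataclass
class LinearDeviationModel:
    """Assembled LP: objective vector, constraints, and bookkeeping."""

    survey: DietSurvey
    system: ConstraintSystem
    c: np.ndarray                 # objective over (u, d, U, D)
    A_ub: np.ndarray | None
    b_ub: np.ndarray | None
    A_eq: np.ndarray | None
    b_eq: np.ndarray | None
    bounds: list[tuple[float, float | None]]
    denominators: dict[str, float]
    include_group_terms: bool
    label: str = "LP"


def build_lp(survey: DietSurvey, system: ConstraintSystem,
             weights: PenaltyWeightSet | None = None,
             *, include_group_terms: bool = True,
             use_category_weights: bool = True,
             zero_baseline_denominator: dict[str, float] | None = None,
             label: str = "LP") -> LinearDeviationModel:
    """Assemble the piecewise-linear model over the same constraint system.

    ``zero_baseline_denominator`` overrides the denominator for named
    zero-baseline categories; the default is the category's (imputed)
    intake SD.
    """
    cats, grps = survey.categories, survey.groups
    n, m = len(cats), len(grps)
    nv = 2 * n + (2 * m if include_group_terms else 0)
    q0 = np.array([c.baseline_intake for c in cats])
    idx = {cid: k for k, cid in enumerate(survey.category_ids)}

    denoms: dict[str, float] = {}
    overrides = zero_baseline_denominator or {}
    for c in cats:
        if c.baseline_intake > 0:
            denoms[c.id] = c.baseline_intake
        else:
            d = overrides.get(c.id, c.intake_sd)
            if d <= 0:
                raise ValueError(
                    f"category {c.id!r} has zero baseline and no positive "
                    "fallback denominator (impute its SD first)")
            denoms[c.id] = d

    cvec = np.zeros(nv)
    for k, c in enumerate(cats):
        wp = weights.w_plus[c.id] if (weights and use_category_weights) else 1.0
        wm = weights.w_minus[c.id] if (weights and use_category_weights) else 1.0
        cvec[k] = wp / denoms[c.id]
        cvec[n + k] = wm / denoms[c.id]
    if include_group_terms:
        for j, g in enumerate(grps):
            if g.baseline_total <= 0:
                raise ValueError(f"group {g.id!r} has non-positive baseline "
                                 "total; disable group terms or fix the data")
            z = weights.z[g.id] if weights else 2.0
            cvec[2 * n + j] = z / g.baseline_total
            cvec[2 * n + m + j] = z / g.baseline_total

    A_ub_rows, b_ub, A_eq_rows, b_eq = [], [], [], []
    # mapped constraint rows: a.q = a.q0 + a.(u - d)
    for r in system.rows:
        row = np.zeros(nv)
        row[:n] = r.coeffs
        row[n:2 * n] = -r.coeffs
        shift = float(r.coeffs @ q0)
        if r.is_equality:
            A_eq_rows.append(row); b_eq.append(r.lower - shift)
        else:
            if r.upper is not None:
                A_ub_rows.append(row); b_ub.append(r.upper - shift)
            if r.lower is not None:
                A_ub_rows.append(-row); b_ub.append(-(r.lower - shift))
    # group links: U_j - D_j = sum members (u_i - d_i)
    if include_group_terms:
        for j, g in enumerate(grps):
            row = np.zeros(nv)
            row[2 * n + j] = 1.0
            row[2 * n + m + j] = -1.0
            for cid in g.member_ids:
                i = idx[cid]
                row[i] -= 1.0
                row[n + i] += 1.0
            A_eq_rows.append(row); b_eq.append(0.0)

    bounds: list[tuple[float, float | None]] = []
    bounds += [(0.0, None)] * n                      # u >= 0
    bounds += [(0.0, float(q0[k])) for k in range(n)]  # 0 <= d <= q0 (q >= 0)
    if include_group_terms:
        bounds += [(0.0, None)] * (2 * m)

    return LinearDeviationModel(
        survey=survey, system=system, c=cvec,
        A_ub=np.array(A_ub_rows) if A_ub_rows else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq_rows) if A_eq_rows else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=bounds, denominators=denoms,
        include_group_terms=include_group_terms, label=label,
    )


def lp_objective_value(model: LinearDeviationModel, diet: DietVector) -> float:
    """Objective of a diet under the linear model (one-sided splits)."""
    survey = model.survey
    n = survey.n_categories
    total = 0.0
    for k, c in enumerate(survey.categories):
        dq = diet.quantities[c.id] - c.baseline_intake
        coef = model.c[k] if dq >= 0 else model.c[n + k]
        total += coef * abs(dq)
    if model.include_group_terms:
        m = survey.n_groups
        gtot = diet.group_totals(survey)
        for j, g in enumerate(survey.groups):
            dQ = gtot[g.id] - g.baseline_total
            coef = model.c[2 * n + j] if dQ >= 0 else model.c[2 * n + m + j]
            total += coef * abs(dQ)
    return total


def solve_lp(model: LinearDeviationModel) -> ScenarioResult:
    """Solve to an optimal vertex; flag possible alternative optima."""
    survey = model.survey
    n, m = survey.n_categories, survey.n_groups
    res = linprog(model.c, A_ub=model.A_ub, b_ub=model.b_ub,
                  A_eq=model.A_eq, b_eq=model.b_eq,
                  bounds=model.bounds, method="highs")
    if res.status == 2:
        from .qp import infeasibility_certificate
        return ScenarioResult(
            label=model.label, status=INFEASIBLE, engine="lp",
            meta={"infeasible_families":
                  infeasibility_certificate(model.system)},
        )
    if res.status == 3:
        return ScenarioResult(label=model.label, status=ERROR, engine="lp",
                              meta={"diagnostic": "LP reported unbounded"})
    if res.status != 0:
        return ScenarioResult(label=model.label, status=ERROR, engine="lp",
                              meta={"diagnostic": res.message})
    x = res.x
    q0 = np.array([c.baseline_intake for c in survey.categories])
    q = q0 + x[:n] - x[n:2 * n]
    diet = DietVector.from_array(survey, q)

    # degeneracy: a variable at a bound with (near-)zero reduced cost hints
    # at alternative optimal vertices
    degenerate = False
    try:
        red = np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals)
        at_bound = np.zeros(len(x), dtype=bool)
        for k, (lo, hi) in enumerate(model.bounds):
            if x[k] - lo <= 1e-9 or (hi is not None and hi - x[k] <= 1e-9):
                at_bound[k] = True
        degenerate = bool(np.any(at_bound & (np.abs(red) <= 1e-9)
                                 & (np.abs(model.c) > 0)))
    except (AttributeError, TypeError):
        pass

    split = DeviationSplit(
        q_plus={cid: float(q0[k] + x[k])
                for k, cid in enumerate(survey.category_ids)},
        q_minus={cid: float(q0[k] - x[n + k])
                 for k, cid in enumerate(survey.category_ids)},
        Q_plus={}, Q_minus={},
    )
    return ScenarioResult(
        label=model.label, status=OPTIMAL, engine="lp",
        diet=diet, objective=float(res.fun),
        totals=diet_totals(diet, survey),
        binding=binding_rows(model.system, q),
        split=split,
        meta={"solver_objective": float(res.fun),
              "degenerate": degenerate, "model": model,
              "u": x[:n].copy(), "d": x[n:2 * n].copy()},
    )
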