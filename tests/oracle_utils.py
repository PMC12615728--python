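"""Independent oracles for the optimization engines.

These deliberately avoid the package's solve paths: the quadratic oracle
minimizes the *reduced* piecewise-quadratic objective directly in q-space
with SLSQP, and the linear oracle enumerates basic feasible solutions
(vertices) exhaustively.  Both are only viable at tiny problem sizes.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from dietopt import ConstraintSystem, DietSurvey, FoodCategory, FoodGroup
from dietopt.weights import PenaltyWeightSet


def random_instance(rng: np.random.Generator, n_max: int = 6):
    """A small random survey plus box and random linear constraints."""
    n = int(rng.integers(2, n_max + 1))
    m = 1 if n < 4 else int(rng.integers(1, 3))
    gids = [f"g{j}" for j in range(m)]
    cats = []
    for i in range(n):
        base = float(rng.uniform(5, 50))
        cats.append(FoodCategory(
            f"c{i}", f"c{i}", gids[i % m], base, float(rng.uniform(1, 10)),
            0.3 * base, 2.5 * base, {"e": float(rng.uniform(50, 500))},
            0.1, 0.1))
    groups = []
    for gid in gids:
        members = tuple(c.id for c in cats if c.group_id == gid)
        total = sum(c.baseline_intake for c in cats if c.group_id == gid)
        groups.append(FoodGroup(gid, gid, members, total,
                                max(0.4 * total, 1.0), 2.0, p95=1.3 * total))
    survey = DietSurvey("toy", cats, groups, energy_target=1.0,
                        energy_nutrient="e")
    system = ConstraintSystem(category_ids=[c.id for c in cats])
    for i, c in enumerate(cats):
        e = np.zeros(n)
        e[i] = 1.0
        system.add(f"box:{c.id}", "feasible-range", e, c.p5, c.p95)
    q0 = np.array([c.baseline_intake for c in cats])
    for r in range(int(rng.integers(1, 4))):
        a = rng.uniform(0.0, 1.0, n)
        v0 = float(a @ q0)
        if rng.random() < 0.5:
            system.add(f"r{r}", "nutrition", a,
                       v0 * float(rng.uniform(1.02, 1.15)), None)
        else:
            system.add(f"r{r}", "nutrition", a, None,
                       v0 * float(rng.uniform(0.85, 0.98)))
    return survey, system


def reduced_objective(survey: DietSurvey, weights: PenaltyWeightSet):
    """The piecewise-quadratic objective as a plain function of q."""
    cats = survey.categories
    q0 = np.array([c.baseline_intake for c in cats])
    sd = np.array([c.intake_sd for c in cats])
    wp = np.array([weights.w_plus[c.id] for c in cats])
    wm = np.array([weights.w_minus[c.id] for c in cats])
    members = [[k for k, c in enumerate(cats) if c.group_id == g.id]
               for g in survey.groups]

    def f(q: np.ndarray) -> float:
        d = (q - q0) / sd
        val = float(np.sum(np.where(d >= 0, wp, wm) * d ** 2))
        for g, idx in zip(survey.groups, members):
            dQ = (q[idx].sum() - g.baseline_total) / g.group_sd
            val += weights.z[g.id] * dQ ** 2
        return val

    return f


def qp_oracle(survey: DietSurvey, system: ConstraintSystem,
              weights: PenaltyWeightSet) -> float | None:
    """SLSQP on the reduced objective, multi-started; best objective found."""
    f = reduced_objective(survey, weights)
    n = len(survey.categories)
    q0 = np.array([c.baseline_intake for c in survey.categories])
    A, lb, ub = system.matrices()
    best = None
    for trial in range(3):
        x0 = q0 * (1.0 + 0.01 * trial)
        res = minimize(f, x0, method="SLSQP",
                       constraints=[LinearConstraint(A, lb, ub)],
                       bounds=[(0, None)] * n,
                       options={"maxiter": 500, "ftol": 1e-12})
        if res.success and (best is None or res.fun < best):
            best = float(res.fun)
    return best


def lp_vertex_oracle(c: np.ndarray, A_ub, b_ub, A_eq, b_eq,
                     bounds) -> float | None:
    """Exhaustive vertex enumeration for a tiny LP (few variables).

    Treats every choice of n active constraints (rows at a bound side or
    variables at a bound) as a candidate basis, solves, keeps feasible
    points, and returns the best objective — None if infeasible.
    """
    n = len(c)
    rows, rhs = [], []
    if A_eq is not None:
        for k in range(len(A_eq)):
            rows.append(np.asarray(A_eq[k], dtype=float))
            rhs.append(float(b_eq[k]))
    n_eq = len(rows)
    cand_rows, cand_rhs = [], []
    if A_ub is not None:
        for k in range(len(A_ub)):
            cand_rows.append(np.asarray(A_ub[k], dtype=float))
            cand_rhs.append(float(b_ub[k]))
    for k, (lo, hi) in enumerate(bounds):
        e = np.zeros(n)
        e[k] = 1.0
        if lo is not None and np.isfinite(lo):
            cand_rows.append(e.copy())
            cand_rhs.append(float(lo))
        if hi is not None and np.isfinite(hi):
            cand_rows.append(e.copy())
            cand_rhs.append(float(hi))

    def feasible(x: np.ndarray) -> bool:
        tol = 1e-7
        if A_ub is not None and np.any(np.asarray(A_ub) @ x
                                       > np.asarray(b_ub) + tol):
            return False
        if A_eq is not None and np.any(np.abs(np.asarray(A_eq) @ x
                                              - np.asarray(b_eq)) > tol):
            return False
        for k, (lo, hi) in enumerate(bounds):
            if lo is not None and x[k] < lo - tol:
                return False
            if hi is not None and np.isfinite(hi) and x[k] > hi + tol:
                return False
        return True

    best = None
    need = n - n_eq
    if need < 0:
        return None
    for combo in itertools.combinations(range(len(cand_rows)), need):
        M = np.array(rows + [cand_rows[k] for k in combo])
        v = np.array(rhs + [cand_rhs[k] for k in combo])
        if M.shape[0] != n or abs(np.linalg.det(M)) < 1e-12:
            continue
        x = np.linalg.solve(M, v)
        if feasible(x):
            val = float(c @ x)
            if best is None or val < best:
                best = val
    return best
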