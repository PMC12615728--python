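"""Quadratic diet-optimization engine.

The objective penalizes SD-standardized deviations from the observed diet at
two levels, with directional popularity weights at the category level and a
group weight z at the group level:

    min  sum_i [ w+_i ((q+_i - q0_i)/sigma_i)^2
               + w-_i ((q-_i - q0_i)/sigma_i)^2 ]
       + sum_j z_j [ ((Q+_j - Q0_j)/sigma_j)^2 + ((Q-_j - Q0_j)/sigma_j)^2 ]

in the split variables q+_i >= q0_i (increases), q-_i <= q0_i (decreases),
linked to the physical quantities by q_i = q+_i + q-_i - q0_i, and
analogously Q+_j, Q-_j for group totals Q_j = sum_{i in S_j} q_i.  Because
the weights are strictly positive the program is strictly convex in the
split variables and the optimal deviation of every category and group is
one-sided (complementarity), a property the audit asserts rather than
assumes.

The solve proceeds in three stages: (1) an LP feasibility check (with an
elastic relaxation that names the violated constraint families when the
system is infeasible); (2) a trust-region interior solve of the convex QP;
(3) an exact KKT polish on the detected active set, accepted only when it
is feasible and at least as good as the interior solution.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .constraints import ConstraintSystem
from .results import (ERROR, INFEASIBLE, OPTIMAL, AuditReport, DeviationSplit,
                      ScenarioResult, binding_rows, diet_totals)
from .survey import DietSurvey, DietVector
from .weights import PenaltyWeightSet

#: absolute feasibility tolerance (g/day scale), scaled by row norm in checks
FEASIBILITY_TOL = 1e-6
#: relative tolerance for objective agreement in audits
OBJECTIVE_RTOL = 1e-6


def objective_value(diet: DietVector, survey: DietSurvey,
                    weights: PenaltyWeightSet) -> float:
    """Reduced objective of a diet: directional weights picked by sign.

    For each category the increase weight applies when q > q0 and the
    decrease weight when q < q0 (at q = q0 the term vanishes); group terms
    use the single group weight z.  Zero iff the diet equals the baseline.
    """
    total = 0.0
    for c in survey.categories:
        if c.intake_sd <= 0:
            raise ValueError(f"category {c.id!r} has non-positive SD")
        dq = diet.quantities[c.id] - c.baseline_intake
        w = weights.w_plus[c.id] if dq >= 0 else weights.w_minus[c.id]
        total += w * (dq / c.intake_sd) ** 2
    gtot = diet.group_totals(survey)
    for g in survey.groups:
        if g.group_sd <= 0:
            raise ValueError(f"group {g.id!r} has non-positive SD")
        dQ = gtot[g.id] - g.baseline_total
        total += weights.z[g.id] * (dQ / g.group_sd) ** 2
    return total


# ---------------------------------------------------------------------------
# Feasibility (LP phase) in q-space
# ---------------------------------------------------------------------------

def _lp_feasible_point(system: ConstraintSystem) -> np.ndarray | None:
    """A feasible q >= 0 for the row system, or None if infeasible."""
    A, lb, ub = system.matrices()
    n = system.n_vars
    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for k, r in enumerate(system.rows):
        if r.is_equality:
            A_eq.append(A[k]); b_eq.append(r.lower)
        else:
            if r.upper is not None:
                A_ub.append(A[k]); b_ub.append(r.upper)
            if r.lower is not None:
                A_ub.append(-A[k]); b_ub.append(-r.lower)
    res = linprog(
        c=np.zeros(n),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=[(0, None)] * n, method="highs",
    )
    return res.x if res.status == 0 else None


def infeasibility_certificate(system: ConstraintSystem) -> list[tuple[str, str]]:
    """Rows that cannot be satisfied jointly, via an elastic relaxation.

    Every row side gets a non-negative slack; the LP minimizes total slack.
    Rows needing positive slack at that minimum are returned as
    (name, family) pairs — an empty list means the system is feasible.
    """
    n = system.n_vars
    sides = []  # (row, sign, bound): sign*+1 => a.q <= bound + s
    for r in system.rows:
        if r.upper is not None:
            sides.append((r, 1.0, r.upper))
        if r.lower is not None:
            sides.append((r, -1.0, -r.lower))
    ns = len(sides)
    A_ub = np.zeros((ns, n + ns))
    b_ub = np.zeros(ns)
    for k, (r, sign, bound) in enumerate(sides):
        A_ub[k, :n] = sign * r.coeffs
        A_ub[k, n + k] = -1.0
        b_ub[k] = bound
    c = np.concatenate([np.zeros(n), np.ones(ns)])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub,
                  bounds=[(0, None)] * (n + ns), method="highs")
    if res.status != 0:
        return [("elastic-lp-failed", "mass")]
    slacks = res.x[n:]
    out = []
    for k, (r, _, _) in enumerate(sides):
        if slacks[k] > 1e-7 and (r.name, r.family) not in out:
            out.append((r.name, r.family))
    return out


# ---------------------------------------------------------------------------
# Split-variable QP assembly and solve
# ---------------------------------------------------------------------------

class _SplitProblem:
    """Index bookkeeping for x = (q+, q-, Q+, Q-)."""

    def __init__(self, survey: DietSurvey, weights: PenaltyWeightSet,
                 system: ConstraintSystem):
        self.survey = survey
        self.system = system
        cats, grps = survey.categories, survey.groups
        n, m = len(cats), len(grps)
        self.n, self.m = n, m
        self.N = 2 * n + 2 * m
        self.q0 = np.array([c.baseline_intake for c in cats])
        self.sd = np.array([c.intake_sd for c in cats])
        self.Q0 = np.array([g.baseline_total for g in grps])
        self.sdg = np.array([g.group_sd for g in grps])
        if np.any(self.sd <= 0) or np.any(self.sdg <= 0):
            raise ValueError("all category and group SDs must be positive")
        wp = np.array([weights.w_plus[c.id] for c in cats])
        wm = np.array([weights.w_minus[c.id] for c in cats])
        z = np.array([weights.z[g.id] for g in grps])
        if np.any(wp <= 0) or np.any(wm <= 0) or np.any(z <= 0):
            raise ValueError("all penalty weights must be positive")
        self.center = np.concatenate([self.q0, self.q0, self.Q0, self.Q0])
        self.diag = np.concatenate([wp / self.sd**2, wm / self.sd**2,
                                    z / self.sdg**2, z / self.sdg**2])
        self.lb = np.concatenate([self.q0, np.zeros(n),
                                  self.Q0, np.zeros(m)])
        self.ub = np.concatenate([np.full(n, np.inf), self.q0,
                                  np.full(m, np.inf), self.Q0])
        # linear rows over x: group links (equalities) + mapped system rows
        idx = {cid: k for k, cid in enumerate(survey.category_ids)}
        rows, rlo, rhi = [], [], []
        for j, g in enumerate(grps):
            row = np.zeros(self.N)
            row[2 * n + j] = 1.0
            row[2 * n + m + j] = 1.0
            s0 = 0.0
            for cid in g.member_ids:
                i = idx[cid]
                row[i] -= 1.0
                row[n + i] -= 1.0
                s0 += self.q0[i]
            rows.append(row)
            rhs = g.baseline_total - s0
            rlo.append(rhs); rhi.append(rhs)
        for r in system.rows:
            row = np.zeros(self.N)
            row[:n] = r.coeffs
            row[n:2 * n] = r.coeffs
            shift = float(r.coeffs @ self.q0)
            rows.append(row)
            rlo.append(-np.inf if r.lower is None else r.lower + shift)
            rhi.append(np.inf if r.upper is None else r.upper + shift)
        self.A = np.array(rows)
        self.rlo = np.array(rlo)
        self.rhi = np.array(rhi)

    # objective and derivatives -----------------------------------------
    def fun(self, x: np.ndarray) -> float:
        d = x - self.center
        return float(self.diag @ d**2)

    def jac(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * self.diag * (x - self.center)

    def hess(self, x: np.ndarray) -> np.ndarray:
        return np.diag(2.0 * self.diag)

    def x_from_q(self, q: np.ndarray) -> np.ndarray:
        """Feasible splits representing diet q (one-sided by construction)."""
        qp = np.maximum(q, self.q0)
        qm = np.minimum(q, self.q0)
        idx = {cid: k for k, cid in enumerate(self.survey.category_ids)}
        Q = np.array([sum(q[idx[cid]] for cid in g.member_ids)
                      for g in self.survey.groups])
        Qp = np.maximum(Q, self.Q0)
        Qm = np.minimum(Q, self.Q0)
        return np.concatenate([qp, qm, Qp, Qm])

    def q_from_x(self, x: np.ndarray) -> np.ndarray:
        n = self.n
        return x[:n] + x[n:2 * n] - self.q0

    # exact equality-constrained polish ---------------------------------
    def polish(self, x: np.ndarray, tol: float = 1e-6) -> np.ndarray | None:
        """Re-solve exactly on the active set detected at x."""
        rows, rhs = [], []
        Av = self.A @ x
        scale = np.maximum(1.0, np.abs(self.A).sum(axis=1))
        for k in range(len(self.A)):
            if self.rlo[k] == self.rhi[k]:
                rows.append(self.A[k]); rhs.append(self.rlo[k])
            elif np.isfinite(self.rlo[k]) and Av[k] - self.rlo[k] <= tol * scale[k]:
                rows.append(self.A[k]); rhs.append(self.rlo[k])
            elif np.isfinite(self.rhi[k]) and self.rhi[k] - Av[k] <= tol * scale[k]:
                rows.append(self.A[k]); rhs.append(self.rhi[k])
        for k in range(self.N):
            if np.isfinite(self.lb[k]) and x[k] - self.lb[k] <= tol:
                e = np.zeros(self.N); e[k] = 1.0
                rows.append(e); rhs.append(self.lb[k])
            elif np.isfinite(self.ub[k]) and self.ub[k] - x[k] <= tol:
                e = np.zeros(self.N); e[k] = 1.0
                rows.append(e); rhs.append(self.ub[k])
        if not rows:
            return self.center.copy()
        C = np.array(rows)
        c = np.array(rhs)
        nc = len(c)
        # KKT system for min (x-v)' D (x-v) s.t. C x = c
        D2 = 2.0 * self.diag
        K = np.zeros((self.N + nc, self.N + nc))
        K[:self.N, :self.N] = np.diag(D2)
        K[:self.N, self.N:] = C.T
        K[self.N:, :self.N] = C
        b = np.concatenate([D2 * self.center, c])
        try:
            sol, *_ = np.linalg.lstsq(K, b, rcond=None)
        except np.linalg.LinAlgError:
            return None
        return sol[:self.N]

    def max_violation(self, x: np.ndarray) -> float:
        v = 0.0
        if len(self.A):
            Av = self.A @ x
            scale = np.maximum(1.0, np.linalg.norm(self.A, axis=1))
            lo = np.where(np.isfinite(self.rlo), (self.rlo - Av) / scale, 0.0)
            hi = np.where(np.isfinite(self.rhi), (Av - self.rhi) / scale, 0.0)
            v = max(v, float(lo.max(initial=0.0)), float(hi.max(initial=0.0)))
        v = max(v, float(np.max(np.where(np.isfinite(self.lb),
                                         self.lb - x, 0.0), initial=0.0)))
        v = max(v, float(np.max(np.where(np.isfinite(self.ub),
                                         x - self.ub, 0.0), initial=0.0)))
        return v


def solve_qp(survey: DietSurvey, weights: PenaltyWeightSet,
             system: ConstraintSystem, label: str = "QP") -> ScenarioResult:
    """Solve the split-variable convex QP; deterministic given its inputs."""
    q_feas = _lp_feasible_point(system)
    if q_feas is None:
        return ScenarioResult(
            label=label, status=INFEASIBLE, engine="qp",
            meta={"infeasible_families": infeasibility_certificate(system)},
        )
    prob = _SplitProblem(survey, weights, system)
    # the baseline diet is the unconstrained minimizer (objective 0): if it
    # is feasible there is nothing to optimize
    x_base = prob.x_from_q(prob.q0)
    if prob.max_violation(x_base) <= 1e-9:
        return _finish(survey, weights, system, prob, x_base, label,
                       polished=False, iterations=0)
    x0 = prob.x_from_q(q_feas)
    constraints = [LinearConstraint(prob.A, prob.rlo, prob.rhi)]
    with warnings.catch_warnings():
        # redundant equality rows (e.g. a fixed category inside the mass
        # band) make the constraint Jacobian rank-deficient; trust-constr
        # handles this via SVD but warns noisily
        warnings.filterwarnings("ignore", message="Singular Jacobian")
        res = minimize(
            prob.fun, x0, jac=prob.jac, hess=prob.hess,
            method="trust-constr",
            bounds=Bounds(prob.lb, prob.ub),
            constraints=constraints,
            options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 800,
                     "verbose": 0},
        )
    if res.status not in (1, 2) and prob.max_violation(res.x) > 1e-5:
        return ScenarioResult(
            label=label, status=ERROR, engine="qp",
            meta={"diagnostic": f"trust-constr status {res.status}: "
                                f"{res.message}"},
        )
    # re-express the solved diet with one-sided splits: for a given q this
    # is the split-optimal representation, so it never worsens the
    # objective and restores exact complementarity
    x = prob.x_from_q(prob.q_from_x(res.x))
    polished = prob.polish(x)
    used_polish = False
    if polished is not None and prob.max_violation(polished) <= 1e-8:
        polished = prob.x_from_q(prob.q_from_x(polished))
        if prob.fun(polished) <= prob.fun(x) + 1e-9 * (1 + abs(prob.fun(x))):
            x = polished
            used_polish = True
    return _finish(survey, weights, system, prob, x, label,
                   polished=used_polish, iterations=int(res.nit))


def _finish(survey: DietSurvey, weights: PenaltyWeightSet,
            system: ConstraintSystem, prob: _SplitProblem, x: np.ndarray,
            label: str, *, polished: bool, iterations: int) -> ScenarioResult:
    q = prob.q_from_x(x)
    diet = DietVector.from_array(survey, q)
    obj = objective_value(diet, survey, weights)
    n, m = prob.n, prob.m
    split = DeviationSplit(
        q_plus=dict(zip(survey.category_ids, x[:n])),
        q_minus=dict(zip(survey.category_ids, x[n:2 * n])),
        Q_plus=dict(zip(survey.group_ids, x[2 * n:2 * n + m])),
        Q_minus=dict(zip(survey.group_ids, x[2 * n + m:])),
    )
    return ScenarioResult(
        label=label, status=OPTIMAL, engine="qp",
        diet=diet, objective=obj,
        totals=diet_totals(diet, survey),
        binding=binding_rows(system, q),
        split=split,
        meta={"solver_objective": prob.fun(x), "polished": polished,
              "iterations": iterations},
    )


def audit_solution(result: ScenarioResult, survey: DietSurvey,
                   weights: PenaltyWeightSet, system: ConstraintSystem,
                   tol: float = FEASIBILITY_TOL) -> AuditReport:
    """Independently re-check a reported optimum.

    Verifies (1) every constraint row within ``tol`` scaled by row norm,
    (2) one-sided deviations (split complementarity) within
    ``tol * max(1, sigma)``, and (3) agreement of the solver's objective
    with a from-scratch recomputation from the diet vector.
    """
    if not result.is_optimal:
        raise ValueError(f"cannot audit a non-optimal result "
                         f"(status {result.status})")
    report = AuditReport()
    q = result.diet.as_array(survey)
    for r in system.rows:
        scale = tol * max(1.0, float(np.linalg.norm(r.coeffs)))
        v = r.value(q)
        if r.lower is not None and v < r.lower - scale:
            report.violations.append(
                f"{r.name} [{r.family}]: value {v:.6g} below lower "
                f"bound {r.lower:.6g}")
        if r.upper is not None and v > r.upper + scale:
            report.violations.append(
                f"{r.name} [{r.family}]: value {v:.6g} above upper "
                f"bound {r.upper:.6g}")
    if result.split is not None:
        for c in survey.categories:
            up = result.split.q_plus[c.id] - c.baseline_intake
            down = c.baseline_intake - result.split.q_minus[c.id]
            if min(up, down) > tol * max(1.0, c.intake_sd):
                report.violations.append(
                    f"complementarity: category {c.id!r} deviates both up "
                    f"({up:.3g}) and down ({down:.3g})")
    if result.engine == "lp" and "model" in result.meta:
        from .lp import lp_objective_value
        recomputed = lp_objective_value(result.meta["model"], result.diet)
    else:
        recomputed = objective_value(result.diet, survey, weights)
    report.objective_recomputed = recomputed
    solver_obj = result.meta.get("solver_objective", result.objective)
    if solver_obj is not None:
        gap = abs(recomputed - solver_obj) / max(1.0, abs(recomputed))
        report.objective_gap = gap
        if gap > max(OBJECTIVE_RTOL, tol):
            report.violations.append(
                f"objective mismatch: recomputed {recomputed:.8g} vs "
                f"solver {solver_obj:.8g}")
    report.binding = binding_rows(system, q, tol)
    return report
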