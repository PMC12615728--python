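"""Quadratic engine: objective, solver correctness, audits."""

import numpy as np
import pytest

from dietopt import (ConstraintSystem, DietVector, audit_solution,
                     build_constraints, category_weights, make_feasible_spec,
                     objective_value, solve_qp)
from dietopt.results import INFEASIBLE, OPTIMAL

import oracle_utils


class TestObjectiveValue:
    def test_zero_iff_baseline(self, tiny_survey):
        w = category_weights(tiny_survey)
        base = tiny_survey.baseline_diet()
        assert objective_value(base, tiny_survey, w) == 0.0
        moved = DietVector(dict(base.quantities))
        moved.quantities["beef"] += 1.0
        assert objective_value(moved, tiny_survey, w) > 0.0

    def test_one_standardized_unit_up(self, tiny_survey):
        """One category alone in its group, moved up by one SD at each level."""
        # juice shares its group with fixed water; move juice by its own SD
        # and choose group SD equal so the group term is one unit too
        tiny_survey.group("drinks").group_sd = 30.0
        w = category_weights(tiny_survey)
        w.w_plus["juice"] = 1.5
        diet = tiny_survey.baseline_diet()
        diet.quantities["juice"] += 30.0  # = juice SD = group SD
        assert objective_value(diet, tiny_survey, w) == pytest.approx(3.5)
        # down one unit with w_minus = 1: 1 + z = 3
        w.w_minus["juice"] = 1.0
        diet.quantities["juice"] -= 60.0
        assert objective_value(diet, tiny_survey, w) == pytest.approx(3.0)

    def test_rejects_nonpositive_sd(self, tiny_survey):
        w = category_weights(tiny_survey)
        tiny_survey.category("beef").intake_sd = 0.0
        with pytest.raises(ValueError):
            objective_value(tiny_survey.baseline_diet(), tiny_survey, w)


class TestSolveQp:
    def test_feasible_baseline_is_the_minimizer(self, tiny_survey):
        """With no binding rows the observed diet itself is optimal."""
        w = category_weights(tiny_survey)
        system = ConstraintSystem(category_ids=tiny_survey.category_ids)
        n = tiny_survey.n_categories
        for k, c in enumerate(tiny_survey.categories):
            e = np.zeros(n)
            e[k] = 1.0
            lo = c.baseline_intake if c.is_fixed else max(c.p5, 0.0)
            hi = c.baseline_intake if c.is_fixed else max(c.p95, 1.0)
            system.add(f"box:{c.id}", "feasible-range", e, lo, hi)
        res = solve_qp(tiny_survey, w, system)
        assert res.status == OPTIMAL
        assert res.objective == pytest.approx(0.0, abs=1e-9)
        for c in tiny_survey.categories:
            assert res.diet.quantities[c.id] == pytest.approx(
                c.baseline_intake, abs=1e-6)

    def test_single_equality_splits_evenly_matching_closed_form(self,
                                                                tiny_survey):
        """Equal weights and SDs: a forced group change spreads evenly.

        Minimizing w[(d1/s)^2 + (d2/s)^2] + z[(d1+d2)/sg]^2 subject to
        d1 + d2 = delta gives d1 = d2 = delta/2 by symmetry, with objective
        2w(delta/2s)^2 + z(delta/sg)^2 (Lagrange closed form).
        """
        w = category_weights(tiny_survey)
        for cid in ("beef", "chicken"):
            w.w_plus[cid] = w.w_minus[cid] = 1.5
            tiny_survey.category(cid).intake_sd = 10.0
        delta = 6.0
        system = ConstraintSystem(category_ids=tiny_survey.category_ids)
        coeffs = np.zeros(tiny_survey.n_categories)
        idx = {cid: k for k, cid in enumerate(tiny_survey.category_ids)}
        coeffs[idx["beef"]] = coeffs[idx["chicken"]] = 1.0
        target = 80.0 + delta
        system.add("forced", "group-total", coeffs, target, target)
        # pin everything else at baseline
        for cid in ("myco", "water", "juice"):
            e = np.zeros(tiny_survey.n_categories)
            e[idx[cid]] = 1.0
            q0 = tiny_survey.category(cid).baseline_intake
            system.add(f"pin:{cid}", "fixed", e, q0, q0)
        res = solve_qp(tiny_survey, w, system)
        assert res.status == OPTIMAL
        assert res.diet.quantities["beef"] == pytest.approx(53.0, abs=1e-5)
        assert res.diet.quantities["chicken"] == pytest.approx(33.0, abs=1e-5)
        sg = tiny_survey.group("meat").group_sd
        z = w.z["meat"]
        expected = 2 * 1.5 * (delta / 2 / 10.0) ** 2 + z * (delta / sg) ** 2
        assert res.objective == pytest.approx(expected, rel=1e-6)

    def test_inverted_box_is_infeasible_with_certificate(self, tiny_survey):
        system = ConstraintSystem(category_ids=tiny_survey.category_ids)
        e = np.zeros(tiny_survey.n_categories)
        e[0] = 1.0
        system.add("box:beef", "feasible-range", e, 200.0, 100.0)
        res = solve_qp(tiny_survey, category_weights(tiny_survey), system)
        assert res.status == INFEASIBLE
        fams = [f for _, f in res.meta["infeasible_families"]]
        assert "feasible-range" in fams

    def test_deterministic_given_inputs(self, tiny_survey):
        w = category_weights(tiny_survey)
        system = ConstraintSystem(category_ids=tiny_survey.category_ids)
        coeffs = np.ones(tiny_survey.n_categories)
        m0 = sum(c.baseline_intake for c in tiny_survey.categories)
        system.add("mass", "mass", coeffs, 0.9 * m0, 0.9 * m0)
        r1 = solve_qp(tiny_survey, w, system)
        r2 = solve_qp(tiny_survey, w, system)
        assert r1.objective == r2.objective
        assert r1.diet.quantities == r2.diet.quantities


def test_small_instance_oracle_agreement():
    """Split-variable solver matches an independent reduced-space minimizer."""
    rng = np.random.default_rng(2024)
    checked = 0
    for _ in range(25):
        survey, system = oracle_utils.random_instance(rng)
        w = category_weights(survey)
        res = solve_qp(survey, w, system)
        if res.status != OPTIMAL:
            continue
        expected = oracle_utils.qp_oracle(survey, system, w)
        assert expected is not None
        assert res.objective == pytest.approx(expected, rel=1e-4, abs=1e-8)
        checked += 1
    assert checked >= 20


def test_tightening_constraints_never_improves_objective(tiny_survey):
    """Shrinking the feasible set cannot decrease the optimum."""
    w = category_weights(tiny_survey)
    idx = {cid: k for k, cid in enumerate(tiny_survey.category_ids)}
    objs = []
    for upper in (45.0, 40.0, 35.0):
        system = ConstraintSystem(category_ids=tiny_survey.category_ids)
        e = np.zeros(tiny_survey.n_categories)
        e[idx["beef"]] = 1.0
        system.add("cap:beef", "feasible-range", e, None, upper)
        res = solve_qp(tiny_survey, w, system)
        assert res.status == OPTIMAL
        objs.append(res.objective)
    assert objs == sorted(objs)


class TestAudit:
    def test_optimal_solution_passes(self, survey7, feasible_spec7):
        w = category_weights(survey7)
        system = build_constraints(survey7, feasible_spec7)
        res = solve_qp(survey7, w, system)
        assert res.status == OPTIMAL
        report = audit_solution(res, survey7, w, system)
        assert report.ok
        assert report.objective_gap <= 1e-6

    def test_corrupted_solution_yields_exactly_one_violation(self,
                                                             tiny_survey):
        w = category_weights(tiny_survey)
        system = ConstraintSystem(category_ids=tiny_survey.category_ids)
        idx = {cid: k for k, cid in enumerate(tiny_survey.category_ids)}
        e = np.zeros(tiny_survey.n_categories)
        e[idx["beef"]] = 1.0
        system.add("box:beef", "feasible-range", e, 20.0, 100.0)
        res = solve_qp(tiny_survey, w, system)
        assert res.status == OPTIMAL
        # push beef outside its box, keep split representation consistent
        res.diet.quantities["beef"] = 150.0
        res.split.q_plus["beef"] = 150.0
        res.split.q_minus["beef"] = 50.0
        res.meta["solver_objective"] = objective_value(
            res.diet, tiny_survey, w)
        report = audit_solution(res, tiny_survey, w, system)
        assert len(report.violations) == 1
        assert "box:beef" in report.violations[0]

    def test_objective_mismatch_is_flagged(self, tiny_survey):
        w = category_weights(tiny_survey)
        system = ConstraintSystem(category_ids=tiny_survey.category_ids)
        res = solve_qp(tiny_survey, w, system)
        res.meta["solver_objective"] = (res.objective or 0.0) + 1.0
        report = audit_solution(res, tiny_survey, w, system)
        assert any("objective mismatch" in v for v in report.violations)

    def test_two_sided_split_is_flagged(self, tiny_survey):
        w = category_weights(tiny_survey)
        system = ConstraintSystem(category_ids=tiny_survey.category_ids)
        res = solve_qp(tiny_survey, w, system)
        res.split.q_plus["beef"] = 60.0   # up 10
        res.split.q_minus["beef"] = 40.0  # and down 10: q unchanged
        report = audit_solution(res, tiny_survey, w, system)
        assert any("complementarity" in v for v in report.violations)
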