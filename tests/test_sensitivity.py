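"""Sensitivity variants: isolation, comparisons, seeded fixture regressions."""

import numpy as np
import pytest

from dietopt import (build_constraints, category_weights, compare_runs,
                     model_matrices, run_variant)
from dietopt.sensitivity import RunConfig, run_scenarios


def _nf_quantity(run, label):
    res = {r.label: r for r in run.results if r.is_optimal}.get(label)
    return None if res is None else res.diet.quantities["new_food"]


class TestVariantMechanics:
    def test_identity_scale_is_bit_identical_to_base(self, survey7,
                                                     binding_spec7,
                                                     base_run, base_config):
        run = run_variant(base_config, "ghge_scale", {"scale": 1.0})
        for a, b in zip(base_run.results, run.results):
            assert a.status == b.status
            if a.is_optimal:
                assert a.objective == b.objective
                assert a.diet.quantities == b.diet.quantities

    def test_ghge_scale_changes_exactly_one_matrix_coefficient(
            self, survey7, binding_spec7):
        w = category_weights(survey7)
        base_sys = build_constraints(survey7, binding_spec7, ghge_cap=20.0)
        scaled = survey7.copy()
        scaled.new_food.ghge *= 0.5
        var_sys = build_constraints(scaled, binding_spec7, ghge_cap=20.0)
        a = model_matrices(survey7, w, base_sys)
        b = model_matrices(scaled, category_weights(scaled), var_sys)
        for key in ("hessian_diag", "center", "row_lower", "row_upper",
                    "var_lower", "var_upper"):
            np.testing.assert_allclose(a[key], b[key])
        diff = a["A"] != b["A"]
        # one category, present twice in the GHGE row (q+ and q- slots)
        assert diff.sum() == 2
        rows_changed = np.unique(np.nonzero(diff)[0])
        assert len(rows_changed) == 1

    def test_no_weights_variant_changes_only_the_hessian(self, survey7,
                                                         binding_spec7):
        w = category_weights(survey7)
        system = build_constraints(survey7, binding_spec7)
        a = model_matrices(survey7, w, system)
        b = model_matrices(survey7, w.without_category_weights(), system)
        np.testing.assert_allclose(a["A"], b["A"])
        np.testing.assert_allclose(a["center"], b["center"])
        n = survey7.n_categories
        # category entries change, group entries (z) do not
        assert not np.allclose(a["hessian_diag"][:2 * n],
                               b["hessian_diag"][:2 * n])
        np.testing.assert_allclose(a["hessian_diag"][2 * n:],
                                   b["hessian_diag"][2 * n:])

    def test_profile_override_requires_complete_profile(self, base_config):
        with pytest.raises(ValueError, match="missing"):
            run_variant(base_config, "profile_override",
                        {"profile": {"protein": 15.0}})

    def test_unknown_variant_rejected(self, base_config):
        with pytest.raises(ValueError):
            run_variant(base_config, "swap_survey")

    def test_variants_do_not_mutate_the_base_survey(self, base_config):
        ghge_before = base_config.survey.new_food.ghge
        run_variant(base_config, "ghge_scale", {"scale": 0.5})
        assert base_config.survey.new_food.ghge == ghge_before


class TestCompareRuns:
    def test_identical_runs_give_all_zero_differences(self, survey7,
                                                      base_run):
        cmp = compare_runs(base_run, base_run, survey7)
        assert np.allclose(cmp.differences["diff"], 0.0)
        assert np.allclose(cmp.new_food_share["share_a"],
                           cmp.new_food_share["share_b"])

    def test_share_table_has_one_row_per_common_scenario(self, survey7,
                                                         base_run, lp_run):
        cmp = compare_runs(base_run, lp_run, survey7)
        common = {r.label for r in base_run.results if r.is_optimal} & \
                 {r.label for r in lp_run.results if r.is_optimal}
        assert set(cmp.new_food_share["scenario"]) == common


class TestFixtureRegressions:
    """Direction-only regressions on the seeded fixture."""

    def test_removing_weights_does_not_decrease_new_food_in_nutr(
            self, base_run, noweights_run):
        base_nf = _nf_quantity(base_run, "NUTR")
        now_nf = _nf_quantity(noweights_run, "NUTR")
        assert now_nf >= base_nf - 1e-6

    def test_removing_weights_increases_new_food_under_ghge_caps(
            self, base_run, noweights_run):
        pairs = [(_nf_quantity(base_run, r.label),
                  _nf_quantity(noweights_run, r.label))
                 for r in base_run.ladder if r.is_optimal]
        pairs = [(a, b) for a, b in pairs if a is not None and b is not None]
        assert pairs and all(b >= a - 1e-6 for a, b in pairs)

    def test_lp_concentrates_changes_in_fewer_categories(self, survey7,
                                                         base_run, lp_run):
        """>5%-of-baseline changes: vertex LP touches fewer categories."""

        def changed_count(res):
            cnt = 0
            for c in survey7.categories:
                q = res.diet.quantities[c.id]
                if c.baseline_intake > 0:
                    if abs(q - c.baseline_intake) > 0.05 * c.baseline_intake:
                        cnt += 1
                elif q > 1e-6:
                    cnt += 1
            return cnt

        qp_res = {r.label: r for r in base_run.results if r.is_optimal}
        lp_res = {r.label: r for r in lp_run.results if r.is_optimal}
        common = sorted(set(qp_res) & set(lp_res))
        assert common
        qp_total = sum(changed_count(qp_res[lab]) for lab in common)
        lp_total = sum(changed_count(lp_res[lab]) for lab in common)
        assert lp_total <= qp_total

    def test_new_food_more_responsive_to_ghge_decrease_than_increase(
            self, base_run, ghge_lo_run, ghge_hi_run):
        """Total |response| of new-food intake across shared scenarios."""

        def response(variant_run):
            total = 0.0
            seen = False
            for r in base_run.results:
                if not r.is_optimal:
                    continue
                a = _nf_quantity(base_run, r.label)
                b = _nf_quantity(variant_run, r.label)
                if b is None:
                    continue
                total += abs(b - a)
                seen = True
            assert seen
            return total

        assert response(ghge_lo_run) >= response(ghge_hi_run) - 1e-6
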