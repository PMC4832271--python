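"""Annotation tree and elicitation-solver tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebfine import (
    AnnotationRecord,
    ElicitationSpec,
    NoRealRootError,
    approximation_diagnostics,
    assign_groups,
    solve_delta_causal_count,
    solve_delta_exact,
    solve_delta_linear,
    solve_delta_quadratic,
    synthetic_annotation_table,
)
from ebfine.priors import causal_count_coefficients
from ebfine.simulate import CASP8_GROUP_SIZES

PAPER_SPEC_R5 = ElicitationSpec(n=CASP8_GROUP_SIZES, p0=0.4, R=5)
PAPER_SPEC_R2 = ElicitationSpec(n=CASP8_GROUP_SIZES, p0=0.4, R=2)


class TestAssignGroups:
    def test_extremes_of_default_tree(self):
        records = [
            AnnotationRecord("all", 1, 1, 1, 1),
            AnnotationRecord("none", 0, 0, 0, 0),
        ]
        groups = assign_groups(records)
        assert groups.group[0] == 4
        assert groups.group[1] == 1

    def test_missing_values_treated_as_zero(self):
        rec = AnnotationRecord("na", 1, None, float("nan"), 1)
        assert rec.values() == (1, 0, 0, 1)
        assert assign_groups([rec]).group[0] == 3

    def test_synthetic_table_reproduces_group_sizes(self):
        table = synthetic_annotation_table(CASP8_GROUP_SIZES, seed=42)
        groups = assign_groups(table)
        assert tuple(groups.sizes(4)) == CASP8_GROUP_SIZES

    def test_unmapped_combination_named_in_error(self):
        rules = [{"when": {"conservation": 1}, "group": 4}]
        with pytest.raises(ValueError, match="conservation"):
            assign_groups([AnnotationRecord("x")], rule_config=rules)

    def test_custom_rule_order_first_match_wins(self):
        rules = [
            {"when": {"regional_location": 1}, "group": 2},
            {"min_positive": 2, "group": 3},
            {"when": {}, "group": 1},
        ]
        recs = [AnnotationRecord("a", 1, 1, 1, 1), AnnotationRecord("b", 0, 1, 1, 0)]
        groups = assign_groups(recs, rule_config=rules, n_groups=3)
        assert list(groups.group) == [2, 3]

    def test_rules_yaml_round_trip(self, tmp_path):
        from ebfine.priors import DEFAULT_RULES, load_rules, save_rules

        path = tmp_path / "rules.yaml"
        save_rules(DEFAULT_RULES, path)
        assert load_rules(path) == DEFAULT_RULES


class TestLinearSolver:
    def test_reproduces_printed_r5_priors(self):
        priors = solve_delta_linear(PAPER_SPEC_R5)
        assert priors.delta[0] == pytest.approx(0.6 / 18523, rel=1e-12)
        assert priors.delta[0] == pytest.approx(3.2e-5, abs=5e-7)
        assert priors.delta[3] == pytest.approx(4e-3, abs=5e-5)
        assert np.allclose(priors.delta[1:] / priors.delta[:-1], 5.0)

    def test_reproduces_printed_r2_prior(self):
        priors = solve_delta_linear(PAPER_SPEC_R2)
        assert priors.delta[0] == pytest.approx(0.00012, abs=5e-6)

    def test_single_group_closed_form(self):
        priors = solve_delta_linear(ElicitationSpec(n=(100,), p0=0.9, R=5))
        assert priors.delta[0] == pytest.approx(0.001)

    def test_monotone_in_inputs(self):
        base = solve_delta_linear(ElicitationSpec(n=(100, 50), p0=0.5, R=3)).delta[0]
        more_snps = solve_delta_linear(ElicitationSpec(n=(200, 50), p0=0.5, R=3)).delta[0]
        bigger_r = solve_delta_linear(ElicitationSpec(n=(100, 50), p0=0.5, R=6)).delta[0]
        lower_p0 = solve_delta_linear(ElicitationSpec(n=(100, 50), p0=0.3, R=3)).delta[0]
        assert more_snps < base and bigger_r < base and lower_p0 > base


class TestQuadraticSolver:
    def test_single_group_hand_expansion(self):
        # n=(2): second-order coefficients as printed give 4 d^2 - 2 d + (1-p0) = 0
        priors = solve_delta_quadratic(ElicitationSpec(n=(2,), p0=0.99, R=5))
        expected = (2 - np.sqrt(4 - 16 * 0.01)) / 8
        assert priors.delta[0] == pytest.approx(expected, rel=1e-12)

    def test_improves_on_linear_when_solvable(self):
        spec = ElicitationSpec(n=CASP8_GROUP_SIZES, p0=0.9, R=5)
        lin = solve_delta_linear(spec)
        quad = solve_delta_quadratic(spec)
        assert abs(quad.achieved_p0 - 0.9) < abs(lin.achieved_p0 - 0.9)

    def test_printed_r5_scenario_has_no_real_roots(self):
        # the second-order truncation fails exactly where the first-order
        # approximation is poor; the exact solver is the documented fallback
        with pytest.raises(NoRealRootError):
            solve_delta_quadratic(PAPER_SPEC_R5)

    def test_delta_vanishes_as_p0_approaches_one(self):
        d = [
            solve_delta_quadratic(ElicitationSpec(n=(10, 5), p0=p0, R=2)).delta[0]
            for p0 in (0.99, 0.999, 0.9999)
        ]
        assert d[0] > d[1] > d[2]
        assert d[2] < 1e-5


class TestExactSolver:
    def test_single_snp_closed_form(self):
        priors = solve_delta_exact(ElicitationSpec(n=(1,), p0=0.5, R=2))
        assert priors.delta[0] == pytest.approx(0.5, abs=1e-12)

    def test_achieved_p0_exact_for_printed_scenario(self):
        priors = solve_delta_exact(PAPER_SPEC_R5)
        assert abs(priors.achieved_p0 - 0.4) < 1e-12

    def test_linear_solution_achieved_p0_diagnostic(self):
        # sum n_j delta_j = 1 - p0 exactly, so the first-order solution's
        # true no-causal probability is ~exp(-(1-p0)) rather than p0
        lin = solve_delta_linear(PAPER_SPEC_R5)
        assert lin.achieved_p0 == pytest.approx(np.exp(-0.6), abs=1e-3)

    def test_group_specific_ratios_supported(self):
        spec = ElicitationSpec(n=(50, 30, 20), p0=0.6, R=(2.0, 7.0))
        priors = solve_delta_exact(spec)
        assert priors.delta[1] / priors.delta[0] == pytest.approx(2.0, rel=1e-12)
        assert priors.delta[2] / priors.delta[1] == pytest.approx(7.0, rel=1e-12)
        assert abs(priors.achieved_p0 - 0.6) < 1e-12

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.lists(st.integers(1, 3000), min_size=1, max_size=5),
        p0=st.floats(0.05, 0.95),
        R=st.floats(1.05, 10.0),
    )
    def test_achieved_p0_property(self, n, p0, R):
        priors = solve_delta_exact(ElicitationSpec(n=tuple(n), p0=p0, R=R))
        assert abs(priors.achieved_p0 - p0) < 1e-12
        assert np.allclose(priors.delta[1:] / priors.delta[:-1], R, rtol=1e-12)

    def test_agrees_with_linear_as_p0_to_one(self):
        rel_gaps = []
        for p0 in (0.9, 0.99, 0.999):
            spec = ElicitationSpec(n=(100, 40), p0=p0, R=4)
            lin = solve_delta_linear(spec).delta[0]
            ex = solve_delta_exact(spec).delta[0]
            rel_gaps.append(abs(ex - lin) / lin)
        assert rel_gaps[0] > rel_gaps[1] > rel_gaps[2]
        assert rel_gaps[2] < 1e-3


class TestCausalCountSolver:
    def test_reduces_to_linear_when_single_causal_certain(self):
        # weights (p0, 1, 0) make the defining identity collapse to the
        # first-order equation sum_j n_j delta_j = 1 - p0
        spec = ElicitationSpec(
            n=(100, 40, 10), p0=0.5, R=3, causal_count_probs=(0.5, 1.0, 0.0)
        )
        cc = solve_delta_causal_count(spec)
        lin = solve_delta_linear(ElicitationSpec(n=(100, 40, 10), p0=0.5, R=3))
        assert cc.delta[0] == pytest.approx(lin.delta[0], rel=1e-12)

    def test_brute_force_scan_oracle(self):
        spec = ElicitationSpec(n=(5, 3), p0=0.3, R=(2.0,), causal_count_probs=(0.3, 0.5, 0.2))
        a, b, c = causal_count_coefficients(spec)
        grid = np.arange(1e-8, 0.1, 1e-8)
        vals = a * grid**2 + b * grid + c
        root_scan = grid[np.argmin(np.abs(vals))]
        cc = solve_delta_causal_count(spec)
        assert cc.delta[0] == pytest.approx(root_scan, abs=1e-8)

    def test_scaling_invariance_of_defining_polynomial(self):
        """f(k n, d/k) = f(n, d): coefficients are degree-homogeneous in n."""
        spec = ElicitationSpec(n=(7, 4, 2), p0=0.4, R=(2.0, 3.0), causal_count_probs=(0.2, 0.6, 0.2))
        scaled = ElicitationSpec(
            n=(21, 12, 6), p0=0.4, R=(2.0, 3.0), causal_count_probs=(0.2, 0.6, 0.2)
        )
        a, b, c = causal_count_coefficients(spec)
        a3, b3, c3 = causal_count_coefficients(scaled)
        d = 0.004
        assert a3 * (d / 3) ** 2 + b3 * (d / 3) + c3 == pytest.approx(
            a * d**2 + b * d + c, rel=1e-12
        )

    def test_requires_causal_count_probs(self):
        with pytest.raises(ValueError, match="causal_count_probs"):
            solve_delta_causal_count(ElicitationSpec(n=(10,), p0=0.5, R=2))


class TestDiagnostics:
    @pytest.mark.parametrize(
        "spec, good",
        [
            (ElicitationSpec(n=(1000, 500), p0=0.99, R=2), True),  # tiny deltas
            (ElicitationSpec(n=(100, 50), p0=0.9, R=3), True),
            (ElicitationSpec(n=(10, 5, 2), p0=0.2, R=10), False),  # large deltas
        ],
    )
    def test_reports_recomputed_quantities(self, spec, good):
        priors = solve_delta_linear(spec)
        report = approximation_diagnostics(spec, priors)
        n = np.asarray(spec.n, float)
        assert report["n_delta"] == pytest.approx((n * priors.delta).tolist())
        assert report["achieved_p0"] == pytest.approx(priors.achieved_p0)
        expected_ind = (spec.cum_ratios / n).tolist()
        assert report["ratio_indicator"] == pytest.approx(expected_ind)
        if good:
            assert report["p0_abs_error"] < 0.01
        else:
            assert report["p0_abs_error"] > 0.01


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        ElicitationSpec(n=(0, 0), p0=0.5, R=2)
    with pytest.raises(ValueError):
        ElicitationSpec(n=(10,), p0=1.5, R=2)
    with pytest.raises(ValueError):
        ElicitationSpec(n=(10, 5), p0=0.5, R=(2.0, 3.0))  # wrong ratio count
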