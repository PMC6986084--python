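"""Empirical-Bayes engine: marginals, EM behavior, workflow contracts."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import betaln, logsumexp

from aponet import (EBConfig, StudyDesign, SimulationParams, WorkflowConfig,
                    beta_nb_predictive, consistent_degs, estimate_size_factors,
                    fit_two_group, generate_counts, two_step_workflow)
from aponet.ebde import de_called, ppde_from_marginals
from aponet.expression import ExpressionMatrix


def _matrix(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"t{i}" for i in range(values.shape[0])],
                     columns=samples))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = _matrix([[10, 10], [3, 3], [7, 7]])
        np.testing.assert_allclose(estimate_size_factors(m).to_numpy(), 1.0)

    def test_doubled_sample_geometric_reference(self):
        m = _matrix([[10, 20], [4, 8], [50, 100]])
        s = estimate_size_factors(m)
        np.testing.assert_allclose(
            s.to_numpy(), [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12)

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(21)
        values = rng.integers(0, 200, size=(80, 5)).astype(float)
        values[:40] += 1  # guarantee some all-nonzero rows
        m = _matrix(values)
        s = estimate_size_factors(m).to_numpy()
        # straightforward oracle loop
        ratios = []
        for g in range(80):
            row = values[g]
            if (row > 0).all():
                geo = np.exp(np.mean(np.log(row)))
                ratios.append(row / geo)
        expected = np.median(np.array(ratios), axis=0)
        np.testing.assert_allclose(s, expected, rtol=1e-12)

    def test_error_without_all_nonzero_transcript(self):
        m = _matrix([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="pseudo-counts"):
            estimate_size_factors(m)


class TestBetaNbPredictive:
    def test_zero_count_closed_form(self):
        for r, a, b in [(1.0, 1.0, 1.0), (2.5, 3.0, 0.7), (0.5, 1.2, 4.0)]:
            expected = betaln(a + r, b) - betaln(a, b)
            assert beta_nb_predictive([0], [r], a, b) == pytest.approx(expected)

    def test_hand_evaluated_half(self):
        assert math.exp(beta_nb_predictive([0], [1.0], 1.0, 1.0)) == \
            pytest.approx(0.5)

    def test_single_sample_density_normalizes(self):
        logs = [beta_nb_predictive([x], [5.0], 2.0, 3.0) for x in range(5001)]
        assert math.exp(logsumexp(logs)) >= 0.999

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            beta_nb_predictive([1], [1.0], -1.0, 1.0)
        with pytest.raises(ValueError):
            beta_nb_predictive([-1], [1.0], 1.0, 1.0)
        with pytest.raises(ValueError):
            beta_nb_predictive([1, 2], [1.0], 1.0, 1.0)


def _toy_two_group(seed=0, n=400):
    rng = np.random.default_rng(seed)
    values = rng.negative_binomial(10, 0.3, size=(n, 6)).astype(float)
    values[0] = [5, 5, 5, 5, 5, 5]  # identical everywhere: no DE evidence
    m = _matrix(values)
    return m, ["s0", "s1", "s2"], ["s3", "s4", "s5"]


class TestFitTwoGroup:
    def test_posteriors_sum_to_one_exactly(self):
        m, ga, gb = _toy_two_group()
        _, table = fit_two_group(m, ga, gb)
        np.testing.assert_array_equal(table.PPEE + table.PPDE, 1.0)

    def test_identical_counts_not_called(self):
        m, ga, gb = _toy_two_group()
        _, table = fit_two_group(m, ga, gb)
        assert table.loc["t0", "PPDE"] < 0.95
        assert table.loc["t0", "call"] == "not_DE"

    def test_sample_order_within_groups_irrelevant(self):
        m, ga, gb = _toy_two_group()
        _, t1 = fit_two_group(m, ga, gb)
        _, t2 = fit_two_group(m, ga[::-1], gb[::-1])
        pd.testing.assert_frame_equal(t1, t2)

    def test_em_loglik_monotone(self):
        m, ga, gb = _toy_two_group(seed=3)
        model, _ = fit_two_group(m, ga, gb)
        trace = np.asarray(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8 * (1 + np.abs(trace[:-1])))

    def test_all_zero_transcript_excluded_with_notice(self):
        m, ga, gb = _toy_two_group()
        values = m.data.copy()
        values.loc["t1"] = 0.0
        m2 = ExpressionMatrix(values)
        with pytest.warns(UserWarning, match="all-zero"):
            _, table = fit_two_group(m2, ga, gb)
        assert "t1" not in table.index
        assert table.attrs["excluded_all_zero"] == ["t1"]

    def test_ppde_monotone_in_group_shift(self):
        # fixed model: scaling one group's counts up never lowers PPDE
        r = np.ones(6) * 5.0
        alpha, beta, p = 1.0, 1.0, 0.1
        base = np.array([10.0, 10, 10, 10, 10, 10])
        last = -1.0
        for factor in [1, 2, 4, 8, 16]:
            x = base.copy()
            x[:3] *= factor
            f_ee = beta_nb_predictive(x, r, alpha, beta)
            f_de = (beta_nb_predictive(x[:3], r[:3], alpha, beta)
                    + beta_nb_predictive(x[3:], r[3:], alpha, beta))
            ppde = float(ppde_from_marginals(f_ee, f_de, p))
            assert ppde >= last - 1e-12
            last = ppde

    def test_p_de_recovered_on_planted_mixture(self, eb_de_fit):
        model, _, _ = eb_de_fit
        assert abs(model.p_de - 0.10) <= 0.05


class TestConsistentDegs:
    @staticmethod
    def _table(called, universe):
        return pd.DataFrame(
            {"PPEE": 0.0, "PPDE": 1.0, "log2FC": 2.0,
             "is_de": [t in called for t in universe],
             "call": ["over_in_A" if t in called else "not_DE"
                      for t in universe]},
            index=list(universe))

    def test_intersection(self):
        u = ["a", "b", "c", "d"]
        out = consistent_degs(self._table({"a", "b", "c"}, u),
                              self._table({"b", "c", "d"}, u))
        assert out == {"b", "c"}

    def test_disjoint_empty(self):
        u = ["a", "b", "c", "d"]
        assert consistent_degs(self._table({"a"}, u),
                               self._table({"d"}, u)) == set()

    def test_identical_tables_full_set(self):
        u = ["a", "b", "c"]
        t = self._table({"a", "c"}, u)
        assert consistent_degs(t, t) == {"a", "c"}


@pytest.fixture(scope="module")
def small_workflow():
    design = StudyDesign()
    params = SimulationParams(n_transcripts=400, seed=12)
    matrix, truth = generate_counts(design, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = two_step_workflow(matrix, design.metadata())
    return design, matrix, truth, result


class TestTwoStepWorkflow:
    def test_all_genotype_pairs_tested_within_apo_class(self, small_workflow):
        _, _, _, result = small_workflow
        apo_pairs = [k for k in result.step1_tables if k[0] == "4X_apo"]
        assert len(apo_pairs) == 3  # A x B, A x C, B x C
        sex2x_pairs = [k for k in result.step1_tables if k[0] == "2X_sex"]
        assert len(sex2x_pairs) == 1

    def test_single_genotype_class_skips_step1(self, small_workflow):
        _, matrix, _, result = small_workflow
        assert result.step1_retained["4X_sex"] == set(matrix.transcript_ids)
        assert not any(k[0] == "4X_sex" for k in result.step1_tables)

    def test_step1_failure_excludes_from_common_and_step2(self, small_workflow):
        _, _, _, result = small_workflow
        failing = set()
        for (cls, _, _), table in result.step1_tables.items():
            failing |= set(table.index[table.PPEE < 0.95])
        assert not (failing & result.common_expressed)
        for table in result.comparisons.values():
            assert not (failing & set(table.index))

    def test_consistent_subset_of_common(self, small_workflow):
        _, _, _, result = small_workflow
        assert result.consistent_degs <= result.common_expressed

    def test_lower_ppde_threshold_calls_strictly_more(self, small_workflow):
        _, _, _, result = small_workflow
        table = result.comparisons[("2X_sex", "4X_apo")]
        loose = (table.PPDE >= 0.5).sum()
        strict = (table.PPDE >= 0.95).sum()
        assert loose > strict

    def test_unknown_class_in_focus_warns(self, small_workflow):
        design, matrix, _, _ = small_workflow
        with pytest.warns(UserWarning, match="focus class"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                res = two_step_workflow(
                    matrix, design.metadata(),
                    WorkflowConfig(focus_class="nope",
                                   eb=EBConfig(max_iter=5)))
        assert res.consistent_degs == set()

    def test_requires_two_classes(self):
        design = StudyDesign(classes=(("A", 2),))
        params = SimulationParams(n_transcripts=50, frac_specific_per_class={},
                                  n_modules=0, module_size=0, seed=1)
        matrix, _ = generate_counts(design, params)
        with pytest.raises(ValueError, match="classes"):
            two_step_workflow(matrix, design.metadata())


def test_de_called_uses_posterior_not_direction():
    table = pd.DataFrame(
        {"PPEE": [0.01, 0.5], "PPDE": [0.99, 0.5], "log2FC": [0.3, 3.0],
         "is_de": [True, False], "call": ["not_DE", "not_DE"]},
        index=["weak_fc_deg", "strong_fc_nondeg"])
    assert de_called(table) == {"weak_fc_deg"}
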