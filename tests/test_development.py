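import numpy as np
import pandas as pd
import pytest

from freevitd import EQ2, EQ3, GeneratorConfig, generate_cohort
from freevitd.cohort import recovery_scenario_config
from freevitd.design import build_design
from freevitd.development import (
    CLINICAL_CANDIDATES,
    ModelConfig,
    develop_equation,
    fit_ols,
    forward_select,
    interaction_search,
    split_cohort,
)
from freevitd.errors import InputError, SingularDesignError


class TestSplitCohort:
    def test_default_rounding_sizes(self):
        frame = pd.DataFrame({"x": np.arange(370)})
        dev, val = split_cohort(frame, 2 / 3, seed=0)
        assert (len(dev), len(val)) == (247, 123)

    def test_explicit_dev_n_reproduces_published_sizes(self):
        frame = pd.DataFrame({"x": np.arange(370)})
        dev, val = split_cohort(frame, 2 / 3, seed=0, dev_n=244)
        assert (len(dev), len(val)) == (244, 126)

    def test_same_seed_identical_membership(self):
        frame = pd.DataFrame({"x": np.arange(100)})
        d1, v1 = split_cohort(frame, 0.5, seed=9)
        d2, v2 = split_cohort(frame, 0.5, seed=9)
        assert d1.index.equals(d2.index) and v1.index.equals(v2.index)

    def test_partition_is_disjoint_and_exhaustive(self):
        frame = pd.DataFrame({"x": np.arange(57)})
        dev, val = split_cohort(frame, 2 / 3, seed=4)
        merged = set(dev.index) | set(val.index)
        assert merged == set(frame.index)
        assert not set(dev.index) & set(val.index)

    def test_too_small_cohort(self):
        with pytest.raises(InputError):
            split_cohort(pd.DataFrame({"x": [1, 2]}), 0.5, seed=0)


class TestFitOls:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        y = 1.5 + 2.0 * X["a"] - 0.7 * X["b"]
        fit = fit_ols(y, X)
        assert fit.params["const"] == pytest.approx(1.5, abs=1e-9)
        assert fit.params["a"] == pytest.approx(2.0, abs=1e-9)
        assert fit.params["b"] == pytest.approx(-0.7, abs=1e-9)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_three_point_hand_example(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 4.0]})
        fit = fit_ols([1.0, 2.0, 3.0], X)
        assert fit.params["x"] == pytest.approx(0.642857, abs=1e-5)
        assert fit.params["const"] == pytest.approx(0.5, abs=1e-9)
        assert fit.adj_r2 == pytest.approx(0.9286, abs=1e-3)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=40)})
        y = 3 * X["a"] + rng.normal(0, 0.3, 40)
        fit0 = fit_ols(y.to_numpy(), X)
        perm = rng.permutation(40)
        fit1 = fit_ols(y.to_numpy()[perm], X.iloc[perm].reset_index(drop=True))
        assert fit0.params["a"] == pytest.approx(fit1.params["a"], rel=1e-9)

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        for cols in (2, 4, 6):
            X = pd.DataFrame(
                rng.normal(size=(60, cols)), columns=[f"c{i}" for i in range(cols)]
            )
            y = rng.normal(size=60)
            fit = fit_ols(y, X)
            A = np.column_stack([np.ones(60), X.to_numpy()])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_singular_design_names_collinear_columns(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=30)})
        with pytest.raises(SingularDesignError) as err:
            fit_ols(rng.normal(size=30), X)
        assert {"a", "b"} <= set(err.value.columns)


class TestForwardSelection:
    def test_informative_variable_retained_noise_rejected(self):
        rng = np.random.default_rng(0)
        n = 2000
        x1 = np.exp(rng.normal(3, 0.6, n))
        frame = pd.DataFrame(
            {
                "d25_3_ng_ml": x1,
                "calcium_mg_dl": rng.normal(8.9, 0.45, n),
                "free25ohd_pg_ml": 2 * np.log(x1) + rng.normal(0, 0.5, n),
            }
        )
        config = ModelConfig(
            forced_variables=(), candidate_variables=("d25_3", "calcium"), seed=0
        )
        trace = forward_select(frame, config)
        assert trace.retained_terms == ["d25_3"]
        rejected = [s.term for s in trace.steps if not s.retained]
        assert "calcium" in rejected

    def test_unreachable_threshold_keeps_forced_model_only(self, default_cohort):
        config = ModelConfig(
            forced_variables=("albumin",),
            candidate_variables=("d25_3", "ipth"),
            retention_threshold=0.999,
            seed=0,
        )
        trace = forward_select(default_cohort, config)
        assert trace.retained_terms == []

    def test_recovers_clinical_equation_predictor_set(self):
        # response generated from the clinical-equation structure with
        # noise SD 1.25 in an identifiability-calibrated cohort
        frame = generate_cohort(recovery_scenario_config(EQ3, n=1000, seed=2))
        config = ModelConfig(candidate_variables=CLINICAL_CANDIDATES, seed=2)
        trace = forward_select(frame, config)
        assert set(trace.retained_terms) == {"d25_3", "albumin", "ipth", "d1_25_3"}

    def test_adjusted_r2_nondecreasing_over_retained_steps(self):
        frame = generate_cohort(recovery_scenario_config(EQ3, n=800, seed=5))
        config = ModelConfig(candidate_variables=CLINICAL_CANDIDATES, seed=5)
        trace = forward_select(frame, config)
        retained = [s for s in trace.steps if s.retained]
        assert retained
        for step in retained:
            assert step.adj_r2_after - step.adj_r2_before >= config.retention_threshold
        values = [s.adj_r2_after for s in retained]
        assert values == sorted(values)

    def test_selection_is_deterministic(self):
        frame = generate_cohort(recovery_scenario_config(EQ3, n=500, seed=3))
        config = ModelConfig(candidate_variables=CLINICAL_CANDIDATES, seed=3)
        t1 = forward_select(frame, config)
        t2 = forward_select(frame, config)
        assert t1.retained_terms == t2.retained_terms
        assert [(s.term, s.adj_r2_after) for s in t1.steps] == [
            (s.term, s.adj_r2_after) for s in t2.steps
        ]


class TestInteractionSearch:
    @staticmethod
    def _interaction_frame(n, gamma, seed):
        rng = np.random.default_rng(seed)
        d3 = np.exp(rng.normal(3.0, 0.6, n))
        d24 = np.exp(rng.normal(0.5, 0.6, n))
        y = (
            1.0
            + 0.8 * np.log(d3)
            - 0.5 * np.log(d24)
            + gamma * np.log(d3) * np.log(d24)
            + rng.normal(0, 0.8, n)
        )
        return pd.DataFrame(
            {"d25_3_ng_ml": d3, "d24_25_3_ng_ml": d24, "free25ohd_pg_ml": y}
        )

    def test_true_interaction_retained(self):
        frame = self._interaction_frame(1000, gamma=1.2, seed=4)
        config = ModelConfig(forced_variables=("d25_3", "d24_25_3"), seed=4)
        chosen, _ = interaction_search(frame, ["d25_3", "d24_25_3"], config)
        assert chosen == [("d25_3", "d24_25_3")]

    def test_absent_interaction_rejected(self):
        frame = self._interaction_frame(1000, gamma=0.0, seed=6)
        config = ModelConfig(forced_variables=("d25_3", "d24_25_3"), seed=6)
        chosen, trace = interaction_search(frame, ["d25_3", "d24_25_3"], config)
        assert chosen == []
        assert any(s.term == "d25_3:d24_25_3" for s in trace.steps)

    def test_self_interaction_excluded(self):
        frame = self._interaction_frame(500, gamma=0.0, seed=7)
        config = ModelConfig(forced_variables=("d25_3",), seed=7)
        chosen, trace = interaction_search(frame, ["d25_3"], config)
        assert chosen == []
        assert not trace.steps  # a single variable forms no pair


class TestDevelopEquation:
    def test_noiseless_cohort_gives_exact_recovery(self):
        config = GeneratorConfig(n=600, seed=9, noise_sd=0.0, truth_model=EQ2)
        frame = generate_cohort(config)
        spec, trace, reports = develop_equation(
            frame, ModelConfig(seed=9), mode="eq2"
        )
        assert spec.metadata["adj_r2"] == pytest.approx(1.0, abs=1e-9)
        fitted = {(v, t): c for v, t, c in spec.terms}
        for v, t, c in EQ2.terms:
            assert fitted[(v, t)] == pytest.approx(c, abs=1e-6)
        assert reports["overall"].rmse == pytest.approx(0.0, abs=1e-9)

    def test_dev_val_rmse_close_for_well_specified_model(self):
        frame = generate_cohort(GeneratorConfig(n=370, seed=14))
        spec, trace, reports = develop_equation(
            frame, ModelConfig(seed=14, dev_n=244), mode="eq2"
        )
        assert abs(trace.val_rmse - trace.dev_rmse) < 0.1

    def test_missing_measured_free_is_input_error(self, default_cohort):
        frame = default_cohort.drop(columns=["free25ohd_pg_ml"])
        with pytest.raises(InputError):
            develop_equation(frame, ModelConfig(seed=0), mode="eq1")

    def test_total_25ohd_excluded_when_d3_forced(self):
        config = ModelConfig(forced_variables=("d25_3",))
        assert "total_25ohd" not in config.candidate_variables


def test_phenotype_block_enters_as_five_indicators(default_cohort):
    design = build_design(default_cohort, ["phenotype"])
    assert design.shape[1] == 5
    assert set(design.sum(axis=1).unique()) <= {0.0, 1.0}
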