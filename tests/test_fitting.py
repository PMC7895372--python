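import numpy as np
import pytest
from scipy.stats import multinomial

from avbind import _params
from avbind._engine import DesignArrays, predict_design
from avbind.design import enumerate_design
from avbind.fitting import (
    DEFAULT_LAMBDA_GRID,
    FitConfig,
    OptimizationFailureError,
    cross_validate,
    fit_model,
    lambda_sweep,
    negative_log_likelihood,
    penalized_objective,
    rmse_cells,
)
from avbind.model_core import VARIANTS, n_free_parameters, predict_condition
from avbind.synthetic import CohortSpec, default_group_params, simulate_cohort, simulate_subject
from conftest import make_observer


@pytest.fixture(scope="module")
def subject(design):
    return simulate_subject(default_group_params(), design, seed=1234)


def brute_force_nll(params, data, conditions):
    """Independent oracle: sum of scipy multinomial log-pmfs, with the
    count-independent multinomial coefficient removed."""
    from scipy.special import gammaln

    total = 0.0
    for cond in conditions:
        x = np.asarray(data.counts[cond])
        n = x.sum()
        p = predict_condition(params, cond)
        log_coeff = gammaln(n + 1) - gammaln(x + 1).sum()
        total -= multinomial.logpmf(x, n, p) - log_coeff
    return total


class TestParameterization:
    @pytest.mark.parametrize(
        "variant,expected",
        [("MLE", 12), ("ReducedJP", 13), ("ReducedBCI", 13), ("FullJP", 14), ("FullBCI", 14)],
    )
    def test_free_parameter_counts(self, variant, expected):
        assert n_free_parameters(variant) == expected
        assert len(_params.free_parameter_names(variant)) == expected
        # pack counts the optimised dimensions (free priors must be interior)
        sync = 0.2 if variant.startswith("Full") else 0.0
        params = make_observer(
            variant=variant, prior_sync=sync, prior_async=0.3 if "BCI" in variant else 0.05
        )
        assert _params.pack(params).shape == (expected,)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_pack_unpack_round_trip(self, variant):
        rng = np.random.default_rng(8)
        z = rng.uniform(-2, 1, size=n_free_parameters(variant))
        params = _params.unpack(z, variant)
        np.testing.assert_allclose(_params.pack(params), z, atol=1e-12)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_every_unconstrained_vector_is_valid(self, variant):
        rng = np.random.default_rng(13)
        for _ in range(20):
            z = rng.uniform(-8, 8, size=n_free_parameters(variant))
            params = _params.unpack(z, variant)  # validation happens in the dataclasses
            assert 0 < params.response_map.b1 < params.response_map.b2 < 1

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_engine_matches_reference_predictions(self, variant, design):
        rng = np.random.default_rng(17)
        arrays = DesignArrays(design)
        for _ in range(5):
            z = rng.uniform(-4, 2, size=n_free_parameters(variant))
            params = _params.unpack(z, variant)
            fast = predict_design(arrays, *_params.unpack_arrays(z, variant)[:6], variant,
                                  _params.unpack_arrays(z, variant)[6])
            slow = np.vstack([predict_condition(params, c) for c in design.conditions])
            np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestObjectives:
    def test_uniform_prediction_nll(self, design):
        """A near-flat posterior predicts ~1/3 per category: NLL = n*ln 3."""
        params = make_observer(
            variant="MLE",
            sigma2_A=(1e4, 1e4, 1e4),
            sigma2_V=(1e4, 1e4, 1e4),
            means=(0.5, 0.5, 0.5, 0.5),
        )
        cond = design.conditions[0]
        data = simulate_subject(default_group_params(), design, seed=0)
        nll = negative_log_likelihood(params, data, [cond])
        assert nll == pytest.approx(25 * np.log(3), rel=1e-3)

    def test_matches_multinomial_oracle(self, design, subject, group_params):
        conditions = design.conditions[:3]
        mine = negative_log_likelihood(group_params, subject, conditions)
        oracle = brute_force_nll(group_params, subject, conditions)
        assert mine == pytest.approx(oracle, rel=1e-10)

    def test_empty_included_set_rejected(self, subject, group_params):
        with pytest.raises(ValueError):
            negative_log_likelihood(group_params, subject, [])

    def test_penalty_arithmetic(self, design, subject):
        params = make_observer(variant="MLE", sigma2_A=(1, 1, 1), sigma2_V=(1, 1, 1))
        nll = negative_log_likelihood(params, subject)
        assert penalized_objective(params, subject, lambda_reg=0.0) == pytest.approx(nll)
        # six unit variances -> six unit precisions -> penalty 7 * 6 = 42
        assert penalized_objective(params, subject, lambda_reg=7.0) == pytest.approx(nll + 42)

    def test_penalty_decreases_with_variance(self, subject):
        lo = make_observer(variant="MLE", sigma2_A=(0.01, 1, 1), sigma2_V=(1, 1, 1))
        hi = make_observer(variant="MLE", sigma2_A=(0.02, 1, 1), sigma2_V=(1, 1, 1))
        pen = lambda p: penalized_objective(p, subject, lambda_reg=7.0) - negative_log_likelihood(p, subject)
        assert pen(hi) < pen(lo)

    def test_fast_objective_matches_reference(self, design, subject):
        """The vectorised training objective equals the public API value."""
        from avbind.fitting import _make_objective

        arrays = DesignArrays(design)
        counts = subject.count_array(design)
        mask = np.ones(42, dtype=bool)
        mask[5] = False
        included = [c for i, c in enumerate(design.conditions) if mask[i]]
        rng = np.random.default_rng(3)
        for variant in ("MLE", "ReducedJP", "FullBCI"):
            obj = _make_objective(counts, arrays, variant, mask, 7.0)
            z = rng.uniform(-3, 1, size=n_free_parameters(variant))
            params = _params.unpack(z, variant)
            assert obj(z) == pytest.approx(penalized_objective(params, subject, included, 7.0), rel=1e-9)


class TestFitModel:
    def test_more_restarts_never_worse(self, design, subject):
        few = fit_model(subject, "MLE", design, FitConfig(n_restarts=3, seed=42))
        many = fit_model(subject, "MLE", design, FitConfig(n_restarts=6, seed=42))
        # same seed: the first 3 starts coincide, so the larger run minimises
        # over a superset of restarts
        assert many.penalized_nll <= few.penalized_nll + 1e-9
        assert len(many.restart_trace) == 6

    def test_optimum_beats_random_probes(self, design, subject):
        fit = fit_model(subject, "MLE", design, FitConfig(n_restarts=8, seed=0))
        rng = np.random.default_rng(1)
        for _ in range(25):
            z = rng.uniform(-6, 3, size=12)
            probe = penalized_objective(_params.unpack(z, "MLE"), subject, lambda_reg=7.0)
            assert fit.penalized_nll <= probe + 1e-9

    def test_penalized_equals_nll_plus_penalty(self, design, subject):
        fit = fit_model(subject, "ReducedJP", design, FitConfig(n_restarts=5, seed=2))
        lik = fit.params.likelihood
        penalty = 7.0 * sum(1.0 / v for v in (*lik.sigma2_A.values(), *lik.sigma2_V.values()))
        assert fit.penalized_nll == pytest.approx(fit.nll + penalty, rel=1e-8)
        assert fit.converged

    def test_full_variant_at_least_as_good_as_reduced(self, design, subject):
        """The Reduced search space is a slice of the Full space."""
        config = FitConfig(n_restarts=12, seed=4)
        reduced = fit_model(subject, "ReducedJP", design, config)
        full = fit_model(subject, "FullJP", design, config,
                         extra_starts=[np.append(reduced.z_opt[:12], [-30.0, reduced.z_opt[12]])])
        assert full.penalized_nll <= reduced.penalized_nll + 1e-6

    def test_recovery_smoke(self):
        """With generous trials the async binding variance is recovered."""
        big = enumerate_design(n_reps=500)
        truth = default_group_params()
        data = simulate_subject(truth, big, seed=77)
        fit = fit_model(data, "ReducedJP", big, FitConfig(n_restarts=10, seed=5))
        assert 0.0 < fit.params.prior.value_async
        assert np.log10(fit.params.prior.value_async) == pytest.approx(np.log10(0.05), abs=1.0)


@pytest.fixture(scope="module")
def cv(design, subject):
    return cross_validate(subject, "ReducedJP", design, FitConfig.profile("test", seed=6))


class TestCrossValidate:

    def test_one_fold_per_condition(self, cv, design):
        assert set(cv.per_fold_predictions) == set(design.conditions)
        for probs in cv.per_fold_predictions.values():
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rmse_definition(self, cv, design, subject):
        predicted = np.vstack([cv.per_fold_predictions[c] for c in design.conditions])
        observed = subject.proportions(design)
        assert cv.rmse == pytest.approx(np.sqrt(np.mean((predicted - observed) ** 2)))

    def test_rmse_cells_arithmetic(self):
        assert rmse_cells([[1, 0, 0]], [[0, 1, 0]]) == pytest.approx(np.sqrt(2 / 3))
        assert rmse_cells([[0.2, 0.3, 0.5]], [[0.2, 0.3, 0.5]]) == 0.0

    def test_rmse_cells_permutation_invariant(self):
        rng = np.random.default_rng(0)
        pred, obs = rng.random((10, 3)), rng.random((10, 3))
        perm = rng.permutation(10)
        assert rmse_cells(pred, obs) == pytest.approx(rmse_cells(pred[perm], obs[perm]))


class TestLambdaSweep:
    def test_single_point_grid(self, design, subject):
        config = FitConfig(n_restarts=2, cv_restarts=1, seed=0)
        result = lambda_sweep([subject], ["MLE"], design, [7.0], config)
        assert result.selected_lambda == 7.0
        assert len(result.curve) == 1

    def test_selected_attains_curve_minimum(self, design):
        tiny = enumerate_design(n_reps=5)  # few trials: regularisation should help
        data = simulate_subject(default_group_params(), tiny, seed=10)
        config = FitConfig(n_restarts=3, cv_restarts=1, seed=1)
        result = lambda_sweep([data], ["MLE"], tiny, [1e-3, 0.2, 7.0], config)
        curve = result.curve
        assert result.selected_lambda == curve.loc[curve.mean_rmse.idxmin(), "lambda"]
        # overfitting at tiny trial counts: the weakest penalty does not win
        assert result.selected_lambda != pytest.approx(1e-3)

    def test_invalid_grids_rejected(self, design, subject):
        with pytest.raises(ValueError):
            lambda_sweep([subject], ["MLE"], design, [], FitConfig())
        with pytest.raises(ValueError):
            lambda_sweep([subject], ["MLE"], design, [-1.0], FitConfig())

    def test_default_grid_spans_published_interval(self):
        assert DEFAULT_LAMBDA_GRID[0] == pytest.approx(1e-3)
        assert DEFAULT_LAMBDA_GRID[-1] == pytest.approx(1e2)
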