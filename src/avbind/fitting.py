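"""Regularised maximum-likelihood fitting, cross-validation and the λ sweep.

Each observer variant is fitted per subject by minimising the negative
multinomial log-likelihood of the response counts (the count-independent
multinomial coefficient is dropped) plus a precision penalty

    penalty = lambda_reg * (sum_k 1/sigma2_A_k + sum_k 1/sigma2_V_k)

over the six SNR-level variances.  The penalty keeps the optimiser away from
degenerate, needle-sharp likelihoods, where a tiny shift of a mean or
boundary would flip predicted response probabilities between 0 and 1.
Optimisation runs in the unconstrained parameterization of
:mod:`avbind._params` with a quasi-Newton local method (L-BFGS-B, numerical
gradients) from many random starting points; the restart with the lowest
penalised objective wins.

Out-of-sample error uses leave-one-condition-out cross-validation: one fold
per condition, fitting on the remaining conditions and predicting the
held-out one.  Held-out error is reported as the root mean squared error
between predicted probabilities and observed proportions over all
(condition, category) cells — never as a log-likelihood, because a held-out
condition can receive a predicted probability of zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _params
from ._engine import DesignArrays, predict_design
from .design import Condition, Design
from .model_core import (
    VARIANT_PRIOR_KIND,
    ObserverParams,
    n_free_parameters,
    predict_condition,
)
from .synthetic import SubjectData

__all__ = [
    "OptimizationFailureError",
    "FitConfig",
    "FitResult",
    "CVResult",
    "SweepResult",
    "DEFAULT_LAMBDA_GRID",
    "negative_log_likelihood",
    "penalized_objective",
    "fit_model",
    "cross_validate",
    "lambda_sweep",
]

logger = logging.getLogger(__name__)

#: Floor applied to predicted probabilities inside the training objective,
#: guarding log(0) when a category's predicted mass underflows.
PROB_FLOOR = 1e-9

#: Default grid for the regularisation-constant sweep (log-spaced).
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 2, 11))


class OptimizationFailureError(RuntimeError):
    """No restart produced a finite objective value."""


# Uniform ranges for random unconstrained starting points, per slot kind.
# Means cover ~(0.08, 0.92) on the axis, variances ~(1e-3, 0.5), boundaries
# most of the interval, binding variances ~(1e-3, 2.7), p_separate ~(.02, .98).
_INIT_RANGES = {
    "mean": (-2.5, 2.5),
    "log_var": (np.log(1e-3), np.log(0.5)),
    "b1": (-2.0, 1.0),
    "b2_gap": (-2.0, 2.0),
    "log_sigma_o2": (-7.0, 1.0),
    "logit_p": (-4.0, 4.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Settings for one fitting run.

    ``profile('paper')`` reproduces the published procedure (λ = 7, 100
    restarts, full restarts per cross-validation fold); ``profile('test')``
    keeps the same λ but runs 20 restarts and warm-started two-start folds,
    which is what the package's own simulations use to stay desk-scale.
    """

    n_restarts: int = 100
    lambda_reg: float = 7.0
    seed: int = 0
    cv_restarts: int | None = None  # starts per CV fold; None = n_restarts
    warm_start: bool = True  # seed each fold with the full-data optimum
    maxiter: int = 400
    ftol: float = 1e-10
    gtol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.cv_restarts is not None and self.cv_restarts < 1:
            raise ValueError("cv_restarts must be >= 1")

    @classmethod
    def profile(cls, name: str, **overrides) -> "FitConfig":
        if name == "paper":
            base = dict(n_restarts=100, cv_restarts=None, warm_start=True)
        elif name == "test":
            base = dict(n_restarts=20, cv_restarts=2, warm_start=True)
        else:
            raise ValueError(f"unknown profile {name!r}")
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start fit of one variant to one subject."""

    params: ObserverParams
    penalized_nll: float
    nll: float
    restart_trace: tuple[float, ...]
    converged: bool
    z_opt: np.ndarray = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class CVResult:
    """Leave-one-condition-out cross-validation of one variant/subject."""

    per_fold_predictions: Mapping[Condition, np.ndarray]
    rmse: float
    per_fold_params: tuple[ObserverParams, ...] | None = None


@dataclass(frozen=True)
class SweepResult:
    selected_lambda: float
    curve: pd.DataFrame  # columns: lambda, mean_rmse


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------


def negative_log_likelihood(
    params: ObserverParams,
    data: SubjectData,
    included: Iterable[Condition] | None = None,
) -> float:
    """Multinomial NLL of the counts under the observer's predictions.

    ``-sum_c sum_k n_ck * log(p_ck)`` over the included conditions, with the
    multinomial coefficient omitted (constant in the parameters) and
    predicted probabilities floored at :data:`PROB_FLOOR`.
    """
    conditions = tuple(included) if included is not None else tuple(data.counts)
    if not conditions:
        raise ValueError("included condition set must be non-empty")
    total = 0.0
    for cond in conditions:
        counts = np.asarray(data.counts[cond], dtype=float)
        probs = np.maximum(predict_condition(params, cond), PROB_FLOOR)
        total -= float(counts @ np.log(probs))
    return total


def _precision_penalty(params: ObserverParams, lambda_reg: float) -> float:
    lik = params.likelihood
    precisions = [1.0 / v for v in lik.sigma2_A.values()] + [1.0 / v for v in lik.sigma2_V.values()]
    return lambda_reg * float(np.sum(precisions))


def penalized_objective(
    params: ObserverParams,
    data: SubjectData,
    included: Iterable[Condition] | None = None,
    lambda_reg: float = 7.0,
) -> float:
    """NLL plus the precision penalty (means, boundaries and prior parameters
    are unpenalised)."""
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    return negative_log_likelihood(params, data, included) + _precision_penalty(params, lambda_reg)


def _make_objective(
    counts: np.ndarray,
    arrays: DesignArrays,
    variant: str,
    mask: np.ndarray,
    lambda_reg: float,
):
    """Fast objective over the unconstrained vector (mirrors the reference
    :func:`penalized_objective`; equivalence is asserted in the tests)."""
    masked_counts = counts[mask].astype(float)
    row_idx = np.flatnonzero(mask)

    def objective(z: np.ndarray) -> float:
        mu_A, mu_V, s2_A, s2_V, b1, b2, prior_vals = _params.unpack_arrays(z, variant)
        probs = predict_design(arrays, mu_A, mu_V, s2_A, s2_V, b1, b2, variant, prior_vals)
        nll = -float(np.sum(masked_counts * np.log(np.maximum(probs[row_idx], PROB_FLOOR))))
        penalty = lambda_reg * float(np.sum(1.0 / s2_A) + np.sum(1.0 / s2_V))
        return nll + penalty

    return objective


def _random_start(rng: np.random.Generator, variant: str) -> np.ndarray:
    kinds = ["mean"] * 4 + ["log_var"] * 6 + ["b1", "b2_gap"]
    prior_kind = VARIANT_PRIOR_KIND[variant]
    n_prior = n_free_parameters(variant) - 12
    if prior_kind == "joint_prior":
        kinds += ["log_sigma_o2"] * n_prior
    elif prior_kind == "bci":
        kinds += ["logit_p"] * n_prior
    lo, hi = np.array([_INIT_RANGES[k] for k in kinds]).T
    return rng.uniform(lo, hi)


def _local_minimize(objective, z0: np.ndarray, config: FitConfig):
    return minimize(
        objective,
        z0,
        method="L-BFGS-B",
        options={"maxiter": config.maxiter, "ftol": config.ftol, "gtol": config.gtol},
    )


def _multistart(
    objective,
    starts: Sequence[np.ndarray],
    config: FitConfig,
) -> tuple[np.ndarray, float, list[float], bool]:
    best_z, best_val, trace, any_success = None, np.inf, [], False
    for z0 in starts:
        try:
            res = _local_minimize(objective, z0, config)
        except FloatingPointError:  # pragma: no cover - defensive
            trace.append(np.inf)
            continue
        val = float(res.fun) if np.isfinite(res.fun) else np.inf
        trace.append(val)
        any_success = any_success or bool(res.success)
        if val < best_val:
            best_val, best_z = val, np.asarray(res.x, dtype=float)
    if best_z is None or not np.isfinite(best_val):
        raise OptimizationFailureError("all restarts failed to reach a finite objective")
    return best_z, best_val, trace, any_success


# ---------------------------------------------------------------------------
# fitting and cross-validation
# ---------------------------------------------------------------------------


def fit_model(
    data: SubjectData,
    variant: str,
    design: Design,
    config: FitConfig | None = None,
    included_mask: np.ndarray | None = None,
    extra_starts: Sequence[np.ndarray] = (),
    n_random_starts: int | None = None,
) -> FitResult:
    """Fit one variant to one subject by penalised maximum likelihood.

    Random starting points are drawn from documented uniform ranges on the
    unconstrained scale, deterministically indexed by ``config.seed`` so a
    rerun reproduces the same restart sequence.  ``extra_starts`` prepends
    caller-supplied starting vectors (used to warm-start CV folds).
    """
    config = config or FitConfig()
    arrays = DesignArrays(design)
    counts = data.count_array(design)
    mask = np.ones(len(design.conditions), dtype=bool) if included_mask is None else included_mask
    if not mask.any():
        raise ValueError("included condition set must be non-empty")
    objective = _make_objective(counts, arrays, variant, mask, config.lambda_reg)

    n_rand = config.n_restarts if n_random_starts is None else n_random_starts
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    starts = list(extra_starts) + [_random_start(rng, variant) for _ in range(n_rand)]
    best_z, best_val, trace, any_success = _multistart(objective, starts, config)

    nll_objective = _make_objective(counts, arrays, variant, mask, 0.0)
    params = _params.unpack(best_z, variant)
    return FitResult(
        params=params,
        penalized_nll=best_val,
        nll=float(nll_objective(best_z)),
        restart_trace=tuple(trace),
        converged=any_success,
        z_opt=best_z,
    )


def rmse_cells(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Root mean squared error over all (condition, category) cells."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def cross_validate(
    data: SubjectData,
    variant: str,
    design: Design,
    config: FitConfig | None = None,
    keep_fold_params: bool = False,
) -> CVResult:
    """Leave-one-condition-out cross-validation (one fold per condition).

    With ``config.warm_start`` the full-data optimum is fitted first and
    added as the first starting point of every fold, alongside
    ``config.cv_restarts - 1`` random restarts; the folds' restart seeds are
    derived deterministically from ``config.seed`` and the fold index.
    """
    config = config or FitConfig()
    n = len(design.conditions)
    fold_starts = config.cv_restarts if config.cv_restarts is not None else config.n_restarts

    warm: list[np.ndarray] = []
    if config.warm_start:
        full = fit_model(data, variant, design, config)
        warm = [full.z_opt]

    n_random = max(fold_starts - len(warm), 0)
    predictions: dict[Condition, np.ndarray] = {}
    fold_params: list[ObserverParams] = []
    for i, cond in enumerate(design.conditions):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_config = replace(config, seed=int(np.random.SeedSequence((config.seed, i)).generate_state(1)[0] % (2**31)))
        fit = fit_model(
            data,
            variant,
            design,
            fold_config,
            included_mask=mask,
            extra_starts=warm,
            n_random_starts=n_random,
        )
        predictions[cond] = predict_condition(fit.params, cond)
        if keep_fold_params:
            fold_params.append(fit.params)
        logger.debug("CV fold %d/%d (%s) done", i + 1, n, variant)

    predicted = np.vstack([predictions[c] for c in design.conditions])
    observed = data.proportions(design)
    return CVResult(
        per_fold_predictions=predictions,
        rmse=rmse_cells(predicted, observed),
        per_fold_params=tuple(fold_params) if keep_fold_params else None,
    )


def lambda_sweep(
    cohort: Sequence[SubjectData],
    variants: Sequence[str],
    design: Design,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    config: FitConfig | None = None,
) -> SweepResult:
    """Select the regularisation constant by cross-validated error.

    For every λ on the grid, the mean CV RMSE over all subjects and variants
    is computed; the λ with the lowest mean wins.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    if any(g < 0 for g in grid):
        raise ValueError("lambda grid values must be >= 0")
    config = config or FitConfig()
    rows = []
    for lam in grid:
        lam_config = replace(config, lambda_reg=float(lam))
        rmses = [
            cross_validate(subject, variant, design, lam_config).rmse
            for subject in cohort
            for variant in variants
        ]
        rows.append({"lambda": float(lam), "mean_rmse": float(np.mean(rmses))})
        logger.info("lambda sweep: lambda=%g mean_rmse=%.5f", lam, rows[-1]["mean_rmse"])
    curve = pd.DataFrame(rows)
    best = curve.loc[curve["mean_rmse"].idxmin(), "lambda"]
    return SweepResult(selected_lambda=float(best), curve=curve)
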