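"""Cohort-level model comparison and derived parameter analyses.

Given per-subject cross-validation results for several observer variants,
this module builds the comparison table (held-out RMSE per subject and
variant, improvement over the forced-fusion MLE baseline, paired Wilcoxon
signed-rank contrasts), tests the fitted binding parameters against zero,
tests the fitted precisions for the expected SNR ordering, and extracts the
per-condition auditory weights implied by a Joint-Prior-family fit.

Statistical conventions: signed-rank tests drop zero differences and use the
exact null distribution for small samples (normal approximation otherwise,
as implemented in scipy); binding-parameter tests against zero are one-sided
one-sample t-tests; precision-ordering tests are one-sided; the Joint Prior
vs BCI contrast is two-sided.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import Design
from .fitting import CVResult, FitResult
from .model_core import auditory_weight

__all__ = [
    "UnsupportedVariantError",
    "ComparisonTable",
    "WeightTable",
    "compare_models",
    "prior_parameter_tests",
    "precision_ordering_tests",
    "extract_auditory_weights",
]


class UnsupportedVariantError(ValueError):
    """The requested analysis does not apply to this model variant."""


#: Contrasts reported by :func:`compare_models`, with their sidedness.
#: "greater" means the first variant is hypothesised to have *lower* CV error
#: (we test improvement = rmse(second) - rmse(first) > 0).
_CONTRASTS = (
    ("ReducedJP", "MLE", "two-sided"),
    ("ReducedBCI", "MLE", "two-sided"),
    ("FullJP", "MLE", "two-sided"),
    ("FullBCI", "MLE", "two-sided"),
    ("ReducedJP", "FullJP", "two-sided"),
    ("ReducedBCI", "FullBCI", "two-sided"),
    ("ReducedJP", "ReducedBCI", "two-sided"),
    ("FullJP", "FullBCI", "two-sided"),
)


@dataclass(frozen=True)
class ComparisonTable:
    """Cross-validated model comparison across a cohort."""

    rmse: pd.DataFrame  # index: subject, columns: variant
    improvement: pd.DataFrame  # columns: variant, mean_improvement (over MLE)
    tests: pd.DataFrame  # columns: first, second, alternative, statistic, p_value, n


@dataclass(frozen=True)
class WeightTable:
    """Auditory weights per bimodal condition implied by one subject's fit."""

    table: pd.DataFrame  # columns: pairing, auditory_snr, visual_snr, soa, w_A


def _signed_rank(first: np.ndarray, second: np.ndarray, alternative: str):
    """Paired Wilcoxon signed-rank test on second - first (improvement of
    the first variant); zero differences dropped."""
    diff = np.asarray(second, dtype=float) - np.asarray(first, dtype=float)
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return math.nan, 1.0, 0
    res = stats.wilcoxon(nonzero, zero_method="wilcox", alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue), int(nonzero.size)


def compare_models(cvs: Mapping[tuple[str, str], CVResult]) -> ComparisonTable:
    """Build the comparison table from per-(subject, variant) CV results.

    Every subject must have a result for every variant; improvement over the
    MLE baseline is only reported when MLE results are present.
    """
    subjects = sorted({s for s, _ in cvs})
    variants = sorted({v for _, v in cvs})
    missing = [(s, v) for s in subjects for v in variants if (s, v) not in cvs]
    if missing:
        raise ValueError(f"missing CV results for {missing[:5]} (every subject needs every variant)")

    rmse = pd.DataFrame(
        {v: [cvs[(s, v)].rmse for s in subjects] for v in variants}, index=pd.Index(subjects, name="subject")
    )

    if "MLE" in variants:
        improvement = pd.DataFrame(
            {
                "variant": variants,
                "mean_improvement": [float((rmse["MLE"] - rmse[v]).mean()) for v in variants],
            }
        )
    else:
        improvement = pd.DataFrame({"variant": variants, "mean_improvement": [math.nan] * len(variants)})

    rows = []
    for first, second, alternative in _CONTRASTS:
        if first in variants and second in variants:
            stat, p, n = _signed_rank(rmse[first].to_numpy(), rmse[second].to_numpy(), alternative)
            rows.append(
                {
                    "first": first,
                    "second": second,
                    "alternative": alternative,
                    "statistic": stat,
                    "p_value": p,
                    "n": n,
                }
            )
    tests = pd.DataFrame(rows, columns=["first", "second", "alternative", "statistic", "p_value", "n"])
    return ComparisonTable(rmse=rmse, improvement=improvement, tests=tests)


def prior_parameter_tests(fits: Mapping[str, FitResult]) -> pd.DataFrame:
    """One-sided t-tests of the binding parameters against zero (no binding
    release) across subjects, plus descriptives.

    The asynchronous parameter is the inferential target; the synchronous one
    is summarised descriptively (it is pinned to zero in Reduced variants).
    A cohort with zero between-subject variance in a parameter is flagged as
    degenerate instead of reporting a t statistic.
    """
    if len(fits) < 2:
        raise ValueError("prior parameter tests require at least 2 subjects")
    rows = []
    for soa, attr in (("sync", "value_sync"), ("async", "value_async")):
        values = np.array([getattr(fit.params.prior, attr) for fit in fits.values()], dtype=float)
        degenerate = bool(np.ptp(values) == 0)
        if degenerate:
            stat, p = math.nan, math.nan
        else:
            res = stats.ttest_1samp(values, 0.0, alternative="greater")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "soa": soa,
                "mean": float(values.mean()),
                "sem": float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else math.nan,
                "statistic": stat,
                "p_value": p,
                "degenerate": degenerate,
                "n": len(values),
            }
        )
    return pd.DataFrame(rows)


def precision_ordering_tests(fits: Mapping[str, FitResult]) -> pd.DataFrame:
    """One-sided paired signed-rank tests that fitted precision decreases
    with SNR: high > mid and mid > low, per modality."""
    if len(fits) < 2:
        raise ValueError("precision ordering tests require at least 2 subjects")
    rows = []
    for modality, attr in (("auditory", "sigma2_A"), ("visual", "sigma2_V")):
        prec = {
            lvl: np.array([1.0 / getattr(f.params.likelihood, attr)[lvl] for f in fits.values()])
            for lvl in ("high", "mid", "low")
        }
        for hi_lvl, lo_lvl in (("high", "mid"), ("mid", "low")):
            stat, p, n = _signed_rank(prec[lo_lvl], prec[hi_lvl], "greater")
            rows.append(
                {
                    "modality": modality,
                    "contrast": f"{hi_lvl}>{lo_lvl}",
                    "statistic": stat,
                    "p_value": p,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def extract_auditory_weights(fit: FitResult, design: Design) -> WeightTable:
    """Per-bimodal-condition auditory weights from a Joint-Prior-family fit.

    Uses the SOA-appropriate binding variance and the SNR-appropriate sensory
    variances; an MLE fit is the zero-binding-variance special case.  BCI
    fits have no single fused weight (their posterior is a mixture), so they
    are rejected.
    """
    if fit.params.prior.kind == "bci":
        raise UnsupportedVariantError("auditory weights are defined for Joint-Prior-family fits only")
    lik = fit.params.likelihood
    rows = []
    for cond in design.audiovisual:
        w = auditory_weight(
            fit.params.prior.value(cond.soa),
            lik.sigma2_A[cond.auditory_snr],
            lik.sigma2_V[cond.visual_snr],
        )
        rows.append(
            {
                "pairing": cond.pairing,
                "auditory_snr": cond.auditory_snr,
                "visual_snr": cond.visual_snr,
                "soa": cond.soa,
                "w_A": w,
            }
        )
    return WeightTable(table=pd.DataFrame(rows))
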