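"""Simulated subjects and cohorts for the audiovisual identification task.

The generator mirrors the generative assumptions of the observer models: for
every condition of the design, a subject's response counts are drawn from a
multinomial over (B, D, G) whose cell probabilities come from
:func:`avbind.model_core.predict_condition` under that subject's ground-truth
parameters.  Cohorts add between-subject heterogeneity by perturbing a group
parameter vector on the unconstrained fitting scale (logit means and
boundaries, log variances, log binding variance / logit separation
probability), which keeps every perturbed subject inside the valid parameter
domain without clipping.

The default cohort emulates the study conditions the analysis is built for:
16 subjects, 42 conditions, 25 repetitions per condition, with a Reduced
Joint Prior ground truth (full binding for synchronous stimuli, a nonzero
binding variance for the 500 ms audio-lead stimuli).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import _params
from .design import Condition, Design, enumerate_design
from .model_core import (
    LikelihoodParams,
    ObserverParams,
    PriorParams,
    ResponseMap,
    predict_condition,
)

__all__ = [
    "SubjectData",
    "CohortSpec",
    "default_group_params",
    "simulate_subject",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SubjectData:
    """Observed response counts per condition for one subject."""

    subject_id: str
    counts: Mapping[Condition, tuple[int, int, int]]

    def __post_init__(self) -> None:
        for cond, triple in self.counts.items():
            if len(triple) != 3 or any(int(c) != c or c < 0 for c in triple):
                raise ValueError(
                    f"counts for {cond} must be three non-negative integers, got {triple}"
                )

    def count_array(self, design: Design) -> np.ndarray:
        """Counts as an (n_conditions, 3) integer array in design order."""
        out = np.zeros((len(design.conditions), 3), dtype=np.int64)
        for i, cond in enumerate(design.conditions):
            try:
                out[i] = self.counts[cond]
            except KeyError as exc:
                raise KeyError(f"subject {self.subject_id} has no counts for {cond}") from exc
        return out

    def proportions(self, design: Design) -> np.ndarray:
        """Observed response proportions per condition (rows sum to 1)."""
        counts = self.count_array(design).astype(float)
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError(f"subject {self.subject_id} has conditions with zero trials")
        return counts / totals


def default_group_params(variant: str = "ReducedJP") -> ObserverParams:
    """Group-level ground truth used by the default synthetic cohort.

    On the unit place-of-articulation axis, B sits near the front (0.1) and G
    near the back (0.9 auditory, 0.8 visual — visual "ga" is harder to tell
    from "da" than the acoustic velar burst, so its mean sits closer to the
    D region).  Clear visual speech is the most reliable cue (variance
    0.003), clear audio close behind (0.005), and each masking step roughly
    triples the variance.  Boundaries split the axis at 1/3 and 2/3.  The
    binding stage is maximal for synchronous stimuli and clearly released
    for the 500 ms audio-lead stimuli (sigma_o2 = 0.05, i.e. prior sd
    comparable to a category separation of ~0.22, or p_separate = 0.7 for
    a BCI ground truth).
    """
    lik = LikelihoodParams(
        mu_A_B=0.10,
        mu_A_G=0.90,
        mu_V_B=0.10,
        mu_V_G=0.80,
        sigma2_A={"high": 0.005, "mid": 0.02, "low": 0.08},
        sigma2_V={"high": 0.003, "mid": 0.02, "low": 0.10},
    )
    rmap = ResponseMap(b1=1.0 / 3.0, b2=2.0 / 3.0)
    if variant == "MLE":
        prior = PriorParams.mle()
    elif variant in ("ReducedJP", "FullJP"):
        sync = 0.0 if variant == "ReducedJP" else 1e-4
        prior = PriorParams(kind="joint_prior", value_sync=sync, value_async=0.05)
    elif variant in ("ReducedBCI", "FullBCI"):
        sync = 0.0 if variant == "ReducedBCI" else 0.01
        prior = PriorParams(kind="bci", value_sync=sync, value_async=0.7)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return ObserverParams(likelihood=lik, prior=prior, response_map=rmap, variant=variant)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated cohort.

    ``between_subject_sd`` is the standard deviation of Gaussian perturbations
    applied per free parameter on the unconstrained scale; 0 makes every
    subject an exact copy of the group observer.
    """

    n_subjects: int = 16
    group_params: ObserverParams = field(default_factory=default_group_params)
    between_subject_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.between_subject_sd < 0:
            raise ValueError("between_subject_sd must be >= 0")


def simulate_subject(params: ObserverParams, design: Design, seed: int | np.random.SeedSequence) -> SubjectData:
    """Draw one subject's response counts: a multinomial per condition."""
    rng = np.random.default_rng(seed)
    counts: dict[Condition, tuple[int, int, int]] = {}
    for cond in design.conditions:
        probs = predict_condition(params, cond)
        draw = rng.multinomial(design.n_reps, probs)
        counts[cond] = tuple(int(x) for x in draw)
    subject_id = f"sim{rng.integers(0, 10**9):09d}"
    return SubjectData(subject_id=subject_id, counts=counts)


def simulate_cohort(
    spec: CohortSpec, design: Design | None = None
) -> tuple[list[SubjectData], list[ObserverParams]]:
    """Simulate a cohort; returns the data and the per-subject ground truth.

    Each subject's free-parameter vector is the group vector plus independent
    Gaussian noise (sd ``spec.between_subject_sd``) on the unconstrained
    scale; pinned parameters (e.g. the synchronous binding variance of a
    Reduced variant) stay pinned for every subject.
    """
    if design is None:
        design = enumerate_design()
    variant = spec.group_params.variant
    z_group = _params.pack(spec.group_params)
    root = np.random.SeedSequence(spec.seed)
    subjects: list[SubjectData] = []
    truths: list[ObserverParams] = []
    for i, child in enumerate(root.spawn(spec.n_subjects)):
        perturb_seq, trial_seq = child.spawn(2)
        rng = np.random.default_rng(perturb_seq)
        z = z_group + spec.between_subject_sd * rng.standard_normal(z_group.shape)
        truth = _params.unpack(z, variant)
        data = simulate_subject(truth, design, trial_seq)
        data = SubjectData(subject_id=f"S{i + 1:02d}", counts=data.counts)
        subjects.append(data)
        truths.append(truth)
    return subjects, truths
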