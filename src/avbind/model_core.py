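"""Closed-form Bayesian observer models for audiovisual syllable identification.

The observer represents a syllable on a one-dimensional place-of-articulation
axis (B articulated at the front of the mouth, G at the back), confined to the
unit interval.  Each sensory cue contributes a Gaussian likelihood on that
axis, with a mean per consonant and a variance per SNR level.  Three observer
variants map a bimodal stimulus to a posterior over the auditory axis:

* **MLE** — forced fusion: inverse-variance weighting of the auditory and
  visual means, the classic maximum-likelihood cue-combination rule.
* **Joint Prior (JP)** — the two cues share a Gaussian "binding ridge" prior
  along the audio=visual diagonal whose cross-diagonal variance ``sigma_o2``
  sets how strongly they are coupled; ``sigma_o2 = 0`` recovers the MLE and
  ``sigma_o2 -> inf`` fully segregates the cues.
* **BCI (Bayesian causal inference)** — a mixture of the forced-fusion
  posterior (common cause) and the auditory marginal (separate causes),
  weighted by the prior probability of separate causes ``p_separate``.

Because observers report what they *heard*, the posterior is marginalised
over visual representations; read-out applies two response boundaries to the
truncated posterior, mapping probability mass in three sub-intervals to the
response categories B, D and G.  D has no stimulus-level mean of its own: it
is the middle read-out interval, which is how fused ("da") percepts arise
from intermediate posteriors.

``Reduced`` variants pin the synchronous-condition prior parameter to full
binding (0) and fit only the asynchronous one; ``Full`` variants fit both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
from scipy.special import ndtr

from .design import NA, SNR_LEVELS, Condition

__all__ = [
    "InvalidParameterError",
    "ConfigurationError",
    "DegeneratePosteriorError",
    "RESPONSE_CATEGORIES",
    "VARIANTS",
    "VARIANT_PRIOR_KIND",
    "Gaussian1D",
    "GaussianMixture1D",
    "LikelihoodParams",
    "PriorParams",
    "ResponseMap",
    "ObserverParams",
    "n_free_parameters",
    "auditory_weight",
    "joint_prior_posterior",
    "mle_posterior",
    "bci_posterior",
    "category_probabilities",
    "predict_condition",
]


class InvalidParameterError(ValueError):
    """A model parameter violates its domain (e.g. non-positive variance)."""


class ConfigurationError(ValueError):
    """An unknown variant, SNR level or condition key was requested."""


class DegeneratePosteriorError(ArithmeticError):
    """The posterior carries essentially no mass on the response interval."""


RESPONSE_CATEGORIES = ("B", "D", "G")

VARIANTS = ("MLE", "ReducedJP", "FullJP", "ReducedBCI", "FullBCI")
VARIANT_PRIOR_KIND = {
    "MLE": "mle",
    "ReducedJP": "joint_prior",
    "FullJP": "joint_prior",
    "ReducedBCI": "bci",
    "FullBCI": "bci",
}


def n_free_parameters(variant: str) -> int:
    """Free parameters fitted per subject: 12 shared (4 category means,
    6 SNR variances, 2 boundaries) plus 0/1/2 prior parameters."""
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}")
    if variant == "MLE":
        return 12
    return 13 if variant.startswith("Reduced") else 14


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gaussian1D:
    """A Gaussian on the place-of-articulation axis."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not (self.variance > 0 and math.isfinite(self.variance)):
            raise InvalidParameterError(f"variance must be positive and finite, got {self.variance}")
        if not math.isfinite(self.mean):
            raise InvalidParameterError(f"mean must be finite, got {self.mean}")


@dataclass(frozen=True)
class GaussianMixture1D:
    """A finite mixture of :class:`Gaussian1D` components."""

    components: tuple[Gaussian1D, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights):
            raise InvalidParameterError("components and weights must have equal length")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise InvalidParameterError("mixture weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise InvalidParameterError(f"mixture weights must sum to 1, got {w.sum()}")


@dataclass(frozen=True)
class LikelihoodParams:
    """Category means and SNR-level variances of the sensory likelihoods.

    ``sigma2_A`` / ``sigma2_V`` map SNR level ("high"/"mid"/"low") to the
    variance of the auditory / visual likelihood; precisions are their
    inverses.  Sensory noise is conditionally independent across modalities,
    so the bimodal likelihood has zero covariance.
    """

    mu_A_B: float
    mu_A_G: float
    mu_V_B: float
    mu_V_G: float
    sigma2_A: Mapping[str, float]
    sigma2_V: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, table in (("sigma2_A", self.sigma2_A), ("sigma2_V", self.sigma2_V)):
            if set(table) != set(SNR_LEVELS):
                raise InvalidParameterError(f"{name} must have exactly the keys {SNR_LEVELS}")
            for level, v in table.items():
                if not (v > 0 and math.isfinite(v)):
                    raise InvalidParameterError(f"{name}[{level!r}] must be positive, got {v}")

    def mean(self, modality: str, consonant: str) -> float:
        key = f"mu_{'A' if modality == 'auditory' else 'V'}_{consonant}"
        return getattr(self, key)

    def variance(self, modality: str, snr: str) -> float:
        table = self.sigma2_A if modality == "auditory" else self.sigma2_V
        try:
            return table[snr]
        except KeyError as exc:
            raise ConfigurationError(f"unknown SNR level {snr!r}") from exc


@dataclass(frozen=True)
class PriorParams:
    """Binding-stage parameters, one per synchrony condition.

    For ``joint_prior`` the values are cross-diagonal prior variances
    ``sigma_o2 >= 0`` (0 = full binding); for ``bci`` they are probabilities
    of separate causes in [0, 1] (0 = full binding).  The ``mle`` kind pins
    both to full binding.
    """

    kind: str
    value_sync: float = 0.0
    value_async: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("mle", "joint_prior", "bci"):
            raise InvalidParameterError(f"unknown prior kind {self.kind!r}")
        for label, v in (("value_sync", self.value_sync), ("value_async", self.value_async)):
            if self.kind == "mle":
                if v != 0.0:
                    raise InvalidParameterError("MLE prior pins both values to full binding (0)")
            elif self.kind == "joint_prior":
                if not (v >= 0 and math.isfinite(v)):
                    raise InvalidParameterError(f"{label} must be a finite variance >= 0, got {v}")
            else:  # bci
                if not 0.0 <= v <= 1.0:
                    raise InvalidParameterError(f"{label} must be a probability in [0, 1], got {v}")

    def value(self, soa: str) -> float:
        if soa == "sync":
            return self.value_sync
        if soa == "async":
            return self.value_async
        raise ConfigurationError(f"unknown SOA {soa!r}")

    @classmethod
    def mle(cls) -> "PriorParams":
        return cls(kind="mle")


@dataclass(frozen=True)
class ResponseMap:
    """Finite response interval and the two category boundaries.

    Mass on [lo, b1] maps to B, (b1, b2] to D and (b2, hi] to G, each
    renormalised by the mass on [lo, hi] (tails outside the interval are
    discarded, not lumped into the end categories).
    """

    b1: float
    b2: float
    interval_lo: float = 0.0
    interval_hi: float = 1.0

    def __post_init__(self) -> None:
        if not self.interval_lo < self.b1 < self.b2 < self.interval_hi:
            raise InvalidParameterError(
                f"boundaries must satisfy lo < b1 < b2 < hi, got "
                f"{self.interval_lo}, {self.b1}, {self.b2}, {self.interval_hi}"
            )


@dataclass(frozen=True)
class ObserverParams:
    """Full parameter set of one model variant for one subject."""

    likelihood: LikelihoodParams
    prior: PriorParams
    response_map: ResponseMap
    variant: str

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        expected_kind = VARIANT_PRIOR_KIND[self.variant]
        if self.prior.kind != expected_kind:
            raise InvalidParameterError(
                f"variant {self.variant} requires prior kind {expected_kind!r}, got {self.prior.kind!r}"
            )
        if self.variant.startswith("Reduced") and self.prior.value_sync != 0.0:
            raise InvalidParameterError("Reduced variants pin the synchronous prior to full binding (0)")

    @property
    def n_free(self) -> int:
        return n_free_parameters(self.variant)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _check_variances(sigma2_A: float, sigma2_V: float) -> None:
    if not (sigma2_A > 0 and math.isfinite(sigma2_A)):
        raise InvalidParameterError(f"auditory variance must be positive, got {sigma2_A}")
    if not (sigma2_V > 0 and math.isfinite(sigma2_V)):
        raise InvalidParameterError(f"visual variance must be positive, got {sigma2_V}")


def auditory_weight(sigma_o2: float, sigma2_A: float, sigma2_V: float) -> float:
    """Weight of the auditory mean in the fused estimate.

    ``w_A = (2*sigma_o2 + sigma2_V) / (2*sigma_o2 + sigma2_V + sigma2_A)``.
    At ``sigma_o2 = 0`` this is the inverse-variance MLE weight; as
    ``sigma_o2`` grows the weight tends to 1 regardless of the sensory
    precisions (full segregation: the report follows the auditory cue).
    """
    if not (sigma_o2 >= 0):
        raise InvalidParameterError(f"prior variance must be >= 0, got {sigma_o2}")
    _check_variances(sigma2_A, sigma2_V)
    coupled = 2.0 * sigma_o2 + sigma2_V
    return coupled / (coupled + sigma2_A)


def joint_prior_posterior(
    mu_A: float, sigma2_A: float, mu_V: float, sigma2_V: float, sigma_o2: float
) -> Gaussian1D:
    """Auditory-axis marginal posterior of the Joint Prior observer.

    Mean ``w_A*mu_A + (1 - w_A)*mu_V`` and variance ``w_A * sigma2_A``, with
    ``w_A`` from :func:`auditory_weight`.
    """
    w_A = auditory_weight(sigma_o2, sigma2_A, sigma2_V)
    return Gaussian1D(mean=w_A * mu_A + (1.0 - w_A) * mu_V, variance=w_A * sigma2_A)


def mle_posterior(mu_A: float, sigma2_A: float, mu_V: float, sigma2_V: float) -> Gaussian1D:
    """Forced-fusion posterior: the Joint Prior posterior at ``sigma_o2 = 0``."""
    return joint_prior_posterior(mu_A, sigma2_A, mu_V, sigma2_V, 0.0)


def bci_posterior(
    mu_A: float, sigma2_A: float, mu_V: float, sigma2_V: float, p_separate: float
) -> GaussianMixture1D:
    """BCI posterior for an auditory report: fusion/segregation mixture.

    Component 1 is the forced-fusion posterior weighted by the common-cause
    probability ``1 - p_separate``; component 2 is the auditory marginal
    ``N(mu_A, sigma2_A)`` weighted by ``p_separate`` (the segregation branch
    of a "what did you hear" report is the auditory likelihood alone).
    """
    if not 0.0 <= p_separate <= 1.0:
        raise InvalidParameterError(f"p_separate must be in [0, 1], got {p_separate}")
    fused = mle_posterior(mu_A, sigma2_A, mu_V, sigma2_V)
    segregated = Gaussian1D(mean=mu_A, variance=sigma2_A)
    return GaussianMixture1D(components=(fused, segregated), weights=(1.0 - p_separate, p_separate))


def _segment_masses(z: np.ndarray) -> np.ndarray:
    """Masses of the standard normal between consecutive cut z-scores.

    Segments entirely in the upper tail are computed from the mirrored CDF
    to avoid the catastrophic cancellation of ``ndtr(z2) - ndtr(z1)`` when
    both values round to 1.
    """
    lower = np.diff(ndtr(z), axis=-1)
    upper = -np.diff(ndtr(-z), axis=-1)
    return np.maximum(np.where(z[..., :-1] > 0, upper, lower), 0.0)


def _gaussian_interval_probs(mean: float, variance: float, rmap: ResponseMap) -> np.ndarray:
    sd = math.sqrt(variance)
    cuts = np.array([rmap.interval_lo, rmap.b1, rmap.b2, rmap.interval_hi])
    masses = _segment_masses((cuts - mean) / sd)
    total = masses.sum()
    if total < 1e-300:
        raise DegeneratePosteriorError(
            f"posterior N({mean}, {variance}) has no mass on the response interval"
        )
    return masses / total


def category_probabilities(
    dist: Union[Gaussian1D, GaussianMixture1D], rmap: ResponseMap
) -> np.ndarray:
    """Map a posterior to response probabilities over (B, D, G).

    Each Gaussian component is truncated to the response interval and
    renormalised; mixtures are the weight-average of their components'
    category probabilities.
    """
    if isinstance(dist, Gaussian1D):
        return _gaussian_interval_probs(dist.mean, dist.variance, rmap)
    if isinstance(dist, GaussianMixture1D):
        out = np.zeros(3)
        for comp, w in zip(dist.components, dist.weights):
            if w > 0:
                out += w * _gaussian_interval_probs(comp.mean, comp.variance, rmap)
        return out
    raise TypeError(f"unsupported distribution type {type(dist).__name__}")


def predict_condition(params: ObserverParams, cond: Condition) -> np.ndarray:
    """Predicted response probabilities over (B, D, G) for one condition.

    Unimodal conditions read out the corresponding unimodal likelihood on the
    shared axis with the shared boundaries; bimodal conditions read out the
    variant's posterior using the prior parameter of the condition's SOA.
    """
    lik = params.likelihood
    rmap = params.response_map
    if cond.modality == "auditory_only":
        dist: Union[Gaussian1D, GaussianMixture1D] = Gaussian1D(
            mean=lik.mean("auditory", cond.auditory_consonant),
            variance=lik.variance("auditory", cond.auditory_snr),
        )
        return category_probabilities(dist, rmap)
    if cond.modality == "visual_only":
        dist = Gaussian1D(
            mean=lik.mean("visual", cond.visual_consonant),
            variance=lik.variance("visual", cond.visual_snr),
        )
        return category_probabilities(dist, rmap)

    mu_A = lik.mean("auditory", cond.auditory_consonant)
    mu_V = lik.mean("visual", cond.visual_consonant)
    s2_A = lik.variance("auditory", cond.auditory_snr)
    s2_V = lik.variance("visual", cond.visual_snr)
    kind = VARIANT_PRIOR_KIND[params.variant]
    if kind == "mle":
        dist = mle_posterior(mu_A, s2_A, mu_V, s2_V)
    elif kind == "joint_prior":
        dist = joint_prior_posterior(mu_A, s2_A, mu_V, s2_V, params.prior.value(cond.soa))
    else:
        dist = bci_posterior(mu_A, s2_A, mu_V, s2_V, params.prior.value(cond.soa))
    return category_probabilities(dist, rmap)
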