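"""Unconstrained parameterization shared by fitting and cohort simulation.

Layout of the free-parameter vector ``z`` (length 12, 13 or 14):

====  ======================================  =========================
slot  parameter                               transform
====  ======================================  =========================
0-3   mu_A_B, mu_A_G, mu_V_B, mu_V_G          logistic into (0, 1)
4-6   sigma2_A at high, mid, low SNR          exp (log-variance)
7-9   sigma2_V at high, mid, low SNR          exp
10    boundary b1                             logistic into (0, 1)
11    boundary gap: b2 = b1 + (1-b1)*s(z)     positive-gap logistic
12+   prior parameters                        log sigma_o2 / logit p
====  ======================================  =========================

MLE has no prior slot; Reduced variants fit only the asynchronous prior
parameter (slot 12); Full variants fit sync (12) and async (13).  The
positive-gap boundary parameterization keeps 0 < b1 < b2 < 1 for any real
``z``, so every unconstrained vector maps to a valid observer.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

from .design import SNR_LEVELS
from .model_core import (
    VARIANT_PRIOR_KIND,
    ConfigurationError,
    LikelihoodParams,
    ObserverParams,
    PriorParams,
    ResponseMap,
    n_free_parameters,
)

# exp() argument clip: keeps variances within [~1e-18, ~1e17] and finite.
_EXP_CLIP = 40.0

_MEAN_NAMES = ("mu_A_B", "mu_A_G", "mu_V_B", "mu_V_G")


def free_parameter_names(variant: str) -> tuple[str, ...]:
    names = list(_MEAN_NAMES)
    names += [f"sigma2_A_{lvl}" for lvl in SNR_LEVELS]
    names += [f"sigma2_V_{lvl}" for lvl in SNR_LEVELS]
    names += ["b1", "b2_gap"]
    kind = VARIANT_PRIOR_KIND[variant]
    if kind != "mle":
        label = "sigma_o2" if kind == "joint_prior" else "p_separate"
        if variant.startswith("Full"):
            names += [f"{label}_sync", f"{label}_async"]
        else:
            names += [f"{label}_async"]
    return tuple(names)


def _safe_exp(z: np.ndarray | float) -> np.ndarray | float:
    return np.exp(np.clip(z, -_EXP_CLIP, _EXP_CLIP))


def unpack_arrays(z: np.ndarray, variant: str):
    """Map an unconstrained vector to raw parameter arrays.

    Returns ``(mu_A, mu_V, s2_A, s2_V, b1, b2, prior_vals)`` where the mean
    and variance arrays are indexed by consonant (B, G) and SNR (high, mid,
    low) and ``prior_vals`` is the (sync, async) pair on the natural scale.
    """
    z = np.asarray(z, dtype=float)
    if z.shape != (n_free_parameters(variant),):
        raise ConfigurationError(
            f"variant {variant} expects {n_free_parameters(variant)} free parameters, got {z.shape}"
        )
    means = expit(z[0:4])
    mu_A = means[0:2]
    mu_V = means[2:4]
    s2_A = _safe_exp(z[4:7])
    s2_V = _safe_exp(z[7:10])
    b1 = expit(z[10])
    b2 = b1 + (1.0 - b1) * expit(z[11])
    kind = VARIANT_PRIOR_KIND[variant]
    if kind == "mle":
        prior_vals = np.zeros(2)
    else:
        raw = _safe_exp(z[12:]) if kind == "joint_prior" else expit(z[12:])
        if variant.startswith("Full"):
            prior_vals = np.asarray(raw, dtype=float)
        else:
            prior_vals = np.array([0.0, float(raw[0])])
    return mu_A, mu_V, s2_A, s2_V, float(b1), float(b2), prior_vals


def unpack(z: np.ndarray, variant: str) -> ObserverParams:
    """Build a validated :class:`ObserverParams` from an unconstrained vector."""
    mu_A, mu_V, s2_A, s2_V, b1, b2, prior_vals = unpack_arrays(z, variant)
    lik = LikelihoodParams(
        mu_A_B=float(mu_A[0]),
        mu_A_G=float(mu_A[1]),
        mu_V_B=float(mu_V[0]),
        mu_V_G=float(mu_V[1]),
        sigma2_A=dict(zip(SNR_LEVELS, map(float, s2_A))),
        sigma2_V=dict(zip(SNR_LEVELS, map(float, s2_V))),
    )
    prior = PriorParams(
        kind=VARIANT_PRIOR_KIND[variant],
        value_sync=float(prior_vals[0]),
        value_async=float(prior_vals[1]),
    )
    return ObserverParams(
        likelihood=lik,
        prior=prior,
        response_map=ResponseMap(b1=b1, b2=b2),
        variant=variant,
    )


def pack(params: ObserverParams) -> np.ndarray:
    """Inverse of :func:`unpack` (free prior parameters must be positive /
    strictly inside (0, 1) so their transforms are defined)."""
    lik = params.likelihood
    rmap = params.response_map
    z = [logit(getattr(lik, name)) for name in _MEAN_NAMES]
    z += [np.log(lik.sigma2_A[lvl]) for lvl in SNR_LEVELS]
    z += [np.log(lik.sigma2_V[lvl]) for lvl in SNR_LEVELS]
    z.append(logit(rmap.b1))
    z.append(logit((rmap.b2 - rmap.b1) / (1.0 - rmap.b1)))
    kind = params.prior.kind
    if kind != "mle":
        values = []
        if params.variant.startswith("Full"):
            values.append(params.prior.value_sync)
        values.append(params.prior.value_async)
        for v in values:
            z.append(np.log(v) if kind == "joint_prior" else logit(v))
    out = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValueError("parameters on the boundary of their domain cannot be packed")
    return out
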