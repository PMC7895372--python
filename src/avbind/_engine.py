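"""Vectorised prediction engine used inside the optimisation loop.

Evaluates all conditions of a design in one shot from raw parameter arrays.
It must agree with :func:`avbind.model_core.predict_condition` to machine
precision; the public per-condition functions remain the reference
implementation and the test suite asserts the equivalence.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from .design import SNR_LEVELS, Design
from .model_core import VARIANT_PRIOR_KIND

_SNR_INDEX = {lvl: i for i, lvl in enumerate(SNR_LEVELS)}
_CONS_INDEX = {"B": 0, "G": 1}


class DesignArrays:
    """Integer index arrays describing a design, precomputed once per fit."""

    __slots__ = (
        "n",
        "uni_rows",
        "uni_modality",  # 0 = auditory, 1 = visual
        "uni_cons",
        "uni_snr",
        "av_rows",
        "av_a_cons",
        "av_v_cons",
        "av_a_snr",
        "av_v_snr",
        "av_soa",
    )

    def __init__(self, design: Design) -> None:
        uni_rows, uni_modality, uni_cons, uni_snr = [], [], [], []
        av_rows, av_a_cons, av_v_cons, av_a_snr, av_v_snr, av_soa = [], [], [], [], [], []
        for i, c in enumerate(design.conditions):
            if c.modality == "auditory_only":
                uni_rows.append(i)
                uni_modality.append(0)
                uni_cons.append(_CONS_INDEX[c.auditory_consonant])
                uni_snr.append(_SNR_INDEX[c.auditory_snr])
            elif c.modality == "visual_only":
                uni_rows.append(i)
                uni_modality.append(1)
                uni_cons.append(_CONS_INDEX[c.visual_consonant])
                uni_snr.append(_SNR_INDEX[c.visual_snr])
            else:
                av_rows.append(i)
                av_a_cons.append(_CONS_INDEX[c.auditory_consonant])
                av_v_cons.append(_CONS_INDEX[c.visual_consonant])
                av_a_snr.append(_SNR_INDEX[c.auditory_snr])
                av_v_snr.append(_SNR_INDEX[c.visual_snr])
                av_soa.append(0 if c.soa == "sync" else 1)
        self.n = len(design.conditions)
        self.uni_rows = np.asarray(uni_rows, dtype=np.intp)
        self.uni_modality = np.asarray(uni_modality, dtype=np.intp)
        self.uni_cons = np.asarray(uni_cons, dtype=np.intp)
        self.uni_snr = np.asarray(uni_snr, dtype=np.intp)
        self.av_rows = np.asarray(av_rows, dtype=np.intp)
        self.av_a_cons = np.asarray(av_a_cons, dtype=np.intp)
        self.av_v_cons = np.asarray(av_v_cons, dtype=np.intp)
        self.av_a_snr = np.asarray(av_a_snr, dtype=np.intp)
        self.av_v_snr = np.asarray(av_v_snr, dtype=np.intp)
        self.av_soa = np.asarray(av_soa, dtype=np.intp)


def _truncated_probs(mean: np.ndarray, var: np.ndarray, b1: float, b2: float) -> np.ndarray:
    """Category masses of N(mean, var) truncated to [0, 1]; shape (k, 3).

    Mirrors model_core._segment_masses: upper-tail segments use the mirrored
    CDF so that distant posteriors keep accurate relative masses.
    """
    sd = np.sqrt(var)
    cuts = np.array([0.0, b1, b2, 1.0])
    z = (cuts[None, :] - mean[:, None]) / sd[:, None]
    lower = np.diff(ndtr(z), axis=1)
    upper = -np.diff(ndtr(-z), axis=1)
    masses = np.maximum(np.where(z[:, :-1] > 0, upper, lower), 0.0)
    total = np.maximum(masses.sum(axis=1), 1e-300)
    return masses / total[:, None]


def predict_design(
    arrays: DesignArrays,
    mu_A: np.ndarray,
    mu_V: np.ndarray,
    s2_A: np.ndarray,
    s2_V: np.ndarray,
    b1: float,
    b2: float,
    variant: str,
    prior_vals: np.ndarray,
) -> np.ndarray:
    """Predicted (n_conditions, 3) category probabilities for a design."""
    out = np.empty((arrays.n, 3))

    if arrays.uni_rows.size:
        mean = np.where(
            arrays.uni_modality == 0, mu_A[arrays.uni_cons], mu_V[arrays.uni_cons]
        )
        var = np.where(
            arrays.uni_modality == 0, s2_A[arrays.uni_snr], s2_V[arrays.uni_snr]
        )
        out[arrays.uni_rows] = _truncated_probs(mean, var, b1, b2)

    if arrays.av_rows.size:
        a_var = s2_A[arrays.av_a_snr]
        v_var = s2_V[arrays.av_v_snr]
        a_mean = mu_A[arrays.av_a_cons]
        v_mean = mu_V[arrays.av_v_cons]
        kind = VARIANT_PRIOR_KIND[variant]
        if kind == "bci":
            w_A = v_var / (v_var + a_var)
            fused = _truncated_probs(w_A * a_mean + (1.0 - w_A) * v_mean, w_A * a_var, b1, b2)
            segregated = _truncated_probs(a_mean, a_var, b1, b2)
            p_sep = prior_vals[arrays.av_soa][:, None]
            out[arrays.av_rows] = (1.0 - p_sep) * fused + p_sep * segregated
        else:
            sigma_o2 = np.zeros_like(a_var) if kind == "mle" else prior_vals[arrays.av_soa]
            coupled = 2.0 * sigma_o2 + v_var
            w_A = coupled / (coupled + a_var)
            out[arrays.av_rows] = _truncated_probs(
                w_A * a_mean + (1.0 - w_A) * v_mean, w_A * a_var, b1, b2
            )
    return out
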