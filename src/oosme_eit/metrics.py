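"""Accuracy metrics: relative accuracy, error ratios and the OO-SME
voltage-change decomposition.

RA (relative accuracy) is the complement of the mean relative conductivity
error over object elements,

    RA = 100 * max(0, 1 - (1/N_o) sum_i |dsigma*_i - dsigma_i| / |dsigma_i|),

clamped to [0, 100]%: a perfect reconstruction scores 100%, an estimate no
better than zero (or with the wrong sign) scores 0%.

The error ratio of a voltage model is the L2-norm ratio 100*||e||/||dU*||
of its approximation error to the measured voltage change.  The component
"ratios" of the OO-SME decomposition are projection coefficients
r_k = <c_k, dU> / <dU, dU>, which sum to exactly 1 whenever
c1 + c2 + c3 = dU holds exactly (true sensitivity change).
"""

from __future__ import annotations

import numpy as np

from .models import oosme_components

__all__ = ["relative_accuracy", "mean_relative_error", "error_ratio",
           "component_ratios"]


def mean_relative_error(dsigma_star, dsigma_true, object_mask) -> float:
    """Mean of |dsigma*_i - dsigma_i| / |dsigma_i| over the object mask."""
    est = np.asarray(dsigma_star, float)
    true = np.asarray(dsigma_true, float)
    mask = np.asarray(object_mask, bool)
    if not mask.any():
        raise ValueError("empty object mask")
    if np.any(true[mask] == 0):
        raise ValueError("true conductivity change vanishes on the object")
    return float(np.mean(np.abs(est[mask] - true[mask]) / np.abs(true[mask])))


def relative_accuracy(dsigma_star, dsigma_true, object_mask) -> float:
    """RA in percent (complement of the mean relative error, clamped)."""
    err = mean_relative_error(dsigma_star, dsigma_true, object_mask)
    return 100.0 * max(0.0, 1.0 - err)


def error_ratio(e, dU, elementwise: bool = False) -> float:
    """Ratio of approximation error to voltage change, in percent.

    Default is the L2-norm ratio 100*||e||/||dU||; ``elementwise=True``
    averages |e_m| / |dU_m| instead.
    """
    e = np.asarray(e, float)
    dU = np.asarray(dU, float)
    if elementwise:
        nz = dU != 0
        return 100.0 * float(np.mean(np.abs(e[nz]) / np.abs(dU[nz])))
    denom = np.linalg.norm(dU)
    if denom == 0:
        raise ValueError("zero voltage change")
    return 100.0 * float(np.linalg.norm(e) / denom)


def component_ratios(S_b, dS, sigma_b, dsigma, dU) -> tuple:
    """Projection coefficients (r1, r2, r3) of the OO-SME components on dU.

    r_k = <c_k, dU> / <dU, dU> with c1 = S_b dsigma, c2 = dS sigma_b,
    c3 = dS dsigma.
    """
    dU = np.asarray(dU, float)
    denom = float(dU @ dU)
    if denom == 0:
        raise ValueError("zero voltage change")
    return tuple(float(c @ dU) / denom
                 for c in oosme_components(S_b, dS, sigma_b, dsigma))
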