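"""Voltage-change approximation models and their approximation error.

Four competing approximations of the measured voltage change dU caused by a
conductivity change dsigma:

* linear:        u = S_b dsigma
* updating:      u = S_b* dsigma, with S_b* recomputed at an updated
                 background sigma_b + dsigma_init
* second-order:  u = (S_b + S_b_dag) dsigma, with S_b_dag the elementwise
                 squares of S_b (the pivots of the row-wise outer products
                 [S_b]_m^T [S_b]_m) standing in for the Hessian
* OO-SME:        u = S_b dsigma + dS sigma_b + dS dsigma

The OO-SME form is an algebraic identity when dS is the true sensitivity
change S_o - S_b, so its approximation error e = dU - u vanishes to solver
precision; the other models carry a model error that no amount of data can
remove.  In reconstruction dS is replaced by an estimate dS* built from a
first-pass linear reconstruction.

The second-order surrogate is implemented verbatim with no scale factor;
its units (squared sensitivity) are inconsistent with S_b, which is part of
why its contribution is small — it is kept as the published baseline.
"""

from __future__ import annotations

import numpy as np

from .forward import ConductivityField
from .sensitivity import SensitivityMatrix

__all__ = [
    "ConductivityField",
    "u_linear",
    "u_updating",
    "estimate_second_order",
    "u_second_order",
    "u_oosme",
    "oosme_components",
    "approximation_error",
]


def _values(S) -> np.ndarray:
    return S.values if isinstance(S, SensitivityMatrix) else np.asarray(S, float)


def _vec(x) -> np.ndarray:
    return x.values if isinstance(x, ConductivityField) else np.asarray(x, float)


def u_linear(S_b, dsigma) -> np.ndarray:
    """Linear model u = S_b dsigma."""
    return _values(S_b) @ _vec(dsigma)


def u_updating(S_b_star, dsigma) -> np.ndarray:
    """Sensitivity-updating model u = S_b* dsigma.

    ``S_b_star`` is the sensitivity matrix recomputed at the updated
    background field sigma_b + dsigma_init (the caller chooses the update).
    """
    return _values(S_b_star) @ _vec(dsigma)


def estimate_second_order(S_b) -> np.ndarray:
    """Second-order surrogate S_b_dag: elementwise squares of S_b.

    Row m holds the diagonal ("pivots") of the rank-1 matrix
    [S_b]_m^T [S_b]_m.
    """
    return _values(S_b) ** 2


def u_second_order(S_b, S_b_dag, dsigma) -> np.ndarray:
    """Second-order sensitivity model u = (S_b + S_b_dag) dsigma."""
    return (_values(S_b) + _values(S_b_dag)) @ _vec(dsigma)


def oosme_components(S_b, dS, sigma_b, dsigma) -> tuple:
    """The three OO-SME components (S_b dsigma, dS sigma_b, dS dsigma)."""
    Sb, dSv = _values(S_b), _values(dS)
    sb, ds = _vec(sigma_b), _vec(dsigma)
    return Sb @ ds, dSv @ sb, dSv @ ds


def u_oosme(S_b, dS, sigma_b, dsigma) -> np.ndarray:
    """OO-SME model u = S_b dsigma + dS sigma_b + dS dsigma."""
    c1, c2, c3 = oosme_components(S_b, dS, sigma_b, dsigma)
    return c1 + c2 + c3


def approximation_error(dU: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Approximation error e = dU - u(dsigma)."""
    dU, u = np.asarray(dU, float), np.asarray(u, float)
    if dU.shape != u.shape:
        raise ValueError("shape mismatch between dU and u")
    return dU - u
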