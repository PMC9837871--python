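"""Sensitivity matrices relating element conductivities to boundary voltages.

For electrode combination m the sensitivity of element e is

    S[m, e] = (1/I) * (grad phi_mc . grad phi_mv) * area_e

where phi_mc is the FEM potential with the stimulation pair driven at
current I and phi_mv the potential with the *measurement* pair driven at the
same current (reciprocal excitation).  With P1 elements both gradients are
constant per element, so the integral over the element is exact.

The matrix satisfies the discrete Green identity S(sigma) . sigma =
U(sigma): row m contracted with the conductivity vector reproduces the
measured voltage exactly (to solver precision), because the measurement
weights equal the load weights of the reciprocal excitation.  This identity
is what makes the decomposition

    dU = S_b dsigma + dS sigma_b + dS dsigma,   dS = S_o - S_b

exact rather than a truncated expansion.  Note S is not the Jacobian
dU/dsigma: differentiating U = S(sigma) sigma also moves S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import ConductivityField, ForwardSolver, element_gradients
from .mesh import Mesh
from .protocol import Protocol

__all__ = ["SensitivityMatrix", "compute_sensitivity", "sensitivity_change",
           "save_sensitivity"]


@dataclass
class SensitivityMatrix:
    """M x N sensitivity matrix (V.m/S) at a reference conductivity."""

    values: np.ndarray
    sigma_ref: ConductivityField
    protocol: Protocol
    current_mA: float

    def __post_init__(self):
        expected = (len(self.protocol), self.sigma_ref.mesh.n_elements)
        if self.values.shape != expected:
            raise ValueError(f"sensitivity shape {self.values.shape} != {expected}")

    @property
    def shape(self):
        return self.values.shape


def compute_sensitivity(mesh: Mesh, sigma: ConductivityField, protocol: Protocol,
                        current_mA: float = 1.0) -> SensitivityMatrix:
    """Assemble S at ``sigma`` from one FEM solve per distinct electrode pair."""
    solver = ForwardSolver(mesh, sigma, current_mA)
    G, areas = element_gradients(mesh)
    tri = mesh.elements

    def grad_field(pair):
        phi = solver.solve_pair(pair).node_potentials
        return np.einsum("eij,ej->ei", G, phi[tri])  # (N, 2)

    grads: dict = {}
    for pair in map(tuple, np.vstack([protocol.combinations[:, :2],
                                      protocol.combinations[:, 2:]])):
        if pair not in grads:
            grads[pair] = grad_field(pair)

    I = current_mA  # mA: with potentials in mV, S . sigma gives U in mV
    S = np.empty((len(protocol), mesh.n_elements))
    for m, (sp, sn, mp, mn) in enumerate(protocol.combinations):
        gc = grads[(sp, sn)]
        gv = grads[(mp, mn)]
        S[m] = (gc * gv).sum(axis=1) * areas / I
    return SensitivityMatrix(S, sigma, protocol, current_mA)


def sensitivity_change(S_b: SensitivityMatrix, S_o: SensitivityMatrix) -> SensitivityMatrix:
    """dS = S_o - S_b (same mesh, protocol and current)."""
    if S_b.shape != S_o.shape:
        raise ValueError("sensitivity shapes differ")
    if not np.array_equal(S_b.protocol.combinations, S_o.protocol.combinations):
        raise ValueError("sensitivities computed for different protocols")
    if S_b.current_mA != S_o.current_mA:
        raise ValueError("sensitivities computed at different currents")
    return SensitivityMatrix(S_o.values - S_b.values, S_b.sigma_ref,
                             S_b.protocol, S_b.current_mA)


def save_sensitivity(S: SensitivityMatrix, path) -> None:
    """Export as Matrix Market (.mtx) or plain CSV, by file extension."""
    path = str(path)
    if path.endswith(".mtx"):
        from scipy.io import mmwrite

        mmwrite(path, S.values)
    else:
        np.savetxt(path, S.values, delimiter=",")
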