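"""Quasi-static FEM forward solver for the disk domain.

Solves the conduction equation  div(sigma grad phi) = 0  with piecewise
linear triangular elements.  Current +I is injected with uniform density
over the positive electrode arc and -I over the negative arc (gap model);
the boundary carries zero Neumann flux elsewhere.  The potential is fixed
by the zero-mean gauge over all nodes — the injected-current boundary value
problem only determines phi up to a constant, and every observable here is
a potential difference, so the gauge is unobservable.

Electrode voltages are read as the boundary-length-weighted mean potential
over the arc nodes.  These weights are exactly the consistent FEM load
weights of a uniform current density on the arc, which makes the discrete
Green identity  S(sigma) . sigma = U(sigma)  hold to machine precision
(see the sensitivity module).

Units: node coordinates are mm (converted to m here), conductivity S/m,
current mA, potentials and voltages mV — the natural units of an
impedance-analyzer front end (mV/mA keeps transfer impedances in Ohms).
In these units boundary voltages are O(1-10) and sensitivity entries O(1),
which is the scale at which the hybrid Noser+Laplace regularizer and the
second-order sensitivity surrogate are balanced.  The 2D model assumes
unit thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import Mesh
from .protocol import Protocol

__all__ = [
    "ConductivityField",
    "PotentialField",
    "MeasurementFrame",
    "ForwardSolver",
    "element_gradients",
    "solve_potentials",
    "measure",
    "voltage_change",
    "save_frame",
    "load_frame",
]


@dataclass
class ConductivityField:
    """Per-element conductivity in S/m bound to a mesh."""

    values: np.ndarray
    mesh: Mesh

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mesh.n_elements,):
            raise ValueError("conductivity length must equal element count")
        if not np.all(self.values > 0):
            raise ValueError("conductivity must be strictly positive")


@dataclass
class PotentialField:
    node_potentials: np.ndarray  # mV, zero mean
    stim_pair: tuple
    current_mA: float
    gauge: str = "zero-mean over all nodes"


@dataclass
class MeasurementFrame:
    """Boundary voltages (mV) aligned with a protocol's combination order."""

    voltages: np.ndarray
    protocol: Protocol
    current_mA: float

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.shape != (len(self.protocol),):
            raise ValueError("frame length must equal protocol size")


def element_gradients(mesh: Mesh):
    """Per-element shape-function gradient operators.

    Returns ``(G, areas_m2)`` where ``G`` has shape (N, 2, 3) in 1/m such
    that the constant gradient of a P1 field ``phi`` on element e is
    ``G[e] @ phi[elements[e]]``, and ``areas_m2`` are element areas in m^2.
    """
    coords = mesh.node_coords * 1e-3  # mm -> m
    p = coords[mesh.elements]  # (N, 3, 2)
    x, y = p[..., 0], p[..., 1]
    areas = mesh.element_areas * 1e-6  # mm^2 -> m^2
    G = np.empty((mesh.n_elements, 2, 3))
    # grad N_i = (y_j - y_k, x_k - x_j) / (2A), (i, j, k) cyclic
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        G[:, 0, i] = (y[:, j] - y[:, k]) / (2 * areas)
        G[:, 1, i] = (x[:, k] - x[:, j]) / (2 * areas)
    return G, areas


def _electrode_weights(mesh: Mesh, electrode: int) -> tuple:
    """(node indices, normalized boundary-length weights) of an arc.

    Trapezoid weights of the arc's boundary segments; identical to the
    consistent P1 load of a uniform current density on the arc.
    """
    nodes = mesh.electrode_nodes[electrode - 1]
    if len(nodes) == 1:
        return nodes, np.array([1.0])
    pts = mesh.node_coords[nodes]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    w = np.zeros(len(nodes))
    w[:-1] += seg / 2
    w[1:] += seg / 2
    return nodes, w / w.sum()


class ForwardSolver:
    """Factorizes the FEM system once and solves many stimulation pairs."""

    def __init__(self, mesh: Mesh, sigma: ConductivityField, current_mA: float = 1.0):
        if sigma.mesh is not mesh:
            raise ValueError("conductivity bound to a different mesh")
        self.mesh = mesh
        self.sigma = sigma
        self.current_mA = float(current_mA)
        self._gradients, self._areas_m2 = element_gradients(mesh)
        self._lu = self._factorize()
        self._cache: dict = {}

    def _factorize(self):
        mesh, G, areas = self.mesh, self._gradients, self._areas_m2
        # local stiffness k_e = sigma_e * A_e * G_e^T G_e  (unit thickness)
        ke = (self.sigma.values * areas)[:, None, None] * np.einsum(
            "eij,eik->ejk", G, G
        )
        tri = mesh.elements
        rows = np.repeat(tri, 3, axis=1).ravel()
        cols = np.tile(tri, (1, 3)).ravel()
        K = sp.coo_matrix(
            (ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
        ).tocsr()
        # ground node 0 to lift the constant nullspace; the load always sums
        # to zero, so grounding only shifts the solution by a constant
        K = K.tolil()
        K[0, :] = 0.0
        K[:, 0] = 0.0
        K[0, 0] = 1.0
        return splu(K.tocsc())

    def load_vector(self, stim_pair: tuple) -> np.ndarray:
        pos, neg = stim_pair
        L = self.mesh.n_electrodes
        if not (1 <= pos <= L and 1 <= neg <= L) or pos == neg:
            raise ValueError("invalid stimulation pair")
        I = self.current_mA * 1e-3  # A
        f = np.zeros(self.mesh.n_nodes)
        n_pos, w_pos = _electrode_weights(self.mesh, pos)
        n_neg, w_neg = _electrode_weights(self.mesh, neg)
        f[n_pos] += I * w_pos
        f[n_neg] -= I * w_neg
        return f

    def solve_pair(self, stim_pair: tuple) -> PotentialField:
        key = tuple(int(e) for e in stim_pair)
        if key not in self._cache:
            f = self.load_vector(key)
            f[0] = 0.0  # grounded node
            phi = self._lu.solve(f) * 1e3  # V -> mV
            phi -= phi.mean()
            self._cache[key] = PotentialField(phi, key, self.current_mA)
        return self._cache[key]

    def electrode_voltage(self, phi: np.ndarray, meas_pair: tuple) -> float:
        """Arc-mean potential difference between a measurement pair."""
        n_pos, w_pos = _electrode_weights(self.mesh, meas_pair[0])
        n_neg, w_neg = _electrode_weights(self.mesh, meas_pair[1])
        return float(w_pos @ phi[n_pos] - w_neg @ phi[n_neg])

    def measure(self, protocol: Protocol) -> MeasurementFrame:
        volts = np.empty(len(protocol))
        for m, (sp_, sn, mp, mn) in enumerate(protocol.combinations):
            phi = self.solve_pair((sp_, sn)).node_potentials
            volts[m] = self.electrode_voltage(phi, (mp, mn))
        return MeasurementFrame(volts, protocol, self.current_mA)


def solve_potentials(mesh: Mesh, sigma: ConductivityField, stim_pair: tuple,
                     current_mA: float = 1.0) -> PotentialField:
    """One-shot potential solve (convenience wrapper over ForwardSolver)."""
    return ForwardSolver(mesh, sigma, current_mA).solve_pair(stim_pair)


def measure(mesh: Mesh, sigma: ConductivityField, protocol: Protocol,
            current_mA: float = 1.0) -> MeasurementFrame:
    """Simulate a full measurement frame (one FEM solve per stim pair)."""
    return ForwardSolver(mesh, sigma, current_mA).measure(protocol)


def voltage_change(frame_b: MeasurementFrame, frame_o: MeasurementFrame) -> np.ndarray:
    """Elementwise voltage change dU = U_o - U_b between two frames."""
    if frame_b.protocol is not frame_o.protocol and not np.array_equal(
        frame_b.protocol.combinations, frame_o.protocol.combinations
    ):
        raise ValueError("frames measured with different protocols")
    if frame_b.current_mA != frame_o.current_mA:
        raise ValueError("frames measured at different currents")
    return frame_o.voltages - frame_b.voltages


def save_frame(frame: MeasurementFrame, path) -> None:
    prot = frame.protocol
    n = prot.n_per_loop
    df = pd.DataFrame(
        prot.combinations,
        columns=["stim_pos", "stim_neg", "meas_pos", "meas_neg"],
    )
    df.insert(0, "loop", np.arange(len(prot)) // n + 1)
    df.insert(1, "index_in_loop", np.arange(len(prot)) % n + 1)
    df["voltage_mV"] = frame.voltages
    df.to_csv(path, index=False)


def load_frame(path, protocol: Protocol, current_mA: float = 1.0) -> MeasurementFrame:
    df = pd.read_csv(path)
    return MeasurementFrame(df["voltage_mV"].to_numpy(float), protocol, current_mA)
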