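"""Regularized least-squares reconstruction of the conductivity change.

The reconstruction minimizes

    || dU - u(dsigma) ||_2^2 + mu^2 || R(dsigma) ||_2^2

with the hybrid prior  ||R(x)||^2 = 0.5 * sum_e w_e x_e^2 + 0.5 * x^T L x,
where w_e is the column energy of the background sensitivity matrix (Noser
weighting, penalizing elements the data constrain strongly) and L is the
graph Laplacian of the element adjacency (penalizing jumps between
edge-sharing triangles).  The minimizer solves the normal equations

    (A^T A + mu^2 (0.5 diag(w) + 0.5 L)) x = A^T rhs

which are solved matrix-free by conjugate gradients from a zero start.

The regularization factor mu balances data fit against noise amplification.
A truncated-SVD argument bounds the noise term of the reconstruction by the
data term when  sigma_1 / mu^2 <= 10^(SNR/20)  with sigma_1 the largest
singular value of the background sensitivity matrix; ``select_mu`` takes
the equality case, mu = sqrt(sigma_1 * 10^(-SNR/20)).

Two-step flow: step 1 reconstructs dsigma_init with the linear model; step
2 re-estimates the model operator at the updated background (per model) and
solves again.  For OO-SME, step 2 solves with operator S_o* = S_b + dS* and
right-hand side dU - dS* sigma_b, which is the regularized least-squares
form of matching dU with S_b dsigma + dS* sigma_b + dS* dsigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .forward import ConductivityField, MeasurementFrame, voltage_change
from .mesh import Mesh
from .protocol import Protocol
from .sensitivity import SensitivityMatrix, compute_sensitivity, sensitivity_change

__all__ = [
    "RegularizerPair",
    "SolverConfig",
    "ReconstructionResult",
    "noser_weights",
    "laplace_operator",
    "laplace_penalty",
    "select_mu",
    "solve_regularized",
    "reconstruct",
    "MODEL_NAMES",
]

MODEL_NAMES = ("linear", "updating", "second_order", "oosme")


def noser_weights(S_b) -> np.ndarray:
    """Noser weights w_e = sum_m S_b[m, e]^2 (column energies of S_b)."""
    values = S_b.values if isinstance(S_b, SensitivityMatrix) else np.asarray(S_b, float)
    return (values**2).sum(axis=0)


def laplace_operator(mesh: Mesh) -> sp.csr_matrix:
    """Graph Laplacian L of the element edge-adjacency (N x N, PSD).

    x^T L x = sum_e sum_{k in adj(e)} x_e (x_e - x_k); boundary elements
    simply have fewer neighbor terms.
    """
    rows, cols, vals = [], [], []
    for e, neigh in enumerate(mesh.element_adjacency):
        rows.append(e)
        cols.append(e)
        vals.append(float(len(neigh)))
        for k in neigh:
            rows.append(e)
            cols.append(k)
            vals.append(-1.0)
    n = mesh.n_elements
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def laplace_penalty(mesh: Mesh, sigma) -> float:
    """Quadratic smoothness penalty sigma^T L sigma."""
    x = sigma.values if isinstance(sigma, ConductivityField) else np.asarray(sigma, float)
    L = laplace_operator(mesh)
    return float(x @ (L @ x))


def select_mu(S_b, snr_db: float) -> float:
    """mu = sqrt(sigma_1 * 10^(-SNR/20)), sigma_1 the top singular value."""
    values = S_b.values if isinstance(S_b, SensitivityMatrix) else np.asarray(S_b, float)
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    sigma1 = float(np.linalg.svd(values, compute_uv=False)[0])
    if sigma1 <= 0:
        raise ValueError("degenerate sensitivity matrix (zero largest singular value)")
    return float(np.sqrt(sigma1 * 10.0 ** (-snr_db / 20.0)))


@dataclass
class RegularizerPair:
    """Hybrid Noser + Laplace prior with fixed 0.5/0.5 mix."""

    noser_weights: np.ndarray
    laplace_operator: sp.spmatrix
    mix: tuple = (0.5, 0.5)

    @classmethod
    def from_background(cls, S_b: SensitivityMatrix, mesh: Mesh) -> "RegularizerPair":
        return cls(noser_weights(S_b), laplace_operator(mesh))

    def apply(self, x: np.ndarray) -> np.ndarray:
        a, b = self.mix
        return a * self.noser_weights * x + b * (self.laplace_operator @ x)


@dataclass
class SolverConfig:
    mu: float | str = "auto"           # regularization factor, or "auto" from SNR
    snr_db: float = 40.0               # SNR used for mu selection (and noise)
    cg_tol: float = 1e-8               # relative residual stopping tolerance
    cg_max_iter: int = 500
    step2_iterations: int = 1
    sigma_floor: float = 1e-4          # S/m, floor for updated backgrounds
    seed: int = 0


@dataclass
class ReconstructionResult:
    dsigma_init: np.ndarray
    dsigma_updated: np.ndarray | None
    model_name: str
    residual_norms: list = field(default_factory=list)  # per step: array over CG iters
    functional_values: list = field(default_factory=list)
    mu_used: float = np.nan
    iterations_used: list = field(default_factory=list)
    S_step2: SensitivityMatrix | None = None  # updated matrix (updating/oosme)

    @property
    def dsigma(self) -> np.ndarray:
        """Final estimate: step-2 result when present, else step 1."""
        return self.dsigma_init if self.dsigma_updated is None else self.dsigma_updated


def solve_regularized(A, rhs: np.ndarray, reg: RegularizerPair, mu: float,
                      config: SolverConfig | None = None):
    """CG on the regularized normal equations; returns (x, info dict).

    ``info`` holds per-iteration residual norms ||A^T rhs - H x_k|| and the
    functional values 0.5 x^T H x - x^T A^T rhs (monotone under CG), plus
    the iteration count and a convergence flag.
    """
    if config is None:
        config = SolverConfig()
    if mu <= 0:
        raise ValueError("mu must be positive")
    Av = A.values if isinstance(A, SensitivityMatrix) else np.asarray(A, float)
    rhs = np.asarray(rhs, float)
    if Av.shape[0] != rhs.shape[0]:
        raise ValueError("operator / rhs shape mismatch")

    mu2 = mu**2

    def H(x):
        return Av.T @ (Av @ x) + mu2 * reg.apply(x)

    b = Av.T @ rhs
    x = np.zeros(Av.shape[1])
    r = b.copy()
    p = r.copy()
    rs = r @ r
    b_norm = np.sqrt(rs)
    residuals = [b_norm]
    functionals = [0.0]
    n_iter = 0
    if b_norm > 0:
        for k in range(config.cg_max_iter):
            Hp = H(p)
            alpha = rs / (p @ Hp)
            x += alpha * p
            r -= alpha * Hp
            rs_new = r @ r
            residuals.append(np.sqrt(rs_new))
            functionals.append(0.5 * x @ H(x) - x @ b)
            n_iter = k + 1
            if np.sqrt(rs_new) <= config.cg_tol * b_norm:
                break
            p = r + (rs_new / rs) * p
            rs = rs_new
    converged = residuals[-1] <= config.cg_tol * b_norm or b_norm == 0
    if not converged:
        warnings.warn(
            f"CG stopped at {n_iter} iterations with relative residual "
            f"{residuals[-1] / b_norm:.2e}", RuntimeWarning)
    info = {
        "residual_norms": np.array(residuals),
        "functional_values": np.array(functionals),
        "iterations": n_iter,
        "converged": converged,
    }
    return x, info


def reconstruct(model: str, frame_b: MeasurementFrame, frame_o: MeasurementFrame,
                mesh: Mesh, sigma_b: ConductivityField, protocol: Protocol,
                config: SolverConfig | None = None, dU: np.ndarray | None = None,
                S_b: SensitivityMatrix | None = None) -> ReconstructionResult:
    """Two-step reconstruction of dsigma with the chosen model.

    Parameters
    ----------
    model : one of ``linear``, ``updating``, ``second_order``, ``oosme``.
    dU : optional measured voltage change overriding ``frame_o - frame_b``
        (use this to feed a noisy voltage change).
    S_b : optional precomputed background sensitivity (reused across models).
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    if config is None:
        config = SolverConfig()
    if dU is None:
        dU = voltage_change(frame_b, frame_o)
    if S_b is None:
        S_b = compute_sensitivity(mesh, sigma_b, protocol, frame_b.current_mA)

    reg = RegularizerPair.from_background(S_b, mesh)
    mu = select_mu(S_b, config.snr_db) if config.mu == "auto" else float(config.mu)

    result = ReconstructionResult(None, None, model, mu_used=mu)

    def solve(A, rhs):
        x, info = solve_regularized(A, rhs, reg, mu, config)
        result.residual_norms.append(info["residual_norms"])
        result.functional_values.append(info["functional_values"])
        result.iterations_used.append(info["iterations"])
        return x

    # Step 1: linear first pass.  The first-order voltage response to a
    # conductivity increase is a voltage decrease, so the Taylor-based
    # models (linear, updating, second-order) reconstruct with the
    # Jacobian-signed operator -S; the OO-SME step is an exact algebraic
    # identity in S itself and keeps the positive sign.
    dsigma = solve(-S_b.values, dU)
    result.dsigma_init = dsigma

    if model == "linear":
        return result

    current = frame_b.current_mA
    for _ in range(config.step2_iterations):
        updated = np.maximum(sigma_b.values + dsigma, config.sigma_floor)
        sigma_upd = ConductivityField(updated, mesh)
        if model == "second_order":
            from .models import estimate_second_order

            A = S_b.values + estimate_second_order(S_b)
            dsigma = solve(-A, dU)
        elif model == "updating":
            S_b_star = compute_sensitivity(mesh, sigma_upd, protocol, current)
            result.S_step2 = S_b_star
            dsigma = solve(-S_b_star.values, dU)
        else:  # oosme
            # Self-consistent OO-SME update.  With dS* re-estimated at the
            # current iterate, the model voltage change
            # S_b x + dS* sigma_b + dS* x equals the exact FEM change
            # U(sigma_b + x) - U(sigma_b) (Green identity applied twice), so
            # matching it to dU is the data-consistent subproblem.  Its
            # first-order response about the iterate is -S_o* dx, which
            # gives, in the total variable x:
            #   minimize || S_o* x - (S_o*(x_k + sigma_o*) - U_b - dU) ||^2
            #            + mu^2 ||R(x)||^2.
            S_o_star = compute_sensitivity(mesh, sigma_upd, protocol, current)
            result.S_step2 = S_o_star
            x_k = sigma_upd.values - sigma_b.values  # after flooring
            rhs = S_o_star.values @ (x_k + sigma_upd.values) - frame_b.voltages - dU
            dsigma = solve(S_o_star.values, rhs)
    result.dsigma_updated = dsigma
    return result
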