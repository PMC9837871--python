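"""Regularizers, mu selection, CG solver and the two-step reconstruction."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from oosme_eit import (ConductivityField, ForwardSolver, Mesh,
                       laplace_operator, laplace_penalty, noser_weights,
                       reconstruct, relative_accuracy, select_mu,
                       solve_regularized, voltage_change)
from oosme_eit.inversion import RegularizerPair, SolverConfig
from oosme_eit.phantoms import make_phantom, phantom_preset


def two_element_mesh():
    """Two triangles sharing an edge (unit square split on the diagonal)."""
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    elements = np.array([[0, 1, 2], [0, 2, 3]])
    return Mesh(coords, elements, [np.array([0]), np.array([2])], 1.0)


def test_noser_weights_toy():
    S = np.array([[1.0, 0.0], [2.0, 1.0], [0.0, 2.0]])
    assert np.allclose(noser_weights(S), [5.0, 5.0])
    assert noser_weights(np.zeros((3, 2)))[0] == 0.0


def test_laplace_two_elements():
    mesh = two_element_mesh()
    a, b = 0.7, 0.2
    assert laplace_penalty(mesh, np.array([a, b])) == pytest.approx((a - b) ** 2)
    assert laplace_penalty(mesh, np.array([3.0, 3.0])) == pytest.approx(0.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_laplace_psd(mesh_tiny, seed):
    x = np.random.default_rng(seed).standard_normal(mesh_tiny.n_elements)
    assert laplace_penalty(mesh_tiny, x) >= -1e-9 * (x @ x)


def test_laplace_constant_field_zero(mesh_tiny):
    assert laplace_penalty(mesh_tiny, np.full(mesh_tiny.n_elements, 2.5)) == \
        pytest.approx(0.0, abs=1e-9)


def test_select_mu_closed_form():
    S = np.diag([4.0, 1.0])
    assert select_mu(S, 40.0) == pytest.approx(0.2)
    assert select_mu(S, 0.0) == pytest.approx(2.0)
    assert select_mu(S, 80.0) < select_mu(S, 40.0)  # mu -> 0 as SNR -> inf
    with pytest.raises(ValueError):
        select_mu(np.zeros((2, 2)), 40.0)


def _toy_regularizer(n, seed=0):
    rng = np.random.default_rng(seed)
    w = 0.1 + rng.random(n)
    main = np.full(n, 2.0)
    main[[0, -1]] = 1.0
    L = sp.diags([main, -np.ones(n - 1), -np.ones(n - 1)], [0, -1, 1]).tocsr()
    return RegularizerPair(w, L)


def test_cg_matches_dense_direct_solve():
    """CG on the normal equations vs an explicit factorization, 20 unknowns."""
    rng = np.random.default_rng(3)
    A = rng.standard_normal((12, 20))
    b = rng.standard_normal(12)
    reg = _toy_regularizer(20)
    mu = 0.3
    x, info = solve_regularized(A, b, reg, mu, SolverConfig(cg_tol=1e-12))
    H = A.T @ A + mu**2 * (0.5 * np.diag(reg.noser_weights)
                           + 0.5 * reg.laplace_operator.toarray())
    x_direct = np.linalg.solve(H, A.T @ b)
    assert np.linalg.norm(x - x_direct) <= 1e-8 * np.linalg.norm(x_direct)
    assert info["converged"]


def test_cg_zero_rhs_gives_zero():
    reg = _toy_regularizer(20)
    x, info = solve_regularized(np.eye(20), np.zeros(20), reg, 1.0)
    assert np.all(x == 0.0) and info["iterations"] == 0


def test_solution_shrinks_with_mu():
    rng = np.random.default_rng(5)
    A = rng.standard_normal((15, 30))
    b = rng.standard_normal(15)
    reg = _toy_regularizer(30, seed=1)
    norms = [np.linalg.norm(solve_regularized(A, b, reg, mu)[0])
             for mu in (0.1, 1.0, 10.0, 100.0)]
    assert all(n1 > n2 for n1, n2 in zip(norms, norms[1:]))


def test_cg_functional_monotone():
    rng = np.random.default_rng(6)
    A = rng.standard_normal((30, 60))
    b = rng.standard_normal(30)
    _, info = solve_regularized(A, b, _toy_regularizer(60, 2), 0.5)
    f = info["functional_values"]
    assert np.all(np.diff(f) <= 1e-12 * max(1.0, np.abs(f).max()))
    assert info["residual_norms"][-1] < info["residual_norms"][0]


def test_invalid_mu_rejected():
    reg = _toy_regularizer(4)
    with pytest.raises(ValueError):
        solve_regularized(np.eye(4), np.ones(4), reg, 0.0)


@pytest.fixture(scope="module")
def phantom_frames(mesh_small, sigma_bg_small, protocol_qa16, frame_bg_small):
    _, sigma_o, mask = make_phantom(mesh_small, phantom_preset(1))
    frame_o = ForwardSolver(mesh_small, sigma_o).measure(protocol_qa16)
    dsigma = sigma_o.values - sigma_bg_small.values
    return frame_o, dsigma, mask


@pytest.mark.parametrize("model", ["linear", "updating", "second_order", "oosme"])
def test_zero_voltage_change_gives_zero_image(model, mesh_small, sigma_bg_small,
                                              protocol_qa16, frame_bg_small,
                                              S_bg_small):
    res = reconstruct(model, frame_bg_small, frame_bg_small, mesh_small,
                      sigma_bg_small, protocol_qa16, SolverConfig(),
                      S_b=S_bg_small)
    assert np.linalg.norm(res.dsigma) <= 1e-6


def test_unknown_model_rejected(mesh_small, sigma_bg_small, protocol_qa16,
                                frame_bg_small):
    with pytest.raises(ValueError):
        reconstruct("bogus", frame_bg_small, frame_bg_small, mesh_small,
                    sigma_bg_small, protocol_qa16)


def test_oosme_step2_is_linear_solve_with_shifted_data(
        mesh_small, sigma_bg_small, protocol_qa16, frame_bg_small, S_bg_small,
        phantom_frames):
    """The step-2 system equals a plain solve with S_o* and shifted rhs."""
    frame_o, _, _ = phantom_frames
    cfg = SolverConfig()
    res = reconstruct("oosme", frame_bg_small, frame_o, mesh_small,
                      sigma_bg_small, protocol_qa16, cfg, S_b=S_bg_small)
    dU = voltage_change(frame_bg_small, frame_o)
    reg = RegularizerPair.from_background(S_bg_small, mesh_small)
    x_k = np.maximum(sigma_bg_small.values + res.dsigma_init, cfg.sigma_floor) \
        - sigma_bg_small.values
    S_o_star = res.S_step2
    rhs = S_o_star.values @ (x_k + sigma_bg_small.values + x_k) \
        - frame_bg_small.voltages - dU
    x, _ = solve_regularized(S_o_star.values, rhs, reg, res.mu_used, cfg)
    assert np.linalg.norm(x - res.dsigma_updated) <= 1e-10 * np.linalg.norm(x)


def test_oosme_second_step_improves_on_first(
        mesh_small, sigma_bg_small, protocol_qa16, frame_bg_small, S_bg_small,
        phantom_frames):
    """Noiseless single-circle phantom: the OO-SME update raises RA."""
    frame_o, dsigma_true, mask = phantom_frames
    res = reconstruct("oosme", frame_bg_small, frame_o, mesh_small,
                      sigma_bg_small, protocol_qa16, SolverConfig(),
                      S_b=S_bg_small)
    ra1 = relative_accuracy(res.dsigma_init, dsigma_true, mask)
    ra2 = relative_accuracy(res.dsigma_updated, dsigma_true, mask)
    assert ra2 > ra1


def test_reconstruction_deterministic(mesh_small, sigma_bg_small, protocol_qa16,
                                      frame_bg_small, S_bg_small, phantom_frames):
    frame_o, _, _ = phantom_frames
    a = reconstruct("linear", frame_bg_small, frame_o, mesh_small,
                    sigma_bg_small, protocol_qa16, S_b=S_bg_small)
    b = reconstruct("linear", frame_bg_small, frame_o, mesh_small,
                    sigma_bg_small, protocol_qa16, S_b=S_bg_small)
    assert np.array_equal(a.dsigma, b.dsigma)
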