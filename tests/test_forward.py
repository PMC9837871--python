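"""FEM forward solver: conservation, symmetries, analytic disk oracle."""

import numpy as np
import pytest

from oosme_eit import (ConductivityField, ForwardSolver, MeasurementFrame,
                       build_disk_mesh, build_protocol, solve_potentials,
                       voltage_change)


@pytest.fixture(scope="module")
def homog_tiny(mesh_tiny):
    return ConductivityField(np.full(mesh_tiny.n_elements, 0.05), mesh_tiny)


def test_current_linearity(mesh_tiny, homog_tiny):
    p1 = solve_potentials(mesh_tiny, homog_tiny, (1, 4), 1.0).node_potentials
    p2 = solve_potentials(mesh_tiny, homog_tiny, (1, 4), 2.0).node_potentials
    assert np.allclose(p2, 2 * p1, rtol=1e-12, atol=1e-12)


def test_stim_swap_negates_field(mesh_tiny, homog_tiny):
    p = solve_potentials(mesh_tiny, homog_tiny, (2, 6), 1.0).node_potentials
    q = solve_potentials(mesh_tiny, homog_tiny, (6, 2), 1.0).node_potentials
    assert np.allclose(q, -p, rtol=1e-10, atol=1e-12)


def test_conductivity_scaling(mesh_tiny, homog_tiny, protocol_adj8):
    u1 = ForwardSolver(mesh_tiny, homog_tiny).measure(protocol_adj8).voltages
    sk = ConductivityField(3.0 * homog_tiny.values, mesh_tiny)
    u3 = ForwardSolver(mesh_tiny, sk).measure(protocol_adj8).voltages
    assert np.allclose(u3, u1 / 3.0, rtol=1e-10)


def test_load_vector_conserves_current(mesh_tiny, homog_tiny):
    solver = ForwardSolver(mesh_tiny, homog_tiny)
    f = solver.load_vector((3, 7))
    assert abs(f.sum()) < 1e-12 * solver.current_mA


def test_zero_mean_gauge(mesh_tiny, homog_tiny):
    phi = solve_potentials(mesh_tiny, homog_tiny, (1, 5)).node_potentials
    assert abs(phi.mean()) < 1e-12 * np.abs(phi).max()
    assert np.all(np.isfinite(phi))


def test_reciprocity(mesh_small, sigma_bg_small, protocol_qa16, frame_bg_small):
    """Swapping stimulation and measurement pairs reproduces the voltage."""
    v = frame_bg_small.voltages
    scale = np.abs(v).max()
    for i, j in protocol_qa16.reciprocal_pairs():
        assert abs(v[i] - v[j]) <= 1e-8 * scale


def test_homogeneous_loops_rotationally_symmetric(frame_bg_small, protocol_qa16):
    """All 16 loops show the same 13-voltage pattern up to rotation."""
    combos = protocol_qa16.combinations
    L, per = 16, protocol_qa16.n_per_loop
    aligned = np.empty((L, per))
    for l in range(L):
        idx = slice(l * per, (l + 1) * per)
        rel = (combos[idx, 2] - combos[idx, 0]) % L
        aligned[l] = frame_bg_small.voltages[idx][np.argsort(rel)]
    dev = np.abs(aligned - aligned.mean(axis=0)).max() / np.abs(aligned).max()
    assert dev < 0.01


def test_boundary_potential_matches_analytic_disk():
    """Narrow-arc FEM solution vs superposed boundary log-potentials.

    A point current source on the boundary of a homogeneous disk has the
    closed-form potential phi = (I / (pi sigma)) ln(|z - z_sink|/|z - z_src|)
    (unit thickness).  Compared at boundary nodes at least two electrode
    pitches away from either electrode.
    """
    mesh = build_disk_mesh(100.0, 16, 3000, refinement_seed=5,
                           electrode_coverage=0.08)
    sigma = 0.05
    field = solve_potentials(
        mesh, ConductivityField(np.full(mesh.n_elements, sigma), mesh), (1, 9), 1.0)
    R = mesh.diameter / 2
    z_src = R * np.array([1.0, 0.0])
    z_snk = R * np.array([-1.0, 0.0])
    r = np.linalg.norm(mesh.node_coords, axis=1)
    boundary = np.where(r > 0.999 * R)[0]
    ang = np.arctan2(mesh.node_coords[boundary, 1], mesh.node_coords[boundary, 0])
    pitch = 2 * np.pi / 16
    far = (np.abs(np.angle(np.exp(1j * ang))) >= 2 * pitch) & (
        np.abs(np.angle(np.exp(1j * (ang - np.pi)))) >= 2 * pitch)
    nodes = boundary[far]
    d_src = np.linalg.norm(mesh.node_coords[nodes] - z_src, axis=1)
    d_snk = np.linalg.norm(mesh.node_coords[nodes] - z_snk, axis=1)
    phi_an = 1e3 * (1e-3 / (np.pi * sigma)) * np.log(d_snk / d_src)  # mV
    phi_fem = field.node_potentials[nodes]
    phi_an -= phi_an.mean()
    phi_fem -= phi_fem.mean()
    assert np.abs(phi_fem - phi_an).max() <= 0.03 * np.abs(phi_an).max()


def test_nonpositive_conductivity_rejected(mesh_tiny):
    with pytest.raises(ValueError):
        ConductivityField(np.zeros(mesh_tiny.n_elements), mesh_tiny)


def test_voltage_change_basics(frame_bg_small, protocol_qa16):
    assert np.allclose(voltage_change(frame_bg_small, frame_bg_small), 0.0)
    shifted = MeasurementFrame(frame_bg_small.voltages + 0.5, protocol_qa16,
                               frame_bg_small.current_mA)
    assert np.allclose(voltage_change(frame_bg_small, shifted), 0.5)
    other = MeasurementFrame(frame_bg_small.voltages, protocol_qa16, 2.0)
    with pytest.raises(ValueError):
        voltage_change(frame_bg_small, other)
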