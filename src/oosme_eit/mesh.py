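"""Triangulated disk domain with boundary electrode arcs.

The domain is a circular tank of diameter ``d`` discretized into linear
triangles, with ``L`` electrodes evenly spaced on the circumference.  Each
electrode is modelled as an arc of boundary nodes (gap model: current enters
through the arc, there is no contact impedance and no electrode metal in the
mesh).  Node coordinates are stored in millimetres; conversion to SI happens
inside the forward solver.

The triangulation is built from structured concentric rings of points passed
through a Delaunay triangulation.  Ring point counts grow linearly with
radius so triangle quality stays high, and the outermost ring is a multiple
of the electrode count so that every electrode arc is sampled identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["Mesh", "build_disk_mesh", "save_mesh", "load_mesh"]


@dataclass
class Mesh:
    """Triangulated disk with electrode arcs.

    Attributes
    ----------
    node_coords : (P, 2) float array, mm
    elements : (N, 3) int array
        Node indices (0-based, counter-clockwise orientation).
    electrode_nodes : list of int arrays
        For each of the L electrodes, the boundary node indices of its arc,
        ordered counter-clockwise.  Electrode 1 is centred on the positive
        x-axis; electrodes are numbered counter-clockwise.
    diameter : float, mm
    """

    node_coords: np.ndarray
    elements: np.ndarray
    electrode_nodes: list
    diameter: float
    element_areas: np.ndarray = field(default=None, repr=False)  # mm^2
    element_adjacency: list = field(default=None, repr=False)

    def __post_init__(self):
        if self.element_areas is None:
            self.element_areas = _triangle_areas(self.node_coords, self.elements)
        if self.element_adjacency is None:
            self.element_adjacency = _edge_adjacency(self.elements)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_nodes)

    def element_centroids(self) -> np.ndarray:
        """(N, 2) centroid coordinates in mm."""
        return self.node_coords[self.elements].mean(axis=1)


def _triangle_areas(coords: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p = coords[elements]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])


def _edge_adjacency(elements: np.ndarray) -> list:
    """Per-element list of edge-sharing neighbour element indices."""
    edge_map: dict = {}
    for ei, tri in enumerate(elements):
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (a, b) if a < b else (b, a)
            edge_map.setdefault(key, []).append(ei)
    adj = [[] for _ in range(len(elements))]
    for elems in edge_map.values():
        if len(elems) == 2:
            a, b = elems
            adj[a].append(b)
            adj[b].append(a)
    return [sorted(x) for x in adj]


def build_disk_mesh(
    diameter_mm: float,
    n_electrodes: int,
    target_elements: int,
    refinement_seed: int = 0,
    electrode_coverage: float = 0.5,
) -> Mesh:
    """Build a triangulated disk with ``n_electrodes`` boundary arcs.

    Parameters
    ----------
    diameter_mm : disk diameter in mm.
    n_electrodes : number of electrodes (even, >= 4), evenly spaced.
    target_elements : requested triangle count; the realized count is within
        25% of this.
    refinement_seed : seed for the small deterministic jitter applied to
        interior points (breaks Delaunay degeneracies; boundary nodes are
        never moved).
    electrode_coverage : fraction of the inter-electrode pitch covered by
        each arc (default 0.5, i.e. arc width equals half the pitch).
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    if n_electrodes < 4 or n_electrodes % 2:
        raise ValueError("need an even number of electrodes, at least 4")
    if target_elements < 10 * n_electrodes:
        raise ValueError("target_elements too small for this electrode count")
    if not 0 < electrode_coverage <= 1:
        raise ValueError("electrode_coverage must be in (0, 1]")

    radius = diameter_mm / 2.0
    n_rings = max(2, int(round(np.sqrt(target_elements / 6.0))))
    # outer ring count: multiple of L, near 6*n_rings for equilateral-ish cells
    per_pitch = max(2, int(round(6.0 * n_rings / n_electrodes)))
    n_boundary = n_electrodes * per_pitch

    rng = np.random.default_rng(refinement_seed)
    pts = [np.zeros((1, 2))]
    for k in range(1, n_rings + 1):
        r = radius * k / n_rings
        if k == n_rings:
            nk = n_boundary
        else:
            nk = max(6, int(round(n_boundary * k / n_rings)))
        theta = 2 * np.pi * np.arange(nk) / nk
        ring = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        if k < n_rings:
            # jitter interior rings by a small fraction of the local spacing
            spacing = 2 * np.pi * r / nk
            ring += 0.10 * spacing * rng.uniform(-1, 1, size=ring.shape)
        pts.append(ring)
    coords = np.vstack(pts)

    tri = Delaunay(coords)
    elements = tri.simplices.copy()
    # enforce counter-clockwise orientation
    areas = _triangle_areas(coords, elements)
    flip = areas < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]
    areas = np.abs(areas)
    keep = areas > 1e-12 * radius**2
    elements = elements[keep]
    areas = areas[keep]

    # boundary nodes are the last n_boundary points, at exact angles 2*pi*j/n_b
    boundary_idx = np.arange(len(coords) - n_boundary, len(coords))
    boundary_angles = np.mod(
        np.arctan2(coords[boundary_idx, 1], coords[boundary_idx, 0]), 2 * np.pi
    )
    pitch = 2 * np.pi / n_electrodes
    half_arc = 0.5 * electrode_coverage * pitch
    electrode_nodes = []
    for l in range(n_electrodes):
        center = l * pitch
        delta = np.angle(np.exp(1j * (boundary_angles - center)))
        sel = np.abs(delta) <= half_arc + 1e-9
        order = np.argsort(delta[sel])
        electrode_nodes.append(boundary_idx[sel][order])

    mesh = Mesh(coords, elements, electrode_nodes, float(diameter_mm),
                element_areas=areas)
    if not (0.75 * target_elements <= mesh.n_elements <= 1.25 * target_elements):
        raise ValueError(
            f"realized element count {mesh.n_elements} not within 25% of "
            f"target {target_elements}"
        )
    return mesh


def save_mesh(mesh: Mesh, path) -> None:
    """Write a mesh as plain text (1-based indices).

    Line formats: ``node id x y``, ``element id n1 n2 n3``,
    ``electrode el_id node ids...``, plus a ``diameter`` header line.
    """
    with open(path, "w") as fh:
        fh.write(f"diameter {mesh.diameter:.17g}\n")
        for i, (x, y) in enumerate(mesh.node_coords, start=1):
            fh.write(f"node {i} {x:.17g} {y:.17g}\n")
        for i, (a, b, c) in enumerate(mesh.elements, start=1):
            fh.write(f"element {i} {a + 1} {b + 1} {c + 1}\n")
        for l, nodes in enumerate(mesh.electrode_nodes, start=1):
            ids = " ".join(str(n + 1) for n in nodes)
            fh.write(f"electrode {l} {ids}\n")


def load_mesh(path) -> Mesh:
    nodes, elements, electrodes, diameter = [], [], {}, None
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            tag = parts[0]
            if tag == "diameter":
                diameter = float(parts[1])
            elif tag == "node":
                nodes.append((float(parts[2]), float(parts[3])))
            elif tag == "element":
                elements.append([int(p) - 1 for p in parts[2:5]])
            elif tag == "electrode":
                electrodes[int(parts[1])] = np.array(
                    [int(p) - 1 for p in parts[2:]], dtype=int
                )
    electrode_nodes = [electrodes[k] for k in sorted(electrodes)]
    return Mesh(np.asarray(nodes), np.asarray(elements, dtype=int),
                electrode_nodes, diameter)
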