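"""Conductivity phantoms and noise models for the simulation study.

The study conditions mimic a fat/lean-meat tissue phantom: a homogeneous
fat background at 0.021 S/m with lean-meat inclusions at 0.267 S/m (values
at 100 Hz), i.e. a conductivity step of 0.246 S/m.  Four presets provide
circular inclusions whose diameters are fixed fractions (0.32, 0.27, 0.34,
0.18) of the tank diameter; positions are package choices since only the
sizes are standardized.

Two noise sources are modelled:

* conductivity inhomogeneity: an additive uniform perturbation of up to a
  given fraction (default 20%) of the conductivity step, applied to a
  random subset (default 40%) of elements of the object field;
* measurement noise: Gaussian white noise added to the voltage change,
  rescaled so its maximum magnitude is 10^(-SNR/20) of the maximum
  background voltage (a max-amplitude, not an RMS, convention).

``estimate_snr`` inverts the measurement-noise model from data alone using
reciprocity: a combination and its reciprocal measure the same transfer
voltage, so half their difference estimates the noise and their mean the
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import ConductivityField, MeasurementFrame
from .mesh import Mesh
from .protocol import Protocol

__all__ = [
    "CircleObject",
    "PhantomSpec",
    "NoiseSpec",
    "phantom_preset",
    "make_phantom",
    "add_conductivity_noise",
    "add_measurement_noise",
    "estimate_snr",
    "SIGMA_FAT",
    "SIGMA_LEAN",
]

SIGMA_FAT = 0.021   # S/m, fat background at 100 Hz
SIGMA_LEAN = 0.267  # S/m, lean meat object at 100 Hz


@dataclass(frozen=True)
class CircleObject:
    """Circular inclusion; center and diameter as fractions of tank diameter."""

    cx: float
    cy: float
    diameter: float


@dataclass
class PhantomSpec:
    objects: list
    sigma_background: float = SIGMA_FAT
    sigma_object: float = SIGMA_LEAN
    preset: int | None = None

    @property
    def dsigma_mag(self) -> float:
        return self.sigma_object - self.sigma_background


# Circular approximations of the four standard object layouts; diameters are
# the standardized fractions a=0.32, b=0.27, c=0.34, e=0.18 of the tank
# diameter, positions chosen to keep each object well inside the boundary.
_PRESETS = {
    1: [CircleObject(0.20, 0.00, 0.32)],
    2: [CircleObject(-0.18, 0.15, 0.27)],
    3: [CircleObject(0.00, -0.18, 0.34)],
    4: [CircleObject(0.22, 0.12, 0.18), CircleObject(-0.20, -0.10, 0.27)],
}


def phantom_preset(preset: int) -> PhantomSpec:
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset}; choose from {sorted(_PRESETS)}")
    return PhantomSpec(list(_PRESETS[preset]), preset=preset)


@dataclass
class NoiseSpec:
    """Noise conditions of the simulation study."""

    cond_fraction: float = 0.4    # fraction of elements perturbed
    cond_magnitude: float = 0.2   # perturbation bound as fraction of |dsigma|
    snr_db: float = 40.0          # measurement SNR in dB
    cond_seed: int = 0
    meas_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.cond_fraction <= 1 and 0 <= self.cond_magnitude <= 1):
            raise ValueError("noise fractions must lie in [0, 1]")


def make_phantom(mesh: Mesh, spec: PhantomSpec):
    """Build (sigma_b, sigma_o, object_mask) on a mesh.

    The background field is constant; elements whose centroid falls inside
    any object circle take the object conductivity.
    """
    d = mesh.diameter
    for obj in spec.objects:
        if np.hypot(obj.cx, obj.cy) + obj.diameter / 2 >= 0.5:
            raise ValueError(f"object {obj} extends outside the disk")
    centroids = mesh.element_centroids()
    mask = np.zeros(mesh.n_elements, dtype=bool)
    for obj in spec.objects:
        center = np.array([obj.cx * d, obj.cy * d])
        r = obj.diameter * d / 2
        mask |= np.linalg.norm(centroids - center, axis=1) <= r
    sigma_b = np.full(mesh.n_elements, spec.sigma_background)
    sigma_o = sigma_b.copy()
    sigma_o[mask] = spec.sigma_object
    return (ConductivityField(sigma_b, mesh), ConductivityField(sigma_o, mesh), mask)


def add_conductivity_noise(sigma_o: ConductivityField, dsigma_mag: float,
                           fraction: float = 0.4, magnitude: float = 0.2,
                           seed: int = 0, floor: float = 1e-4) -> ConductivityField:
    """Perturb a random subset of elements by uniform conductivity noise.

    ``floor(fraction * N)`` elements, chosen without replacement, receive an
    additive perturbation drawn uniformly from
    [-magnitude * dsigma_mag, +magnitude * dsigma_mag]; the result is floored
    at ``floor`` S/m to keep the field strictly positive.
    """
    if not (0 <= fraction <= 1 and 0 <= magnitude <= 1):
        raise ValueError("fraction and magnitude must lie in [0, 1]")
    values = sigma_o.values.copy()
    n_perturb = int(np.floor(fraction * len(values)))
    if n_perturb and magnitude > 0:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(values), size=n_perturb, replace=False)
        values[idx] += rng.uniform(-magnitude * dsigma_mag,
                                   magnitude * dsigma_mag, size=n_perturb)
        values = np.maximum(values, floor)
    return ConductivityField(values, sigma_o.mesh)


def add_measurement_noise(frame_b: MeasurementFrame, dU: np.ndarray,
                          snr_db: float, seed: int = 0) -> np.ndarray:
    """Noisy voltage change dU* = dU + noise with max-amplitude SNR scaling.

    Gaussian white noise is rescaled so max|noise| equals
    10^(-snr_db/20) * max|U_b|.  An infinite SNR returns dU unchanged.
    """
    dU = np.asarray(dU, float)
    if np.isinf(snr_db):
        return dU.copy()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(dU))
    target_max = 10.0 ** (-snr_db / 20.0) * np.max(np.abs(frame_b.voltages))
    noise *= target_max / np.max(np.abs(noise))
    return dU + noise


def estimate_snr(frame: MeasurementFrame, protocol: Protocol) -> float:
    """Reciprocity-based SNR estimate in dB.

    For every reciprocal combination pair, noise = half the voltage
    difference and signal = the mean; the SNR is the average of
    20*log10(|signal| / |noise|) over pairs with nonzero noise.  Returns
    ``inf`` for a perfectly reciprocal (noise-free) frame.
    """
    pairs = protocol.reciprocal_pairs()
    if not pairs:
        raise ValueError("protocol contains no reciprocal combination pairs")
    v = frame.voltages
    ratios = []
    scale = np.abs(v).max()
    for i, j in pairs:
        noise = 0.5 * abs(v[i] - v[j])
        signal = 0.5 * abs(v[i] + v[j])
        # differences at float round-off are solver noise, not measurement noise
        if noise > 1e-12 * scale:
            ratios.append(20.0 * np.log10(signal / noise))
    if not ratios:
        return np.inf
    return float(np.mean(ratios))
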