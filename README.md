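# oosme-eit

2D electrical impedance tomography (EIT) with **object-oriented sensitivity
matrix estimation (OO-SME)**: a full simulation-and-reconstruction stack for
quantifying conductive inclusions (e.g. lean meat or muscle in a fat
background) from boundary voltage measurements on a 16-electrode circular
tank.

EIT reconstructs the conductivity change Δσ inside a domain from the change
ΔU of boundary voltages. The standard linear model approximates the voltage
change as u(Δσ) = S<sup>b</sup>Δσ with the background sensitivity matrix
S<sup>b</sup>, which at high contrast carries an approximation error of
several hundred percent of ΔU. The OO-SME model instead uses the exact
discrete identity

> ΔU = S<sup>b</sup>Δσ + ΔS σ<sup>b</sup> + ΔS Δσ,  ΔS = S<sup>o</sup> − S<sup>b</sup>,

where S<sup>o</sup> is the sensitivity matrix of the object field. Because
S(σ)·σ = U(σ) holds exactly for the piecewise-linear FEM discretization
(verified to machine precision in the tests), this decomposition has **zero**
model error when ΔS is known; reconstruction estimates ΔS from a first-pass
linear image and solves a second regularized least-squares problem.

The package provides:

- `mesh` / `protocol` — triangulated disk domains (d = 100 mm, 16 electrode
  arcs) and quasi-adjacent stimulation/measurement protocols
  (16 loops × 13 = 208 combinations);
- `forward` — sparse FEM solver for ∇·(σ∇φ) = 0 with gap-model current
  injection; voltages in mV at mA drive;
- `sensitivity` — S(σ) from reciprocal excitations, exact Green identity;
- `models` — the four voltage-change approximations (linear,
  sensitivity-updating, second-order, OO-SME) and their errors e = ΔU − u;
- `inversion` — hybrid Noser + Laplace regularized least squares minimized
  by conjugate gradients, SNR-based choice of the regularization factor μ,
  and the two-step reconstruction flow;
- `phantoms` — fat/lean conductivity phantoms (0.021 / 0.267 S/m),
  conductivity inhomogeneity noise, SNR-controlled measurement noise, and
  reciprocity-based SNR estimation;
- `metrics` / `experiment` — relative accuracy (RA), error ratios, the
  three-component decomposition, and a batch experiment driver;
- a thin CLI: `oosme-eit simulate|reconstruct|evaluate`.

## Worked example

`examples/03_reconstruct_models.py` simulates a single-circle lean-meat
phantom (diameter 0.32 d) with conductivity noise (20% of Δσ on 40% of
elements) and 40 dB measurement noise, then reconstructs with all four
models:

```
      linear: RA = 10.91 %  (mu = 1.842, CG iterations = [322])
second_order: RA = 19.06 %  (mu = 1.842, CG iterations = [322, 500])
    updating: RA = 19.39 %  (mu = 1.842, CG iterations = [322, 398])
       oosme: RA = 15.43 %  (mu = 1.842, CG iterations = [322, 396])
```

RA is the complement of the mean relative conductivity error over the
object elements: 100% is a perfect quantitative reconstruction, 0% a total
miss. The one-step linear model only localizes the object; the two-step
models recover noticeably more of its amplitude. `examples/02_sensitivity_identity.py`
prints the exact decomposition: the linear component alone projects onto ΔU
with coefficient ≈ −7, i.e. it overshoots the measured change several-fold
with the wrong sign, while the three OO-SME components sum to ΔU exactly —
the reason the ΔS terms are indispensable at a 12× conductivity contrast.

Each example is a short narrative script; run them as
`python examples/01_forward_simulation.py` etc.

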