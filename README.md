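# densefit

Lagrangian displacement and strain analysis for cine DENSE cardiac MRI.

## The problem

DENSE (Displacement ENcoding with Stimulated Echoes) encodes absolute tissue
displacement into the MRI signal phase: after unwrapping, the phase of every
myocardial pixel in every cine frame is an independent measurement of the
**Eulerian** displacement of whatever tissue currently occupies that pixel,
relative to the reference configuration at the ECG R-wave
(`displacement = phase / (2π·ke)`, with `ke` the encoding frequency in
cycles/mm). Cardiologists, however, need **Lagrangian** quantities — the
path of each material point of myocardium through the cardiac cycle — from
which the finite strain tensor, circumferential strain (Ecc) curves, and
diastolic-function metrics are derived.

`densefit` reconstructs the Lagrangian trajectory field `L_f` on the
reference-mask pixel lattice by solving, frame by frame,

```
argmin_{L_f}  ‖A L_f − E_f‖² + ‖λ B L_f‖² + ‖μ (L_f − L_{f−1})‖² ,   L_0 = 0
```

where `E_f` are the measured Eulerian displacements, `A` is the sparse
bilinear interpolation matrix evaluating the nodal field at the
back-projected measurement locations `X_p = p − E_f(p)`, and `B` stacks
second-difference stencils along each axis. The three terms enforce data
fidelity, spatial smoothness, and temporal smoothness — no through-time
motion model. Stacking gives `Â = [A; λB; μI]`, `Ê_f = [E_f; 0; μL_{f−1}]`
and the closed-form least-squares solution `L_f = (ÂᵀÂ)⁻¹ÂᵀÊ_f`, followed by
a three-frame moving-mean filter. The package also implements the prior
**two-step** method as a comparator (per-frame spatial solve with `μ = 0`,
then an ordinary least-squares fit of each node's trajectory to a 10th-order
polynomial or 5th-order Fourier basis), the full strain pipeline
(`F = ∂x/∂X`, `E = ½(FᵀF − I)`, polar rotation to Err/Ecc, strain rate,
PEDSR and diastasis strain rate), evaluation metrics (MAPE against the raw
Eulerian data, ground-truth RMSE, error-injection recovery), and a synthetic
cine DENSE phantom — an incompressible contracting/twisting annulus with a
cardiac-like activation profile and exact analytic ground truth — so the
whole pipeline is testable without clinical data.

## Worked example

```bash
python examples/02_solve_and_compare.py
```

```
calibrated weights: lambda = 11.6, mu = 0.03
RSTLS     RMSE vs truth 0.063 mm | MAPE x 0.124, y 0.128 (fraction of measured displacement, pixels with |E| >= 0.1 mm)
two-step  RMSE vs truth 0.115 mm | MAPE x 0.156, y 0.157 (fraction of measured displacement, pixels with |E| >= 0.1 mm)
```

On a noisy phantom (phase noise 0.05 rad ≈ 0.08 mm per measurement) the
spatiotemporal solve halves the trajectory error against the known ground
truth and agrees better with the raw Eulerian measurements (lower MAPE) than
the two-step method. The diastolic consequences:

```bash
python examples/03_strain_and_diastole.py
```

```
RSTLS     end-systolic Ecc -0.1218 | PEDSR 1.093 1/s | diastasis |rate| 0.019 1/s
two-step  end-systolic Ecc -0.1216 | PEDSR 0.977 1/s | diastasis |rate| 0.074 1/s
analytic  end-systolic Ecc -0.1245 | PEDSR 1.167 1/s | diastasis |rate| 0.000 1/s (flat plateau by construction)
```

Both methods capture end-systolic strain, but the polynomial fit of the
two-step method undershoots the peak early diastolic strain rate (its
through-time model rounds off the sharp E-wave) and reports spurious strain
rate during diastasis, where the true curve is flat — the model-driven
oscillation artifact. `examples/01_simulate_phantom.py` and
`examples/04_error_injection.py` demonstrate the simulator and the
self-correction property (an injected 50% perpendicular measurement error
perturbs the trajectory by well under the error magnitude and vanishes
within a frame).

A thin CLI mirrors the library:

```bash
densefit simulate --out run/          # phantom stack + ground truth
densefit solve --input run/phantom --out run/traj.csv
densefit strain --trajectories run/traj.csv --tr 15 --out run/curves.csv
densefit pipeline --method twostep --out run2/   # end-to-end with manifest
```

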