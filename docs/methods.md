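# Methods

## Displacement model and solver

Cine DENSE phase data give, for every myocardial pixel `p` of every frame
`f`, the Eulerian displacement `E_f(p)` of the tissue currently at `p`
(displacement = phase / (2π·ke); segmentation and phase unwrapping are
assumed done upstream and are out of scope). The unknown is the Lagrangian
displacement field `L_f` sampled at the pixel centers of the *reference*
(frame-0) mask — the node set. The material-point identity
`E_f(p) = L_f(p − E_f(p))` links the two descriptions: the tissue now at `p`
started at the back-projected point `X_p = p − E_f(p)`. Each frame is solved
as

    argmin_L ‖A L − E_f‖² + ‖λ B L‖² + ‖μ (L − L_{f−1})‖²

* `A` (rows = measurements) holds the bilinear weights of the ≤4 nodes of
  the reference cell containing each `X_p`, so `A L` predicts the measured
  data. At mask boundaries, weights are renormalized over the valid corners
  (preserving the partition of unity, hence exactness for constant fields);
  a measurement whose cell contains no node is dropped and counted in the
  per-frame diagnostics.
* `B` (rows = stencils) stacks the 1-D second difference `[1, −2, 1]/h²`
  along x and along y, one row per node whose two axis neighbors lie on the
  mask. Boundary rows are omitted rather than one-sided, to avoid biased
  curvature penalties at edges; solvability is guaranteed by the `μI` block
  regardless.
* The temporal term uses the one-sided difference `L_f − L_{f−1}` (a central
  difference would destroy the frame-by-frame closed form and require an
  iterative solve). `L_0 = 0`: frame 0 is the displacement-encoding
  reference, and the containers pin it to zero exactly — so strain at frame
  0 is exactly zero under any noise level.

Frames 1…F−1 are solved sequentially, rebuilding `A` from each frame's own
measurements; the two encoding directions share the operators and are solved
independently (two right-hand sides through one factorization). The normal
equations `(ÂᵀÂ)L = ÂᵀÊ` are solved with a sparse LU factorization (the
matrix is symmetric positive definite for μ > 0); an iterative least-squares
(LSMR) fallback guards against a failed factorization. A three-frame
moving-mean filter in time (truncated windows at the sequence ends, frame 0
re-pinned to zero) is applied as a final denoising step.

The two-step comparator solves each frame with μ = 0 (minimum-norm LSMR
solution, since `[A; λB]` can be rank deficient — the curvature operator
annihilates affine fields), then replaces each node's trajectory with an
ordinary least-squares fit of a through-time model: polynomial of order 10
(default) or Fourier basis of order 5. Time is normalized to [0, 1] to keep
the order-10 Vandermonde tractable, and the frame-0 zero sample is included
as a data point (a soft zero constraint, identical across both basis
families).

## Regularization weights

`λ` multiplies an operator carrying `1/h²`, so the package default
`λ = 0.01·h²` (h = pixel spacing in mm) makes the effective curvature
penalty independent of pixel size; `μ = 0.1` is the default temporal weight.
These are starting points, not optima. The recommended procedure — and what
`densefit.evaluate.calibrate_weights` automates — is to simulate DENSE data
with known motion (the phantom), run the solver over a coarse logarithmic
grid (λ ∈ 0.01h²·{1, 10, 100}, μ ∈ {0.03, 0.1, 0.3}), and keep the pair
minimizing trajectory RMSE against ground truth. On the default phantom this
selects λ ≈ 11.6, μ = 0.03 and improves noiseless recovery from ≈5% to ≈1%
of peak displacement. The phantom experiments in the tests and acceptance
script use the calibrated weights, with the two-step comparator given the
same λ so the comparison isolates the temporal treatment.

## Phantom

The synthetic phantom is an annulus (endocardial radius 20 mm, epicardial
33 mm at rest) on a 64×64 grid of 3.4 mm pixels, undergoing the polar map

    r(t) = sqrt(r² − a(t)·c),  θ(t) = θ + a(t)·twist,  c = (2β − β²)·r_endo²

— area-preserving by construction (det F = 1 exactly), with the constant `c`
chosen so the endocardial radius shrinks by exactly the fraction β at peak
activation. Defaults: β = 0.25 and 8° twist, giving peak endocardial
excursion ≈5 mm, global Ecc ≈ −0.125 and PEDSR ≈ 1.2 s⁻¹ — healthy
mid-ventricular short-axis values. An optional rigid translation (default
off) supports translation-only test cases without breaking incompressibility.
The activation `a(t)` is a chain of cubic smoothsteps over 40 frames at
TR = 15 ms: rise 0→1 over systole (frames 0–14), E-wave fall to a diastasis
plateau of 0.25 (frames 14–22), a flat plateau (frames 22–34), and an atrial
kick down to 0.05. The sharp E-wave and flat plateau are deliberate: they
are exactly the features a through-time polynomial distorts, so they
discriminate the two solvers.

Masks: a pixel belongs to frame t's mask iff its center lies inside the
deformed annulus; the reference mask is the frame-0 mask. Measurements are
`p − inverse_motion_map(p, t)` (the inverse is analytic, so the data are
exact samples of the true field), plus Gaussian noise of standard deviation
`σ_phase/(2π·ke)` mm applied independently per pixel, direction, and frame —
defining σ in phase units (default 0.05 rad) keeps its meaning constant
across encoding frequencies (default ke = 0.1 cycles/mm, one of the two
standard acquisition values). Everything is driven by one seed;
regeneration is bit-identical.

What the phantom does **not** emulate: through-plane motion, regional wall
heterogeneity, signal magnitude and T1/T2 effects, phase wrapping, spiral
k-space sampling, view sharing, and segmentation error. Passing tests
therefore demonstrate correctness of the estimation pipeline under the
stated motion and noise model, not clinical performance.

## Strain pipeline

Deformed positions are `x = X + L`. The deformation gradient at each node is
the least-squares fit of `dx ≈ F dX` over the node's mask neighbors within a
1-node radius (up to 8 neighbors); nodes whose neighbor offsets span fewer
than two independent directions are excluded from strain maps. On the exact
phantom field this estimator's interior-node error is <0.5% at 3.4 mm
spacing. Then `E = ½(FᵀF − I)` (zero for any rigid motion), rotated to polar
components about the ventricular center (default: reference-mask centroid;
the phantom tests pass the true center) using the angle of each node's
*reference* position — E is a referential tensor, so a referential rotation
keeps the pipeline consistent. The rotation is the basis change whose first
row is the radial unit vector, so `E_polar[0,0] = Err` and
`E_polar[1,1] = Ecc`; conjugating with the rotation of the opposite sign
would swap the roles, a convention pitfall caught by checking against the
phantom's analytic principal directions (radial stretch `r/r(t) > 1`,
circumferential `r(t)/r < 1`).

Global and segmental curves are mean Ecc over member nodes (N equal angular
sectors, default 6, counterclockwise from a configurable reference angle).
Strain rate is the first difference of Ecc over TR, reported in s⁻¹. PEDSR
is the maximum (positive) rate in the early-diastolic window after end
systole; diastasis strain rate is the mean |rate| over the diastasis window.
End systole defaults to the global-Ecc minimum, early diastole to the next
25% of remaining frames, diastasis up to the final 15% of the sequence — all
overridable, and the phantom experiments pass the activation breakpoints
explicitly.

## Evaluation

MAPE per frame and direction is `(1/n)Σ|E_i − (A L)_i|/|E_i|` over pixels
with `|E_i| ≥ ε` (default ε = 0.1 mm, reported with every result): the
measured displacement is near zero in early systole and late diastole, where
the ratio is undefined in practice; excluded pixels are counted. MAPE is
reported as a fraction. The error-injection experiment adds a vector
perpendicular (counterclockwise by default) to one pixel's measurement at
50% of its magnitude and measures how many frames the affected node's
trajectory stays more than a tolerance away from the clean solution — the
self-correction property that per-frame data fidelity confers.

## Numerical choices and limitations

* Problem sizes: the default phantom has 188 nodes × 40 frames; a full
  two-method comparison over ten noise seeds runs in seconds on one core.
* The near-square per-frame system (≈190 measurements for 188 nodes) makes
  the solution sensitive to λ; with weak regularization, bilinear
  interpolation error amplifies into node-scale oscillation.
* Representing a curved displacement field by bilinear interpolation on
  3.4 mm pixels floors the *solved-field* deformation-gradient error at
  ≈2.5–3% (interior nodes, any weights), even when trajectory RMSE is ≈1% of
  peak; the gradient estimator itself is an order of magnitude better on the
  exact field. Finer pixels or a higher-order interpolant (out of scope)
  would lower this floor.
* Strain is 2D in-plane; no 3D extension, no torsion metrics, no AHA
  17-segment mapping.
* The moving-mean filter slightly attenuates sharp temporal features
  (≈4–6% of the analytic PEDSR at TR = 15 ms, together with the discrete
  sampling of the rate); this is the price of its noise suppression and is
  visible in the acceptance numbers.
* With very high noise the μ-anchored sequential solve can underperform the
  heavily-smoothing two-step method; the comparisons here are at 0.05 rad
  phase noise, a realistic level for the stated acquisition.
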