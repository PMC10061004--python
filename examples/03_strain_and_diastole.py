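"""Circumferential strain curves and diastolic function metrics.

Computes the Lagrangian finite strain tensor from the solved trajectories,
rotates it to the short-axis polar frame (Err radial, Ecc circumferential),
aggregates global Ecc and strain-rate curves, and extracts the peak early
diastolic strain rate (PEDSR) and the strain rate during diastasis — the two
metrics where through-time model fitting distorts diastole.
"""

import numpy as np

import densefit as df
from densefit.strain import DiastolicWindows, diastolic_metrics

spec = df.PhantomSpec(seed=1)
truth = df.generate_ground_truth(spec)
series, masks = df.generate_eulerian_series(spec, truth)
nodes = df.NodeSet.from_mask(masks[0], spec.spacing)
lam, mu = 11.56, 0.03  # see 02_solve_and_compare.py for the calibration

windows = DiastolicWindows(
    spec.end_systole_frame, spec.end_ewave_frame, spec.end_diastasis_frame
)
results = {}
for name, traj in (
    ("RSTLS", df.solve_sequence(series, nodes, df.SolverConfig(lam=lam, mu=mu))),
    ("two-step", df.solve_two_step(series, nodes, lam=lam)),
):
    field = df.compute_strain_field(traj, nodes, center=spec.center_xy)
    curves = df.aggregate_curves(field, spec.tr_ms, n_segments=6)
    m = diastolic_metrics(curves.global_ecc, spec.tr_ms, windows)
    results[name] = (field, m)
    print(f"{name:9s} end-systolic Ecc {m.end_systolic_strain:+.4f} | "
          f"PEDSR {m.pedsr:.3f} 1/s | diastasis |rate| {m.diastasis_rate:.3f} 1/s")

# analytic reference: Ecc = -a(t) c / (2 r^2), differentiated at fine steps
field = results["RSTLS"][0]
r = np.linalg.norm(truth.positions[field.valid] - spec.center_xy, axis=-1)
tf = np.linspace(0, (spec.n_frames - 1) * spec.tr_ms, 20001)
af = df.phantom.activation_continuous(spec, tf)
ecc = (-af[:, None] * spec.contraction_constant / (2 * r[None, :] ** 2)).mean(axis=1)
rate = np.diff(ecc) / np.diff(tf) * 1000
sel = (tf[:-1] >= windows.end_systole * spec.tr_ms) & (tf[:-1] <= windows.end_ewave * spec.tr_ms)
print(f"analytic  end-systolic Ecc {ecc.min():+.4f} | PEDSR {rate[sel].max():.3f} 1/s | "
      "diastasis |rate| 0.000 1/s (flat plateau by construction)")
# The two-step method underestimates PEDSR (the E-wave is oversmoothed by the
# polynomial) and reports spurious strain rate during diastasis (model-driven
# oscillation on a flat segment); the spatiotemporal solve tracks both.
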