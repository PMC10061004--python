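"""Self-correction: a corrupted measurement does not propagate.

Adds an error vector perpendicular to one pixel's Eulerian displacement
(50% of its magnitude) in a single frame, re-runs the spatiotemporal solve,
and tracks how far the affected material point's trajectory deviates from
the clean solution — because every frame re-enforces fidelity with its own
measurements, the deviation dies out instead of accumulating.
"""

import numpy as np

import densefit as df

spec = df.PhantomSpec(seed=1)
truth = df.generate_ground_truth(spec)
series, masks = df.generate_eulerian_series(spec, truth)
nodes = df.NodeSet.from_mask(masks[0], spec.spacing)
cfg = df.SolverConfig(lam=11.56, mu=0.03)
clean = df.solve_sequence(series, nodes, cfg)
peak = np.linalg.norm(truth.disp, axis=-1).max()

for label, frame in (("mid-systole", 7), ("diastole", 30)):
    mags = np.linalg.norm(series.frames[frame].disp, axis=1)
    pixel = int(np.argmax(mags))
    corrupted = df.inject_error(series, frame, pixel, fraction=0.5)
    corrupt = df.solve_sequence(corrupted, nodes, cfg)
    Xp = df.back_project(series.frames[frame])[pixel]
    node = int(np.argmin(np.linalg.norm(nodes.positions - Xp, axis=1)))
    res = df.recovery_profile(clean, corrupt, node, frame, tol=0.1 * peak)
    print(f"{label:12s} injected {0.5 * mags[pixel]:.2f} mm error at frame {frame}: "
          f"max trajectory deviation {res.deviation.max():.3f} mm, "
          f"back within {res.tol:.2f} mm after {res.recovery_frames} frame(s)")
# The deviation stays far below the injected error magnitude (the frame's
# other ~190 measurements and the smoothness penalties absorb it) and the
# trajectory rejoins its clean form immediately after the corrupted frame.
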