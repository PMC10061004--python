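"""Two-step comparator: spatial-only solve, then a through-time model fit.

This is the prior approach to Lagrangian displacement estimation from cine
DENSE phase data: each frame is first solved independently with data
fidelity and spatial regularization only (the spatiotemporal objective with
mu = 0), and each node's trajectory is then replaced by an ordinary least
squares fit of a through-time model — a 10th-order polynomial by default, or
a 5th-order Fourier basis.  Imposing such a temporal model tends to
over-smooth abrupt features (post-systolic shortening, the E-wave) and to
introduce model-driven oscillations during diastasis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .containers import EulerianSeries, LagrangianTrajectories
from .operators import NodeSet, back_project, build_interp_matrix, build_second_derivative
from .rstls import assemble_augmented, default_lambda

__all__ = ["TimeModelConfig", "solve_spatial_only", "fit_through_time", "solve_two_step"]


@dataclass(frozen=True)
class TimeModelConfig:
    """Through-time model family and order.

    ``family`` is "polynomial" (default order 10) or "fourier" (order 5
    harmonics over the cine duration); ``zero_at_t0`` includes the frame-0
    zero-displacement sample as a data point of the fit.
    """

    family: str = "polynomial"
    order: int | None = None
    zero_at_t0: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("polynomial", "fourier"):
            raise ValueError(f"unknown model family '{self.family}'")
        if self.order is not None and self.order < 1:
            raise ValueError(f"model order must be >= 1, got {self.order}")

    @property
    def resolved_order(self) -> int:
        if self.order is not None:
            return self.order
        return 10 if self.family == "polynomial" else 5


def solve_spatial_only(
    series: EulerianSeries,
    nodes: NodeSet,
    lam: float | None = None,
    min_measurements: int = 10,
) -> LagrangianTrajectories:
    """Per-frame spatially regularized solve (mu = 0), frames independent.

    Each frame minimizes ``||A L - E||^2 + ||lambda B L||^2`` on its own.
    Without the temporal identity block the stacked operator can be rank
    deficient (the curvature operator annihilates affine fields), so the
    minimum-norm least-squares solution is returned via LSMR and any frame
    whose residual system is rank deficient is flagged in the diagnostics.
    """
    F = series.n_frames
    n = nodes.n
    lam = default_lambda(nodes.spacing) if lam is None else lam
    B = build_second_derivative(nodes).matrix

    disp = np.zeros((F, n, 2))
    diagnostics = []
    for f in range(1, F):
        frame = series.frames[f]
        if frame.n == 0:
            raise ValueError(f"frame {f} has no measurements")
        points = back_project(frame)
        A_op = build_interp_matrix(nodes, points)
        m = A_op.matrix.shape[0]
        if m < min_measurements:
            raise ValueError(
                f"frame {f} has only {m} usable measurement rows (minimum {min_measurements})"
            )
        E_f = frame.disp[A_op.row_source]
        system = assemble_augmented(A_op.matrix, B, lam, 0.0, E_f, np.zeros((n, 2)))
        # drop the zero-weight mu block entirely: stack [A; lam B] only
        A_hat = system.A_hat[: m + B.shape[0]]
        E_hat = system.E_hat[: m + B.shape[0]]
        sol = np.empty((n, 2))
        deficient = False
        for k in range(2):
            res = spla.lsmr(A_hat, E_hat[:, k], atol=1e-12, btol=1e-12, maxiter=8 * n)
            sol[:, k] = res[0]
            deficient = deficient or res[1] == 0
        disp[f] = sol
        diagnostics.append({"frame": f, "rows": m, "dropped": A_op.n_dropped, "rank_flag": deficient})

    return LagrangianTrajectories(
        disp=disp,
        ref_positions=nodes.positions,
        times_ms=series.enc.frame_times_ms,
        diagnostics=diagnostics,
    )


def _design_matrix(cfg: TimeModelConfig, t_norm: np.ndarray) -> np.ndarray:
    order = cfg.resolved_order
    if cfg.family == "polynomial":
        return np.vander(t_norm, order + 1, increasing=True)
    cols = [np.ones_like(t_norm)]
    for k in range(1, order + 1):
        cols.append(np.sin(2 * np.pi * k * t_norm))
        cols.append(np.cos(2 * np.pi * k * t_norm))
    return np.column_stack(cols)


def fit_through_time(
    traj: LagrangianTrajectories, cfg: TimeModelConfig = TimeModelConfig()
) -> LagrangianTrajectories:
    """Replace each node's trajectory by its through-time model fit.

    Per node and direction an ordinary least squares fit over all frames
    (time normalized to [0, 1] for conditioning; the frame-0 zero sample is
    included as data when ``zero_at_t0``).  Frame 0 of the returned
    trajectories remains exactly zero — it is the reference configuration.
    """
    F = traj.n_frames
    dof = cfg.resolved_order + 1 if cfg.family == "polynomial" else 2 * cfg.resolved_order + 1
    if dof >= F:
        raise ValueError(
            f"model with {dof} degrees of freedom needs more than {F} frames"
        )
    t_norm = traj.times_ms / traj.times_ms[-1]
    fit_rows = np.arange(F) if cfg.zero_at_t0 else np.arange(1, F)
    X = _design_matrix(cfg, t_norm[fit_rows])
    X_all = _design_matrix(cfg, t_norm)

    flat = traj.disp[fit_rows].reshape(fit_rows.size, -1)  # (frames, n*2)
    coef, *_ = np.linalg.lstsq(X, flat, rcond=None)
    fitted = (X_all @ coef).reshape(F, traj.n_points, 2)
    fitted[0] = 0.0
    return LagrangianTrajectories(
        disp=fitted,
        ref_positions=traj.ref_positions,
        times_ms=traj.times_ms,
        point_ids=traj.point_ids,
        diagnostics=traj.diagnostics,
    )


def solve_two_step(
    series: EulerianSeries,
    nodes: NodeSet,
    lam: float | None = None,
    model: TimeModelConfig = TimeModelConfig(),
) -> LagrangianTrajectories:
    """The full comparator pipeline: spatial-only solve, then time fitting.

    Exactly ``fit_through_time(solve_spatial_only(...))`` — there is no
    hidden coupling between the two steps.
    """
    return fit_through_time(solve_spatial_only(series, nodes, lam=lam), cfg=model)
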