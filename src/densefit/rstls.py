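"""Regularized spatiotemporal least squares (RSTLS) displacement solver.

Each cine frame ``f`` is solved for the nodal Lagrangian displacement field
``L_f`` by minimizing

    || A L_f - E_f ||^2  +  || lambda B L_f ||^2  +  || mu (L_f - L_{f-1}) ||^2

where ``A`` interpolates the nodal field to the back-projected measurement
locations, ``E_f`` holds the measured Eulerian displacements, ``B`` is the
second-derivative (curvature) operator, and the third term anchors the
solution softly to the previous frame (one-sided first-order temporal
difference, which keeps the problem a single linear least squares per
frame).  Stacking gives the augmented system

    A_hat = [A; lambda B; mu I],   E_hat_f = [E_f; 0; mu L_{f-1}]

with ``L_0 = 0`` (no Lagrangian displacement before the first frame), solved
sequentially for f = 1..F-1 via the normal equations
``L_f = (A_hat^T A_hat)^-1 A_hat^T E_hat_f``; with mu > 0 the system always
has full column rank.  Both encoding directions share the same operators and
are solved independently.  As a final denoising step a three-frame moving
mean filter is applied in time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .containers import EulerianSeries, LagrangianTrajectories
from .operators import NodeSet, back_project, build_interp_matrix, build_second_derivative

__all__ = [
    "SolverConfig",
    "AugmentedSystem",
    "RankDeficientError",
    "default_lambda",
    "assemble_augmented",
    "solve_frame",
    "solve_sequence",
    "temporal_mean_filter",
]

log = logging.getLogger(__name__)


class RankDeficientError(np.linalg.LinAlgError):
    """The augmented operator lost full column rank (mu = 0 misused here)."""


def default_lambda(spacing: float) -> float:
    """Default spatial weight, 0.01 * spacing**2.

    The curvature stencil carries a 1/spacing**2 factor, so this scaling
    makes the effective penalty per node independent of pixel size.
    """
    return 0.01 * spacing**2


@dataclass(frozen=True)
class SolverConfig:
    """Weights and numerical controls for the sequential solve.

    ``lam`` is the spatial-smoothness weight (None -> 0.01 * spacing**2);
    ``mu`` the temporal weight, which must be positive for RSTLS (mu = 0 is
    the spatial-only stage of the two-step comparator).  ``kernel`` is the
    moving-mean window in frames (odd; 1 disables).
    """

    lam: float | None = None
    mu: float = 0.1
    kernel: int = 3
    cond_tol: float = 1e12
    min_measurements: int = 10

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if self.mu <= 0:
            raise ValueError(
                "mu must be > 0 for the spatiotemporal solver "
                "(use the two-step solver for the mu = 0 spatial-only stage)"
            )
        if self.kernel % 2 == 0:
            raise ValueError(f"temporal filter kernel must be odd, got {self.kernel}")

    def resolve_lambda(self, spacing: float) -> float:
        return default_lambda(spacing) if self.lam is None else self.lam


@dataclass
class AugmentedSystem:
    """Stacked operator A_hat = [A; lambda B; mu I] and right-hand side E_hat."""

    A_hat: sp.csr_matrix
    E_hat: np.ndarray  # (rows,) or (rows, 2)
    n_nodes: int
    mu: float
    blocks: dict = field(default_factory=dict)  # A, B, lam kept for the normal equations


def assemble_augmented(
    A: sp.spmatrix,
    B: sp.spmatrix,
    lam: float,
    mu: float,
    E_f: np.ndarray,
    L_prev: np.ndarray,
) -> AugmentedSystem:
    """Stack the data, spatial, and temporal blocks of one frame's system.

    ``E_f`` and ``L_prev`` may carry one column per encoding direction.
    For the first frame pass ``L_prev = 0`` (no displacement before it).
    """
    E_f = np.asarray(E_f, dtype=float)
    L_prev = np.asarray(L_prev, dtype=float)
    n = A.shape[1]
    if B.shape[1] != n:
        raise ValueError(f"A has {n} columns but B has {B.shape[1]}")
    if E_f.shape[0] != A.shape[0]:
        raise ValueError(f"E_f has {E_f.shape[0]} rows but A has {A.shape[0]}")
    if L_prev.shape[0] != n:
        raise ValueError(f"L_prev has {L_prev.shape[0]} entries but there are {n} nodes")
    if E_f.ndim != L_prev.ndim:
        raise ValueError("E_f and L_prev must have matching dimensionality")

    A_hat = sp.vstack([A, lam * B, mu * sp.identity(n, format="csr")], format="csr")
    zeros_shape = (B.shape[0],) + E_f.shape[1:]
    E_hat = np.concatenate([E_f, np.zeros(zeros_shape), mu * L_prev], axis=0)
    return AugmentedSystem(
        A_hat=A_hat, E_hat=E_hat, n_nodes=n, mu=mu, blocks={"A": A, "B": B, "lam": lam}
    )


def solve_frame(system: AugmentedSystem) -> tuple[np.ndarray, float]:
    """Least-squares solution of one augmented frame system.

    Solves the normal equations ``(A_hat^T A_hat) L = A_hat^T E_hat`` with a
    sparse LU factorization (the matrix is symmetric positive definite for
    mu > 0), falling back to an iterative least-squares solve if the
    factorization fails.  Returns the solution and the residual norm
    ``||A_hat L - E_hat||``.
    """
    if system.mu <= 0:
        raise RankDeficientError(
            "augmented system with mu = 0 may be rank deficient; "
            "use the two-step spatial-only solver instead"
        )
    A_hat, E_hat = system.A_hat, system.E_hat
    M = (A_hat.T @ A_hat).tocsc()
    rhs = A_hat.T @ E_hat
    try:
        lu = spla.splu(M)
        L = lu.solve(np.asarray(rhs))
    except RuntimeError:  # singular/failed factorization: robust iterative fallback
        log.warning("sparse factorization failed; falling back to LSMR")
        if E_hat.ndim == 1:
            L = spla.lsmr(A_hat, E_hat, atol=1e-12, btol=1e-12)[0]
        else:
            L = np.column_stack(
                [spla.lsmr(A_hat, E_hat[:, k], atol=1e-12, btol=1e-12)[0] for k in range(E_hat.shape[1])]
            )
    residual = float(np.linalg.norm(A_hat @ L - E_hat))
    return L, residual


def solve_sequence(
    series: EulerianSeries,
    nodes: NodeSet,
    cfg: SolverConfig = SolverConfig(),
    apply_filter: bool = True,
) -> LagrangianTrajectories:
    """Sequential RSTLS solve over all frames, both encoding directions.

    Frame 0 is the reference configuration (L = 0 exactly); frames 1..F-1
    are solved in order, each rebuilding the interpolation matrix from that
    frame's back-projected measurements and anchoring to the previous
    frame's solution.  The moving-mean temporal filter (``cfg.kernel``) is
    applied as a final step.
    """
    F = series.n_frames
    n = nodes.n
    lam = cfg.resolve_lambda(nodes.spacing)
    B = build_second_derivative(nodes).matrix

    disp = np.zeros((F, n, 2))
    diagnostics = []
    L_prev = np.zeros((n, 2))
    for f in range(1, F):
        frame = series.frames[f]
        points = back_project(frame)
        A_op = build_interp_matrix(nodes, points)
        m = A_op.matrix.shape[0]
        if m < cfg.min_measurements:
            raise ValueError(
                f"frame {f} has only {m} usable measurement rows "
                f"(minimum {cfg.min_measurements}); {A_op.n_dropped} dropped"
            )
        E_f = frame.disp[A_op.row_source]
        system = assemble_augmented(A_op.matrix, B, lam, cfg.mu, E_f, L_prev)
        L, residual = solve_frame(system)
        disp[f] = L
        L_prev = L
        diagnostics.append(
            {"frame": f, "rows": m, "dropped": A_op.n_dropped, "residual": residual}
        )
        log.debug("frame %d: %d rows (%d dropped), residual %.3e", f, m, A_op.n_dropped, residual)

    traj = LagrangianTrajectories(
        disp=disp,
        ref_positions=nodes.positions,
        times_ms=series.enc.frame_times_ms,
        diagnostics=diagnostics,
    )
    if apply_filter and cfg.kernel > 1:
        traj = temporal_mean_filter(traj, cfg.kernel)
        traj.disp[0] = 0.0  # frame 0 is the reference configuration by contract
    return traj


def temporal_mean_filter(traj: LagrangianTrajectories, k: int = 3) -> LagrangianTrajectories:
    """Moving mean in time with an odd kernel of ``k`` frames.

    Windows are truncated at the ends of the sequence (mean over the frames
    actually available).
    """
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    F = traj.n_frames
    if k > F:
        raise ValueError(f"kernel size {k} exceeds sequence length {F}")
    half = k // 2
    padded = np.concatenate(
        [np.zeros((half,) + traj.disp.shape[1:]), traj.disp, np.zeros((half,) + traj.disp.shape[1:])]
    )
    csum = np.cumsum(padded, axis=0)
    csum = np.concatenate([np.zeros((1,) + csum.shape[1:]), csum], axis=0)
    sums = csum[k:] - csum[:-k]  # (F,) window sums over padded array
    counts = np.minimum(np.arange(F) + half + 1, F) - np.maximum(np.arange(F) - half, 0)
    smoothed = sums / counts[:, None, None]
    return LagrangianTrajectories(
        disp=smoothed,
        ref_positions=traj.ref_positions,
        times_ms=traj.times_ms,
        point_ids=traj.point_ids,
        diagnostics=traj.diagnostics,
    )
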