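"""Lagrangian finite strain, polar rotation, strain rate, and regional curves.

From the solved trajectories the deformation gradient F = dx/dX is estimated
per node by a least-squares plane fit over the node's masked neighbors; the
Lagrangian finite strain is E = (F^T F - I)/2, which vanishes for rigid
motion.  Strain tensors are rotated into the short-axis polar frame about
the ventricular center,

    E_polar = R E R^T,   R = [[cos t, -sin t], [sin t, cos t]],

so that E_polar[0, 0] is the radial strain (Err) and E_polar[1, 1] the
circumferential strain (Ecc).  Strain rate is the first difference of Ecc
between consecutive frames divided by TR, reported in 1/s.  Diastolic
function is summarized by the peak early diastolic strain rate (PEDSR) and
the mean absolute strain rate during diastasis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import LagrangianTrajectories
from .operators import NodeSet

__all__ = [
    "StrainField",
    "StrainCurves",
    "DiastolicWindows",
    "DiastolicMetrics",
    "deformation_gradient",
    "lagrangian_strain",
    "to_polar",
    "strain_rate",
    "aggregate_curves",
    "diastolic_metrics",
    "mask_centroid",
]

log = logging.getLogger(__name__)

_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class StrainField:
    """Per-node, per-frame deformation gradient and strain tensors.

    ``valid`` marks nodes whose neighborhood supported a full-rank gradient
    estimate; tensors at invalid nodes are NaN.  ``theta`` is the polar
    angle of each node's reference position about the ventricular center.
    """

    F: np.ndarray  # (frames, n, 2, 2)
    E: np.ndarray  # (frames, n, 2, 2)
    E_polar: np.ndarray | None  # (frames, n, 2, 2) once to_polar has run
    valid: np.ndarray  # (n,) bool
    theta: np.ndarray | None  # (n,) radians
    center: np.ndarray | None  # (2,) mm

    @property
    def ecc(self) -> np.ndarray:
        if self.E_polar is None:
            raise ValueError("polar strain not computed yet; call to_polar first")
        return self.E_polar[:, :, 1, 1]

    @property
    def err(self) -> np.ndarray:
        if self.E_polar is None:
            raise ValueError("polar strain not computed yet; call to_polar first")
        return self.E_polar[:, :, 0, 0]


def deformation_gradient(traj: LagrangianTrajectories, nodes: NodeSet) -> tuple[np.ndarray, np.ndarray]:
    """Estimate F = dx/dX per node and frame from nodal trajectories.

    For each node the 2x2 gradient minimizing ``sum_k ||dx_k - F dX_k||^2``
    over the node's mask neighbors within a 1-node radius (8-neighborhood)
    is computed, with ``dX_k`` the reference offset to neighbor ``k`` and
    ``dx_k`` the deformed offset.  Nodes whose neighbor offsets span fewer
    than 2 independent directions are excluded (returned invalid).  F is the
    identity exactly at frame 0.

    Returns ``(F, valid)`` with F of shape (frames, n, 2, 2).
    """
    n = nodes.n
    F_frames = traj.n_frames
    if traj.n_points != n:
        raise ValueError("trajectory point count does not match node set")

    nbr_lists: list[np.ndarray] = []
    valid = np.zeros(n, dtype=bool)
    nrows, ncols = nodes.grid_shape
    for k in range(n):
        r, c = nodes.ij[k]
        nbrs = []
        for dr, dc in _NEIGHBOR_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and nodes.ordinal[rr, cc] >= 0:
                nbrs.append(nodes.ordinal[rr, cc])
        nbrs = np.asarray(nbrs, dtype=int)
        nbr_lists.append(nbrs)
        if nbrs.size >= 2:
            dX = nodes.positions[nbrs] - nodes.positions[k]
            S = dX.T @ dX
            valid[k] = np.linalg.matrix_rank(S, tol=1e-9 * nodes.spacing**2) == 2

    n_excluded = int(np.sum(~valid))
    if n_excluded:
        log.debug("deformation gradient undefined at %d of %d nodes", n_excluded, n)

    out = np.full((F_frames, n, 2, 2), np.nan)
    out[0] = np.eye(2)
    x_all = traj.ref_positions[None, :, :] + traj.disp  # (frames, n, 2)
    for k in range(n):
        if not valid[k]:
            continue
        nbrs = nbr_lists[k]
        dX = nodes.positions[nbrs] - nodes.positions[k]  # (m, 2)
        S_inv = np.linalg.inv(dX.T @ dX)
        dx = x_all[:, nbrs, :] - x_all[:, k : k + 1, :]  # (frames, m, 2)
        # F = (sum dx dX^T) (sum dX dX^T)^-1
        cross = np.einsum("fmi,mj->fij", dx, dX)
        out[:, k] = cross @ S_inv
    out[0, valid] = np.eye(2)
    return out, valid


def lagrangian_strain(F: np.ndarray) -> np.ndarray:
    """Lagrangian finite strain E = (F^T F - I)/2 (symmetric by construction)."""
    F = np.asarray(F, dtype=float)
    return 0.5 * (np.einsum("...ba,...bc->...ac", F, F) - np.eye(2))


def to_polar(E: np.ndarray, positions: np.ndarray, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate strain tensors into the polar frame about ``center``.

    The node angle is taken from the *reference* position (strain is a
    referential quantity).  Returns ``(E_polar, theta)`` where
    ``E_polar[..., 0, 0]`` is Err and ``E_polar[..., 1, 1]`` is Ecc.
    """
    positions = np.asarray(positions, dtype=float)
    center = np.asarray(center, dtype=float)
    rel = positions - center
    r = np.linalg.norm(rel, axis=-1)
    if np.any(r < 1e-9):
        raise ValueError("a node coincides with the polar center; angle undefined")
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    cos, sin = np.cos(theta), np.sin(theta)
    # Basis change into (radial, circumferential): row 1 of R is the radial
    # unit vector (cos t, sin t), so (R E R^T)[0, 0] = u_r^T E u_r = Err.
    R = np.empty((theta.size, 2, 2))
    R[:, 0, 0] = cos
    R[:, 0, 1] = sin
    R[:, 1, 0] = -sin
    R[:, 1, 1] = cos
    E_polar = np.einsum("nab,...nbc,ndc->...nad", R, E, R)
    return E_polar, theta


def compute_strain_field(
    traj: LagrangianTrajectories, nodes: NodeSet, center: np.ndarray | None = None
) -> StrainField:
    """Full strain pipeline: gradient, strain tensor, polar rotation."""
    center = mask_centroid(nodes) if center is None else np.asarray(center, dtype=float)
    F, valid = deformation_gradient(traj, nodes)
    E = lagrangian_strain(F)
    E_polar, theta = to_polar(E, nodes.positions, center)
    return StrainField(F=F, E=E, E_polar=E_polar, valid=valid, theta=theta, center=center)


def mask_centroid(nodes: NodeSet) -> np.ndarray:
    """Ventricular center estimate: centroid of the reference mask."""
    return nodes.positions.mean(axis=0)


def strain_rate(curve: np.ndarray, tr_ms: float) -> np.ndarray:
    """First-difference strain rate in 1/s: (E[f+1] - E[f]) / TR."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape[-1] < 2:
        raise ValueError("need at least 2 frames to compute a strain rate")
    return np.diff(curve, axis=-1) / (tr_ms / 1000.0)


@dataclass
class StrainCurves:
    """Global and segmental circumferential strain and strain-rate curves."""

    times_ms: np.ndarray  # (F,)
    global_ecc: np.ndarray  # (F,)
    global_rate: np.ndarray  # (F-1,) 1/s
    segment_ecc: np.ndarray  # (n_segments, F)
    segment_rate: np.ndarray  # (n_segments, F-1) 1/s
    segment_of_node: np.ndarray  # (n,) int, -1 for invalid nodes
    tr_ms: float


def aggregate_curves(
    field: StrainField,
    tr_ms: float,
    n_segments: int = 6,
    ref_angle: float = 0.0,
) -> StrainCurves:
    """Mean Ecc per frame, globally and over equal angular segments.

    Segments are ``n_segments`` equal sectors about the center, measured
    counterclockwise from ``ref_angle``; only nodes with a defined strain
    contribute.  An empty segment is an error naming the segment.
    """
    ecc = field.ecc  # (F, n)
    valid = field.valid
    F = ecc.shape[0]
    if not valid.any():
        raise ValueError("no node has a defined strain tensor")

    global_ecc = ecc[:, valid].mean(axis=1)
    seg_idx = np.floor(((field.theta - ref_angle) % (2 * np.pi)) / (2 * np.pi / n_segments)).astype(int)
    seg_idx = np.clip(seg_idx, 0, n_segments - 1)
    seg_of_node = np.where(valid, seg_idx, -1)

    segment_ecc = np.empty((n_segments, F))
    for s in range(n_segments):
        members = seg_of_node == s
        if not members.any():
            raise ValueError(f"segment {s} of {n_segments} contains no nodes with defined strain")
        segment_ecc[s] = ecc[:, members].mean(axis=1)

    return StrainCurves(
        times_ms=np.arange(F) * tr_ms,
        global_ecc=global_ecc,
        global_rate=strain_rate(global_ecc, tr_ms),
        segment_ecc=segment_ecc,
        segment_rate=strain_rate(segment_ecc, tr_ms),
        segment_of_node=seg_of_node,
        tr_ms=tr_ms,
    )


@dataclass(frozen=True)
class DiastolicWindows:
    """Frame-index boundaries of the diastolic analysis windows.

    Early diastole spans frames ``(end_systole, end_ewave]``; diastasis
    spans ``(end_ewave, end_diastasis]``.
    """

    end_systole: int
    end_ewave: int
    end_diastasis: int


@dataclass
class DiastolicMetrics:
    """Diastolic summary of one Ecc curve."""

    pedsr: float  # 1/s, peak early diastolic strain rate (positive recovery)
    diastasis_rate: float  # 1/s, mean |strain rate| during diastasis
    end_systolic_strain: float
    windows: DiastolicWindows


def detect_windows(ecc: np.ndarray) -> DiastolicWindows:
    """Heuristic diastolic windows from a global Ecc curve.

    End systole is the frame of minimum Ecc; early diastole covers the next
    25% of the remaining frames; diastasis runs from there up to the final
    15% of the sequence (atrial kick).
    """
    F = ecc.shape[0]
    es = int(np.argmin(ecc))
    remaining = F - 1 - es
    if remaining < 2:
        raise ValueError("end systole too close to the end of the sequence to define windows")
    ew = es + max(1, int(round(0.25 * remaining)))
    dias_end = max(ew + 1, F - 1 - int(round(0.15 * F)))
    dias_end = min(dias_end, F - 1)
    return DiastolicWindows(end_systole=es, end_ewave=ew, end_diastasis=dias_end)


def diastolic_metrics(
    ecc: np.ndarray, tr_ms: float, windows: DiastolicWindows | None = None
) -> DiastolicMetrics:
    """PEDSR and diastasis strain rate of a circumferential strain curve.

    PEDSR is the maximum strain rate (positive, as Ecc recovers from its
    negative end-systolic value toward zero) within the early-diastolic
    window; the diastasis rate is the mean absolute strain rate over the
    diastasis window.
    """
    ecc = np.asarray(ecc, dtype=float)
    F = ecc.shape[0]
    if windows is None:
        windows = detect_windows(ecc)
    if not 0 <= windows.end_systole < windows.end_ewave <= windows.end_diastasis <= F - 1:
        raise ValueError(
            f"diastolic windows {windows} are outside the {F}-frame sequence or unordered"
        )
    rate = strain_rate(ecc, tr_ms)  # rate[f] covers the interval f -> f+1
    early = rate[windows.end_systole : windows.end_ewave]
    dias = rate[windows.end_ewave : windows.end_diastasis]
    pedsr = float(np.max(early)) if early.size else 0.0
    dias_rate = float(np.mean(np.abs(dias))) if dias.size else 0.0
    return DiastolicMetrics(
        pedsr=pedsr,
        diastasis_rate=dias_rate,
        end_systolic_strain=float(ecc[windows.end_systole]),
        windows=windows,
    )
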