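"""Sparse operators on the masked reference grid.

The Lagrangian displacement field is discretized on the pixel centers of the
reference-frame myocardial mask (the *node set*).  Two sparse operators act
on nodal values:

* ``A`` — bilinear interpolation from the nodes to scattered reference
  positions.  Each Eulerian measurement at pixel ``p`` with displacement
  ``e`` is a sample of the Lagrangian field at the back-projected reference
  position ``X_p = p - e`` (the material point now at ``p`` started there),
  so ``A @ L`` predicts the measured Eulerian displacements.
* ``B`` — second differences along each spatial axis, penalizing curvature
  of the nodal field (spatial-smoothness regularization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .containers import FrameMeasurements, pixel_centers

__all__ = ["NodeSet", "SparseOperator", "back_project", "build_interp_matrix", "build_second_derivative"]


@dataclass(frozen=True)
class NodeSet:
    """Ordered reference-mask pixel centers carrying the nodal unknowns.

    Ordering is deterministic: row-major over the reference mask.
    """

    ij: np.ndarray  # (n, 2) integer (row, col) grid indices
    positions: np.ndarray  # (n, 2) pixel-center (x, y) positions, mm
    ordinal: np.ndarray  # (rows, cols) int; node ordinal or -1 off the mask
    spacing: float

    @classmethod
    def from_mask(cls, mask: np.ndarray, spacing: float) -> "NodeSet":
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not mask.any():
            raise ValueError("reference mask is empty")
        rows, cols = np.nonzero(mask)  # row-major order
        ij = np.column_stack([rows, cols])
        ordinal = np.full(mask.shape, -1, dtype=int)
        ordinal[rows, cols] = np.arange(rows.size)
        return cls(ij=ij, positions=pixel_centers(ij, spacing), ordinal=ordinal, spacing=spacing)

    @property
    def n(self) -> int:
        return self.ij.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.ordinal.shape


@dataclass
class SparseOperator:
    """A sparse matrix plus row provenance.

    ``row_source`` records which measurement (for ``A``) or which
    (axis, node) stencil (for ``B``) produced each row; ``n_dropped`` counts
    measurement rows discarded because no valid node supported them.
    """

    matrix: sp.csr_matrix
    row_source: np.ndarray
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)


def back_project(frame: FrameMeasurements) -> np.ndarray:
    """Estimated reference positions of the material points observed in a frame.

    The pixel at position ``p`` measures displacement ``e`` of the tissue
    that currently occupies it, so that tissue started at ``X_p = p - e``.
    """
    return frame.positions - frame.disp


def build_interp_matrix(nodes: NodeSet, points: np.ndarray) -> SparseOperator:
    """Bilinear interpolation matrix from nodal values to scattered points.

    Row ``j`` holds the bilinear weights of the (up to four) nodes at the
    corners of the reference grid cell containing ``points[j]``; weights are
    renormalized over the corners that are valid nodes, so every surviving
    row sums to 1.  Points whose enclosing cell contains no valid node are
    dropped; their indices are recorded in ``meta["dropped_rows"]``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    h = nodes.spacing
    nrows, ncols = nodes.grid_shape

    # fractional (row, col) index of each point in the grid of pixel centers
    fc = points[:, 0] / h - 0.5  # x -> column
    fr = points[:, 1] / h - 0.5  # y -> row
    c0 = np.floor(fc).astype(int)
    r0 = np.floor(fr).astype(int)
    tc = fc - c0
    tr = fr - r0

    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    vals_out: list[np.ndarray] = []
    kept: list[int] = []
    dropped: list[int] = []

    corner_dr = np.array([0, 0, 1, 1])
    corner_dc = np.array([0, 1, 0, 1])

    for j in range(points.shape[0]):
        rr = r0[j] + corner_dr
        cc = c0[j] + corner_dc
        w = np.array(
            [
                (1 - tr[j]) * (1 - tc[j]),
                (1 - tr[j]) * tc[j],
                tr[j] * (1 - tc[j]),
                tr[j] * tc[j],
            ]
        )
        inside = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
        ords = np.full(4, -1, dtype=int)
        ords[inside] = nodes.ordinal[rr[inside], cc[inside]]
        valid = ords >= 0
        wsum = w[valid].sum()
        if wsum <= 0.0:
            dropped.append(j)
            continue
        w = w[valid] / wsum
        keep_w = w > 0.0  # points on cell edges produce exact-zero corner weights
        kept.append(j)
        rows_out.append(np.full(int(keep_w.sum()), len(kept) - 1))
        cols_out.append(ords[valid][keep_w])
        vals_out.append(w[keep_w])

    if kept:
        mat = sp.csr_matrix(
            (np.concatenate(vals_out), (np.concatenate(rows_out), np.concatenate(cols_out))),
            shape=(len(kept), nodes.n),
        )
    else:
        mat = sp.csr_matrix((0, nodes.n))
    return SparseOperator(
        matrix=mat,
        row_source=np.asarray(kept, dtype=int),
        n_dropped=len(dropped),
        meta={"dropped_rows": np.asarray(dropped, dtype=int)},
    )


def build_second_derivative(nodes: NodeSet) -> SparseOperator:
    """Second-difference operator along each spatial axis on the masked grid.

    One row per node whose two axis neighbors both lie on the mask, holding
    the 1D stencil ``[1, -2, 1] / h**2``; nodes lacking a full stencil along
    an axis contribute no row along that axis (no one-sided stencils).  All
    x-direction rows are stacked above all y-direction rows.
    """
    h2 = nodes.spacing**2
    nrows, ncols = nodes.grid_shape
    ordinal = nodes.ordinal

    data: list[float] = []
    ri: list[int] = []
    ci: list[int] = []
    source: list[tuple[str, int]] = []
    row = 0
    # axis "x" = column neighbors, axis "y" = row neighbors
    for axis, (dr, dc) in (("x", (0, 1)), ("y", (1, 0))):
        for k in range(nodes.n):
            r, c = nodes.ij[k]
            rm, cm = r - dr, c - dc
            rp, cp = r + dr, c + dc
            if not (0 <= rm and 0 <= cm and rp < nrows and cp < ncols):
                continue
            om, op = ordinal[rm, cm], ordinal[rp, cp]
            if om < 0 or op < 0:
                continue
            ri.extend([row, row, row])
            ci.extend([om, k, op])
            data.extend([1.0 / h2, -2.0 / h2, 1.0 / h2])
            source.append((axis, k))
            row += 1

    mat = sp.csr_matrix((data, (ri, ci)), shape=(row, nodes.n))
    return SparseOperator(matrix=mat, row_source=np.array(source, dtype=object), meta={})
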