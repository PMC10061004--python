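"""Shared in-memory containers for cine DENSE analysis.

Conventions used throughout the package:

* spatial units are mm, time is ms internally (strain rate is converted to
  1/s at the reporting boundary);
* images are ``(rows, cols)`` arrays; a pixel at integer grid index
  ``(row, col)`` has its *center* at ``x = (col + 0.5) * spacing``,
  ``y = (row + 0.5) * spacing``, with the origin at the image corner;
* frame 0 is the displacement-encoding reference: the Lagrangian
  displacement at frame 0 is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EncodingParams",
    "PhaseStack",
    "FrameMeasurements",
    "EulerianSeries",
    "LagrangianTrajectories",
    "pixel_centers",
]

TWO_PI = 2.0 * np.pi


def pixel_centers(ij: np.ndarray, spacing: float) -> np.ndarray:
    """Map integer grid indices ``(row, col)`` to pixel-center positions (x, y) in mm."""
    ij = np.asarray(ij)
    out = np.empty(ij.shape, dtype=float)
    out[..., 0] = (ij[..., 1] + 0.5) * spacing  # x = column direction
    out[..., 1] = (ij[..., 0] + 0.5) * spacing  # y = row direction
    return out


@dataclass(frozen=True)
class EncodingParams:
    """Acquisition metadata needed to interpret a DENSE phase stack.

    Parameters
    ----------
    ke : float
        Displacement-encoding frequency in cycles/mm; phase and displacement
        are related by ``displacement = phase / (2 pi ke)``.
    spacing : float
        In-plane pixel spacing in mm (isotropic).
    tr_ms : float
        Frame interval (temporal resolution) in ms.
    n_frames : int
        Number of cine frames, including the reference frame 0.
    """

    ke: float
    spacing: float
    tr_ms: float
    n_frames: int

    def __post_init__(self) -> None:
        if not self.ke > 0:
            raise ValueError(f"encoding frequency ke must be > 0, got {self.ke}")
        if not self.spacing > 0:
            raise ValueError(f"pixel spacing must be > 0, got {self.spacing}")
        if not self.tr_ms > 0:
            raise ValueError(f"TR must be > 0, got {self.tr_ms}")
        if self.n_frames < 2:
            raise ValueError(f"need at least 2 frames, got {self.n_frames}")

    @property
    def frame_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr_ms


@dataclass
class PhaseStack:
    """Segmented, phase-unwrapped cine DENSE phase images.

    One unwrapped phase grid per frame and in-plane encoding direction
    (x, y), in radians, plus the per-frame myocardial mask.
    """

    phase_x: np.ndarray  # (F, rows, cols) radians
    phase_y: np.ndarray  # (F, rows, cols) radians
    masks: np.ndarray  # (F, rows, cols) bool
    enc: EncodingParams

    def __post_init__(self) -> None:
        self.phase_x = np.asarray(self.phase_x, dtype=float)
        self.phase_y = np.asarray(self.phase_y, dtype=float)
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.phase_x.shape != self.phase_y.shape:
            raise ValueError(
                "x- and y-encoded stacks have different shapes: "
                f"{self.phase_x.shape} vs {self.phase_y.shape}"
            )
        if self.masks.shape != self.phase_x.shape:
            raise ValueError(
                f"mask shape {self.masks.shape} does not match phase shape {self.phase_x.shape}"
            )
        if self.phase_x.ndim != 3:
            raise ValueError("phase stacks must be (frames, rows, cols)")
        if self.phase_x.shape[0] != self.enc.n_frames:
            raise ValueError(
                f"stack has {self.phase_x.shape[0]} frames but metadata says {self.enc.n_frames}"
            )
        for f in range(self.masks.shape[0]):
            if not self.masks[f].any():
                raise ValueError(f"myocardial mask is empty in frame {f}")
        for name, arr in (("x", self.phase_x), ("y", self.phase_y)):
            bad = ~np.isfinite(arr[self.masks])
            if bad.any():
                raise ValueError(f"non-finite {name}-encoded phase at masked pixels")

    @property
    def n_frames(self) -> int:
        return self.phase_x.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.phase_x.shape[1:]


@dataclass
class FrameMeasurements:
    """Masked-pixel Eulerian displacement measurements for one frame."""

    ij: np.ndarray  # (m, 2) integer (row, col) grid indices
    positions: np.ndarray  # (m, 2) pixel-center positions (x, y) in mm
    disp: np.ndarray  # (m, 2) measured Eulerian displacement (x, y) in mm

    @property
    def n(self) -> int:
        return self.ij.shape[0]


@dataclass
class EulerianSeries:
    """Per-frame scattered Eulerian displacement measurements.

    The phase of each masked pixel in each frame is an independent
    measurement of the absolute displacement of whatever tissue currently
    occupies that pixel, relative to the reference configuration.
    """

    frames: list[FrameMeasurements]
    enc: EncodingParams

    def __post_init__(self) -> None:
        if len(self.frames) != self.enc.n_frames:
            raise ValueError(
                f"series has {len(self.frames)} frames but metadata says {self.enc.n_frames}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class LagrangianTrajectories:
    """Material-point displacement paths over the full cine sequence.

    ``disp[f, i]`` is the (x, y) displacement in mm of material point ``i``
    (at reference position ``ref_positions[i]``) at frame ``f``.  Frame 0 is
    the reference configuration, so ``disp[0] == 0`` always.
    """

    disp: np.ndarray  # (F, n, 2) mm
    ref_positions: np.ndarray  # (n, 2) mm
    times_ms: np.ndarray  # (F,)
    point_ids: np.ndarray = field(default=None)  # (n,) int
    diagnostics: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=float)
        self.ref_positions = np.asarray(self.ref_positions, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.disp.ndim != 3 or self.disp.shape[2] != 2:
            raise ValueError("disp must be (frames, points, 2)")
        if self.disp.shape[1] != self.ref_positions.shape[0]:
            raise ValueError("point count mismatch between disp and ref_positions")
        if self.disp.shape[0] != self.times_ms.shape[0]:
            raise ValueError("frame count mismatch between disp and times_ms")
        if self.point_ids is None:
            self.point_ids = np.arange(self.disp.shape[1])
        else:
            self.point_ids = np.asarray(self.point_ids, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.disp.shape[0]

    @property
    def n_points(self) -> int:
        return self.disp.shape[1]

    def deformed_positions(self, f: int) -> np.ndarray:
        """Positions x = X + L of all material points at frame ``f`` (mm)."""
        return self.ref_positions + self.disp[f]
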