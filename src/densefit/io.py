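"""On-disk formats: NIfTI phase stacks, JSON sidecars, CSV trajectories.

Phase stacks are written as one NIfTI file per encoding direction with the
cine frames along the third axis, a NIfTI mask stack, and a JSON sidecar
carrying the acquisition metadata (encoding frequency, pixel spacing, TR,
frame count, plus any extra provenance the caller supplies).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import (
    TWO_PI,
    EncodingParams,
    EulerianSeries,
    FrameMeasurements,
    LagrangianTrajectories,
    PhaseStack,
    pixel_centers,
)

__all__ = [
    "phase_to_displacement",
    "write_stack",
    "read_stack",
    "write_trajectories",
    "read_trajectories",
]

_TRAJ_COLUMNS = ["point_id", "frame", "X_x", "X_y", "Lx", "Ly"]


def phase_to_displacement(stack: PhaseStack) -> EulerianSeries:
    """Convert unwrapped phase to Eulerian displacement: d = phase / (2 pi ke).

    One measurement record per masked pixel per frame, both encoding
    directions combined into a 2-vector.
    """
    scale = 1.0 / (TWO_PI * stack.enc.ke)
    frames: list[FrameMeasurements] = []
    for t in range(stack.n_frames):
        rows, cols = np.nonzero(stack.masks[t])
        px = stack.phase_x[t, rows, cols]
        py = stack.phase_y[t, rows, cols]
        for name, vals in (("x", px), ("y", py)):
            bad = ~np.isfinite(vals)
            if bad.any():
                i = int(np.argmax(bad))
                raise ValueError(
                    f"non-finite {name}-encoded phase at masked pixel "
                    f"(row={rows[i]}, col={cols[i]}) in frame {t}"
                )
        ij = np.column_stack([rows, cols])
        disp = np.column_stack([px, py]) * scale
        frames.append(
            FrameMeasurements(ij=ij, positions=pixel_centers(ij, stack.enc.spacing), disp=disp)
        )
    return EulerianSeries(frames=frames, enc=stack.enc)


def _nifti(data: np.ndarray, spacing: float) -> nib.Nifti1Image:
    # frames along the 3rd axis; in-plane voxel size in mm
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    return nib.Nifti1Image(np.moveaxis(np.asarray(data), 0, -1), affine)


def write_stack(stack: PhaseStack, prefix: str | Path, extra_meta: dict | None = None) -> dict:
    """Write a phase stack as NIfTI files plus a JSON sidecar.

    Creates ``<prefix>_phase_x.nii``, ``<prefix>_phase_y.nii``,
    ``<prefix>_mask.nii`` and ``<prefix>_meta.json``; returns the path map.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "phase_x": prefix.with_name(prefix.name + "_phase_x.nii"),
        "phase_y": prefix.with_name(prefix.name + "_phase_y.nii"),
        "mask": prefix.with_name(prefix.name + "_mask.nii"),
        "meta": prefix.with_name(prefix.name + "_meta.json"),
    }
    nib.save(_nifti(stack.phase_x, stack.enc.spacing), paths["phase_x"])
    nib.save(_nifti(stack.phase_y, stack.enc.spacing), paths["phase_y"])
    nib.save(_nifti(stack.masks.astype(np.uint8), stack.enc.spacing), paths["mask"])
    meta = {
        "ke_cycles_per_mm": stack.enc.ke,
        "pixel_spacing_mm": stack.enc.spacing,
        "tr_ms": stack.enc.tr_ms,
        "n_frames": stack.enc.n_frames,
    }
    if extra_meta:
        meta.update(extra_meta)
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_stack(prefix: str | Path) -> PhaseStack:
    """Read a phase stack written by :func:`write_stack` (lossless round trip)."""
    prefix = Path(prefix)
    meta_path = prefix.with_name(prefix.name + "_meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("ke_cycles_per_mm", "pixel_spacing_mm", "tr_ms", "n_frames"):
        if key not in meta:
            raise KeyError(f"sidecar {meta_path} is missing required key '{key}'")
    enc = EncodingParams(
        ke=meta["ke_cycles_per_mm"],
        spacing=meta["pixel_spacing_mm"],
        tr_ms=meta["tr_ms"],
        n_frames=int(meta["n_frames"]),
    )

    def load(tag: str) -> np.ndarray:
        path = prefix.with_name(prefix.name + f"_{tag}.nii")
        if not path.exists():
            raise FileNotFoundError(f"missing {tag} image {path}")
        return np.moveaxis(np.asarray(nib.load(path).get_fdata()), -1, 0)

    phase_x, phase_y, mask = load("phase_x"), load("phase_y"), load("mask")
    if phase_x.shape[0] != phase_y.shape[0]:
        raise ValueError(
            f"frame-count mismatch between encoding directions: "
            f"x has {phase_x.shape[0]}, y has {phase_y.shape[0]}"
        )
    if mask.shape != phase_x.shape:
        raise ValueError(f"mask shape {mask.shape} does not match phase grid {phase_x.shape}")
    return PhaseStack(phase_x=phase_x, phase_y=phase_y, masks=mask > 0.5, enc=enc)


def write_trajectories(traj: LagrangianTrajectories, path: str | Path) -> None:
    """Write Lagrangian trajectories as long-format CSV.

    Columns: point_id, frame, X_x, X_y, Lx, Ly — one row per material point
    per frame, at full float precision.
    """
    F, n = traj.n_frames, traj.n_points
    frame_idx = np.repeat(np.arange(F), n)
    pid = np.tile(traj.point_ids, F)
    ref = np.tile(traj.ref_positions, (F, 1))
    d = traj.disp.reshape(F * n, 2)
    df = pd.DataFrame(
        {
            "point_id": pid,
            "frame": frame_idx,
            "X_x": ref[:, 0],
            "X_y": ref[:, 1],
            "Lx": d[:, 0],
            "Ly": d[:, 1],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path: str | Path, tr_ms: float = 1.0) -> LagrangianTrajectories:
    """Read trajectories written by :func:`write_trajectories`.

    Every point must appear in every frame 0..F-1 (frame gaps are an error);
    malformed rows raise with the offending line number.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed trajectory CSV {path}: {err}") from err
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV {path} is missing columns {missing}")
    for col in ("X_x", "X_y", "Lx", "Ly"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(df.index[bad][0]) + 2
            raise ValueError(f"malformed value in column '{col}' at line {line} of {path}")
    if df.empty:
        return LagrangianTrajectories(
            disp=np.zeros((0, 0, 2)),
            ref_positions=np.zeros((0, 2)),
            times_ms=np.zeros(0),
            point_ids=np.zeros(0, dtype=int),
        )

    pids = np.sort(df["point_id"].unique())
    frames = np.sort(df["frame"].unique())
    F = int(frames.max()) + 1
    if not np.array_equal(frames, np.arange(F)):
        raise ValueError(f"trajectory CSV {path} has frame gaps: found frames {frames.tolist()}")
    counts = df.groupby("point_id")["frame"].nunique()
    if (counts != F).any():
        bad_pid = counts.index[counts != F][0]
        raise ValueError(f"point {bad_pid} in {path} does not cover all {F} frames")

    df = df.sort_values(["frame", "point_id"], kind="stable")
    n = pids.size
    disp = df[["Lx", "Ly"]].to_numpy(dtype=float).reshape(F, n, 2)
    ref = df[df["frame"] == 0].sort_values("point_id")[["X_x", "X_y"]].to_numpy(dtype=float)
    return LagrangianTrajectories(
        disp=disp,
        ref_positions=ref,
        times_ms=np.arange(F) * tr_ms,
        point_ids=pids.astype(int),
    )
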