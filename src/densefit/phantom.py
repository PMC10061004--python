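"""Synthetic cine DENSE phantom with analytically known ground truth.

The phantom is an annular "myocardium" (short-axis left-ventricular slice)
undergoing area-preserving radial contraction composed with a rigid twist
about the slice center, modulated by a cardiac-like activation profile
``a(t)`` in [0, 1] (systolic rise, early-diastolic E-wave fall, diastasis
plateau, atrial kick).  Because the motion map, its inverse, and its
Jacobian are available in closed form, the phantom delivers exact Lagrangian
ground truth — displacement and strain — against which displacement solvers
can be scored.

The motion of a material point at reference polar radius ``r`` is::

    r(t)     = sqrt(r**2 - a(t) * c),   c = (2 b - b**2) * r_endo**2
    theta(t) = theta + a(t) * twist

where ``b`` is the peak endocardial contraction fraction, so the endocardial
radius shrinks by exactly the fraction ``b`` at peak activation, and the
polar map preserves area (det F = 1) at every point and time.  An optional
rigid translation ``a(t) * translation`` is added on top; it leaves det F
and strain unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import (
    TWO_PI,
    EncodingParams,
    EulerianSeries,
    FrameMeasurements,
    PhaseStack,
    pixel_centers,
)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "activation",
    "activation_continuous",
    "motion_map",
    "inverse_motion_map",
    "motion_jacobian",
    "analytic_strain",
    "analytic_circumferential_strain",
    "generate_ground_truth",
    "generate_eulerian_series",
    "synthesize_phase_stack",
    "phase_noise_to_displacement_sd",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the annular motion phantom.

    Defaults emulate a healthy mid-ventricular short-axis cine DENSE
    acquisition: 3.4 mm pixels, 15 ms temporal resolution, 40 frames,
    encoding frequency 0.1 cycles/mm, and an annulus contracting to a peak
    global circumferential strain of roughly -0.13 with 8 degrees of twist.
    """

    grid_shape: tuple[int, int] = (64, 64)  # (rows, cols) pixels
    spacing: float = 3.4  # mm
    center: tuple[float, float] | None = None  # (x, y) mm; None -> grid center
    r_endo: float = 20.0  # endocardial radius at rest, mm
    r_epi: float = 33.0  # epicardial radius at rest, mm
    contraction: float = 0.25  # peak endocardial radial contraction fraction
    twist_deg: float = 8.0  # peak twist, degrees
    translation: tuple[float, float] = (0.0, 0.0)  # peak rigid translation, mm
    n_frames: int = 40
    tr_ms: float = 15.0
    end_systole_frame: int = 14
    end_ewave_frame: int = 22
    end_diastasis_frame: int = 34
    plateau_level: float = 0.25  # activation level during diastasis
    end_level: float = 0.05  # activation after the atrial kick
    phase_noise_sd: float = 0.05  # radians
    ke: float = 0.1  # cycles/mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_endo < self.r_epi:
            raise ValueError(
                f"need 0 < r_endo < r_epi, got r_endo={self.r_endo}, r_epi={self.r_epi}"
            )
        if not 0 <= self.contraction < 1:
            raise ValueError(f"contraction fraction must be in [0, 1), got {self.contraction}")
        if self.phase_noise_sd < 0:
            raise ValueError(f"phase noise sd must be >= 0, got {self.phase_noise_sd}")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not (
            0 < self.end_systole_frame
            < self.end_ewave_frame
            <= self.end_diastasis_frame
            < self.n_frames
        ):
            raise ValueError("activation breakpoints must be strictly ordered within the sequence")
        if not (0 <= self.end_level <= self.plateau_level <= 1):
            raise ValueError("need 0 <= end_level <= plateau_level <= 1")

    @property
    def center_xy(self) -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, dtype=float)
        rows, cols = self.grid_shape
        return np.array([cols * self.spacing / 2.0, rows * self.spacing / 2.0])

    @property
    def contraction_constant(self) -> float:
        """``c`` such that r(t) = sqrt(r**2 - a(t) c) moves the endocardium by the stated fraction."""
        b = self.contraction
        return (2.0 * b - b**2) * self.r_endo**2

    @property
    def twist_rad(self) -> float:
        return np.deg2rad(self.twist_deg)

    @property
    def encoding(self) -> EncodingParams:
        return EncodingParams(ke=self.ke, spacing=self.spacing, tr_ms=self.tr_ms, n_frames=self.n_frames)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def activation_continuous(spec: PhantomSpec, t_ms: np.ndarray) -> np.ndarray:
    """Activation a(t) at arbitrary times (ms), piecewise cubic smoothstep.

    Rises 0 -> 1 over systole, falls to ``plateau_level`` over the E-wave,
    holds flat through diastasis, then falls to ``end_level`` with the
    atrial kick.  a(0) = 0 exactly.
    """
    t = np.asarray(t_ms, dtype=float)
    t_es = spec.end_systole_frame * spec.tr_ms
    t_ew = spec.end_ewave_frame * spec.tr_ms
    t_dia = spec.end_diastasis_frame * spec.tr_ms
    t_end = (spec.n_frames - 1) * spec.tr_ms

    a = np.empty(t.shape, dtype=float)
    a[:] = spec.end_level
    seg = t <= t_es
    a[seg] = _smoothstep(t[seg] / t_es)
    seg = (t > t_es) & (t <= t_ew)
    a[seg] = 1.0 - (1.0 - spec.plateau_level) * _smoothstep((t[seg] - t_es) / (t_ew - t_es))
    seg = (t > t_ew) & (t <= t_dia)
    a[seg] = spec.plateau_level
    seg = (t > t_dia) & (t <= t_end)
    if t_end > t_dia:
        a[seg] = spec.plateau_level - (spec.plateau_level - spec.end_level) * _smoothstep(
            (t[seg] - t_dia) / (t_end - t_dia)
        )
    return a


def activation(spec: PhantomSpec) -> np.ndarray:
    """Activation sampled at the frame times; ``activation(spec)[0] == 0``."""
    return activation_continuous(spec, np.arange(spec.n_frames) * spec.tr_ms)


def _check_in_annulus(spec: PhantomSpec, X: np.ndarray) -> np.ndarray:
    r = np.linalg.norm(X - spec.center_xy, axis=-1)
    tol = 1e-9 * spec.r_epi
    bad = (r < spec.r_endo - tol) | (r > spec.r_epi + tol)
    if np.any(bad):
        raise ValueError(
            f"{int(np.sum(bad))} reference point(s) lie outside the rest annulus "
            f"[{spec.r_endo}, {spec.r_epi}] mm"
        )
    return r


def _frame_activation(spec: PhantomSpec, t: int) -> float:
    if not 0 <= t < spec.n_frames:
        raise ValueError(f"frame index {t} outside 0..{spec.n_frames - 1}")
    return float(activation(spec)[t])


def motion_map(spec: PhantomSpec, X: np.ndarray, t: int) -> np.ndarray:
    """Deformed position x(X, t) of reference points X (mm) at frame ``t``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = _check_in_annulus(spec, X)
    a = _frame_activation(spec, t)
    u = X - spec.center_xy
    r_cur = np.sqrt(np.maximum(r**2 - a * spec.contraction_constant, 0.0))
    phi = a * spec.twist_rad
    scale = np.where(r > 0, r_cur / np.maximum(r, 1e-300), 0.0)
    v = u * scale[:, None]
    cos, sin = np.cos(phi), np.sin(phi)
    rot = np.column_stack([cos * v[:, 0] - sin * v[:, 1], sin * v[:, 0] + cos * v[:, 1]])
    return spec.center_xy + rot + a * np.asarray(spec.translation, dtype=float)


def inverse_motion_map(spec: PhantomSpec, x: np.ndarray, t: int) -> np.ndarray:
    """Reference position X of the material point occupying ``x`` at frame ``t`` (exact)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    a = _frame_activation(spec, t)
    v = x - spec.center_xy - a * np.asarray(spec.translation, dtype=float)
    rho = np.linalg.norm(v, axis=-1)
    r_ref = np.sqrt(rho**2 + a * spec.contraction_constant)
    phi = -a * spec.twist_rad
    cos, sin = np.cos(phi), np.sin(phi)
    w = np.column_stack([cos * v[:, 0] - sin * v[:, 1], sin * v[:, 0] + cos * v[:, 1]])
    scale = np.where(rho > 0, r_ref / np.maximum(rho, 1e-300), 0.0)
    return spec.center_xy + w * scale[:, None]


def motion_jacobian(spec: PhantomSpec, X: np.ndarray, t: int) -> np.ndarray:
    """Analytic deformation gradient F = dx/dX, shape (n, 2, 2).

    In the polar basis the map has principal stretches ``r/r(t)`` (radial)
    and ``r(t)/r`` (circumferential); the rigid twist and translation do not
    alter the stretches.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = _check_in_annulus(spec, X)
    a = _frame_activation(spec, t)
    k = a * spec.contraction_constant
    u = X - spec.center_xy
    r_cur = np.sqrt(np.maximum(r**2 - k, 0.0))
    # M = (r'/r) I + (k / (r^3 r')) u u^T ; F = R(phi) M
    lam_c = r_cur / r
    coef = k / (r**3 * r_cur)
    eye = np.eye(2)
    M = lam_c[:, None, None] * eye + coef[:, None, None] * (u[:, :, None] * u[:, None, :])
    phi = a * spec.twist_rad
    cos, sin = np.cos(phi), np.sin(phi)
    R = np.array([[cos, -sin], [sin, cos]])
    return np.einsum("ab,nbc->nac", R, M)


def analytic_strain(spec: PhantomSpec, X: np.ndarray, t: int) -> np.ndarray:
    """Exact Lagrangian finite strain E = (F^T F - I)/2 at reference points X."""
    F = motion_jacobian(spec, X, t)
    return 0.5 * (np.einsum("nba,nbc->nac", F, F) - np.eye(2))


def analytic_circumferential_strain(spec: PhantomSpec, r: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Closed-form Ecc = -a c / (2 r^2) at reference radius r and activation a."""
    r = np.asarray(r, dtype=float)
    a = np.asarray(a, dtype=float)
    return -(a * spec.contraction_constant) / (2.0 * r**2)


@dataclass
class GroundTruth:
    """Exact Lagrangian kinematics of the phantom on the reference mask.

    ``disp[f, i]`` is the true displacement (mm) of the material point whose
    reference position is ``positions[i]``; ``strain[f, i]`` the true
    Lagrangian strain tensor.  Frame 0 is the rest configuration
    (``disp[0] == 0``, ``strain[0] == 0``), and det F = 1 everywhere.
    """

    ij: np.ndarray  # (n, 2) reference-mask grid indices
    positions: np.ndarray  # (n, 2) reference positions X, mm
    disp: np.ndarray  # (F, n, 2) true Lagrangian displacement, mm
    strain: np.ndarray  # (F, n, 2, 2) true Lagrangian strain
    reference_mask: np.ndarray  # (rows, cols) bool


def _annulus_mask(spec: PhantomSpec, r_in: float, r_out: float) -> np.ndarray:
    rows, cols = spec.grid_shape
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    centers = pixel_centers(np.stack([ii, jj], axis=-1), spec.spacing)
    r = np.linalg.norm(centers - spec.center_xy, axis=-1)
    return (r >= r_in) & (r <= r_out)


def generate_ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Exact Lagrangian displacement and strain at every reference-mask pixel."""
    mask0 = _annulus_mask(spec, spec.r_endo, spec.r_epi)
    rows, cols = np.nonzero(mask0)
    ij = np.column_stack([rows, cols])
    X = pixel_centers(ij, spec.spacing)
    F_frames = spec.n_frames
    disp = np.zeros((F_frames, X.shape[0], 2))
    strain = np.zeros((F_frames, X.shape[0], 2, 2))
    for t in range(F_frames):
        disp[t] = motion_map(spec, X, t) - X
        strain[t] = analytic_strain(spec, X, t)
    return GroundTruth(ij=ij, positions=X, disp=disp, strain=strain, reference_mask=mask0)


def phase_noise_to_displacement_sd(spec: PhantomSpec) -> float:
    """Displacement-equivalent noise sd (mm) for the spec's phase noise sd."""
    return spec.phase_noise_sd / (TWO_PI * spec.ke)


def generate_eulerian_series(
    spec: PhantomSpec, truth: GroundTruth | None = None
) -> tuple[EulerianSeries, np.ndarray]:
    """Simulate the per-frame Eulerian displacement measurements and masks.

    A pixel belongs to the frame-``t`` mask iff its center lies inside the
    deformed annulus.  The noiseless Eulerian displacement at masked pixel
    ``p`` is ``p - inverse_motion_map(p, t)``; Gaussian noise of standard
    deviation ``phase_noise_sd / (2 pi ke)`` mm is then added independently
    per pixel, direction, and frame from the spec's seed.

    Returns the series and the (F, rows, cols) boolean mask stack.
    """
    if truth is None:
        truth = generate_ground_truth(spec)
    rng = np.random.default_rng(spec.seed)
    sd = phase_noise_to_displacement_sd(spec)
    act = activation(spec)
    c = spec.contraction_constant
    shift = np.asarray(spec.translation, dtype=float)

    frames: list[FrameMeasurements] = []
    masks = np.zeros((spec.n_frames,) + spec.grid_shape, dtype=bool)
    rows_g, cols_g = spec.grid_shape
    jj, ii = np.meshgrid(np.arange(cols_g), np.arange(rows_g))
    all_ij = np.stack([ii, jj], axis=-1).reshape(-1, 2)
    all_pos = pixel_centers(all_ij, spec.spacing)

    for t in range(spec.n_frames):
        a = act[t]
        r_in = np.sqrt(max(spec.r_endo**2 - a * c, 0.0))
        r_out = np.sqrt(max(spec.r_epi**2 - a * c, 0.0))
        rel = all_pos - spec.center_xy - a * shift
        r = np.linalg.norm(rel, axis=-1)
        inside = (r >= r_in) & (r <= r_out)
        ij = all_ij[inside]
        pos = all_pos[inside]
        disp = pos - inverse_motion_map(spec, pos, t)
        noise = rng.normal(0.0, sd, size=disp.shape) if sd > 0 else 0.0
        frames.append(FrameMeasurements(ij=ij, positions=pos, disp=disp + noise))
        masks[t][ij[:, 0], ij[:, 1]] = True

    return EulerianSeries(frames=frames, enc=spec.encoding), masks


def synthesize_phase_stack(
    series: EulerianSeries, masks: np.ndarray, enc: EncodingParams | None = None
) -> PhaseStack:
    """Encode Eulerian displacements as unwrapped phase: phase = 2 pi ke d."""
    enc = enc or series.enc
    F = series.n_frames
    shape = masks.shape[1:]
    phase_x = np.zeros((F,) + shape)
    phase_y = np.zeros((F,) + shape)
    for t, fr in enumerate(series.frames):
        if not np.all(np.isfinite(fr.disp)):
            raise ValueError(f"non-finite displacement in frame {t}")
        phase_x[t][fr.ij[:, 0], fr.ij[:, 1]] = TWO_PI * enc.ke * fr.disp[:, 0]
        phase_y[t][fr.ij[:, 0], fr.ij[:, 1]] = TWO_PI * enc.ke * fr.disp[:, 1]
    return PhaseStack(phase_x=phase_x, phase_y=phase_y, masks=np.asarray(masks, dtype=bool), enc=enc)


def noiseless(spec: PhantomSpec) -> PhantomSpec:
    """Copy of ``spec`` with the phase noise switched off."""
    return replace(spec, phase_noise_sd=0.0)
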