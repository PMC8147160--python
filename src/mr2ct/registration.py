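"""Multimodal rigid registration by Mattes mutual information.

The similarity metric is mutual information estimated from a Parzen-windowed
joint histogram over a seeded uniform voxel sample: a zero-order (box)
kernel on the fixed-image intensity axis and a cubic B-spline kernel on the
moving-image axis, with bin edges spanning the 1st-99th intensity
percentiles of the overlap (the standard outlier guard for this metric).
MI = H(fixed) + H(moving) - H(joint), entropies summed over the bins, in
nats.

The rigid transform maps a fixed-image physical point p to the moving image
as R(p - c) + c + t, with R built from per-axis rotation angles in degrees
(applied as Rz @ Ry @ Rx, axis 0 being the slice/longitudinal axis, so an
"in-plane" rotation is a rotation about axis 0) and t a translation in mm.

Optimization is derivative-free: two resolution levels (smoothed,
2x-decimated, then full resolution), cyclic coordinate descent over the six
parameters with a golden-section line search and a shrinking bracket.  The
sample set is drawn deterministically from the config seed, so the
objective is smooth along each search line and a run is reproducible.

Deformable registration is deliberately not estimated here: a displacement
field produced by an external tool can be applied with
:func:`apply_deformation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar

from .volume import Modality, Volume


@dataclass
class MattesConfig:
    bins: int = 50
    samples: int = 500
    fixed_kernel_order: int = 0
    moving_kernel_order: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.samples < self.bins:
            raise ValueError("samples must be >= bins")
        if (self.fixed_kernel_order, self.moving_kernel_order) != (0, 3):
            raise ValueError("only box/cubic-B-spline kernels are implemented")


@dataclass
class RigidTransform:
    """Rotation (degrees, about axes 0/1/2) + translation (mm) about a center."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for v in (*self.rotation_deg, *self.translation_mm, *self.center_mm):
            if not np.isfinite(v):
                raise ValueError("non-finite transform parameter")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on (slice, row, col) mm coordinates."""
        a0, a1, a2 = np.deg2rad(self.rotation_deg)

        def rot(axis: int, ang: float) -> np.ndarray:
            c, s = np.cos(ang), np.sin(ang)
            i, j = [x for x in range(3) if x != axis]
            m = np.eye(3)
            m[i, i] = c
            m[j, j] = c
            m[i, j] = -s
            m[j, i] = s
            return m

        return rot(2, a2) @ rot(1, a1) @ rot(0, a0)

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Map fixed-space physical points (n, 3) into moving space."""
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (points_mm - c) @ self.matrix.T + c + t

    def to_dict(self) -> dict:
        return {"rotation_deg": list(self.rotation_deg),
                "translation_mm": list(self.translation_mm),
                "center_mm": list(self.center_mm)}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tuple(d["rotation_deg"]), tuple(d["translation_mm"]),
                   tuple(d["center_mm"]))


def volume_center_mm(vol: Volume) -> tuple[float, float, float]:
    return tuple((np.array(vol.shape) - 1) / 2 * np.array(vol.spacing))


# ---------------------------------------------------------------------------
# Parzen kernels


def _cubic_bspline(u: np.ndarray) -> np.ndarray:
    """Third-order B-spline kernel, support |u| < 2, integrates to 1."""
    au = np.abs(u)
    out = np.zeros_like(au)
    inner = au < 1
    outer = (au >= 1) & (au < 2)
    out[inner] = (4 - 6 * au[inner] ** 2 + 3 * au[inner] ** 3) / 6
    out[outer] = (2 - au[outer]) ** 3 / 6
    return out


def _sample_points(fixed: Volume, n: int, seed: int) -> np.ndarray:
    """Uniform voxel-index sample over the fixed grid, shape (n, 3)."""
    rng = np.random.default_rng(seed)
    flat = rng.choice(int(np.prod(fixed.shape)), size=min(n, int(np.prod(fixed.shape))),
                      replace=False)
    return np.stack(np.unravel_index(flat, fixed.shape), axis=1).astype(float)


def mattes_mi(fixed: Volume, moving: Volume, t: RigidTransform | None = None,
              cfg: MattesConfig | None = None) -> float:
    """Mattes mutual information (nats) between fixed and transformed moving."""
    cfg = cfg or MattesConfig()
    t = t or RigidTransform(center_mm=volume_center_mm(fixed))

    idx = _sample_points(fixed, cfg.samples, cfg.seed)
    f_vals = fixed.data[tuple(idx.astype(int).T)]

    pts_mm = idx * np.array(fixed.spacing)
    moved_mm = t.apply(pts_mm)
    moved_idx = moved_mm / np.array(moving.spacing)

    shape = np.array(moving.shape)
    inside = np.all((moved_idx >= 0) & (moved_idx <= shape - 1), axis=1)
    if inside.sum() < cfg.bins:
        raise ValueError("empty (or nearly empty) overlap between volumes")
    f_vals = f_vals[inside]
    m_vals = ndimage.map_coordinates(moving.data, moved_idx[inside].T, order=1)

    if np.ptp(f_vals) == 0 or np.ptp(m_vals) == 0:
        raise ValueError("constant image in overlap region")

    return _mi_from_samples(f_vals, m_vals, cfg.bins)


def _mi_from_samples(f_vals: np.ndarray, m_vals: np.ndarray, bins: int) -> float:
    f_lo, f_hi = np.percentile(f_vals, [1, 99])
    m_lo, m_hi = np.percentile(m_vals, [1, 99])
    if f_hi <= f_lo:
        f_lo, f_hi = f_vals.min(), f_vals.max()
    if m_hi <= m_lo:
        m_lo, m_hi = m_vals.min(), m_vals.max()

    f_bin = np.clip(((f_vals - f_lo) / (f_hi - f_lo) * bins).astype(int), 0, bins - 1)
    # continuous bin coordinate on the moving axis for the B-spline kernel
    m_pos = np.clip((m_vals - m_lo) / (m_hi - m_lo) * bins, 0.0, bins - 1e-9)

    joint = np.zeros((bins, bins))
    base = np.floor(m_pos).astype(int)
    for off in (-2, -1, 0, 1):
        j = base + off
        w = _cubic_bspline(m_pos - j - 0.5)
        valid = (j >= 0) & (j < bins)
        np.add.at(joint, (f_bin[valid], j[valid]), w[valid])

    total = joint.sum()
    if total <= 0:
        return 0.0
    joint /= total
    pf = joint.sum(axis=1)
    pm = joint.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    return entropy(pf) + entropy(pm) - entropy(joint.ravel())


# ---------------------------------------------------------------------------
# Rigid optimization


@dataclass
class OptimizerSettings:
    """Coordinate-descent settings for rigid registration."""

    max_sweeps: int = 12
    bracket_mm: float = 10.0          # initial translation bracket half-width
    bracket_deg: float = 10.0         # initial rotation bracket half-width
    shrink: float = 0.6               # bracket shrink per sweep
    xtol: float = 0.02                # line-search tolerance (param units)
    ftol: float = 1e-5                # sweep improvement threshold (nats)
    levels: int = 2                   # multiresolution levels (coarse first)
    samples: int | None = 4000        # metric samples during optimization
    optimize_rotation: bool = True


@dataclass
class RegistrationResult:
    transform: RigidTransform
    mi: float
    converged: bool
    history: list[float] = field(default_factory=list)


def _decimate(vol: Volume, factor: int) -> Volume:
    sm = ndimage.gaussian_filter(vol.data, sigma=[0 if s < 2 * factor else factor / 2
                                                  for s in vol.shape])
    sl = tuple(slice(None, None, 1 if s < 2 * factor else factor) for s in vol.shape)
    data = sm[sl]
    spacing = tuple(sp * (1 if s < 2 * factor else factor)
                    for sp, s in zip(vol.spacing, vol.shape))
    return Volume(data, spacing=spacing, modality=vol.modality, units=vol.units)


def rigid_register(fixed: Volume, moving: Volume,
                   cfg: MattesConfig | None = None,
                   opt: OptimizerSettings | None = None,
                   initial: RigidTransform | None = None) -> RegistrationResult:
    """Maximize Mattes MI over rigid parameters by coordinate descent."""
    cfg = cfg or MattesConfig()
    opt = opt or OptimizerSettings()
    center = volume_center_mm(fixed)
    params = np.zeros(6)  # (rot0, rot1, rot2) deg, (t0, t1, t2) mm
    if initial is not None:
        params[:3] = initial.rotation_deg
        params[3:] = initial.translation_mm

    samples = opt.samples or cfg.samples
    history: list[float] = []
    converged = False

    for level in range(opt.levels - 1, -1, -1):
        factor = 2**level
        if factor > 1:
            fx, mv = _decimate(fixed, factor), _decimate(moving, factor)
        else:
            fx, mv = fixed, moving
        level_cfg = replace(cfg, samples=max(samples // factor, cfg.bins))

        def negmi(p: np.ndarray) -> float:
            tr = RigidTransform(tuple(p[:3]), tuple(p[3:]), center)
            try:
                return -mattes_mi(fx, mv, tr, level_cfg)
            except ValueError:
                return 0.0  # out of overlap: as bad as independence

        br_deg, br_mm = opt.bracket_deg, opt.bracket_mm
        current = negmi(params)
        for _ in range(opt.max_sweeps):
            previous = current
            param_order = ([3, 4, 5, 0, 1, 2] if opt.optimize_rotation
                           else [3, 4, 5])
            for i in param_order:
                half = br_deg if i < 3 else br_mm

                def line(x: float) -> float:
                    p = params.copy()
                    p[i] = x
                    return negmi(p)

                res = minimize_scalar(
                    line, bounds=(params[i] - half, params[i] + half),
                    method="bounded", options={"xatol": opt.xtol})
                if res.fun < current:
                    params[i] = float(res.x)
                    current = float(res.fun)
            history.append(-current)
            br_deg *= opt.shrink
            br_mm *= opt.shrink
            if previous - current < opt.ftol:
                converged = True
                break
        else:
            converged = False

    if not converged:
        warnings.warn("rigid registration did not converge; returning best-so-far",
                      RuntimeWarning)
    transform = RigidTransform(tuple(params[:3]), tuple(params[3:]), center)
    final_mi = mattes_mi(fixed, moving, transform, replace(cfg, samples=samples))
    return RegistrationResult(transform=transform, mi=final_mi,
                              converged=converged, history=history)


# ---------------------------------------------------------------------------
# Resampling


def resample(moving: Volume, t: RigidTransform, reference: Volume,
             fill: float | None = None) -> Volume:
    """Resample ``moving`` through ``t`` onto the reference grid (trilinear).

    Out-of-field voxels take ``fill`` (default -1000 for CT, 0 otherwise).
    """
    if fill is None:
        fill = -1000.0 if moving.modality in (Modality.CT, Modality.PSEUDO_CT) else 0.0
    idx = np.indices(reference.shape).reshape(3, -1).T.astype(float)
    pts_mm = idx * np.array(reference.spacing)
    moved_idx = t.apply(pts_mm) / np.array(moving.spacing)
    vals = ndimage.map_coordinates(moving.data, moved_idx.T, order=1,
                                   mode="constant", cval=fill)
    return Volume(vals.reshape(reference.shape), spacing=reference.spacing,
                  modality=moving.modality, units=moving.units)


def apply_deformation(moving: Volume, disp_field: np.ndarray, reference: Volume,
                      fill: float | None = None) -> Volume:
    """Warp ``moving`` by a per-voxel displacement field (pull-back, trilinear).

    ``disp_field`` has shape ``reference.shape + (3,)`` and gives, at each
    reference voxel, the displacement in voxel units added to the identity
    map before sampling the moving image.  This *applies* an externally
    estimated field; it does not estimate one.
    """
    if fill is None:
        fill = -1000.0 if moving.modality in (Modality.CT, Modality.PSEUDO_CT) else 0.0
    disp_field = np.asarray(disp_field, dtype=float)
    if disp_field.shape != reference.shape + (3,):
        raise ValueError(f"displacement field shape {disp_field.shape} does not "
                         f"match reference {reference.shape} + (3,)")
    idx = np.indices(reference.shape).astype(float)
    coords = idx + np.moveaxis(disp_field, -1, 0)
    vals = ndimage.map_coordinates(moving.data, coords.reshape(3, -1), order=1,
                                   mode="constant", cval=fill)
    return Volume(vals.reshape(reference.shape), spacing=reference.spacing,
                  modality=moving.modality, units=moving.units)
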