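"""Velocity-field container and 4D-flow error corrections.

Phase-contrast velocity data carry three classes of systematic error that
must be removed before any kinetic-energy or trans-valvular quantification:

* **aliasing** — velocities beyond the encoding limit (VENC) wrap around by
  multiples of 2·VENC;
* **residual background phase offsets** — slowly varying spurious velocity
  baselines left after on-scanner eddy-current/Maxwell compensation, removed
  here with a magnitude-weighted local phase-correction (LPC) filter
  estimated from static tissue, slice by slice;
* **spatial misalignment** between the cine stack (which provides the
  endocardial segmentation) and the 4D-flow acquisition, corrected with a
  user-supplied rigid transform.

Conventions: arrays are indexed ``(phase, z, y, x, component)`` with velocity
components ordered ``(vx, vy, vz)`` in cm/s; physical coordinates are
``origin + index * spacing`` with voxel-center addressing, 0-based indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import CoverageError, GeometryError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "VelocityField",
    "RigidTransform",
    "detect_static_mask",
    "local_phase_correction",
    "unwrap_velocity",
    "apply_rigid_transform",
]


@dataclass
class VelocityField:
    """Time-resolved three-component velocity volume with grid geometry.

    Attributes
    ----------
    v : ndarray, shape (n_phases, nz, ny, nx, 3)
        Velocity in cm/s, components (vx, vy, vz).
    mag : ndarray, shape (nz, ny, nx), optional
        Co-registered signal magnitude (arbitrary units, >= 0), used to
        weight the background-offset estimate.
    voxel_mm : tuple (dx, dy, dz)
        Voxel spacing in mm.
    phase_ms : float
        Temporal spacing of the reconstructed cardiac phases, ms.
    venc : float
        Velocity-encoding limit, cm/s.
    origin_mm : tuple (x0, y0, z0)
        Physical position of voxel (0, 0, 0), mm.
    """

    v: np.ndarray
    voxel_mm: tuple
    phase_ms: float
    venc: float
    mag: Optional[np.ndarray] = None
    origin_mm: tuple = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 5 or self.v.shape[-1] != 3:
            raise ParameterError("velocity array must have shape (T, Z, Y, X, 3)")
        if self.v.shape[0] < 2:
            raise ParameterError("at least two cardiac phases are required")
        if self.venc <= 0:
            raise ParameterError("VENC must be positive")
        if any(s <= 0 for s in self.voxel_mm):
            raise ParameterError("voxel spacing must be positive")

    @property
    def n_phases(self) -> int:
        return self.v.shape[0]

    @property
    def grid_shape(self) -> tuple:
        """Spatial shape as (nz, ny, nx)."""
        return self.v.shape[1:4]

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.voxel_mm
        return dx * dy * dz / 1000.0

    def speed(self) -> np.ndarray:
        """Velocity magnitude |v| per phase and voxel, cm/s."""
        return np.sqrt((self.v ** 2).sum(axis=-1))

    def voxel_centers_mm(self):
        """Physical voxel-center coordinate axes (x, y, z), each 1-D mm."""
        nz, ny, nx = self.grid_shape
        dx, dy, dz = self.voxel_mm
        x0, y0, z0 = self.origin_mm
        return (x0 + np.arange(nx) * dx,
                y0 + np.arange(ny) * dy,
                z0 + np.arange(nz) * dz)

    def copy(self) -> "VelocityField":
        return replace(self, v=self.v.copy(),
                       mag=None if self.mag is None else self.mag.copy(),
                       meta=dict(self.meta))


@dataclass(frozen=True)
class RigidTransform:
    """Rigid body motion: rotation (deg, about the volume center) + translation (mm).

    ``rotation_deg = (rx, ry, rz)`` is applied as R = Rz @ Ry @ Rx in the
    physical (x, y, z) frame; ``translation_mm`` is added afterwards.
    """

    rotation_deg: tuple = (0.0, 0.0, 0.0)
    translation_mm: tuple = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.rotation_deg))
                and np.all(np.isfinite(self.translation_mm))):
            raise ParameterError("rigid transform must be finite")


def detect_static_mask(field_: VelocityField,
                       std_threshold: float = 2.0,
                       mag_threshold: float = 0.2) -> np.ndarray:
    """Locate signal-bearing static tissue for background-offset estimation.

    A voxel is *static* when the temporal standard deviation of its speed is
    below ``std_threshold`` (cm/s) and — when a magnitude volume is present —
    its magnitude is at least ``mag_threshold`` times the volume median, so
    that noisy air is excluded.

    Returns a boolean volume of shape (nz, ny, nx).
    """
    sd = field_.speed().std(axis=0)
    static = sd < std_threshold
    if field_.mag is not None:
        med = float(np.median(field_.mag))
        static &= field_.mag >= mag_threshold * med
    n = int(static.sum())
    log.info("static-tissue mask: %d voxels (%.1f%%)", n, 100.0 * n / static.size)
    return static


def local_phase_correction(field_: VelocityField,
                           static: np.ndarray,
                           kernel_mm: float = 24.0) -> VelocityField:
    """Subtract residual background velocity offsets (LPC filter).

    For every slice and velocity component, the offset surface is estimated
    as the magnitude-weighted moving average (window of width ``kernel_mm``)
    of the *temporal-mean* velocity over static-tissue voxels, and subtracted
    from all phases.  Static tissue has zero true velocity, so its temporal
    mean estimates the local offset; weighting by signal magnitude
    de-emphasises noisy pixels.  Regions farther than the window from any
    static voxel (deep blood pool) receive the slice-wide weighted mean.

    Flowing-region velocities therefore change only by the estimated offset.
    """
    dx, dy, _ = field_.voxel_mm
    kx = max(1, int(round(kernel_mm / dx)))
    ky = max(1, int(round(kernel_mm / dy)))
    if kernel_mm < min(dx, dy):
        raise ParameterError("LPC kernel smaller than one voxel")
    if not np.any(static):
        raise GeometryError("LPC requires a non-empty static-tissue mask")

    out = field_.copy()
    vmean = field_.v.mean(axis=0)  # (Z, Y, X, 3)
    weight = static.astype(float)
    if field_.mag is not None:
        weight = weight * field_.mag
    nz = field_.grid_shape[0]
    n_skipped = 0
    offsets = np.zeros_like(vmean)
    for z in range(nz):
        w = weight[z]
        if not np.any(w > 0):
            n_skipped += 1
            log.warning("LPC: slice %d has no static tissue, skipped", z)
            continue
        den = ndimage.uniform_filter(w, size=(ky, kx), mode="constant")
        global_mean = np.zeros(3)
        for c in range(3):
            num = ndimage.uniform_filter(w * vmean[z, :, :, c],
                                         size=(ky, kx), mode="constant")
            global_mean[c] = (w * vmean[z, :, :, c]).sum() / w.sum()
            off = np.where(den > 1e-12, num / np.maximum(den, 1e-12),
                           global_mean[c])
            offsets[z, :, :, c] = off
    out.v = field_.v - offsets[None]
    out.meta["lpc_offsets"] = offsets
    out.meta["lpc_slices_skipped"] = n_skipped
    log.info("LPC applied: window %.0f mm, mean |offset| %.3f cm/s, %d slices skipped",
             kernel_mm, float(np.abs(offsets).mean()), n_skipped)
    return out


def unwrap_velocity(field_: VelocityField, max_iter: int = 15) -> VelocityField:
    """Correct single phase-aliasing wraps against a local median reference.

    Each component is compared to the median of its 3x3x3 spatial
    neighbourhood across the adjacent cardiac phases; voxels jumping by more
    than 1.0·VENC are shifted by the nearest integer multiple of 2·VENC.
    Only single wraps (one VENC interval) are corrected per sweep; sweeps
    repeat until stable so wrapped regions erode from their rim inwards.
    Double wraps relative to the local reference are flagged, not fixed.

    No voxel is altered by anything other than an integer multiple of
    2·VENC, so structurally correct output equals the truth exactly.
    """
    venc = field_.venc
    out = field_.copy()
    arr = out.v
    n_fixed_total = 0
    n_flagged = 0
    for _ in range(max_iter):
        med = ndimage.median_filter(arr, size=(3, 3, 3, 3, 1), mode="nearest")
        diff = arr - med
        k = np.rint(diff / (2.0 * venc))
        fix = (np.abs(k) == 1) & (np.abs(diff) > venc)
        n_flagged = int(np.count_nonzero(np.abs(k) >= 2))
        n = int(np.count_nonzero(fix))
        if n == 0:
            break
        arr[fix] -= 2.0 * venc * k[fix]
        n_fixed_total += n
    out.meta["unwrap_voxels_corrected"] = n_fixed_total
    out.meta["unwrap_voxels_flagged_multiwrap"] = n_flagged
    log.info("unwrap: corrected %d voxel-component wraps, flagged %d multi-wraps",
             n_fixed_total, n_flagged)
    return out


def apply_rigid_transform(field_: VelocityField, T: RigidTransform) -> VelocityField:
    """Resample the field under a rigid transform (trilinear) and rotate vectors.

    The transform maps input physical coordinates to output coordinates as
    ``x_out = R (x_in - c) + c + t`` about the volume center ``c``; velocity
    vectors are rotated by the same R.  The zero transform is the identity.
    """
    R = T.matrix()
    t = np.asarray(T.translation_mm, dtype=float)
    if np.allclose(R, np.eye(3)) and np.allclose(t, 0.0):
        return field_.copy()

    nz, ny, nx = field_.grid_shape
    dx, dy, dz = field_.voxel_mm
    x0, y0, z0 = field_.origin_mm
    spacing = np.array([dx, dy, dz])
    origin = np.array([x0, y0, z0])
    center = origin + spacing * (np.array([nx, ny, nz]) - 1) / 2.0

    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1) * spacing + origin  # (Z,Y,X,3) xyz
    # pull-back: sample the input at R^-1 (x_out - c - t) + c
    src = (pts.reshape(-1, 3) - center - t) @ R + center  # R^-1 = R.T, right-mult
    idx = (src - origin) / spacing  # fractional (x, y, z) indices
    in_bounds = np.all((idx >= -0.5) & (idx <= np.array([nx, ny, nz]) - 0.5), axis=1)
    if not np.any(in_bounds):
        raise CoverageError("rigid transform maps the entire FOV out of bounds")
    coords = np.stack([idx[:, 2], idx[:, 1], idx[:, 0]])  # (z, y, x) order

    out = field_.copy()
    # rotate vector components first, then resample each rotated component
    v_rot = field_.v @ R.T
    for ti in range(field_.n_phases):
        for c in range(3):
            out.v[ti, :, :, :, c] = ndimage.map_coordinates(
                v_rot[ti, :, :, :, c], coords, order=1, mode="constant",
                cval=0.0).reshape(nz, ny, nx)
    if field_.mag is not None:
        out.mag = ndimage.map_coordinates(field_.mag, coords, order=1,
                                          mode="constant", cval=0.0
                                          ).reshape(nz, ny, nx)
    out.meta["rigid_transform"] = {"rotation_deg": list(T.rotation_deg),
                                   "translation_mm": list(T.translation_mm)}
    return out
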