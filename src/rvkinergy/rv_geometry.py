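"""Time-resolved RV geometry from short-axis endocardial contours.

The right ventricle is segmented on a stack of short-axis cine slices.
Manual contours are drawn only at a handful of keyframe phases; this module
propagates them to every reconstructed phase, converts the contour stack
into a cylindrical-coordinate surface mesh (per-level centroid + radius as a
function of angle), rasterises the mesh onto the 4D-flow voxel grid, and
derives the standard volumetric/functional metrics (EDV, ESV, SV, EF,
TAPSE, right atrial area), optionally indexed to body surface area.

Conventions: contour points are physical (x, y) mm in the short-axis plane;
slices are ordered by ascending z with the apex at low z and the base at
high z; phases are 0-based with cyclic wrap across the R-R interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShPolygon

from .errors import GeometryError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "ContourStack", "RVMesh", "VolumeMetrics",
    "polygon_area_mm2", "polygon_centroid",
    "propagate_contours", "build_mesh", "mesh_to_mask",
    "volumes_from_contours", "volumes_from_masks", "compute_volumes",
    "compute_tapse", "compute_raa",
]

#: default keyframe phases of the manual segmentation (0-based; the
#: clinical convention numbers them 1, 6, 12, 18, 24 of 30)
DEFAULT_KEYFRAMES = (0, 5, 11, 17, 23)


@dataclass
class ContourStack:
    """Endocardial contours per phase and slice.

    ``contours[phase][slice]`` is an (M, 2) array of (x, y) mm vertices of a
    simple closed polygon (implicitly closed; last vertex != first), or
    ``None`` where the slice was not segmented at that phase.
    """

    contours: list
    slice_z_mm: np.ndarray
    slice_thickness_mm: float
    n_phases: int

    def __post_init__(self) -> None:
        self.slice_z_mm = np.asarray(self.slice_z_mm, dtype=float)
        if self.slice_thickness_mm <= 0:
            raise ParameterError("slice thickness must be positive")
        if np.any(np.diff(self.slice_z_mm) <= 0):
            raise ParameterError("slice positions must be strictly ascending")

    @property
    def n_slices(self) -> int:
        return len(self.slice_z_mm)

    def keyframe_subset(self, phases: Sequence[int] = DEFAULT_KEYFRAMES
                        ) -> "ContourStack":
        """Keep contours only at ``phases`` (others set to None)."""
        kept = [self.contours[p] if p in set(phases) else [None] * self.n_slices
                for p in range(self.n_phases)]
        return ContourStack(kept, self.slice_z_mm.copy(),
                            self.slice_thickness_mm, self.n_phases)


@dataclass
class RVMesh:
    """Cylindrical-coordinate RV surface per phase.

    radii[phase, level, angle] is the distance (mm) from the per-level
    centroid to the endocardial boundary along a uniform angle grid;
    level_z_mm are ascending level-plane positions shared across phases and
    dz_mm the level slab thickness, so the enclosed volume is
    sum(0.5 * r^2 * dtheta * dz).
    """

    radii: np.ndarray          # (T, L, A) mm
    centroids: np.ndarray      # (T, L, 2) mm
    level_z_mm: np.ndarray     # (L,)
    dz_mm: float

    @property
    def n_angles(self) -> int:
        return self.radii.shape[2]

    def volume_ml(self) -> np.ndarray:
        """Enclosed volume per phase, ml (midpoint rule in angle)."""
        dtheta = 2.0 * np.pi / self.n_angles
        vol_mm3 = 0.5 * (self.radii ** 2).sum(axis=(1, 2)) * dtheta * self.dz_mm
        return vol_mm3 / 1000.0


@dataclass
class VolumeMetrics:
    """Global RV volumetric function (Simpson disc summation)."""

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    es_phase: int
    bsa_m2: Optional[float] = None
    volume_ml: Optional[np.ndarray] = None

    @property
    def edvi_ml_m2(self):
        return None if self.bsa_m2 is None else self.edv_ml / self.bsa_m2

    @property
    def esvi_ml_m2(self):
        return None if self.bsa_m2 is None else self.esv_ml / self.bsa_m2

    @property
    def svi_ml_m2(self):
        return None if self.bsa_m2 is None else self.sv_ml / self.bsa_m2

    def as_dict(self) -> dict:
        d = {"edv_ml": self.edv_ml, "esv_ml": self.esv_ml, "sv_ml": self.sv_ml,
             "ef_pct": self.ef_pct, "es_phase": int(self.es_phase)}
        if self.bsa_m2 is not None:
            d.update(bsa_m2=self.bsa_m2, edvi_ml_m2=self.edvi_ml_m2,
                     esvi_ml_m2=self.esvi_ml_m2, svi_ml_m2=self.svi_ml_m2)
        return d


# ---------------------------------------------------------------- polygons

def polygon_area_mm2(points: np.ndarray) -> float:
    """Shoelace area (mm^2) of an implicitly closed polygon, >= 0."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of an implicitly closed polygon."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        raise GeometryError("degenerate polygon (zero area)")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def _ray_radii(points: np.ndarray, center: np.ndarray,
               angles: np.ndarray) -> np.ndarray:
    """Distance from ``center`` to the polygon boundary along each angle.

    Vectorised ray/segment intersection.  For non-star-shaped polygons the
    nearest intersection is used (fallback, logged by the caller).  Rays
    that miss entirely (numerically) fall back to the nearest vertex.
    """
    p = np.asarray(points, dtype=float) - center
    q = np.roll(p, -1, axis=0)
    d = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (A, 2)
    e = q - p                                               # (E, 2)
    # solve p + s e = t d  ->  cross products
    denom = d[:, None, 0] * (-e[None, :, 1]) - d[:, None, 1] * (-e[None, :, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (p[None, :, 0] * (-e[None, :, 1]) - p[None, :, 1] * (-e[None, :, 0])) / denom
        s = (d[:, None, 0] * p[None, :, 1] - d[:, None, 1] * p[None, :, 0]) / denom
    valid = (np.abs(denom) > 1e-12) & (s >= -1e-9) & (s <= 1 + 1e-9) & (t > 1e-9)
    t = np.where(valid, t, np.inf)
    r = t.min(axis=1)
    miss = ~np.isfinite(r)
    if np.any(miss):
        r[miss] = np.sqrt((p ** 2).sum(axis=1)).min()
    return r


# ------------------------------------------------------------- propagation

def propagate_contours(keyframes: ContourStack, n_phases: Optional[int] = None,
                       n_vertices: int = 64) -> ContourStack:
    """Interpolate keyframe contours to every cardiac phase.

    Each keyframe polygon is resampled to ``n_vertices`` rays at uniform
    angles from its area centroid (anchored at angle 0); the per-vertex
    radius and the centroid are then interpolated linearly in phase between
    flanking keyframes, cyclically across the R-R wrap, so keyframe phases
    are reproduced exactly.  A slice present in one flanking keyframe but
    absent in the other is ramped to zero area (radius scaled by the square
    root of the phase weight) and logged.
    """
    n_phases = n_phases or keyframes.n_phases
    key_phases = [p for p in range(keyframes.n_phases)
                  if any(c is not None for c in keyframes.contours[p])]
    if len(key_phases) < 2:
        raise ParameterError("at least two keyframe phases are required")

    angles = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    n_slices = keyframes.n_slices
    # per keyframe, per slice: (centroid, radii) or None
    resampled = {}
    for p in key_phases:
        per_slice = []
        for s in range(n_slices):
            poly = keyframes.contours[p][s]
            if poly is None:
                per_slice.append(None)
                continue
            poly = np.asarray(poly, dtype=float)
            if len(poly) < 8:
                raise GeometryError(f"contour phase {p} slice {s}: <8 vertices")
            c = polygon_centroid(poly)
            per_slice.append((c, _ray_radii(poly, c, angles)))
        resampled[p] = per_slice

    out = []
    for t in range(n_phases):
        if t in resampled:  # keyframes are exact fixed points
            out.append([None if p is None else np.asarray(p, dtype=float).copy()
                        for p in keyframes.contours[t]])
            continue
        # flanking keyframes, cyclic in phase
        prev = max([p for p in key_phases if p <= t], default=None)
        nxt = min([p for p in key_phases if p >= t], default=None)
        if prev is None:  # before first keyframe: wrap from last
            prev, span = key_phases[-1], key_phases[0] + n_phases - key_phases[-1]
            w = (t + n_phases - prev) / span
        elif nxt is None:  # after last keyframe: wrap to first
            nxt, span = key_phases[0], key_phases[0] + n_phases - prev
            w = (t - prev) / span
        elif prev == nxt:
            w = 0.0
            nxt = prev
        else:
            w = (t - prev) / (nxt - prev)
        per_slice = []
        for s in range(n_slices):
            a, b = resampled[prev][s], resampled[nxt][s]
            if a is None and b is None:
                per_slice.append(None)
                continue
            if a is None or b is None:
                ref = b if a is None else a
                ramp = w if a is None else 1.0 - w  # weight of present frame
                if ramp <= 0:
                    per_slice.append(None)
                    continue
                log.info("slice %d absent in one flanking keyframe at phase %d:"
                         " area-ramped", s, t)
                c, r = ref[0], ref[1] * np.sqrt(ramp)
            else:
                c = (1 - w) * a[0] + w * b[0]
                r = (1 - w) * a[1] + w * b[1]
            pts = c[None, :] + r[:, None] * np.stack(
                [np.cos(angles), np.sin(angles)], axis=1)
            per_slice.append(pts)
        out.append(per_slice)
    return ContourStack(out, keyframes.slice_z_mm.copy(),
                        keyframes.slice_thickness_mm, n_phases)


# -------------------------------------------------------------------- mesh

def build_mesh(contours: ContourStack, n_angles: int = 128,
               n_levels: Optional[int] = None) -> RVMesh:
    """Build the cylindrical RV mesh from a full (all-phase) contour stack.

    Levels are midpoints of ``n_levels`` equal slabs spanning the full disc
    extent (first slice bottom face to last slice top face).  The radius at
    a level/angle is interpolated linearly in z between the flanking slice
    contours' ray radii (constant extrapolation beyond the outermost slice
    centers), mirroring disc summation with a finer axial step.
    Defaults to 3 levels per slice.
    """
    T = contours.n_phases
    zs = contours.slice_z_mm
    dz_slice = contours.slice_thickness_mm
    n_levels = n_levels or 3 * contours.n_slices
    z_lo = zs[0] - dz_slice / 2.0
    z_hi = zs[-1] + dz_slice / 2.0
    dz = (z_hi - z_lo) / n_levels
    level_z = z_lo + (np.arange(n_levels) + 0.5) * dz
    angles = 2.0 * np.pi * np.arange(n_angles) / n_angles

    radii = np.zeros((T, n_levels, n_angles))
    cents = np.zeros((T, n_levels, 2))
    for t in range(T):
        slice_data = []
        for s in range(contours.n_slices):
            poly = contours.contours[t][s]
            if poly is None:
                slice_data.append(None)
                continue
            c = polygon_centroid(poly)
            slice_data.append((c, _ray_radii(np.asarray(poly), c, angles)))
        present = [s for s, d in enumerate(slice_data) if d is not None]
        if len(present) < 2:
            raise GeometryError(f"phase {t}: contours on fewer than 2 slices")
        zs_p = zs[present]
        cs = np.stack([slice_data[s][0] for s in present])
        rs = np.stack([slice_data[s][1] for s in present])
        for li, zl in enumerate(level_z):
            if zl <= zs_p[0]:
                cents[t, li], radii[t, li] = cs[0], rs[0]
            elif zl >= zs_p[-1]:
                cents[t, li], radii[t, li] = cs[-1], rs[-1]
            else:
                j = int(np.searchsorted(zs_p, zl)) - 1
                w = (zl - zs_p[j]) / (zs_p[j + 1] - zs_p[j])
                cents[t, li] = (1 - w) * cs[j] + w * cs[j + 1]
                radii[t, li] = (1 - w) * rs[j] + w * rs[j + 1]
    return RVMesh(radii, cents, level_z, dz)


def mesh_to_mask(mesh: RVMesh, grid_shape: tuple, voxel_mm: tuple,
                 origin_mm: tuple = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Rasterise the mesh onto a voxel grid: (T, nz, ny, nx) boolean.

    A voxel belongs to the RV when its center lies at a level slab (along z)
    and its in-plane distance from the level centroid does not exceed the
    (angle-interpolated) mesh radius; centers exactly on the surface are
    inside (closed-boundary rule).
    """
    nz, ny, nx = grid_shape
    dx, dy, dzv = voxel_mm
    x0, y0, z0 = origin_mm
    T, L, A = mesh.radii.shape
    xs = x0 + np.arange(nx) * dx
    ys = y0 + np.arange(ny) * dy
    zs = z0 + np.arange(nz) * dzv
    z_lo = mesh.level_z_mm[0] - mesh.dz_mm / 2.0
    z_hi = mesh.level_z_mm[-1] + mesh.dz_mm / 2.0
    eps = 1e-6 * mesh.dz_mm

    mask = np.zeros((T, nz, ny, nx), dtype=bool)
    X, Y = np.meshgrid(xs, ys, indexing="xy")  # (ny, nx) with Y rows
    for t in range(T):
        for zi, zv in enumerate(zs):
            # closed boundary rule: faces belong to the enclosed region
            if not (z_lo - eps <= zv <= z_hi + eps):
                continue
            li = int(np.clip((zv - z_lo) / mesh.dz_mm, 0, L - 1))
            cx, cy = mesh.centroids[t, li]
            ddx, ddy = X - cx, Y - cy
            dist = np.hypot(ddx, ddy)
            theta = np.mod(np.arctan2(ddy, ddx), 2.0 * np.pi)
            pos = theta / (2.0 * np.pi) * A
            j0 = np.floor(pos).astype(int) % A
            j1 = (j0 + 1) % A
            w = pos - np.floor(pos)
            r = (1 - w) * mesh.radii[t, li, j0] + w * mesh.radii[t, li, j1]
            mask[t, zi] = dist <= r + 1e-9
        if not mask[t].any():
            raise GeometryError(f"phase {t}: empty RV mask")
    return mask


# ------------------------------------------------------------ volumetrics

def volumes_from_contours(contours: ContourStack) -> np.ndarray:
    """Disc-summed RV volume per phase, ml (area x slice thickness)."""
    vols = np.zeros(contours.n_phases)
    for t in range(contours.n_phases):
        a = sum(polygon_area_mm2(p) for p in contours.contours[t]
                if p is not None)
        vols[t] = a * contours.slice_thickness_mm / 1000.0
    return vols


def volumes_from_masks(masks: np.ndarray, voxel_mm: tuple) -> np.ndarray:
    """Voxel-counted volume per phase, ml."""
    dx, dy, dz = voxel_mm
    return masks.reshape(masks.shape[0], -1).sum(axis=1) * dx * dy * dz / 1000.0


def compute_volumes(volume_ml: np.ndarray,
                    bsa_m2: Optional[float] = None) -> VolumeMetrics:
    """EDV/ESV/SV/EF from a per-phase volume series.

    EDV is the maximum, ESV the minimum (earliest phase on ties), EF =
    100*SV/EDV; indexed variants divide by BSA.
    """
    v = np.asarray(volume_ml, dtype=float)
    if v.size < 2:
        raise ParameterError("need at least two phases")
    if bsa_m2 is not None and bsa_m2 <= 0:
        raise ParameterError("BSA must be positive")
    edv = float(v.max())
    es = int(np.argmin(v))
    esv = float(v[es])
    sv = edv - esv
    ef = 100.0 * sv / edv if edv > 0 else 0.0
    return VolumeMetrics(edv, esv, sv, ef, es, bsa_m2, v)


def compute_tapse(annulus_mm: np.ndarray, es_phase: Optional[int] = None,
                  long_axis: Sequence[float] = (0.0, 0.0, -1.0)
                  ) -> Optional[float]:
    """Tricuspid annular plane systolic excursion, mm.

    ``annulus_mm`` holds the lateral tricuspid annulus landmark per phase,
    (T, 3) mm, from the 4-chamber view.  The excursion is the displacement
    from end-diastole (phase 0) projected onto the apex-ward long-axis unit
    vector, evaluated at end-systole (or its maximum over the cycle when
    ``es_phase`` is None).  Returns None when any landmark is missing.
    """
    p = np.asarray(annulus_mm, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ParameterError("need landmark positions for at least 2 phases")
    if np.any(~np.isfinite(p)):
        log.warning("TAPSE: missing landmark, metric reported absent")
        return None
    axis = np.asarray(long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = (p - p[0]) @ axis
    if es_phase is not None:
        return float(abs(proj[es_phase]))
    return float(np.max(np.abs(proj)))


def compute_raa(polygon_mm: np.ndarray,
                bsa_m2: Optional[float] = None) -> dict:
    """Right atrial area (cm^2) of a 4-chamber contour at end-systole.

    The contour is drawn just before tricuspid valve opening.  Reported in
    cm^2 (with the BSA-indexed value when BSA is given); the sign of the
    vertex ordering is irrelevant (shoelace absolute value).
    """
    p = np.asarray(polygon_mm, dtype=float)
    if len(p) < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    sh = _ShPolygon(p)
    if not sh.is_valid:
        raise GeometryError("self-intersecting right atrial contour")
    area_cm2 = polygon_area_mm2(p) / 100.0
    if area_cm2 <= 0:
        raise GeometryError("degenerate (zero-area) right atrial contour")
    out = {"raa_cm2": area_cm2}
    if bsa_m2 is not None:
        if bsa_m2 <= 0:
            raise ParameterError("BSA must be positive")
        out["raai_cm2_m2"] = area_cm2 / bsa_m2
    return out
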