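"""Retrospective valve tracking: tricuspid through-plane flow quantification.

A measurement plane follows the tricuspid annulus through the cardiac cycle
(landmarks from the 4- and 2-chamber views), oriented perpendicular to the
inflow direction.  Velocities are reformatted onto the plane, projected onto
its normal, corrected for through-plane annular motion and residual phase
offset by subtracting the mean velocity sampled in the adjacent myocardium,
and integrated over the valve aperture to give the flow-rate curve, the
tricuspid stroke volume and the diastolic E/A peak velocities.

Sign convention: apex-ward (into the RV during diastole) is positive
through-plane velocity, so diastolic inflow integrates to positive volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage

from .errors import CoverageError, GeometryError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "AnnularTrack", "ValvePlane", "PlaneVelocityMaps", "TVFlowCurve",
    "track_plane", "reformat_plane_velocity", "myocardial_ring_mask",
    "background_correct_plane", "tv_flow_metrics",
]


@dataclass
class AnnularTrack:
    """Tricuspid annulus landmarks per phase.

    ``landmarks_mm`` has shape (T, 4, 3): two points from the 4-chamber and
    two from the 2-chamber view, physical (x, y, z) mm.  ``apex_mm`` (T, 3)
    optionally provides the RV apex, which fixes the inflow direction.
    """

    landmarks_mm: np.ndarray
    apex_mm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.landmarks_mm = np.asarray(self.landmarks_mm, dtype=float)
        if self.landmarks_mm.ndim != 3 or self.landmarks_mm.shape[1:] != (4, 3):
            raise ParameterError("landmarks must have shape (T, 4, 3)")
        if self.apex_mm is not None:
            self.apex_mm = np.asarray(self.apex_mm, dtype=float)

    @property
    def n_phases(self) -> int:
        return self.landmarks_mm.shape[0]


@dataclass
class ValvePlane:
    """One phase's measurement plane: center, unit normal, in-plane basis."""

    center_mm: np.ndarray
    normal: np.ndarray
    e1: np.ndarray
    e2: np.ndarray


@dataclass
class PlaneVelocityMaps:
    """Reformatted through-plane velocity maps on a common in-plane grid."""

    v_through: np.ndarray        # (T, Nb, Na) cm/s, + = apex-ward
    a_mm: np.ndarray             # (Na,) in-plane coordinate along e1
    b_mm: np.ndarray             # (Nb,) along e2
    inside_aperture: np.ndarray  # (T, Nb, Na) bool, per-phase aperture
    aperture_area_cm2: np.ndarray  # (T,) exact polygon area
    pitch_mm: float
    planes: list


@dataclass
class TVFlowCurve:
    """Tricuspid through-plane flow metrics."""

    q_ml_s: np.ndarray
    mean_vel_cm_s: np.ndarray
    peak_vel_cm_s: np.ndarray
    sv_ml: float
    peak_e_vel: Optional[float]
    peak_a_vel: Optional[float]
    ea_vel_ratio: Optional[float]

    def as_dict(self) -> dict:
        return {"sv_ml": self.sv_ml, "peak_e_vel_cm_s": self.peak_e_vel,
                "peak_a_vel_cm_s": self.peak_a_vel,
                "ea_vel_ratio": self.ea_vel_ratio}


def track_plane(track: AnnularTrack) -> list:
    """Per-phase valve plane from the annular landmark track.

    The plane center is the mean of the four landmarks.  The normal (the
    inflow direction) points from the annular center toward the RV apex
    landmark when one is supplied; otherwise it is the best-fit plane normal
    of the landmarks (smallest singular vector), with its sign fixed
    apex-ward (-z) by the short-axis convention.  Collinear landmarks leave
    the plane undefined.
    """
    planes = []
    for t in range(track.n_phases):
        pts = track.landmarks_mm[t]
        if len(np.unique(pts, axis=0)) < 3:
            raise GeometryError(f"phase {t}: annular landmarks not distinct")
        center = pts.mean(axis=0)
        centered = pts - center
        _, s, vt = np.linalg.svd(centered)
        if s[1] < 1e-9:
            raise GeometryError(f"phase {t}: collinear landmarks, plane undefined")
        if track.apex_mm is not None:
            n = track.apex_mm[t] - center
            if np.linalg.norm(n) < 1e-9:
                raise GeometryError(f"phase {t}: apex coincides with annulus")
        else:
            n = vt[2]
            if n[2] > 0:  # apex-ward = -z by convention
                n = -n
        n = n / np.linalg.norm(n)
        # in-plane basis: e1 along the first landmark's in-plane projection
        raw = centered[0] - np.dot(centered[0], n) * n
        if np.linalg.norm(raw) < 1e-9:
            raw = np.array([1.0, 0.0, 0.0]) - n[0] * n
        e1 = raw / np.linalg.norm(raw)
        e2 = np.cross(n, e1)
        planes.append(ValvePlane(center, n, e1, e2))
    return planes


def _project(points_xyz: np.ndarray, plane: ValvePlane) -> np.ndarray:
    """Project 3-D points into the plane's (a, b) coordinates."""
    d = np.asarray(points_xyz, dtype=float) - plane.center_mm
    return np.stack([d @ plane.e1, d @ plane.e2], axis=-1)


def reformat_plane_velocity(field_, planes: list, aperture_xyz: list,
                            pitch_mm: Optional[float] = None,
                            margin_mm: float = 20.0) -> PlaneVelocityMaps:
    """Sample through-plane velocity on a regular in-plane grid per phase.

    The grid covers the aperture polygon's in-plane bounding box plus
    ``margin_mm`` (room for the myocardial background ROI) at a pitch of
    half the smallest voxel dimension (oversampling stabilises the flux
    integral).  Velocities are interpolated trilinearly and projected onto
    the plane normal.  ``aperture_xyz`` is the valve aperture polygon per
    phase as (M, 3) physical points lying in the plane.
    """
    T = field_.n_phases
    if len(planes) != T or len(aperture_xyz) != T:
        raise ParameterError("need one plane and aperture polygon per phase")
    pitch = pitch_mm or 0.5 * min(field_.voxel_mm)

    # common in-plane grid from the union of per-phase aperture extents
    ab0 = [_project(ap, pl) for ap, pl in zip(aperture_xyz, planes)]
    lo = np.min([ab.min(axis=0) for ab in ab0], axis=0) - margin_mm
    hi = np.max([ab.max(axis=0) for ab in ab0], axis=0) + margin_mm
    a = np.arange(lo[0], hi[0] + pitch / 2, pitch)
    b = np.arange(lo[1], hi[1] + pitch / 2, pitch)
    A, B = np.meshgrid(a, b, indexing="xy")  # (Nb, Na)

    dx, dy, dz = field_.voxel_mm
    x0, y0, z0 = field_.origin_mm
    nzg, nyg, nxg = field_.grid_shape
    vmaps = np.zeros((T, B.shape[0], B.shape[1]))
    any_inside = False
    for t, pl in enumerate(planes):
        pts = (pl.center_mm[None, :]
               + A.reshape(-1, 1) * pl.e1[None, :]
               + B.reshape(-1, 1) * pl.e2[None, :])
        idx = (pts - np.array([x0, y0, z0])) / np.array([dx, dy, dz])
        inb = np.all((idx > -0.5) & (idx < np.array([nxg, nyg, nzg]) - 0.5),
                     axis=1)
        any_inside |= bool(inb.any())
        coords = np.stack([idx[:, 2], idx[:, 1], idx[:, 0]])
        comp = [ndimage.map_coordinates(field_.v[t, :, :, :, c], coords,
                                        order=1, mode="constant", cval=0.0)
                for c in range(3)]
        v3 = np.stack(comp, axis=-1)
        vmaps[t] = (v3 @ pl.normal).reshape(B.shape)
    if not any_inside:
        raise CoverageError("valve plane aperture lies entirely outside the FOV")

    # per-phase aperture mask and exact polygon area (the contoured valve
    # aperture opens and closes through the cycle)
    from .rv_geometry import polygon_area_mm2
    pts2 = np.stack([A.ravel(), B.ravel()], axis=1)
    inside = np.zeros((T,) + B.shape, dtype=bool)
    area_cm2 = np.zeros(T)
    for t in range(T):
        inside[t] = _MplPath(ab0[t]).contains_points(
            pts2, radius=1e-9).reshape(B.shape)
        area_cm2[t] = polygon_area_mm2(ab0[t]) / 100.0
    return PlaneVelocityMaps(vmaps, a, b, inside, area_cm2, pitch, planes)


def myocardial_ring_mask(maps: PlaneVelocityMaps, aperture_ab: np.ndarray,
                         inner_margin_mm: float = 6.0,
                         outer_margin_mm: float = 14.0) -> np.ndarray:
    """Myocardial ROI: a ring around the aperture in the reformatted plane.

    The ring lies between the aperture polygon radially offset by the inner
    and outer margins (about its centroid), sampling annular myocardium and
    adjacent static tissue.
    """
    from .rv_geometry import polygon_centroid
    c = polygon_centroid(aperture_ab)
    d = aperture_ab - c
    r = np.linalg.norm(d, axis=1, keepdims=True)
    u = d / np.maximum(r, 1e-9)
    inner = c + d + u * inner_margin_mm
    outer = c + d + u * outer_margin_mm
    A, B = np.meshgrid(maps.a_mm, maps.b_mm, indexing="xy")
    pts = np.stack([A.ravel(), B.ravel()], axis=1)
    m_out = _MplPath(outer).contains_points(pts)
    m_in = _MplPath(inner).contains_points(pts)
    return (m_out & ~m_in).reshape(B.shape)


def background_correct_plane(maps: PlaneVelocityMaps,
                             myocardium_roi: np.ndarray) -> PlaneVelocityMaps:
    """Subtract the per-phase mean myocardial through-plane velocity.

    Removes both the annular through-plane motion (the plane itself moves
    with the valve) and any residual phase offset.  An empty ROI skips the
    correction with a warning.
    """
    if not np.any(myocardium_roi):
        log.warning("background correction skipped: empty myocardial ROI")
        return maps
    corrected = maps.v_through.copy()
    for t in range(corrected.shape[0]):
        corrected[t] -= corrected[t][myocardium_roi].mean()
    return PlaneVelocityMaps(corrected, maps.a_mm, maps.b_mm,
                             maps.inside_aperture, maps.aperture_area_cm2,
                             maps.pitch_mm, maps.planes)


def tv_flow_metrics(maps: PlaneVelocityMaps, phase_ms: float, timing,
                    forward_only: bool = True) -> TVFlowCurve:
    """Flow-rate curve, tricuspid stroke volume and E/A peak velocities.

    The per-phase flow rate is the mean in-aperture through-plane velocity
    times the exact aperture polygon area (ml/s).  Stroke volume integrates
    the diastolic flow (forward-only by default; set ``forward_only=False``
    for net flow).  Peak E and A velocities are the maxima of the per-phase
    peak in-aperture velocity over the respective diastolic windows.
    """
    if not np.any(maps.inside_aperture):
        raise GeometryError("aperture contains no sample points")
    T = maps.v_through.shape[0]
    mean_v = np.array([maps.v_through[t][maps.inside_aperture[t]].mean()
                       for t in range(T)])
    peak_v = np.array([maps.v_through[t][maps.inside_aperture[t]].max()
                       for t in range(T)])
    q = mean_v * maps.aperture_area_cm2  # cm/s * cm^2 = ml/s
    dt_s = phase_ms / 1000.0
    qd = q[timing.diastole]
    sv = float(np.sum(np.maximum(qd, 0.0) if forward_only else qd) * dt_s)
    if sv <= 0:
        log.warning("no diastolic forward flow: TV SV = 0")
        sv = max(sv, 0.0)
    pe = float(peak_v[timing.e_window].max())
    pa = float(peak_v[timing.a_window].max())
    ea = None if pa <= 0 else pe / pa
    return TVFlowCurve(q, mean_v, peak_v, sv,
                       pe if pe > 0 else None, pa if pa > 0 else None, ea)
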