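"""Phantom 4D-flow datasets with analytic ground truth, and synthetic cohorts.

No subject-level data accompany the study this package operationalises, so
validation rests on two simulators:

* a **cardiac flow phantom**: a time-varying solid of revolution (tapered
  stack of short-axis discs) whose cavity volume traces EDV -> ESV -> EDV
  with a two-stage (E/A) refilling, filled with a spatially uniform,
  long-axis-aligned velocity whose magnitude follows a three-peak program
  (systolic ejection, early- and late-diastolic filling).  Uniform speed
  makes the total kinetic energy exactly 0.5*rho*V(t)*v(t)^2 in closed
  form, so every downstream stage can be checked against arithmetic.  A
  parabolic (Poiseuille-like) profile is available for realism, in which
  case truth comes from the voxelised oracle rather than the closed form.

* a **synthetic cohort** built with a Gaussian-copula, single-factor
  construction: each metric's latent variable loads on the common age
  latent with exactly the programmed Spearman correlation, and marginals
  are Gaussians truncated to positivity (matching reported mean +/- SD
  summaries).  Rank correlations survive the monotone marginal transforms
  exactly.

Defaults emulate a 30-phase, 3 mm isotropic, VENC 150 cm/s acquisition and
a 53-subject healthy cohort aged 20-80.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath
from scipy import stats

from . import ke_mapping
from .errors import ParameterError, SizingError, SpecificationError
from .flow_preprocess import VelocityField
from .rv_geometry import ContourStack, polygon_area_mm2
from .valve_flow import AnnularTrack

log = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec", "PhantomTruth", "CohortSpec",
    "make_geometry", "make_velocity_field", "wrap_velocities",
    "make_annular_track", "calibrate_ea_ratio",
    "make_cohort", "DEFAULT_EFFECTS",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Acquisition geometry + physiology program of the flow phantom.

    Speeds are peak intracavity magnitudes (cm/s).  With ``conserve_mass``
    the diastolic speed program is rescaled by a single factor so that the
    inflow through the valve plane integrates exactly to the cine stroke
    volume (incompressible filling); the E/A speed ratio is preserved.
    """

    grid_shape: tuple = (48, 48, 16)      # (nx, ny, nz)
    voxel_mm: tuple = (3.0, 3.0, 3.0)
    n_phases: int = 30
    phase_ms: float = 40.0
    venc: float = 150.0
    edv_ml: float = 150.0
    esv_ml: float = 60.0
    es_phase: int = 10
    v_sys: float = 24.0
    v_e: float = 14.0
    v_a: float = 9.0
    noise_sd: float = 1.5
    offset_model: Optional[dict] = None
    seed: int = 0
    # geometry details
    n_slices: int = 10
    taper: float = 0.3
    n_vertices: int = 48
    e_fraction: float = 0.6      # fraction of refilling volume in the E phase
    e_window_frac: float = 0.55  # fraction of diastole spanned by the E bump
    profile: str = "uniform"     # or "parabolic"
    conserve_mass: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.es_phase < self.n_phases - 2):
            raise SpecificationError("need 0 < es_phase < n_phases - 2")
        if not (0 < self.esv_ml <= self.edv_ml):
            raise SpecificationError("need 0 < ESV <= EDV")
        if self.venc <= 0:
            raise SpecificationError("VENC must be positive")
        if min(self.v_sys, self.v_e, self.v_a) < 0 or self.noise_sd < 0:
            raise SpecificationError("speeds and noise SD must be >= 0")
        if self.profile not in ("uniform", "parabolic"):
            raise SpecificationError("profile must be 'uniform' or 'parabolic'")


@dataclass
class PhantomTruth:
    """Analytic ground truth carried alongside the generated data."""

    volume_ml: np.ndarray
    speed_cm_s: np.ndarray = None
    ke_uJ: np.ndarray = None
    kei_uJ_ml: np.ndarray = None
    ke_params: "ke_mapping.KEParameters" = None
    timing: "ke_mapping.CardiacTiming" = None
    tv_sv_ml: float = None
    warnings: list = field(default_factory=list)


# ------------------------------------------------------------- programs

def volume_program(spec: PhantomSpec) -> np.ndarray:
    """Cavity volume per phase, ml: EDV -> ESV (at es_phase) -> EDV.

    Emptying follows a half-cosine; refilling is two smooth stages carrying
    ``e_fraction`` of the volume in the first ``e_window_frac`` of diastole
    (early filling) and the rest late (atrial filling), so dV/dt shows the
    E and A waves.
    """
    t = np.arange(spec.n_phases, dtype=float)
    es, n = spec.es_phase, spec.n_phases
    w = np.empty_like(t)
    sysl = t <= es
    w[sysl] = 0.5 * (1 + np.cos(np.pi * t[sysl] / es))
    tau = (t[~sysl] - es) / (n - es)
    fe, fw = spec.e_fraction, spec.e_window_frac
    h = lambda u: 0.5 * (1 - np.cos(np.pi * np.clip(u, 0, 1)))
    w[~sysl] = np.where(tau <= fw,
                        fe * h(tau / fw),
                        fe + (1 - fe) * h((tau - fw) / (1 - fw)))
    return spec.esv_ml + (spec.edv_ml - spec.esv_ml) * w


def speed_program(spec: PhantomSpec) -> np.ndarray:
    """Unscaled intracavity speed magnitude per phase, cm/s.

    Three smooth sin^2 bumps: systolic (peak v_sys at mid-systole), early
    diastolic (v_e) over the first ``e_window_frac`` of diastole, late
    diastolic (v_a) over the rest; zero at end-systole.
    """
    t = np.arange(spec.n_phases, dtype=float)
    es, n = spec.es_phase, spec.n_phases
    s = np.zeros_like(t)
    sysl = (t > 0) & (t < es)
    s[sysl] = spec.v_sys * np.sin(np.pi * t[sysl] / es) ** 2
    dia = t > es
    tau = (t[dia] - es) / (n - es)
    fw = spec.e_window_frac
    s[dia] = np.where(tau <= fw,
                      spec.v_e * np.sin(np.pi * tau / fw) ** 2,
                      spec.v_a * np.sin(np.pi * (tau - fw) / (1 - fw)) ** 2)
    return s


# ------------------------------------------------------------- geometry

def _slice_layout(spec: PhantomSpec):
    """Slice centers (mm), thickness (mm) and taper factors of the stack.

    The cavity height is an integer number of voxel layers, with its axial
    faces midway between voxel-center planes, so the discrete voxel
    membership carries no axial quantisation bias and the in-plane
    agreement with the closed-form volume is what the voxel checks measure.
    """
    nx, ny, nz = spec.grid_shape
    dzv = spec.voxel_mm[2]
    m = max(4, int(round(0.8 * nz)))  # voxel layers spanned by the cavity
    height = m * dzv
    th = height / spec.n_slices
    zmid = (nz - 1) * dzv / 2.0
    z_lo = np.round((zmid - height / 2.0 - dzv / 2.0) / dzv) * dzv + dzv / 2.0
    zc = z_lo + (np.arange(spec.n_slices) + 0.5) * th
    k = np.arange(spec.n_slices)
    f = 1.0 - spec.taper * (spec.n_slices - 1 - k) / max(spec.n_slices - 1, 1)
    return zc, th, f


def _cavity_center(spec: PhantomSpec) -> np.ndarray:
    """In-plane cavity center, offset off the grid symmetry axes so that
    voxel-membership discretisation errors do not align across slices."""
    nx, ny, _ = spec.grid_shape
    dx, dy, _ = spec.voxel_mm
    return np.array([(nx - 1) / 2.0 * dx + 0.4 * dx,
                     (ny - 1) / 2.0 * dy + 0.3 * dy])


#: valve (tricuspid-inflow) measurement plane sits at this slice, counted
#: from the base; interior to the stack so reformatting stays in-grid
PLANE_SLICE_FROM_BASE = 2


def make_geometry(spec: PhantomSpec):
    """Per-phase, per-slice endocardial contours of the phantom cavity.

    The cavity is a tapered stack of regular polygons (apex slices narrower
    by ``taper``).  Polygon radii are scaled so that the *shoelace* disc
    summation reproduces the programmed volume exactly, making the contour
    stack itself the volumetric ground truth.

    Returns (ContourStack, PhantomTruth with the volume series).
    """
    vols = volume_program(spec)
    zc, th, f = _slice_layout(spec)
    center = _cavity_center(spec)
    nx, ny, _ = spec.grid_shape
    dx, dy, _ = spec.voxel_mm
    nv = spec.n_vertices
    # regular n-gon of "radius" r has area 0.5*nv*sin(2pi/nv)*r^2; inflate r
    # so the polygon area equals the target circle area exactly
    g = np.sqrt(np.pi / (0.5 * nv * np.sin(2 * np.pi / nv)))
    angles = 2 * np.pi * np.arange(nv) / nv
    unit = np.stack([np.cos(angles), np.sin(angles)], axis=1)

    r_base_max = g * np.sqrt(vols.max() * 1000.0 / (np.pi * th * f.sum()))
    half_x = min(center[0], (nx - 1) * dx - center[0])
    half_y = min(center[1], (ny - 1) * dy - center[1])
    if r_base_max > min(half_x, half_y):
        raise SizingError(
            f"cavity radius {r_base_max:.1f} mm exceeds grid half-extent "
            f"{min(half_x, half_y):.1f} mm")

    contours = []
    for t in range(spec.n_phases):
        r0 = g * np.sqrt(vols[t] * 1000.0 / (np.pi * th * f.sum()))
        per_slice = [center + r0 * np.sqrt(fk) * unit for fk in f]
        contours.append(per_slice)
    stack = ContourStack(contours, zc, th, spec.n_phases)
    return stack, PhantomTruth(volume_ml=vols)


def _phase_masks(spec: PhantomSpec, contours: ContourStack) -> np.ndarray:
    """Voxel membership of the cavity per phase (nearest-slice polygon)."""
    nx, ny, nz = spec.grid_shape
    dx, dy, dzv = spec.voxel_mm
    zc, th = contours.slice_z_mm, contours.slice_thickness_mm
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    zs = np.arange(nz) * dzv
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    masks = np.zeros((spec.n_phases, nz, ny, nx), dtype=bool)
    z_lo, z_hi = zc[0] - th / 2.0, zc[-1] + th / 2.0
    for t in range(spec.n_phases):
        slice_inside = {}
        for zi, zv in enumerate(zs):
            if not (z_lo <= zv < z_hi):
                continue
            k = min(int((zv - z_lo) / th), contours.n_slices - 1)
            if k not in slice_inside:
                path = _MplPath(contours.contours[t][k])
                slice_inside[k] = path.contains_points(
                    pts, radius=1e-9).reshape(ny, nx)
            masks[t, zi] = slice_inside[k]
    return masks


def plane_slice_index(spec: PhantomSpec) -> int:
    return spec.n_slices - 1 - PLANE_SLICE_FROM_BASE


def _plane_areas_cm2(spec: PhantomSpec, contours: ContourStack) -> np.ndarray:
    k = plane_slice_index(spec)
    return np.array([polygon_area_mm2(contours.contours[t][k])
                     for t in range(spec.n_phases)]) / 100.0


def make_velocity_field(spec: PhantomSpec, contours: ContourStack,
                        truth: Optional[PhantomTruth] = None):
    """Realise the phantom velocity field and complete the ground truth.

    Inside the cavity the velocity is long-axis aligned (z) with the
    programmed per-phase magnitude: base-ward (+z) during systolic ejection,
    apex-ward (-z, i.e. inflow-positive through the valve plane) during
    diastolic filling.  Outside: zero, plus the configured background
    offset model and Gaussian noise.  A magnitude volume distinguishes
    signal-bearing tissue from noisy air at the FOV margin.

    Returns (VelocityField, PhantomTruth).
    """
    if truth is None:
        truth = PhantomTruth(volume_ml=volume_program(spec))
    vols = truth.volume_ml
    s = speed_program(spec)
    es, n = spec.es_phase, spec.n_phases
    dia = np.arange(es + 1, n)

    if spec.conserve_mass:
        areas = _plane_areas_cm2(spec, contours)
        influx = float((s[dia] * areas[dia]).sum() * spec.phase_ms / 1000.0)
        sv = float(vols.max() - vols.min())
        if influx > 0:
            lam = sv / influx
            s = s.copy()
            s[dia] *= lam
            log.info("mass conservation: diastolic speeds scaled by %.3f", lam)

    masks = _phase_masks(spec, contours)
    nx, ny, nz = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    v = np.zeros((n, nz, ny, nx, 3))

    # axial sign: +z (base-ward) in systole, -z (apex-ward inflow) in diastole
    sign = np.where(np.arange(n) <= es, 1.0, -1.0)
    if spec.profile == "uniform":
        for t in range(n):
            v[t, :, :, :, 2][masks[t]] = sign[t] * s[t]
    else:
        shape = _parabolic_shape(spec, contours, masks)
        for t in range(n):
            v[t, :, :, :, 2] = sign[t] * s[t] * shape[t]

    # magnitude volume: signal-bearing body, noisy air ring at the margin
    dx, dy, _ = spec.voxel_mm
    center = _cavity_center(spec)
    X, Y = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dy, indexing="xy")
    body_r = 0.95 * min(min(center[0], (nx - 1) * dx - center[0]),
                        min(center[1], (ny - 1) * dy - center[1]))
    body = (np.hypot(X - center[0], Y - center[1]) <= body_r)
    mag = np.where(body[None, :, :], 100.0, 6.0) * np.ones((nz, 1, 1))

    if spec.offset_model is not None:
        v += _offset_volume(spec)[None, :, :, :, :]
    if spec.noise_sd > 0:
        v += rng.normal(0.0, spec.noise_sd, size=v.shape)
        air = ~body
        v[:, :, air, :] += rng.normal(0.0, 3.0 * spec.noise_sd,
                                      size=v[:, :, air, :].shape)

    if np.max(np.abs(s)) > spec.venc:
        truth.warnings.append(
            f"programmed speed {np.max(np.abs(s)):.0f} cm/s exceeds VENC "
            f"{spec.venc:.0f}; wrap_velocities() will alias it")
        log.warning(truth.warnings[-1])

    field_ = VelocityField(v, spec.voxel_mm, spec.phase_ms, spec.venc,
                           mag=mag, meta={"phantom": True})

    # --- analytic truth ---------------------------------------------------
    truth.speed_cm_s = s
    if spec.profile == "uniform":
        ke = (0.5 * ke_mapping.RHO_BLOOD_G_CM3 * vols * s ** 2
              * ke_mapping.ERG_TO_UJ)  # 0.05 * 1.06 * V[ml=cm^3] * v^2
    else:
        # voxel oracle: sum over the clean (pre-noise/offset) field
        vvox = field_.voxel_volume_cm3
        ke = np.array([
            ke_mapping.voxel_ke(s[t] * shape[t][masks[t]], vvox).sum()
            for t in range(n)])
    edv = float(vols.max())
    truth.ke_uJ = ke
    truth.kei_uJ_ml = ke / edv
    truth.timing = ke_mapping.detect_cardiac_phases(vols, truth.kei_uJ_ml)
    truth.ke_params = ke_mapping.extract_ke_parameters(
        ke_mapping.KECurve(ke, ke / edv, spec.phase_ms, edv), truth.timing)
    areas = _plane_areas_cm2(spec, contours)
    truth.tv_sv_ml = float((np.maximum(s[dia], 0) * areas[dia]).sum()
                           * spec.phase_ms / 1000.0)
    return field_, truth


def _parabolic_shape(spec, contours, masks):
    """Per-phase spatial factor for the Poiseuille-like profile (peak 2x mean)."""
    from .rv_geometry import polygon_centroid, _ray_radii
    nx, ny, nz = spec.grid_shape
    dx, dy, dzv = spec.voxel_mm
    zc, th = contours.slice_z_mm, contours.slice_thickness_mm
    X, Y = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dy, indexing="xy")
    angles = 2 * np.pi * np.arange(256) / 256
    shape = np.zeros((spec.n_phases, nz, ny, nx))
    z_lo = zc[0] - th / 2.0
    for t in range(spec.n_phases):
        for zi in range(nz):
            if not masks[t, zi].any():
                continue
            k = min(int((zi * dzv - z_lo) / th), contours.n_slices - 1)
            poly = contours.contours[t][k]
            c = polygon_centroid(poly)
            rr = _ray_radii(np.asarray(poly), c, angles)
            theta = np.mod(np.arctan2(Y - c[1], X - c[0]), 2 * np.pi)
            ri = np.interp(theta.ravel(), angles, rr, period=2 * np.pi
                           ).reshape(ny, nx)
            rho = np.hypot(X - c[0], Y - c[1]) / np.maximum(ri, 1e-9)
            shape[t, zi] = np.where(masks[t, zi],
                                    2.0 * np.clip(1 - rho ** 2, 0, None), 0.0)
    return shape


def _offset_volume(spec: PhantomSpec) -> np.ndarray:
    """Background offset field (z, y, x, 3) in cm/s from the offset model.

    Models: {"kind": "constant", "value": [ox, oy, oz]} or
    {"kind": "linear", "axis": "x"|"y", "amplitude": a} (offset ramps from
    -a to +a across the FOV, applied to every component).
    """
    nx, ny, nz = spec.grid_shape
    off = np.zeros((nz, ny, nx, 3))
    m = spec.offset_model
    if m["kind"] == "constant":
        off += np.asarray(m["value"], dtype=float)
    elif m["kind"] == "linear":
        a = float(m["amplitude"])
        if m.get("axis", "x") == "x":
            ramp = np.linspace(-a, a, nx)[None, None, :]
        else:
            ramp = np.linspace(-a, a, ny)[None, :, None]
        off += ramp[..., None]
    else:
        raise SpecificationError(f"unknown offset model kind: {m['kind']}")
    return off


def wrap_velocities(field_: VelocityField) -> VelocityField:
    """Emulate phase aliasing: map every component into [-VENC, VENC).

    v -> ((v + VENC) mod 2 VENC) - VENC.  Idempotent on in-range fields.
    """
    out = field_.copy()
    venc = field_.venc
    out.v = np.mod(out.v + venc, 2.0 * venc) - venc
    return out


def make_annular_track(spec: PhantomSpec, contours: ContourStack):
    """Annular landmarks, apex track and valve aperture polygons.

    Landmarks sit on the plane-slice contour at the 4-chamber (0/180 deg)
    and 2-chamber (90/270 deg) orientations.  The aperture polygon is the
    plane-slice contour dilated radially by ``margin_mm`` so it captures
    the full (interpolation-smoothed) inflow jet.

    Returns (AnnularTrack, aperture polygons per phase as (M, 3) mm).
    """
    from .rv_geometry import polygon_centroid
    k = plane_slice_index(spec)
    zc = contours.slice_z_mm
    z_plane = zc[k]
    z_apex = zc[0]
    margin_mm = 1.5 * max(spec.voxel_mm[:2])
    lms, apices, apertures = [], [], []
    for t in range(spec.n_phases):
        poly = np.asarray(contours.contours[t][k])
        c = polygon_centroid(poly)
        d = poly - c
        r = np.linalg.norm(d, axis=1, keepdims=True)
        ap2 = c + d * (1 + margin_mm / np.maximum(r, 1e-9))
        apertures.append(np.column_stack([ap2, np.full(len(ap2), z_plane)]))
        idx = [0, len(poly) // 2, len(poly) // 4, 3 * len(poly) // 4]
        lm = np.column_stack([poly[idx], np.full(4, z_plane)])
        lms.append(lm)
        apices.append([c[0], c[1], z_apex])
    return AnnularTrack(np.asarray(lms), np.asarray(apices)), apertures


def calibrate_ea_ratio(spec: PhantomSpec, target: float,
                       v_e: Optional[float] = None) -> PhantomSpec:
    """Return a spec whose *truth* KEi_EDV E/A ratio equals ``target``.

    On the uniform-speed phantom KEi peaks scale with V(t) v(t)^2, and the
    E and A speed bumps have disjoint support, so the ratio is
    (v_e/v_a)^2 * (V at E peak / V at A peak) in closed form; v_a is solved
    accordingly (v_e kept, or overridden).  Mass-conservation rescaling
    multiplies both bumps equally and cannot change the ratio.
    """
    if target <= 0:
        raise ParameterError("target E/A ratio must be positive")
    ve = spec.v_e if v_e is None else v_e
    vols = volume_program(spec)
    se = speed_program(replace(spec, v_sys=0.0, v_e=1.0, v_a=0.0))
    sa = speed_program(replace(spec, v_sys=0.0, v_e=0.0, v_a=1.0))
    me = float((vols * se ** 2).max())
    ma = float((vols * sa ** 2).max())
    va = ve * np.sqrt(me / (ma * target))
    return replace(spec, v_e=ve, v_a=float(va))


# --------------------------------------------------------------- cohorts

#: per-metric calibration (mean, SD, Spearman rho with age) of the healthy
#: reference cohort the generator emulates
DEFAULT_EFFECTS = {
    "rvedvi_ml_m2":    {"mean": 84.77, "sd": 23.1, "rho": -0.485},
    "rvesvi_ml_m2":    {"mean": 35.74, "sd": 11.7, "rho": -0.478},
    "rvsvi_ml_m2":     {"mean": 51.19, "sd": 10.1, "rho": -0.436},
    "rvef_pct":        {"mean": 59.46, "sd": 6.14, "rho": 0.261},
    "raai_cm2_m2":     {"mean": 12.54, "sd": 2.21, "rho": 0.031},
    "tapse_mm":        {"mean": 28.36, "sd": 6.47, "rho": -0.307},
    "peak_e_vel":      {"mean": 49.85, "sd": 10.1, "rho": -0.165},
    "peak_a_vel":      {"mean": 38.8,  "sd": 10.9, "rho": 0.4},
    "ea_vel_ratio":    {"mean": 1.37,  "sd": 0.4,  "rho": -0.458},
    "tv_sv_ml":        {"mean": 87.9,  "sd": 23.0, "rho": -0.434, "factor": 2},
    "global_kei":      {"mean": 4.6,   "sd": 1.89, "rho": -0.074},
    "min_kei":         {"mean": 0.71,  "sd": 0.57, "rho": 0.0},
    "systolic_kei":    {"mean": 8.12,  "sd": 3.88, "rho": -0.106},
    "diastolic_kei":   {"mean": 2.68,  "sd": 1.08, "rho": -0.172},
    "peak_e_kei":      {"mean": 5.53,  "sd": 2.81, "rho": -0.3},
    "peak_a_kei":      {"mean": 4.59,  "sd": 1.88, "rho": 0.42},
    "kei_ea_ratio":    {"mean": 1.51,  "sd": 0.84, "rho": -0.531, "factor": 1},
}


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort with programmed age effects."""

    n_subjects: int = 53
    age_range: tuple = (20.0, 80.0)
    sex_fraction_female: float = 21.0 / 53.0
    effect_table: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise SpecificationError("need at least 3 subjects")
        for name, e in self.effect_table.items():
            if not -1.0 <= e["rho"] <= 1.0:
                raise SpecificationError(
                    f"{name}: rank correlation {e['rho']} outside [-1, 1]")
            if e["sd"] < 0:
                raise SpecificationError(f"{name}: negative SD")


#: loading of each independent age component in the two-factor construction
_FACTOR_WEIGHT = 0.68


def make_cohort(spec: CohortSpec):
    """Draw a cohort whose population Spearman(age, metric) is as programmed.

    Gaussian-copula latent construction.  The age latent is

        z0 = w (u1 + u2) + sqrt(1 - 2 w^2) e0,   w = 0.68,

    with u1, u2, e0 independent standard normals.  A metric tagged
    ``factor: 1`` (or 2) loads on u1 (u2) alone — such metrics carry
    *independent* information about age and are the programmed independent
    predictors for multivariate selection; untagged metrics load on z0
    directly.  In every case the Pearson loading is scaled so the latent
    correlation with z0 is r_i = 2 sin(pi rho_i / 6), which makes the
    *rank* correlation of the bivariate Gaussian pair equal the programmed
    rho_i; the construction is positive semi-definite for any feasible
    loadings.  Ages map uniformly onto ``age_range``; metrics map onto
    positives-truncated Gaussians with the calibrated mean/SD.  Both maps
    are strictly monotone, so programmed rank correlations are preserved
    exactly in the population.

    Returns (DataFrame, truth record of programmed effects).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    u1 = rng.standard_normal(n)
    u2 = rng.standard_normal(n)
    e0 = rng.standard_normal(n)
    w = _FACTOR_WEIGHT
    z0 = w * (u1 + u2) + np.sqrt(1.0 - 2.0 * w ** 2) * e0
    lo, hi = spec.age_range
    age = lo + (hi - lo) * stats.norm.cdf(z0)
    sex = np.where(rng.random(n) < spec.sex_fraction_female, "F", "M")
    bsa_mu = np.where(sex == "F", 1.70, 1.94)
    bsa_sd = np.where(sex == "F", 0.20, 0.13)
    bsa = stats.truncnorm.ppf(stats.norm.cdf(rng.standard_normal(n)),
                              (0.8 - bsa_mu) / bsa_sd, np.inf,
                              loc=bsa_mu, scale=bsa_sd)

    data = {"subject_id": [f"S{i:03d}" for i in range(n)],
            "age_years": age, "sex": sex, "bsa_m2": bsa}
    for name, e in spec.effect_table.items():
        r = 2.0 * np.sin(np.pi * e["rho"] / 6.0)
        fac = e.get("factor", 0)
        if fac == 0:
            z = r * z0 + np.sqrt(1.0 - r ** 2) * rng.standard_normal(n)
        else:
            load = r / w  # corr(z0, u_f) = w, so corr(z0, z_i) = r
            if abs(load) > 1.0:
                raise SpecificationError(
                    f"{name}: |rho|={abs(e['rho'])} infeasible on an "
                    f"independent factor (max {w:.2f} latent loading)")
            u = u1 if fac == 1 else u2
            z = load * u + np.sqrt(1.0 - load ** 2) * rng.standard_normal(n)
        a = (0.0 - e["mean"]) / e["sd"] if e["sd"] > 0 else -np.inf
        data[name] = stats.truncnorm.ppf(stats.norm.cdf(z), a, np.inf,
                                         loc=e["mean"], scale=e["sd"])
    df = pd.DataFrame(data)
    truth = {"programmed_rho": {k: e["rho"]
                                for k, e in spec.effect_table.items()},
             "seed": spec.seed, "n_subjects": n}
    return df, truth
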