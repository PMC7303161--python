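"""Voxel-wise RV blood-flow kinetic energy and its curve-derived parameters.

For every voxel inside the time-resolved RV mask the kinetic energy is

    KE = 1/2 * rho_blood * V_voxel * v_voxel^2

with rho_blood = 1.06 g/cm^3, V_voxel the voxel volume in cm^3 and v_voxel
the velocity magnitude in cm/s, which yields erg; 1 erg = 0.1 uJ.  The unit
conversion is the single most error-prone step of the whole chain and is
therefore centralised in ``ERG_TO_UJ``.  Per-phase totals are normalised to
the cine-derived end-diastolic volume (KEi_EDV, uJ/ml), and six parameters
summarise the curve: global (cycle mean), systolic and diastolic means, the
cycle minimum, the early (E) and late/atrial (A) diastolic filling peaks,
and their ratio E/A — the diastolic-function index of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GeometryError, ParameterError, TimingError

log = logging.getLogger(__name__)

__all__ = [
    "RHO_BLOOD_G_CM3", "ERG_TO_UJ",
    "KECurve", "CardiacTiming", "KEParameters",
    "voxel_ke", "ke_curve", "detect_cardiac_phases", "extract_ke_parameters",
]

#: density of blood, g/cm^3
RHO_BLOOD_G_CM3 = 1.06
#: cgs energy (g cm^2/s^2) to microjoule
ERG_TO_UJ = 0.1


@dataclass
class KECurve:
    """Per-phase total RV kinetic energy and its EDV-normalised twin."""

    ke_uJ: np.ndarray          # (T,) total KE, uJ
    kei_uJ_ml: np.ndarray      # (T,) KE / EDV, uJ/ml
    phase_ms: float
    edv_ml: float
    rho_g_cm3: float = RHO_BLOOD_G_CM3

    def __post_init__(self) -> None:
        self.ke_uJ = np.asarray(self.ke_uJ, dtype=float)
        self.kei_uJ_ml = np.asarray(self.kei_uJ_ml, dtype=float)
        if np.any(self.ke_uJ < 0):
            raise ParameterError("kinetic energy cannot be negative")

    @property
    def n_phases(self) -> int:
        return self.ke_uJ.size

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.phase_ms


@dataclass
class CardiacTiming:
    """Phase-index windows of the cardiac cycle.

    Systole runs from phase 0 through end-systole (inclusive); diastole is
    everything after.  The E (early filling) and A (atrial filling) windows
    partition diastole.
    """

    es_phase: int
    systole: np.ndarray
    diastole: np.ndarray
    e_window: np.ndarray
    a_window: np.ndarray
    split_fallback: bool = False

    def __post_init__(self) -> None:
        if set(self.e_window) & set(self.a_window):
            raise ParameterError("E and A windows must be disjoint")


@dataclass
class KEParameters:
    """The six KEi_EDV summary parameters (uJ/ml) plus un-indexed twins (mJ)."""

    global_kei: float
    systolic_kei: float
    diastolic_kei: float
    min_kei: float
    peak_e_kei: float
    peak_a_kei: float
    ea_ratio: Optional[float]
    global_ke_mJ: float = float("nan")
    systolic_ke_mJ: float = float("nan")
    diastolic_ke_mJ: float = float("nan")
    peak_e_ke_mJ: float = float("nan")
    peak_a_ke_mJ: float = float("nan")

    def as_dict(self) -> dict:
        return {k: (None if v is None or (isinstance(v, float) and np.isnan(v))
                    else float(v))
                for k, v in self.__dict__.items()}


def voxel_ke(speed_cm_s, voxel_volume_cm3: float,
             rho_g_cm3: float = RHO_BLOOD_G_CM3):
    """Kinetic energy of one voxel, uJ: 0.5 * rho * V * v^2 (erg -> uJ).

    ``speed_cm_s`` is a magnitude; negative inputs are taken by absolute
    value.  Scalar or array.
    """
    if voxel_volume_cm3 <= 0:
        raise ParameterError("voxel volume must be positive")
    if rho_g_cm3 <= 0:
        raise ParameterError("blood density must be positive")
    v = np.abs(np.asarray(speed_cm_s, dtype=float))
    ke = 0.5 * rho_g_cm3 * voxel_volume_cm3 * v ** 2 * ERG_TO_UJ
    return float(ke) if np.isscalar(speed_cm_s) else ke


def ke_curve(field_, masks: np.ndarray, edv_ml: float,
             rho_g_cm3: float = RHO_BLOOD_G_CM3) -> KECurve:
    """Total RV KE per cardiac phase: sum of voxel KE over the phase mask.

    ``edv_ml`` is the cine-derived end-diastolic volume used for KEi_EDV
    normalisation (the segmentation, not the flow-grid mask, defines EDV).
    """
    if masks.shape[0] != field_.n_phases or masks.shape[1:] != field_.grid_shape:
        raise ParameterError("masks must align with the velocity grid")
    if edv_ml <= 0:
        raise ParameterError("EDV must be positive")
    speed = field_.speed()
    vvox = field_.voxel_volume_cm3
    ke = np.zeros(field_.n_phases)
    for t in range(field_.n_phases):
        m = masks[t]
        if not m.any():
            raise GeometryError(f"phase {t}: empty RV mask, KE curve invalid")
        ke[t] = voxel_ke(speed[t][m], vvox, rho_g_cm3).sum()
    return KECurve(ke, ke / edv_ml, field_.phase_ms, edv_ml, rho_g_cm3)


def detect_cardiac_phases(volume_ml: np.ndarray,
                          kei: Optional[np.ndarray] = None) -> CardiacTiming:
    """Locate end-systole and the diastolic E/A windows.

    End-systole is the phase of minimum RV volume (earliest on ties);
    systole is [0, es], diastole (es, last].  When the diastolic KEi curve
    shows two distinct local maxima (the E and A filling peaks) the window
    boundary is placed at the KEi minimum between them; otherwise diastole
    is split at its temporal midpoint and the fallback is flagged.
    """
    v = np.asarray(volume_ml, dtype=float)
    if v.size < 8:
        raise ParameterError("need at least 8 phases for timing detection")
    es = int(np.argmin(v))
    if es == v.size - 1 or v[es:].max() <= v[es] * (1 + 1e-9):
        raise TimingError("volume curve shows no diastolic refilling")
    systole = np.arange(0, es + 1)
    diastole = np.arange(es + 1, v.size)

    split = None
    fallback = True
    if kei is not None:
        k = np.asarray(kei, dtype=float)[diastole]
        # interior local maxima of the diastolic KEi curve
        peaks = [i for i in range(1, k.size - 1)
                 if k[i] > k[i - 1] and k[i] >= k[i + 1]]
        if len(peaks) >= 2:
            top2 = sorted(sorted(peaks, key=lambda i: -k[i])[:2])
            valley = top2[0] + int(np.argmin(k[top2[0]:top2[1] + 1]))
            split = diastole[0] + valley
            fallback = False
    if split is None:
        split = diastole[0] + diastole.size // 2
        log.info("E/A windows: midpoint-split fallback (no distinct peaks)")
    e_win = diastole[diastole <= split]
    a_win = diastole[diastole > split]
    if e_win.size == 0 or a_win.size == 0:
        raise TimingError("diastole too short to define E and A windows")
    return CardiacTiming(es, systole, diastole, e_win, a_win, fallback)


def extract_ke_parameters(curve: KECurve, timing: CardiacTiming,
                          window_stat: str = "mean") -> KEParameters:
    """Summarise a KEi_EDV curve into the six standard parameters.

    ``window_stat`` selects how the systolic/diastolic values condense their
    window: "mean" (time average, the default) or "peak".  The E and A
    values are always window peaks, and their ratio is E/A (undefined and
    reported absent when the A peak is zero).
    """
    if window_stat not in ("mean", "peak"):
        raise ParameterError("window_stat must be 'mean' or 'peak'")
    agg = np.mean if window_stat == "mean" else np.max
    kei, ke = curve.kei_uJ_ml, curve.ke_uJ
    peak_e = float(kei[timing.e_window].max())
    peak_a = float(kei[timing.a_window].max())
    ea = None if peak_a == 0 else peak_e / peak_a
    if ea is None:
        log.warning("A-wave KEi peak is zero; E/A ratio reported absent")
    return KEParameters(
        global_kei=float(kei.mean()),
        systolic_kei=float(agg(kei[timing.systole])),
        diastolic_kei=float(agg(kei[timing.diastole])),
        min_kei=float(kei.min()),
        peak_e_kei=peak_e,
        peak_a_kei=peak_a,
        ea_ratio=ea,
        global_ke_mJ=float(ke.mean()) / 1000.0,
        systolic_ke_mJ=float(agg(ke[timing.systole])) / 1000.0,
        diastolic_ke_mJ=float(agg(ke[timing.diastole])) / 1000.0,
        peak_e_ke_mJ=float(ke[timing.e_window].max()) / 1000.0,
        peak_a_ke_mJ=float(ke[timing.a_window].max()) / 1000.0,
    )
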