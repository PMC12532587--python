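"""Derived echocardiographic parameters and the parameter registry.

All derivations are pure functions of raw chamber dimensions and Doppler
velocities, following current American Society of Echocardiography
quantification conventions: mean left-ventricular (LV) wall thickness,
relative wall thickness, Devereux linear-dimension LV mass (indexed to body
surface area), biplane method-of-discs volumes and ejection fraction, LV
outflow-tract stroke volume, and the transmitral / tissue-Doppler ratios
(E/A, E/e').

The registry attached to each parameter records its units and which
direction of change is clinically *worse* (wall thickening and rising
filling-pressure surrogates worsen upward; contractile and annular-velocity
measures worsen downward).  The worse direction drives the worst-decile
donor selection used by the pattern-mixture imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "WorseDirection",
    "ParameterRegistryEntry",
    "PARAMETER_REGISTRY",
    "EchoMeasurementRecord",
    "mean_lv_wall_thickness",
    "relative_wall_thickness",
    "body_surface_area",
    "lv_mass_devereux",
    "index_to_bsa",
    "biplane_simpson_volume",
    "lvef",
    "stroke_volume_lvot",
    "doppler_ratios",
    "change_from_baseline",
    "derive_panel",
]


class WorseDirection(str, Enum):
    """Direction in which a change from baseline is clinically adverse."""

    DECREASE = "decrease_is_worse"
    INCREASE = "increase_is_worse"


@dataclass(frozen=True)
class ParameterRegistryEntry:
    key: str
    units: str
    worse_direction: WorseDirection
    label: str = ""


def _entry(key: str, units: str, direction: WorseDirection, label: str = "") -> ParameterRegistryEntry:
    return ParameterRegistryEntry(key, units, direction, label or key)


#: Default registry.  The worse direction for each parameter is this
#: package's clinical interpretation (a restrictive cardiomyopathy worsens by
#: wall thickening, rising filling pressures and falling systolic /
#: annular-velocity indices); it is configurable by passing a modified
#: mapping wherever a registry is accepted.
PARAMETER_REGISTRY: Mapping[str, ParameterRegistryEntry] = {
    e.key: e
    for e in [
        _entry("mean_lv_wall_thickness", "mm", WorseDirection.INCREASE, "Mean LV wall thickness"),
        _entry("relative_wall_thickness", "", WorseDirection.INCREASE, "Relative wall thickness"),
        _entry("lvedd", "mm", WorseDirection.INCREASE, "LV end-diastolic dimension"),
        _entry("lvesd", "mm", WorseDirection.INCREASE, "LV end-systolic dimension"),
        _entry("lvedv", "ml", WorseDirection.INCREASE, "LV end-diastolic volume"),
        _entry("lvesv", "ml", WorseDirection.INCREASE, "LV end-systolic volume"),
        _entry("lv_mass_index", "g m^-2", WorseDirection.INCREASE, "LV mass index"),
        _entry("lvef", "%", WorseDirection.DECREASE, "LV ejection fraction"),
        _entry("abs_gls", "%", WorseDirection.DECREASE, "Absolute global longitudinal strain"),
        _entry("stroke_volume", "ml", WorseDirection.DECREASE, "LV stroke volume"),
        _entry("s_prime_lateral", "mm s^-1", WorseDirection.DECREASE, "TDI lateral s'"),
        _entry("s_prime_septal", "mm s^-1", WorseDirection.DECREASE, "TDI septal s'"),
        _entry("e_a_ratio", "", WorseDirection.INCREASE, "E/A ratio"),
        _entry("e_wave", "mm s^-1", WorseDirection.INCREASE, "E wave velocity"),
        _entry("a_wave", "mm s^-1", WorseDirection.DECREASE, "A wave velocity"),
        _entry("deceleration_time", "ms", WorseDirection.DECREASE, "Deceleration time"),
        _entry("e_prime_lateral", "mm s^-1", WorseDirection.DECREASE, "TDI lateral e'"),
        _entry("e_prime_septal", "mm s^-1", WorseDirection.DECREASE, "TDI septal e'"),
        _entry("e_over_eprime_lateral", "", WorseDirection.INCREASE, "E/e' lateral"),
        _entry("e_over_eprime_septal", "", WorseDirection.INCREASE, "E/e' septal"),
        _entry("e_over_eprime_average", "", WorseDirection.INCREASE, "E/e' average"),
        _entry("la_diameter", "mm", WorseDirection.INCREASE, "LA diameter"),
        _entry("la_volume_index", "ml m^-2", WorseDirection.INCREASE, "LA volume index"),
        _entry("a_prime_lateral", "mm s^-1", WorseDirection.DECREASE, "TDI lateral a'"),
        _entry("a_prime_septal", "mm s^-1", WorseDirection.DECREASE, "TDI septal a'"),
        _entry("rv_free_wall_thickness", "mm", WorseDirection.INCREASE, "RV free wall thickness"),
        _entry("rv_end_diastolic_area", "cm^2", WorseDirection.INCREASE, "RV end-diastolic area"),
        _entry("rv_end_systolic_area", "cm^2", WorseDirection.INCREASE, "RV end-systolic area"),
        _entry("rv_s_prime", "mm s^-1", WorseDirection.DECREASE, "RV S'"),
        _entry("tr_velocity", "m s^-1", WorseDirection.INCREASE, "TR velocity"),
        _entry("ivc_diameter", "mm", WorseDirection.INCREASE, "Maximal IVC diameter"),
    ]
}


def _require_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value is None or not np.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be a finite non-negative number, got {value!r}")


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value is None or not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be a finite positive number, got {value!r}")


def mean_lv_wall_thickness(ivsd_mm: float, pwd_mm: float) -> float:
    """Average of interventricular septal and posterior wall thickness in diastole (mm)."""
    _require_nonneg(ivsd_mm=ivsd_mm, pwd_mm=pwd_mm)
    return (ivsd_mm + pwd_mm) / 2.0


def relative_wall_thickness(pwd_mm: float, lvedd_mm: float) -> float:
    """Relative wall thickness: 2 x posterior wall thickness / LV end-diastolic diameter."""
    _require_nonneg(pwd_mm=pwd_mm)
    _require_positive(lvedd_mm=lvedd_mm)
    return 2.0 * pwd_mm / lvedd_mm


def body_surface_area(height_cm: float, weight_kg: float, formula: str = "dubois") -> float:
    """Body surface area in m^2.

    ``formula`` selects the estimator: ``"dubois"`` (default,
    0.007184 * h^0.725 * w^0.425) or ``"mosteller"`` (sqrt(h*w/3600)).
    """
    _require_positive(height_cm=height_cm, weight_kg=weight_kg)
    if formula == "dubois":
        return 0.007184 * height_cm**0.725 * weight_kg**0.425
    if formula == "mosteller":
        return math.sqrt(height_cm * weight_kg / 3600.0)
    raise ValueError(f"unknown BSA formula {formula!r}; expected 'dubois' or 'mosteller'")


def lv_mass_devereux(ivsd_cm: float, lvedd_cm: float, pwd_cm: float) -> float:
    """Devereux linear-dimension LV mass in grams.

    mass = 0.8 * 1.04 * ((IVSd + LVIDd + PWd)^3 - LVIDd^3) + 0.6, inputs in cm.
    """
    _require_nonneg(ivsd_cm=ivsd_cm, pwd_cm=pwd_cm)
    _require_positive(lvedd_cm=lvedd_cm)
    return 0.8 * 1.04 * ((ivsd_cm + lvedd_cm + pwd_cm) ** 3 - lvedd_cm**3) + 0.6


def index_to_bsa(value: float, bsa_m2: float) -> float:
    """Index a mass or volume to body surface area (per m^2)."""
    _require_positive(bsa_m2=bsa_m2)
    return value / bsa_m2


def biplane_simpson_volume(
    disc_diameters_a4c_cm: Sequence[float],
    disc_diameters_a2c_cm: Sequence[float],
    lv_length_cm: float,
) -> float:
    """Modified biplane Simpson (method of discs) LV volume in ml.

    Each of the 20 elliptical discs has axes a_i (four-chamber) and b_i
    (two-chamber) and thickness L/20:  V = (pi/4) * sum(a_i * b_i) * L/20.
    """
    a = np.asarray(disc_diameters_a4c_cm, dtype=float)
    b = np.asarray(disc_diameters_a2c_cm, dtype=float)
    if a.shape != (20,) or b.shape != (20,):
        raise ValueError("disc diameter vectors must each have length 20")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("disc diameters must be non-negative")
    _require_positive(lv_length_cm=lv_length_cm)
    return float(math.pi / 4.0 * np.sum(a * b) * (lv_length_cm / 20.0))


def lvef(edv_ml: float, esv_ml: float) -> float:
    """Ejection fraction in percent: 100 * (EDV - ESV) / EDV."""
    _require_positive(edv_ml=edv_ml)
    _require_nonneg(esv_ml=esv_ml)
    if esv_ml > edv_ml:
        raise ValueError(f"end-systolic volume {esv_ml} exceeds end-diastolic volume {edv_ml}")
    return 100.0 * (edv_ml - esv_ml) / edv_ml


def stroke_volume_lvot(lvot_diameter_cm: float, lvot_vti_cm: float) -> float:
    """LV outflow-tract stroke volume in ml: pi * (d/2)^2 * VTI."""
    _require_nonneg(lvot_diameter_cm=lvot_diameter_cm, lvot_vti_cm=lvot_vti_cm)
    return math.pi * (lvot_diameter_cm / 2.0) ** 2 * lvot_vti_cm


def doppler_ratios(
    e_wave: float,
    a_wave: Optional[float],
    e_prime_lateral: Optional[float],
    e_prime_septal: Optional[float],
) -> dict:
    """Transmitral and tissue-Doppler ratios.

    Returns a dict with keys ``e_a_ratio``, ``e_over_eprime_lateral``,
    ``e_over_eprime_septal`` and ``e_over_eprime_average``; a ratio whose
    denominator is missing or zero is returned as ``None`` rather than
    aborting the whole record.  The average E/e' divides E by the mean of
    the lateral and septal e' velocities.
    """
    _require_nonneg(e_wave=e_wave)

    def ratio(den: Optional[float]) -> Optional[float]:
        if den is None or not np.isfinite(den) or den <= 0:
            return None
        return e_wave / den

    avg_eprime = None
    if e_prime_lateral is not None and e_prime_septal is not None:
        avg_eprime = (e_prime_lateral + e_prime_septal) / 2.0
    return {
        "e_a_ratio": ratio(a_wave),
        "e_over_eprime_lateral": ratio(e_prime_lateral),
        "e_over_eprime_septal": ratio(e_prime_septal),
        "e_over_eprime_average": ratio(avg_eprime),
    }


class MissingBaselineError(ValueError):
    """Raised when a change-from-baseline series has no baseline value."""


def change_from_baseline(series: Mapping[str, Optional[float]], baseline_key: str = "baseline") -> dict:
    """Per-visit change from baseline for one patient-parameter series.

    ``series`` maps visit label -> value (``None`` for a missed assessment).
    The baseline entry must be present and observed; a missing post-baseline
    value propagates to a missing change.
    """
    base = series.get(baseline_key)
    if base is None or not np.isfinite(base):
        raise MissingBaselineError("baseline value missing; patient excluded for this parameter")
    return {
        visit: (None if value is None or not np.isfinite(value) else value - base)
        for visit, value in series.items()
        if visit != baseline_key
    }


@dataclass
class EchoMeasurementRecord:
    """Raw per-visit measurements from which the derived panel is computed.

    Linear dimensions are in mm except the LVOT diameter and disc diameters
    (cm, as conventionally traced); velocities are tissue-Doppler mm/s except
    the TR jet (m/s).  Any field may be ``None`` when it was not acquired.
    """

    ivsd: Optional[float] = None            # mm
    pwd: Optional[float] = None             # mm
    lvedd: Optional[float] = None           # mm
    lvesd: Optional[float] = None           # mm
    lvot_diameter: Optional[float] = None   # cm
    lvot_vti: Optional[float] = None        # cm
    disc_diameters_a4c_ed: Optional[Sequence[float]] = None  # cm, end-diastole
    disc_diameters_a2c_ed: Optional[Sequence[float]] = None
    disc_diameters_a4c_es: Optional[Sequence[float]] = None  # cm, end-systole
    disc_diameters_a2c_es: Optional[Sequence[float]] = None
    lv_length_ed: Optional[float] = None    # cm
    lv_length_es: Optional[float] = None    # cm
    e_wave: Optional[float] = None          # mm/s
    a_wave: Optional[float] = None          # mm/s
    e_prime_lateral: Optional[float] = None  # mm/s
    e_prime_septal: Optional[float] = None   # mm/s
    a_prime_lateral: Optional[float] = None  # mm/s
    a_prime_septal: Optional[float] = None   # mm/s
    s_prime_lateral: Optional[float] = None  # mm/s
    s_prime_septal: Optional[float] = None   # mm/s
    rv_s_prime: Optional[float] = None       # mm/s
    deceleration_time: Optional[float] = None  # ms
    tr_velocity: Optional[float] = None      # m/s
    ivc_diameter: Optional[float] = None     # mm
    la_diameter: Optional[float] = None      # mm
    la_volume: Optional[float] = None        # ml
    gls: Optional[float] = None              # %, signed as measured (negative = normal shortening)
    height: Optional[float] = None           # cm
    weight: Optional[float] = None           # kg

    def __post_init__(self) -> None:
        for name in ("ivsd", "pwd", "lvedd", "lvesd", "lvot_diameter", "lvot_vti",
                     "e_wave", "a_wave", "e_prime_lateral", "e_prime_septal",
                     "s_prime_lateral", "s_prime_septal", "rv_s_prime",
                     "deceleration_time", "tr_velocity", "ivc_diameter",
                     "la_diameter", "la_volume", "height", "weight"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.lvedd is not None and self.lvesd is not None and self.lvedd < self.lvesd:
            raise ValueError("lvedd must be >= lvesd")


def derive_panel(record: EchoMeasurementRecord, bsa_formula: str = "dubois") -> dict:
    """Compute every derivable registry parameter from one raw record.

    Returns parameter key -> value; parameters whose inputs are absent are
    omitted.  GLS is stored as absolute magnitude (``abs_gls``).
    """
    out: dict = {}
    r = record
    if r.ivsd is not None and r.pwd is not None:
        out["mean_lv_wall_thickness"] = mean_lv_wall_thickness(r.ivsd, r.pwd)
    if r.pwd is not None and r.lvedd is not None and r.lvedd > 0:
        out["relative_wall_thickness"] = relative_wall_thickness(r.pwd, r.lvedd)
    for key in ("lvedd", "lvesd", "e_wave", "a_wave", "deceleration_time",
                "e_prime_lateral", "e_prime_septal", "a_prime_lateral", "a_prime_septal",
                "s_prime_lateral", "s_prime_septal", "rv_s_prime",
                "tr_velocity", "ivc_diameter", "la_diameter"):
        value = getattr(r, key)
        if value is not None:
            out[key] = float(value)
    if r.gls is not None:
        out["abs_gls"] = abs(float(r.gls))

    bsa = None
    if r.height is not None and r.weight is not None:
        bsa = body_surface_area(r.height, r.weight, formula=bsa_formula)
    if r.ivsd is not None and r.pwd is not None and r.lvedd is not None and r.lvedd > 0 and bsa:
        # Linear dimensions arrive in mm; the Devereux formula takes cm.
        mass = lv_mass_devereux(r.ivsd / 10.0, r.lvedd / 10.0, r.pwd / 10.0)
        out["lv_mass_index"] = index_to_bsa(mass, bsa)
    if r.la_volume is not None and bsa:
        out["la_volume_index"] = index_to_bsa(r.la_volume, bsa)

    edv = esv = None
    if r.disc_diameters_a4c_ed is not None and r.disc_diameters_a2c_ed is not None and r.lv_length_ed:
        edv = biplane_simpson_volume(r.disc_diameters_a4c_ed, r.disc_diameters_a2c_ed, r.lv_length_ed)
        out["lvedv"] = edv
    if r.disc_diameters_a4c_es is not None and r.disc_diameters_a2c_es is not None and r.lv_length_es:
        esv = biplane_simpson_volume(r.disc_diameters_a4c_es, r.disc_diameters_a2c_es, r.lv_length_es)
        out["lvesv"] = esv
    if edv is not None and esv is not None and edv > 0:
        out["lvef"] = lvef(edv, esv)
    if r.lvot_diameter is not None and r.lvot_vti is not None:
        out["stroke_volume"] = stroke_volume_lvot(r.lvot_diameter, r.lvot_vti)
    if r.e_wave is not None:
        for key, value in doppler_ratios(r.e_wave, r.a_wave, r.e_prime_lateral, r.e_prime_septal).items():
            if value is not None:
                out[key] = value
    return out
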