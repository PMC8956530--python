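"""Site water availability: climatic water balance and soil AWC.

Two complementary water-supply axes of a forest site:

* **Climatic water balance (CWB)** — monthly precipitation minus
  potential evapotranspiration (mm), summarized as the long-term mean
  monthly balance together with MAP, MAT and growing-season
  precipitation sums.
* **Plant-available water capacity (AWC)** — the soil water held
  between field capacity (pF 1.8, i.e. −60 hPa) and the permanent
  wilting point (pF 4.2, i.e. −1.5 MPa), integrated over the profile to
  a standard depth of 100 cm.  Water contents at the two anchor
  potentials come from van Genuchten retention curves; retention
  parameters are either supplied directly or taken from a
  texture-class-average lookup (Carsel & Parrish 1988 class means,
  USDA texture triangle).

Unit conventions: xylem/soil water *potentials* are negative MPa;
*suctions* (matric head) are positive centimetres of water; pF is
log10 of suction in hPa.  1 cm H₂O = 0.980665 hPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from xylosafe.errors import DomainError, InputError

__all__ = [
    "VanGenuchtenParams",
    "SoilLayer",
    "SoilProfile",
    "monthly_cwb",
    "aggregate_climate",
    "pF_of_potential",
    "potential_of_pF",
    "vg_theta",
    "classify_texture",
    "texture_to_vg",
    "layer_awc",
    "profile_awc",
    "TEXTURE_CLASS_VG",
]

HPA_PER_CM_H2O = 0.980665       # pressure of a 1 cm water column
HPA_PER_MPA = 1e4
PF_FIELD_CAPACITY = math.log10(60.0)      # −60 hPa ≈ pF 1.8
PF_WILTING_POINT = math.log10(1.5 * HPA_PER_MPA)  # −1.5 MPa ≈ pF 4.2


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def monthly_cwb(precipitation, pet):
    """Monthly climatic water balance CWB = P − PET (mm, may be negative)."""
    p = np.asarray(precipitation, dtype=float)
    e = np.asarray(pet, dtype=float)
    if np.any(p < 0) or np.any(e < 0):
        raise DomainError("precipitation and PET must be non-negative")
    out = p - e
    return out if out.ndim else float(out)


def aggregate_climate(
    monthly: pd.DataFrame,
    period: tuple[int, int] = (1991, 2018),
    growing_season: tuple[int, int] = (4, 9),
) -> pd.DataFrame:
    """Long-term site climate summary from a monthly table.

    ``monthly`` needs columns site_id, year, month, precip_mm, pet_mm,
    temp_C.  Returns one row per site with

    * MAP  — mean annual precipitation sum (mm yr⁻¹),
    * MAT  — mean of annual mean temperatures (°C),
    * MSP  — mean early growing-season (April–June) precipitation (mm),
    * MGSP — mean growing-season precipitation over ``growing_season``,
    * CWB  — mean monthly climatic water balance (mm month⁻¹).

    Every month of every year in ``period`` must be present; gaps raise
    an :class:`InputError` listing the missing (site, year, month)
    triples.
    """
    required = {"site_id", "year", "month", "precip_mm", "pet_mm", "temp_C"}
    missing_cols = required - set(monthly.columns)
    if missing_cols:
        raise InputError(f"climate table missing columns: {sorted(missing_cols)}")
    y0, y1 = period
    sub = monthly[(monthly["year"] >= y0) & (monthly["year"] <= y1)].copy()

    gaps = []
    expected = {(y, m) for y in range(y0, y1 + 1) for m in range(1, 13)}
    for site, grp in sub.groupby("site_id"):
        have = set(zip(grp["year"].astype(int), grp["month"].astype(int)))
        for y, m in sorted(expected - have):
            gaps.append((site, y, m))
    if gaps:
        raise InputError(f"incomplete climate record; missing (site, year, month): {gaps[:20]}")

    sub["cwb"] = monthly_cwb(sub["precip_mm"].to_numpy(), sub["pet_mm"].to_numpy())
    annual = sub.groupby(["site_id", "year"]).agg(
        precip=("precip_mm", "sum"), temp=("temp_C", "mean")
    )
    msp_months = sub["month"].isin([4, 5, 6])
    gs_months = sub["month"].between(*growing_season)
    msp = sub[msp_months].groupby(["site_id", "year"])["precip_mm"].sum()
    mgsp = sub[gs_months].groupby(["site_id", "year"])["precip_mm"].sum()

    out = pd.DataFrame(
        {
            "MAP": annual["precip"].groupby("site_id").mean(),
            "MAT": annual["temp"].groupby("site_id").mean(),
            "MSP": msp.groupby("site_id").mean(),
            "MGSP": mgsp.groupby("site_id").mean(),
            "CWB": sub.groupby("site_id")["cwb"].mean(),
        }
    )
    out.index.name = "site_id"
    return out.reset_index()


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------

def pF_of_potential(water_potential_mpa: float) -> float:
    """pF = log10(suction in hPa) of a negative water potential (MPa).

    −1.5 MPa → pF ≈ 4.18 (the conventional wilting point, printed as
    4.2); −60 hPa (−0.006 MPa) → pF ≈ 1.78 (field capacity, 1.8).
    """
    if not water_potential_mpa < 0:
        raise DomainError(f"water potential must be negative, got {water_potential_mpa}")
    return math.log10(-water_potential_mpa * HPA_PER_MPA)


def potential_of_pF(pf: float) -> float:
    """Inverse of :func:`pF_of_potential`: negative MPa from pF."""
    return -(10.0 ** pf) / HPA_PER_MPA


def suction_cm_of_pF(pf: float) -> float:
    """Matric suction in cm of water for a pF value (pF is hPa-based)."""
    return (10.0 ** pf) / HPA_PER_CM_H2O


@dataclass(frozen=True)
class VanGenuchtenParams:
    """van Genuchten retention parameters (suction in cm of water).

    θ(h) = θr + (θs − θr) · [1 + (αh)ⁿ]^(−m) with m = 1 − 1/n.
    """

    theta_r: float
    theta_s: float
    alpha: float  # cm^-1
    n: float

    def __post_init__(self):
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise DomainError(
                f"need 0 <= theta_r < theta_s <= 1, got ({self.theta_r}, {self.theta_s})"
            )
        if self.alpha <= 0:
            raise DomainError(f"alpha must be positive, got {self.alpha}")
        if self.n <= 1:
            raise DomainError(f"n must exceed 1, got {self.n}")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n


def vg_theta(params: VanGenuchtenParams, suction_cm) -> float | np.ndarray:
    """Volumetric water content at a matric suction (cm of water, ≥ 0)."""
    h = np.asarray(suction_cm, dtype=float)
    if np.any(h < 0):
        raise DomainError("suction must be non-negative")
    theta = params.theta_r + (params.theta_s - params.theta_r) * (
        1.0 + (params.alpha * h) ** params.n
    ) ** (-params.m)
    return theta if theta.ndim else float(theta)


# Carsel & Parrish (1988) class-average van Genuchten parameters
# (theta_r, theta_s, alpha [cm^-1], n) for the 12 USDA texture classes.
TEXTURE_CLASS_VG: dict[str, VanGenuchtenParams] = {
    "sand": VanGenuchtenParams(0.045, 0.43, 0.145, 2.68),
    "loamy sand": VanGenuchtenParams(0.057, 0.41, 0.124, 2.28),
    "sandy loam": VanGenuchtenParams(0.065, 0.41, 0.075, 1.89),
    "loam": VanGenuchtenParams(0.078, 0.43, 0.036, 1.56),
    "silt": VanGenuchtenParams(0.034, 0.46, 0.016, 1.37),
    "silt loam": VanGenuchtenParams(0.067, 0.45, 0.020, 1.41),
    "sandy clay loam": VanGenuchtenParams(0.100, 0.39, 0.059, 1.48),
    "clay loam": VanGenuchtenParams(0.095, 0.41, 0.019, 1.31),
    "silty clay loam": VanGenuchtenParams(0.089, 0.43, 0.010, 1.23),
    "sandy clay": VanGenuchtenParams(0.100, 0.38, 0.027, 1.23),
    "silty clay": VanGenuchtenParams(0.070, 0.36, 0.005, 1.09),
    "clay": VanGenuchtenParams(0.068, 0.38, 0.008, 1.09),
}


def classify_texture(sand: float, silt: float, clay: float) -> str:
    """USDA texture-triangle class from sand/silt/clay mass fractions."""
    total = sand + silt + clay
    if abs(total - 1.0) > 1e-6:
        raise InputError(f"texture fractions must sum to 1 (got {total:.6f})")
    if min(sand, silt, clay) < 0:
        raise InputError("texture fractions must be non-negative")
    s, si, c = sand * 100.0, silt * 100.0, clay * 100.0

    if si + 1.5 * c < 15:
        return "sand"
    if si + 1.5 * c >= 15 and si + 2.0 * c < 30:
        return "loamy sand"
    if (7 <= c < 20 and s > 52 and si + 2 * c >= 30) or (c < 7 and si < 50 and si + 2 * c >= 30):
        return "sandy loam"
    if 7 <= c < 27 and 28 <= si < 50 and s <= 52:
        return "loam"
    if si >= 80 and c < 12:
        return "silt"
    if (si >= 50 and 12 <= c < 27) or (50 <= si < 80 and c < 12):
        return "silt loam"
    if 20 <= c < 35 and si < 28 and s > 45:
        return "sandy clay loam"
    if 27 <= c < 40 and 20 < s <= 45:
        return "clay loam"
    if 27 <= c < 40 and s <= 20:
        return "silty clay loam"
    if c >= 35 and s > 45:
        return "sandy clay"
    if c >= 40 and si >= 40:
        return "silty clay"
    if c >= 40 and s <= 45 and si < 40:
        return "clay"
    raise InputError(f"texture ({sand}, {silt}, {clay}) falls outside the triangle rules")


def texture_to_vg(
    sand: float,
    silt: float,
    clay: float,
    bulk_density: float | None = None,
    override: VanGenuchtenParams | None = None,
) -> VanGenuchtenParams:
    """Retention parameters for a soil sample.

    By default a texture-class lookup (class-average parameters); a
    pedotransfer result computed externally (e.g. Rosetta) can be passed
    through ``override`` and is returned verbatim.  ``bulk_density`` is
    accepted for schema completeness but does not alter the class
    averages.
    """
    if override is not None:
        return override
    return TEXTURE_CLASS_VG[classify_texture(sand, silt, clay)]


# ---------------------------------------------------------------------------
# profile AWC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SoilLayer:
    top_cm: float
    bottom_cm: float
    sand: float
    silt: float
    clay: float
    bulk_density: float = 1.4
    stone_fraction: float = 0.0

    def __post_init__(self):
        if self.bottom_cm <= self.top_cm:
            raise InputError("layer bottom must lie below its top")
        if not (0.0 <= self.stone_fraction < 1.0):
            raise InputError("stone fraction must be in [0, 1)")

    @property
    def thickness_cm(self) -> float:
        return self.bottom_cm - self.top_cm


@dataclass(frozen=True)
class SoilProfile:
    site_id: str
    layers: tuple[SoilLayer, ...]

    def __post_init__(self):
        layers = tuple(sorted(self.layers, key=lambda l: l.top_cm))
        object.__setattr__(self, "layers", layers)
        if not layers:
            raise InputError("profile needs at least one layer")
        if layers[0].top_cm != 0:
            raise InputError("layers must start at 0 cm")
        for a, b in zip(layers, layers[1:]):
            if abs(a.bottom_cm - b.top_cm) > 1e-9:
                raise InputError(
                    f"gap or overlap between layers at {a.bottom_cm}–{b.top_cm} cm"
                )

    @property
    def depth_cm(self) -> float:
        return self.layers[-1].bottom_cm


def layer_awc(
    theta_fc: float,
    theta_pwp: float,
    thickness_cm: float,
    stone_fraction: float = 0.0,
    correct_stones: bool = False,
) -> float:
    """Plant-available water (mm) of one layer: (θ_FC − θ_PWP) × thickness.

    Thickness in cm, 10 mm of water per cm of soil per unit Δθ.  With
    ``correct_stones`` the layer storage is reduced by the stone volume
    fraction.
    """
    delta = theta_fc - theta_pwp
    if delta < 0:
        raise DomainError("field-capacity water content below wilting-point content")
    awc = delta * thickness_cm * 10.0
    if correct_stones:
        awc *= 1.0 - stone_fraction
    return awc


def profile_awc(
    profile: SoilProfile,
    params_per_layer: list[VanGenuchtenParams] | None = None,
    standard_depth_cm: float = 100.0,
    correct_stones: bool = False,
) -> float:
    """Profile plant-available water capacity (mm) to a standard depth.

    Each layer contributes [θ(pF 1.8) − θ(pF 4.2)] × thickness; where the
    profile is shallower than ``standard_depth_cm`` the deepest layer's
    retention parameters are extended downwards (homogeneous subsoil
    assumption, e.g. 30–60 cm parameters reused for 60–100 cm).
    """
    if params_per_layer is None:
        params_per_layer = [
            texture_to_vg(l.sand, l.silt, l.clay, l.bulk_density) for l in profile.layers
        ]
    if len(params_per_layer) != len(profile.layers):
        raise InputError("one parameter set per layer required")

    h_fc = suction_cm_of_pF(PF_FIELD_CAPACITY)
    h_pwp = suction_cm_of_pF(PF_WILTING_POINT)

    total = 0.0
    for layer, params in zip(profile.layers, params_per_layer):
        top = layer.top_cm
        bottom = min(layer.bottom_cm, standard_depth_cm)
        if bottom <= top:
            continue
        total += layer_awc(
            vg_theta(params, h_fc),
            vg_theta(params, h_pwp),
            bottom - top,
            layer.stone_fraction,
            correct_stones,
        )
    if profile.depth_cm < standard_depth_cm:
        deepest = profile.layers[-1]
        params = params_per_layer[-1]
        total += layer_awc(
            vg_theta(params, h_fc),
            vg_theta(params, h_pwp),
            standard_depth_cm - profile.depth_cm,
            deepest.stone_fraction,
            correct_stones,
        )
    return total
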