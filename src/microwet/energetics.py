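"""Classical wetting relations and the sessile-drop Gibbs energy functional.

A drop of volume ``V`` sits on a rough surface as a spherical cap with
apparent contact angle ``theta`` (gravity neglected: ``R`` is well below the
capillary length).  Summing the three interfacial energies and dropping the
constant ``gamma_SV * S_SV-total`` reference term gives the excess Gibbs
energy

    G(theta; Ff) = K * F(theta)^(-2/3) * [2 - 2 cos(theta) - sin^2(theta) * Ff]

with the spherical-cap shape function ``F(c) = 2 - 3c + c^3`` (``c`` a
cosine), the energy scale ``K = gamma_LV (3V)^(2/3) pi^(1/3)`` and the
wetting-state parameter ``Ff = r_f f cos(theta_Y) + f - 1`` (composite,
Cassie) or ``Ff = r cos(theta_Y)`` (wetted, Wenzel).  Minimising over
``theta`` at fixed ``Ff`` gives ``cos(theta) = Ff`` whenever ``|Ff| <= 1``,
where the energy collapses to ``K * F(Ff)^(1/3)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any, Mapping

import numpy as np

from .errors import DivergentShapeError, InvalidRoughnessError

__all__ = [
    "WettingConstants",
    "EquilibriumAngle",
    "ContactPatch",
    "shape_function",
    "cassie_cos",
    "wenzel_cos",
    "equilibrium_angle",
    "droplet_radius",
    "interfacial_areas",
    "gibbs_excess",
    "equilibrium_gibbs_excess",
]

_G = 9.80665  # m/s^2


@dataclass(frozen=True)
class WettingConstants:
    """Physical constants of the drop/surface system (SI internally).

    Attributes
    ----------
    young_angle_deg :
        Intrinsic (Young) contact angle on the flat wax chemistry, degrees;
        default 104 (water on leaf wax).
    lv_tension_gamma :
        Liquid-vapor surface tension, N/m; default 0.0728 (water, 20 C).
    droplet_volume :
        Drop volume, m^3; default 5e-9 (5 uL).
    reference_offset :
        The constant ``gamma_SV * S_SV-total`` term, J.  Cancels in every
        energy difference; kept at 0 by default.
    water_density :
        kg/m^3; used only for the capillary-length sanity check.
    """

    young_angle_deg: float = 104.0
    lv_tension_gamma: float = 0.0728
    droplet_volume: float = 5e-9
    reference_offset: float = 0.0
    water_density: float = 998.0

    def __post_init__(self) -> None:
        if not 0.0 < self.young_angle_deg < 180.0:
            raise ValueError(f"Young angle must lie in (0, 180) deg, got {self.young_angle_deg}")
        if self.lv_tension_gamma <= 0:
            raise ValueError("liquid-vapor tension must be positive")
        if self.droplet_volume <= 0:
            raise ValueError("droplet volume must be positive")

    @property
    def cos_young(self) -> float:
        return math.cos(math.radians(self.young_angle_deg))

    @property
    def energy_scale(self) -> float:
        """``K = gamma_LV (3V)^(2/3) pi^(1/3)`` in J; ~648.5 nJ at defaults."""
        return self.lv_tension_gamma * (3.0 * self.droplet_volume) ** (2.0 / 3.0) * math.pi ** (1.0 / 3.0)

    @property
    def capillary_length(self) -> float:
        """``sqrt(gamma / (rho g))`` in m; ~2.7 mm for water."""
        return math.sqrt(self.lv_tension_gamma / (self.water_density * _G))

    @classmethod
    def from_config(cls, mapping: Mapping[str, Any]) -> "WettingConstants":
        """Build from external config: angle in deg, tension in mN/m, volume in uL."""
        kwargs = {}
        if "theta_young_deg" in mapping:
            kwargs["young_angle_deg"] = float(mapping["theta_young_deg"])
        if "gamma_lv_mN_per_m" in mapping:
            kwargs["lv_tension_gamma"] = float(mapping["gamma_lv_mN_per_m"]) * 1e-3
        if "droplet_volume_uL" in mapping:
            kwargs["droplet_volume"] = float(mapping["droplet_volume_uL"]) * 1e-9
        if "water_density_kg_m3" in mapping:
            kwargs["water_density"] = float(mapping["water_density_kg_m3"])
        return cls(**kwargs)

    def to_config(self) -> dict[str, float]:
        return {
            "theta_young_deg": self.young_angle_deg,
            "gamma_lv_mN_per_m": self.lv_tension_gamma * 1e3,
            "droplet_volume_uL": self.droplet_volume * 1e9,
            "water_density_kg_m3": self.water_density,
        }

    def replace(self, **changes: Any) -> "WettingConstants":
        return replace(self, **changes)


@dataclass(frozen=True)
class EquilibriumAngle:
    """Equilibrium cosine with saturation bookkeeping.

    When the formal Cassie/Wenzel cosine falls outside [-1, 1] there is no
    contact angle solving the equilibrium condition; ``saturated`` is set and
    ``angle_deg`` is ``None`` while ``cosine_c`` keeps the formal value.
    """

    cosine_c: float
    angle_deg: float | None
    saturated: bool


@dataclass(frozen=True)
class ContactPatch:
    """Droplet radius and interfacial areas of a sessile drop (SI units).

    ``area_SV_excess`` is measured relative to the dry surface's total
    solid-vapor area and is therefore <= 0 (the drop removes solid-vapor
    interface equal to the true wetted solid area).
    """

    droplet_radius_R: float
    area_LV: float
    area_LS: float
    area_SV_excess: float


def shape_function(cosine_c):
    """Spherical-cap shape function ``F(c) = 2 - 3c + c^3``.

    Total function: formal continuation beyond ``|c| = 1`` is deliberate
    (the composite branch is tracked past Cassie saturation).  On [-1, 1] it
    decreases from 4 (non-wetting sphere) to 0 (complete wetting).
    """
    c = np.asarray(cosine_c, dtype=float)
    out = 2.0 - 3.0 * c + c**3
    return float(out) if np.ndim(cosine_c) == 0 else out


def cassie_cos(constants: WettingConstants, rf, f):
    """Cassie-Baxter cosine ``c = r_f f cos(theta_Y) + f - 1``.

    The formal value is returned even when ``c < -1`` (no equilibrium angle);
    wrap with :func:`equilibrium_angle` to detect saturation.
    """
    rf = np.asarray(rf, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(rf < 1.0 - 1e-12):
        raise InvalidRoughnessError(f"r_f must be >= 1, got min {np.min(rf):g}")
    if np.any(f < 0.0) or np.any(f > 1.0 + 1e-12):
        raise InvalidRoughnessError(f"solid fraction must lie in [0, 1], got {f!r}")
    c = rf * f * constants.cos_young + f - 1.0
    return float(c) if (np.ndim(rf) == 0 and np.ndim(f) == 0) else c


def wenzel_cos(constants: WettingConstants, r):
    """Wenzel cosine ``c = r cos(theta_Y)`` (formal values < -1 permitted)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 1.0 - 1e-12):
        raise InvalidRoughnessError(f"Wenzel roughness must be >= 1, got min {np.min(r):g}")
    c = r * constants.cos_young
    return float(c) if np.ndim(r) == 0 else c


def equilibrium_angle(cosine_c: float) -> EquilibriumAngle:
    """Interpret a formal equilibrium cosine, flagging saturation."""
    if -1.0 <= cosine_c <= 1.0:
        return EquilibriumAngle(cosine_c, math.degrees(math.acos(cosine_c)), False)
    return EquilibriumAngle(cosine_c, None, True)


def droplet_radius(constants: WettingConstants, theta_deg: float) -> float:
    """Spherical-cap radius ``R = (3V/pi)^(1/3) F(theta)^(-1/3)`` (m).

    Inverts the cap volume ``V = (pi/3) R^3 F(theta)``.
    """
    F = shape_function(math.cos(math.radians(theta_deg)))
    if F <= 0.0:
        raise DivergentShapeError(
            f"F(theta) -> 0 at theta = {theta_deg:g} deg; droplet radius diverges"
        )
    return (3.0 * constants.droplet_volume / math.pi) ** (1.0 / 3.0) * F ** (-1.0 / 3.0)


def interfacial_areas(
    constants: WettingConstants,
    theta_deg: float,
    rf: float,
    f: float,
    r: float,
) -> ContactPatch:
    """Interfacial areas of the drop at apparent angle ``theta`` (m^2).

    Composite state: pass the ``(r_f, f)`` of the penetration depth and the
    structure's Wenzel ``r``.  Wetted state: pass ``f = 1`` and ``rf = r``.

    * ``S_LV = 2 pi R^2 (1 - cos theta) + pi R^2 sin^2(theta) (1 - f)``
      (outer cap plus the suspended meniscus under the drop),
    * ``S_LS = pi R^2 sin^2(theta) r_f f`` (true wetted solid area),
    * ``S_SV - S_SV-total = -pi R^2 sin^2(theta) r_f f`` (dry solid removed).
    """
    if not 0.0 < theta_deg <= 180.0:
        raise ValueError(f"theta must lie in (0, 180] deg, got {theta_deg}")
    if f > 1.0 + 1e-12 or rf < 1.0 - 1e-12 or r < 1.0 - 1e-12:
        raise InvalidRoughnessError("invalid roughness arguments")
    R = droplet_radius(constants, theta_deg)
    ct = math.cos(math.radians(theta_deg))
    s2 = 1.0 - ct * ct
    base = math.pi * R**2 * s2
    area_lv = 2.0 * math.pi * R**2 * (1.0 - ct) + base * (1.0 - f)
    area_ls = base * rf * f
    # S_SV = S_SV-total - pi R^2 sin^2 r + pi R^2 sin^2 (r - rf f)
    area_sv_excess = -base * r + base * (r - rf * f)
    return ContactPatch(R, area_lv, area_ls, area_sv_excess)


def gibbs_excess(constants: WettingConstants, theta_deg, Ff):
    """Excess Gibbs energy ``G(theta; Ff)`` of the drop, J.

    ``K F(theta)^(-2/3) [2 - 2 cos(theta) - sin^2(theta) Ff]`` plus the
    reference offset.  Valid for any wetting state through its ``Ff``; at the
    equilibrium angle ``cos(theta) = Ff`` it reduces to
    :func:`equilibrium_gibbs_excess`.
    """
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    ct = np.cos(theta)
    F = 2.0 - 3.0 * ct + ct**3
    if np.any(F <= 0.0):
        raise DivergentShapeError("F(theta) -> 0; Gibbs energy diverges as theta -> 0")
    Ff = np.asarray(Ff, dtype=float)
    G = constants.energy_scale * F ** (-2.0 / 3.0) * (2.0 - 2.0 * ct - (1.0 - ct**2) * Ff)
    G = G + constants.reference_offset
    return float(G) if (np.ndim(theta_deg) == 0 and np.ndim(Ff) == 0) else G


def equilibrium_gibbs_excess(constants: WettingConstants, cosine_c):
    """Equilibrium excess Gibbs energy ``K * F(c)^(1/3)``, J.

    ``c`` is the equilibrium (Cassie or Wenzel) cosine.  Formal ``c < -1`` is
    accepted; callers choosing the plateau policy should clamp to -1 first.
    """
    F = shape_function(cosine_c)
    G = constants.energy_scale * np.cbrt(F) + constants.reference_offset
    return float(G) if np.ndim(cosine_c) == 0 else G
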