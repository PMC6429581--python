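"""Microstructure geometry and roughness factors.

A leaf papilla is idealised as a hemisphere of base radius ``r0`` sitting on
a cylinder of height ``h0`` (``h0 = 0`` recovers the plain hemisphere of the
*Eucalyptus* model; ``h0 > 0`` the hemisphere-capped cylinder of the lotus
model).  Protrusions are arranged with edge-to-edge spacing ``2*d0`` on a
hexagonal or square lattice, one protrusion per primitive cell.

All wetting-relevant quantities — the wetted-cap roughness ratio ``r_f``, the
projected solid fraction ``f`` and the Wenzel roughness factor ``r`` — are
functions of the dimensionless liquid penetration depth ``x = h / r0``
measured from the protrusion apex, and depend on the geometry only through
the dimensionless ratios ``delta = d0/r0`` and ``eta = h0/r0``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Any, Mapping

import numpy as np

from .errors import DepthDomainError, InvalidGeometryError

__all__ = [
    "Packing",
    "MicrostructureGeometry",
    "RoughnessState",
    "unit_cell_area",
    "composite_roughness",
    "wenzel_roughness",
    "wenzel_roughness_at_depth",
    "roughness_state",
]

_MICRON = 1e-6


class Packing(str, Enum):
    """Lattice arrangement of the protrusions (one protrusion per cell)."""

    HEXAGONAL = "hexagonal"
    SQUARE = "square"


@dataclass(frozen=True)
class MicrostructureGeometry:
    """Dimensions of one papilla and its lattice cell, in metres.

    Parameters
    ----------
    base_radius_r0 :
        Radius of the hemispherical cap, ``r0 > 0`` (m).
    cylinder_height_h0 :
        Height of the cylindrical stem under the cap, ``h0 >= 0`` (m).
        Zero gives the hemisphere (*Eucalyptus*) model.
    half_spacing_d0 :
        Half the edge-to-edge distance between neighbouring protrusions,
        ``d0 >= 0`` (m).  The lattice pitch is ``2*(r0 + d0)``.
    packing :
        Hexagonal (default) or square lattice.
    """

    base_radius_r0: float
    cylinder_height_h0: float = 0.0
    half_spacing_d0: float = 0.0
    packing: Packing = Packing.HEXAGONAL

    def __post_init__(self) -> None:
        if not (self.base_radius_r0 > 0 and math.isfinite(self.base_radius_r0)):
            raise InvalidGeometryError(
                f"base radius r0 must be positive and finite, got {self.base_radius_r0!r}"
            )
        if not (self.cylinder_height_h0 >= 0 and math.isfinite(self.cylinder_height_h0)):
            raise InvalidGeometryError(
                f"cylinder height h0 must be >= 0, got {self.cylinder_height_h0!r}"
            )
        if not (self.half_spacing_d0 >= 0 and math.isfinite(self.half_spacing_d0)):
            raise InvalidGeometryError(
                f"half spacing d0 must be >= 0, got {self.half_spacing_d0!r}"
            )
        object.__setattr__(self, "packing", Packing(self.packing))

    @property
    def delta(self) -> float:
        """Spacing ratio ``d0 / r0``."""
        return self.half_spacing_d0 / self.base_radius_r0

    @property
    def eta(self) -> float:
        """Height ratio ``h0 / r0``; 0 for the hemisphere model."""
        return self.cylinder_height_h0 / self.base_radius_r0

    @property
    def is_hemisphere(self) -> bool:
        return self.cylinder_height_h0 == 0.0

    @classmethod
    def from_config(cls, mapping: Mapping[str, Any]) -> "MicrostructureGeometry":
        """Build from external key-value config (lengths in micrometres).

        Recognised keys: ``r0_um``, ``h0_um``, ``spacing_2d0_um``, ``packing``.
        """
        return cls(
            base_radius_r0=float(mapping["r0_um"]) * _MICRON,
            cylinder_height_h0=float(mapping.get("h0_um", 0.0)) * _MICRON,
            half_spacing_d0=float(mapping.get("spacing_2d0_um", 0.0)) * _MICRON / 2.0,
            packing=Packing(mapping.get("packing", "hexagonal")),
        )

    def to_config(self) -> dict[str, Any]:
        """Round-trippable external representation (micrometres)."""
        return {
            "r0_um": self.base_radius_r0 / _MICRON,
            "h0_um": self.cylinder_height_h0 / _MICRON,
            "spacing_2d0_um": 2.0 * self.half_spacing_d0 / _MICRON,
            "packing": self.packing.value,
        }


@dataclass(frozen=True)
class RoughnessState:
    """Roughness quantities at one penetration depth.

    ``cap_area_ratio_rf`` and ``solid_fraction_f`` describe the composite
    (Cassie) state at ``depth_x``; ``wenzel_ratio_r`` is the roughness factor
    of the fully wetted structure whose bottom sits at ``max(depth_x, 1)``.
    """

    depth_x: float
    cap_area_ratio_rf: float
    solid_fraction_f: float
    wenzel_ratio_r: float


def unit_cell_area(geom: MicrostructureGeometry) -> float:
    """Area of the primitive lattice cell holding one protrusion (m^2).

    Hexagonal: ``(sqrt(3)/2) * (2 r0 + 2 d0)^2``; square: ``(2 r0 + 2 d0)^2``.
    With ``d0 = r0`` the hexagonal cell is ``8*sqrt(3)*r0^2``.
    """
    pitch = 2.0 * (geom.base_radius_r0 + geom.half_spacing_d0)
    if geom.packing is Packing.HEXAGONAL:
        return 0.5 * math.sqrt(3.0) * pitch**2
    return pitch**2


def _cap_fraction(geom: MicrostructureGeometry) -> float:
    """``pi r0^2 / cell_area`` — projected solid fraction of a full circle."""
    frac = math.pi * geom.base_radius_r0**2 / unit_cell_area(geom)
    if frac > 1.0:
        warnings.warn(
            "projected protrusion area exceeds the unit cell; solid fraction "
            "will be capped at 1",
            stacklevel=3,
        )
    return frac


def _check_depth(geom: MicrostructureGeometry, x: np.ndarray, lo: float, hi: float) -> None:
    if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
        raise DepthDomainError(
            f"penetration depth must lie in [{lo}, {hi}] for this geometry "
            f"(eta = {geom.eta:g}); got values in "
            f"[{np.min(x):g}, {np.max(x):g}]"
        )


def composite_roughness(geom, depth_x):
    """Composite-state roughness ``(r_f, f)`` at penetration depth ``x``.

    For ``0 <= x <= 1`` (liquid front on the spherical cap)::

        r_f = 2 / (2 - x)           f = pi r0^2 (2x - x^2) / cell_area

    For ``1 < x <= 1 + eta`` (front descending the cylinder wall)::

        r_f = 2x                    f = pi r0^2 / cell_area

    Both branches agree at ``x = 1``.  Accepts scalars or arrays.
    """
    x = np.asarray(depth_x, dtype=float)
    _check_depth(geom, x, 0.0, 1.0 + geom.eta)
    frac = min(_cap_fraction(geom), 1.0)
    on_cap = x <= 1.0
    # np.where evaluates both arms; guard the cap formula against x = 2
    rf = np.where(on_cap, 2.0 / np.maximum(2.0 - x, 1e-300), 2.0 * x)
    f = np.where(on_cap, frac * x * (2.0 - x), frac)
    if np.isscalar(depth_x) or np.ndim(depth_x) == 0:
        return float(rf), float(f)
    return rf, f


def wenzel_roughness(geom: MicrostructureGeometry) -> float:
    """Wenzel roughness factor ``r`` of the fully wetted structure.

    ``r = 1 + (pi r0^2 + 2 pi r0 h0) / cell_area``: the spherical cap adds
    ``pi r0^2`` of true area over its projection, the cylinder wall
    ``2 pi r0 h0``.
    """
    r0, h0 = geom.base_radius_r0, geom.cylinder_height_h0
    return 1.0 + (math.pi * r0**2 + 2.0 * math.pi * r0 * h0) / unit_cell_area(geom)


def wenzel_roughness_at_depth(geom, x_end):
    """Wenzel roughness of a structure whose bottom is reached at ``x_end >= 1``.

    ``r(x_end) = 1 + pi r0^2 (2 x_end - 1) / cell_area``; linear in ``x_end``
    with slope ``2 pi r0^2 / cell_area``.  At ``x_end = 1 + eta`` this equals
    :func:`wenzel_roughness` of the same geometry.
    """
    x = np.asarray(x_end, dtype=float)
    if np.any(x < 1.0 - 1e-12):
        raise DepthDomainError(f"wetted-branch depth must be >= 1, got {np.min(x):g}")
    r = 1.0 + _cap_fraction(geom) * (2.0 * x - 1.0)
    if np.isscalar(x_end) or np.ndim(x_end) == 0:
        return float(r)
    return r


def roughness_state(geom: MicrostructureGeometry, depth_x: float) -> RoughnessState:
    """Bundle ``(r_f, f, r)`` at one depth into a :class:`RoughnessState`."""
    rf, f = composite_roughness(geom, depth_x)
    r = wenzel_roughness_at_depth(geom, max(float(depth_x), 1.0))
    return RoughnessState(
        depth_x=float(depth_x),
        cap_area_ratio_rf=rf,
        solid_fraction_f=f,
        wenzel_ratio_r=r,
    )
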