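"""Wetting-transition analysis over penetration depth.

Tracks the excess Gibbs energy of the drop along two branches:

* the **composite** branch — liquid suspended on the protrusions, front at
  dimensionless depth ``x``, equilibrium cosine from the Cassie relation with
  the depth-dependent ``(r_f, f)``;
* the **wetted** branch — asperities fully filled down to ``x``, cosine from
  the Wenzel relation with ``r(x)``.

From these it extracts the composite minimum (the depth ``x* = 1 +
cos(theta_Y)`` at which a gently deposited drop equilibrates), the energy
barrier ``dG1`` protecting that state, the energy potential ``dG2`` released
by a composite -> wetted transition, and the landmark depths where either
equilibrium relation saturates (``|cos| > 1``) or the branches cross.

Past saturation the equilibrium cosine is continued formally (``c < -1``,
flagged) so the full energy landscape of deep penetration remains visible; a
clamp-to-plateau policy (energy pinned at the non-wetting sphere value) is
available via ``continuation="clamp"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .energetics import (
    ContactPatch,
    WettingConstants,
    cassie_cos,
    equilibrium_gibbs_excess,
    interfacial_areas,
    shape_function,
    wenzel_cos,
)
from .errors import (
    BarrierDefinitionError,
    DepthDomainError,
    NoWettedEquilibriumError,
)
from .geometry import (
    MicrostructureGeometry,
    composite_roughness,
    wenzel_roughness,
    wenzel_roughness_at_depth,
)

__all__ = [
    "BranchCurve",
    "CompositeMinimum",
    "Landmarks",
    "TransitionSummary",
    "composite_cos",
    "composite_branch",
    "wetted_branch",
    "composite_minimum",
    "energy_barrier",
    "energy_potential",
    "landmarks",
    "equilibrium_contact_patch",
    "transition_summary",
]

Continuation = Literal["formal", "clamp"]


@dataclass(frozen=True)
class BranchCurve:
    """Sampled energy branch: arrays indexed by strictly increasing depth."""

    branch: Literal["composite", "wetted"]
    depth_x: np.ndarray
    cosine_c: np.ndarray  # formal equilibrium cosine (may drop below -1)
    shape_F: np.ndarray
    gibbs_excess_J: np.ndarray
    saturated: np.ndarray
    continuation: Continuation = "formal"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.depth_x,
                "cos_c": self.cosine_c,
                "F": self.shape_F,
                "G_excess_nJ": self.gibbs_excess_J * 1e9,
                "branch": self.branch,
                "saturated": self.saturated,
            }
        )


@dataclass(frozen=True)
class CompositeMinimum:
    x_star: float
    cosine_c: float
    shape_F: float


@dataclass(frozen=True)
class Landmarks:
    """Characteristic depths of the transition; absent landmarks are None.

    x_star : composite-minimum depth (always present for theta_Y > 90 deg).
    x_saturation : depth where the Cassie cosine reaches -1 (only on the
        cylinder section, so only when the structure is tall enough).
    x_crossing : depth beyond saturation where the formally continued
        composite and wetted branches exchange stability.
    x_wenzel_limit : deepest structure for which the Wenzel equation still
        has a solution, ``r(x) = -1/cos(theta_Y)``.
    """

    x_star: float
    x_saturation: float | None
    x_crossing: float | None
    x_wenzel_limit: float | None


@dataclass(frozen=True)
class TransitionSummary:
    x_star: float
    F_min: float
    barrier_dG1: float
    potential_dG2: float | None
    landmarks: Landmarks
    equilibrium_patch: ContactPatch
    barrier_eval_x: float
    saturated_wetted: bool = field(default=False)


def composite_cos(geom: MicrostructureGeometry, constants: WettingConstants, depth_x):
    """Formal Cassie cosine of the composite state at depth ``x``."""
    rf, f = composite_roughness(geom, depth_x)
    return cassie_cos(constants, rf, f)


def _curve(constants, branch, x, c, continuation):
    saturated = np.abs(c) > 1.0
    c_eff = np.clip(c, -1.0, 1.0) if continuation == "clamp" else c
    F = shape_function(c_eff)
    G = equilibrium_gibbs_excess(constants, c_eff)
    return BranchCurve(branch, x, c, np.asarray(F), np.asarray(G), saturated, continuation)


def composite_branch(
    geom: MicrostructureGeometry,
    constants: WettingConstants,
    x_grid,
    continuation: Continuation = "formal",
    *,
    allow_extension: bool = False,
) -> BranchCurve:
    """Composite (Cassie) energy branch over ``x_grid`` in [0, 1 + eta].

    With ``allow_extension`` (capped-cylinder geometries only) depths beyond
    the structure bottom are admitted by formally continuing the
    cylinder-section roughness — the deep-penetration energy map of the
    transition diagram.
    """
    x = np.atleast_1d(np.asarray(x_grid, dtype=float))
    if np.any(np.diff(x) <= 0):
        raise ValueError("x_grid must be strictly increasing")
    if allow_extension and geom.eta > 0.0:
        if np.any(x < 0.0):
            raise DepthDomainError("penetration depth must be >= 0")
        inside = x <= 1.0 + geom.eta
        c = np.empty_like(x)
        c[inside] = np.asarray(composite_cos(geom, constants, x[inside]))
        if np.any(~inside):
            c[~inside] = np.asarray(
                composite_cos_unbounded(geom, constants, x[~inside])
            )
    else:
        c = np.asarray(composite_cos(geom, constants, x))
    return _curve(constants, "composite", x, c, continuation)


def wetted_branch(
    geom: MicrostructureGeometry,
    constants: WettingConstants,
    x_grid,
    continuation: Continuation = "formal",
) -> BranchCurve:
    """Wetted (Wenzel) comparison branch over ``x_grid`` in [1, inf).

    ``x`` here parameterises the total structure depth the liquid has filled;
    the roughness grows linearly, so the shape function rises at constant
    slope ``2 pi r0^2 |cos theta_Y| * 3 sin^2 .. `` until Wenzel saturation.
    """
    x = np.atleast_1d(np.asarray(x_grid, dtype=float))
    if np.any(np.diff(x) <= 0):
        raise ValueError("x_grid must be strictly increasing")
    c = np.asarray(wenzel_cos(constants, wenzel_roughness_at_depth(geom, x)))
    return _curve(constants, "wetted", x, c, continuation)


def composite_minimum(
    geom: MicrostructureGeometry, constants: WettingConstants
) -> CompositeMinimum:
    """Minimum of the composite shape function over the cap region.

    For a hydrophobic chemistry the stationary point of the Cassie cosine
    ``c(x) = C (2 x cos(theta_Y) + x (2 - x)) - 1`` is the closed form
    ``x* = 1 + cos(theta_Y)``, independent of the spacing ratio.  Outside
    hydrophobic conditions (or if the closed form leaves (0, 1)) the minimum
    is located by bounded scalar minimisation instead.
    """
    x_closed = 1.0 + constants.cos_young
    if 0.0 < x_closed < 1.0:
        x_star = x_closed
    else:
        res = minimize_scalar(
            lambda x: shape_function(composite_cos(geom, constants, x)),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        x_star = float(res.x)
    c_star = composite_cos(geom, constants, x_star)
    return CompositeMinimum(x_star, c_star, shape_function(c_star))


def _default_barrier_eval_x(
    geom: MicrostructureGeometry, constants: WettingConstants, eval_x_cap: float
) -> float:
    """Hemisphere: fixed cap-region point; capped cylinder: bottom contact or
    Cassie saturation, whichever comes first."""
    if geom.eta == 0.0:
        return eval_x_cap
    x_sat = _saturation_depth(constants)
    return min(1.0 + geom.eta, x_sat if x_sat is not None else math.inf)


def energy_barrier(
    geom: MicrostructureGeometry,
    constants: WettingConstants,
    eval_x: float | None = None,
    *,
    eval_x_cap: float = 0.95,
) -> float:
    """Energy barrier ``dG1`` guarding the composite minimum, J.

    ``dG1 = K [F(x_eval)^(1/3) - F(x*)^(1/3)]`` along the composite branch.
    By default the barrier is evaluated at ``x = 0.95`` for the hemisphere
    model (last sampled composite state before bottom contact) and at
    ``min(1 + eta, x_saturation)`` for the capped-cylinder model.
    """
    if eval_x is None:
        eval_x = _default_barrier_eval_x(geom, constants, eval_x_cap)
    mn = composite_minimum(geom, constants)
    if eval_x <= mn.x_star:
        raise BarrierDefinitionError(
            f"barrier evaluation point {eval_x:g} must exceed x* = {mn.x_star:g}"
        )
    if eval_x > 1.0 + geom.eta + 1e-12:
        raise DepthDomainError(
            f"barrier evaluation point {eval_x:g} beyond structure bottom {1 + geom.eta:g}"
        )
    c_eval = composite_cos(geom, constants, eval_x)
    return equilibrium_gibbs_excess(constants, c_eval) - equilibrium_gibbs_excess(
        constants, mn.cosine_c
    )


def energy_potential(geom: MicrostructureGeometry, constants: WettingConstants) -> float:
    """Energy potential ``dG2`` of the composite -> wetted transition, J.

    Difference between the composite-minimum energy and the wetted-state
    equilibrium energy ``K F(r cos theta_Y)^(1/3)``.  Positive means the
    wetted state lies lower (transition thermodynamically favoured).
    """
    r = wenzel_roughness(geom)
    c_w = wenzel_cos(constants, r)
    if abs(c_w) > 1.0:
        raise NoWettedEquilibriumError(
            f"Wenzel cosine {c_w:.4f} outside [-1, 1]: no wetted equilibrium "
            f"for roughness r = {r:.4f}"
        )
    mn = composite_minimum(geom, constants)
    return equilibrium_gibbs_excess(constants, mn.cosine_c) - equilibrium_gibbs_excess(
        constants, c_w
    )


def _saturation_depth(constants: WettingConstants) -> float | None:
    """Depth where the cylinder-section Cassie cosine hits -1 (any spacing)."""
    if constants.cos_young >= 0.0:
        return None
    return -1.0 / (2.0 * constants.cos_young)


def landmarks(geom: MicrostructureGeometry, constants: WettingConstants) -> Landmarks:
    """Locate the characteristic depths of the transition diagram.

    Cassie saturation happens on the cylinder section of the relief, so
    ``x_saturation`` (and the crossing beyond it) are reported only for
    capped-cylinder geometries (``eta > 0``); both sit on the formal
    continuation of that section, which the deep-penetration energy map
    extends past the physical structure bottom.  The branch crossing is
    found by bracketed root finding between saturation and the Wenzel limit.
    """
    mn = composite_minimum(geom, constants)
    x_sat_raw = _saturation_depth(constants)
    x_sat = None
    if geom.eta > 0.0 and x_sat_raw is not None and x_sat_raw >= 1.0:
        x_sat = x_sat_raw

    x_wl = None
    if constants.cos_young < 0.0:
        # r(x) = 1 + C (2x - 1) = -1/cos(theta_Y), C = pi r0^2 / cell_area
        C = wenzel_roughness_at_depth(geom, 1.0) - 1.0
        target = -1.0 / constants.cos_young
        x_wl = ((target - 1.0) / C + 1.0) / 2.0
        if x_wl < 1.0:
            x_wl = None

    x_cross = None
    if x_sat is not None and x_wl is not None and x_sat < x_wl:

        def gap(x: float) -> float:
            fc = shape_function(composite_cos_unbounded(geom, constants, x))
            fw = shape_function(wenzel_cos(constants, wenzel_roughness_at_depth(geom, x)))
            return fc - fw

        lo, hi = x_sat_raw + 1e-9, x_wl
        if gap(lo) * gap(hi) < 0:
            x_cross = float(brentq(gap, lo, hi, xtol=1e-9))
    return Landmarks(mn.x_star, x_sat, x_cross, x_wl)


def composite_cos_unbounded(
    geom: MicrostructureGeometry, constants: WettingConstants, depth_x: float
):
    """Cylinder-section Cassie cosine without the ``x <= 1 + eta`` bound.

    Used to continue the composite branch past the physical structure bottom
    when mapping the deep-penetration landscape (branch crossing search).
    """
    x = np.asarray(depth_x, dtype=float)
    if np.any(x <= 1.0):
        raise DepthDomainError("unbounded continuation is defined for x > 1 only")
    frac = wenzel_roughness_at_depth(geom, 1.0) - 1.0  # pi r0^2 / cell_area
    c = 2.0 * x * frac * constants.cos_young + frac - 1.0
    return float(c) if np.ndim(depth_x) == 0 else c


def equilibrium_contact_patch(
    geom: MicrostructureGeometry, constants: WettingConstants
) -> ContactPatch:
    """Drop radius and interfacial areas at the composite minimum."""
    mn = composite_minimum(geom, constants)
    theta = math.degrees(math.acos(max(min(mn.cosine_c, 1.0), -1.0)))
    rf, f = composite_roughness(geom, mn.x_star)
    return interfacial_areas(constants, theta, rf, f, wenzel_roughness(geom))


def transition_summary(
    geom: MicrostructureGeometry,
    constants: WettingConstants,
    *,
    eval_x_cap: float = 0.95,
) -> TransitionSummary:
    """One-stop summary: minimum, barrier, potential, landmarks, patch."""
    mn = composite_minimum(geom, constants)
    marks = landmarks(geom, constants)
    barrier = energy_barrier(geom, constants, eval_x_cap=eval_x_cap)
    try:
        potential: float | None = energy_potential(geom, constants)
        saturated = False
    except NoWettedEquilibriumError:
        potential = None
        saturated = True
    return TransitionSummary(
        x_star=mn.x_star,
        F_min=mn.shape_F,
        barrier_dG1=barrier,
        potential_dG2=potential,
        landmarks=marks,
        equilibrium_patch=equilibrium_contact_patch(geom, constants),
        barrier_eval_x=_default_barrier_eval_x(geom, constants, eval_x_cap),
        saturated_wetted=saturated,
    )
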