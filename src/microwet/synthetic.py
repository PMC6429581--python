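"""Synthetic SEM-style geometry measurements and uncertainty propagation.

Real inputs to the model are per-species papilla dimensions measured off SEM
images (ten feature measurements per image, reported as mean +/- sd).  This
module replays that protocol synthetically: each species is a catalog entry
of means and standard deviations, and measurement sets are drawn from
independent normal distributions truncated to positive lengths.  Propagating
a measurement set through the transition analysis turns the printed +/- into
uncertainty bands on F_min, dG1, dG2 and the contact area.

What this emulates and what it does not: draws are i.i.d. — no spatial
correlation between neighbouring papillae, no within-leaf vs between-leaf
variance structure, and no measurement bias model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .energetics import WettingConstants
from .errors import NoWettedEquilibriumError
from .geometry import MicrostructureGeometry, Packing
from .transition import (
    composite_minimum,
    energy_barrier,
    energy_potential,
    equilibrium_contact_patch,
)

__all__ = [
    "SpeciesSpec",
    "MeasurementSet",
    "species_catalog",
    "sample_geometry",
    "propagate_uncertainty",
]

#: Lengths are clipped at this floor (um) so sampled geometries stay valid.
TRUNCATION_FLOOR_UM = 0.1

#: Measurements per SEM image in the emulated protocol.
N_PER_IMAGE = 10


@dataclass(frozen=True)
class SpeciesSpec:
    """Per-species microstructure statistics, micrometres (mean +/- sd).

    ``spacing2d0`` is the edge-to-edge distance ``2 d0`` as measured, i.e.
    twice the half-spacing used by the geometry model.
    """

    name: str
    r0_mean: float
    r0_sd: float
    h0_mean: float
    h0_sd: float
    spacing2d0_mean: float
    spacing2d0_sd: float
    n_per_image: int = N_PER_IMAGE

    def __post_init__(self) -> None:
        if self.r0_mean <= 0 or self.spacing2d0_mean < 0 or self.h0_mean < 0:
            raise ValueError(f"invalid means for species {self.name!r}")
        if min(self.r0_sd, self.h0_sd, self.spacing2d0_sd) < 0:
            raise ValueError(f"standard deviations must be >= 0 for {self.name!r}")

    def mean_geometry(self, packing: Packing = Packing.HEXAGONAL) -> MicrostructureGeometry:
        """Deterministic geometry at the catalog means."""
        return MicrostructureGeometry(
            base_radius_r0=self.r0_mean * 1e-6,
            cylinder_height_h0=self.h0_mean * 1e-6,
            half_spacing_d0=self.spacing2d0_mean * 1e-6 / 2.0,
            packing=packing,
        )


@dataclass(frozen=True)
class MeasurementSet:
    """A reproducible batch of sampled geometries for one species."""

    species: str
    samples: tuple[MicrostructureGeometry, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        rows = [g.to_config() for g in self.samples]
        frame = pd.DataFrame(rows)
        frame.insert(0, "species", self.species)
        return frame


def species_catalog() -> tuple[SpeciesSpec, ...]:
    """The four reference leaf microstructures (micrometres).

    Lotus papillae are hemisphere-capped cylinders; the three *Eucalyptus*
    species are plain hemispheres (zero cylinder height).
    """
    return (
        SpeciesSpec("lotus", 5.0, 0.5, 5.0, 0.5, 10.0, 1.2),
        SpeciesSpec("E. woodwardii", 8.0, 0.8, 0.0, 0.0, 14.0, 2.8),
        SpeciesSpec("E. pachyphylla", 9.0, 0.6, 0.0, 0.0, 9.0, 2.8),
        SpeciesSpec("E. dolorosa", 10.0, 1.0, 0.0, 0.0, 16.0, 5.4),
    )


def sample_geometry(
    spec: SpeciesSpec,
    n: int | None = None,
    seed: int = 0,
    packing: Packing = Packing.HEXAGONAL,
) -> MeasurementSet:
    """Draw ``n`` synthetic geometry measurements for one species.

    r0, h0 and the edge-to-edge spacing are drawn independently from normal
    distributions with the catalog mean/sd, clipped at ``TRUNCATION_FLOOR_UM``
    so all lengths stay positive.  A species with ``h0_mean = 0`` keeps
    ``h0 = 0`` exactly (hemisphere model).  Identical ``(spec, n, seed)``
    yield identical sets.
    """
    if n is None:
        n = spec.n_per_image
    if n < 1:
        raise ValueError(f"need at least one measurement, got n = {n}")
    rng = np.random.default_rng(seed)
    floor = TRUNCATION_FLOOR_UM
    r0 = np.clip(rng.normal(spec.r0_mean, spec.r0_sd, n), floor, None)
    if spec.h0_mean == 0.0:
        h0 = np.zeros(n)
    else:
        h0 = np.clip(rng.normal(spec.h0_mean, spec.h0_sd, n), floor, None)
    spacing = np.clip(rng.normal(spec.spacing2d0_mean, spec.spacing2d0_sd, n), floor, None)
    samples = tuple(
        MicrostructureGeometry(
            base_radius_r0=r * 1e-6,
            cylinder_height_h0=h * 1e-6,
            half_spacing_d0=s * 1e-6 / 2.0,
            packing=packing,
        )
        for r, h, s in zip(r0, h0, spacing)
    )
    return MeasurementSet(spec.name, samples, seed)


def _per_sample_outputs(
    mset: MeasurementSet, constants: WettingConstants, eval_x_cap: float
) -> pd.DataFrame:
    records = []
    for geom in mset.samples:
        mn = composite_minimum(geom, constants)
        patch = equilibrium_contact_patch(geom, constants)
        try:
            dg2 = energy_potential(geom, constants) * 1e9
        except NoWettedEquilibriumError:
            dg2 = np.nan
        records.append(
            {
                "delta": geom.delta,
                "eta": geom.eta,
                "F_min": mn.shape_F,
                "dG1_nJ": energy_barrier(geom, constants, eval_x_cap=eval_x_cap) * 1e9,
                "dG2_nJ": dg2,
                "S_LS_mm2": patch.area_LS * 1e6,
            }
        )
    return pd.DataFrame.from_records(records)


def propagate_uncertainty(
    mset: MeasurementSet,
    constants: WettingConstants,
    *,
    eval_x_cap: float = 0.95,
    return_samples: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Push a measurement set through the transition analysis.

    Returns a summary frame indexed by output quantity (``F_min``,
    ``dG1_nJ``, ``dG2_nJ``, ``S_LS_mm2``) with columns ``mean``, ``sd``,
    ``p2.5``, ``p97.5``, ``n`` and ``n_saturated``.  Samples whose Wenzel
    equation has no solution are excluded from the ``dG2_nJ`` statistics and
    counted under ``n_saturated``.  The energy outputs depend on geometry
    only through ``(delta, eta)``, so common rescaling of a sample leaves
    them unchanged.
    """
    if len(mset) == 0:
        raise ValueError("measurement set is empty")
    per_sample = _per_sample_outputs(mset, constants, eval_x_cap)
    rows = {}
    for col in ("F_min", "dG1_nJ", "dG2_nJ", "S_LS_mm2"):
        vals = per_sample[col].to_numpy()
        ok = vals[~np.isnan(vals)]
        if ok.size == 0:
            stats = {"mean": np.nan, "sd": np.nan, "p2.5": np.nan, "p97.5": np.nan}
        else:
            stats = {
                "mean": ok.mean(),
                "sd": ok.std(ddof=1) if ok.size > 1 else 0.0,
                "p2.5": np.percentile(ok, 2.5),
                "p97.5": np.percentile(ok, 97.5),
            }
        rows[col] = {**stats, "n": ok.size, "n_saturated": int(np.isnan(vals).sum())}
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "quantity"
    if return_samples:
        return summary, per_sample
    return summary
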