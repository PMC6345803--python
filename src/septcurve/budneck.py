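"""Axisymmetric bud-neck orientation theory for cytokinesis.

At the neck of a dividing budding-yeast cell the membrane is a saddle:
the curvature along the mother-bud axis (``c_par``, radius ``R_par``)
and the circumferential curvature (``c_perp``, radius ``R_perp``) carry
opposite signs.  A filament adsorbed radially (parallel to the axis)
bends with ``c_par``; one adsorbed circumferentially bends with
``c_perp`` but its contact-area gain is projected by the angle theta of
the circumferential filament plane with the membrane:

    dg_n(c_par)  = dg_n0 (1 - a_n c_par / 2)            + Lp_n c_par**2 / 2
    dg_n(c_perp) = dg_n0 (1 - a_n c_perp sin(theta) / 2) + Lp_n c_perp**2 / 2

Two shape classes are treated:

* SPHERICAL: sin(theta) = R_perp / R_par, so the area terms cancel and
  the orientation with the smaller curvature magnitude always wins —
  radial (parallel), since |c_par| < |c_perp| there.
* OBLONG (barrel/cylinder/neck, theta ~ pi/2): sin(theta) = 1 and the
  energy gap factorizes as

    dg_n(c_par) - dg_n(c_perp)
        = Lp_n / 2 * (c_par - c_perp) * (c_par + c_perp - c_n)

  with the threshold c_n = dg_n0 a_n / Lp_n = c_1 / n.  With the
  convention c_par - c_perp > 0 the circumferential (perpendicular)
  orientation is preferred exactly when c_par + c_perp > c_n.  Since
  c_n = c_1/n, singles flip before doubles: the mixed band
  c_1 < c_par + c_perp < c_2 has single filaments circumferential while
  paired filaments remain parallel.  Under extreme constriction the
  circumferential curvature finally exceeds the bundle's maximum
  curvature and the assembly must split into two rings on the flanks of
  the neck, where the membrane is wider than the bundle's minimum
  radius R_n_min ~ n^(3/4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .params import Curvature, SeptinModelParams
from . import model

__all__ = [
    "NeckShape",
    "NeckGeometry",
    "Preference",
    "OrientationPreference",
    "Stage",
    "StageLabel",
    "neck_free_energies",
    "preferred_orientation",
    "transition_condition",
    "stage_sequence",
    "phase_diagram",
]


class NeckShape(Enum):
    SPHERICAL = "spherical"
    OBLONG = "oblong"


class Preference(Enum):
    PARALLEL = "parallel"  # radial, along the mother-bud axis
    PERPENDICULAR = "perpendicular"  # circumferential
    DEGENERATE = "degenerate"


class Stage(Enum):
    SPHERE_RADIAL = "sphere_radial"
    CYLINDER_MIXED = "cylinder_mixed"
    NECK_CIRCUMFERENTIAL = "neck_circumferential"
    SPLIT_DOUBLE_RING = "split_double_ring"


@dataclass(frozen=True)
class NeckGeometry:
    """Pointwise axisymmetric shape descriptor at the adsorption site.

    ``R_par_um``: signed radius of curvature along the mother-bud axis
    (negative at a constriction saddle); ``R_perp_um``: signed
    circumferential radius (negative: concave from the binding face).
    For SPHERICAL shapes sin(theta) = R_perp/R_par and geometries with
    |R_perp| > |R_par| are rejected; for OBLONG shapes sin(theta) = 1.
    """

    R_par_um: float
    R_perp_um: float
    shape: NeckShape

    def __post_init__(self) -> None:
        if self.R_par_um == 0.0 or self.R_perp_um == 0.0:
            raise DomainError("radii of curvature cannot be zero")
        if not (math.isfinite(self.R_perp_um)):
            raise DomainError("circumferential radius must be finite")
        if self.shape is NeckShape.SPHERICAL:
            if not math.isfinite(self.R_par_um):
                raise DomainError("spherical shape requires finite R_par")
            if abs(self.R_perp_um) > abs(self.R_par_um):
                raise DomainError(
                    "spherical shape requires |R_perp| <= |R_par| "
                    f"(got {self.R_perp_um} vs {self.R_par_um})"
                )

    @property
    def c_par(self) -> Curvature:
        if math.isinf(self.R_par_um):
            return Curvature(0.0)
        return Curvature.from_radius_um(self.R_par_um)

    @property
    def c_perp(self) -> Curvature:
        return Curvature.from_radius_um(self.R_perp_um)

    @property
    def sin_theta(self) -> float:
        """Sine of the angle of the circumferential filament plane with
        the membrane."""
        if self.shape is NeckShape.OBLONG:
            return 1.0
        return self.R_perp_um / self.R_par_um


@dataclass(frozen=True)
class OrientationPreference:
    preferred: Preference
    gap: float  # dg_n(c_par) - dg_n(c_perp), k_bT nm^-1


@dataclass(frozen=True)
class StageLabel:
    stage: Stage
    per_n: Mapping[int, Preference] = field(default_factory=dict)


def neck_free_energies(
    params: SeptinModelParams, n: int, geom: NeckGeometry
) -> tuple[float, float]:
    """(dg_par, dg_perp): adsorption free energies per unit length of the
    radial and circumferential orientations, k_bT nm^-1."""
    b = model.bundle_properties(params, n)
    cp = geom.c_par.per_nm
    cq = geom.c_perp.per_nm
    dg_par = b.dg_n_flat * (1.0 - 0.5 * b.a_n_nm * cp) + 0.5 * params.kT * b.Lp_n_nm * cp * cp
    dg_perp = (
        b.dg_n_flat * (1.0 - 0.5 * b.a_n_nm * cq * geom.sin_theta)
        + 0.5 * params.kT * b.Lp_n_nm * cq * cq
    )
    return dg_par, dg_perp


def preferred_orientation(
    params: SeptinModelParams, n: int, geom: NeckGeometry
) -> OrientationPreference:
    """Preferred adsorption orientation at the given geometry.

    SPHERICAL: the area terms cancel exactly and the gap reduces to
    Lp_n (c_par^2 - c_perp^2)/2, independent of dg_n0 and a_n.
    OBLONG: full energy comparison with sin(theta) = 1.
    PERPENDICULAR is preferred iff the gap dg_par - dg_perp > 0.
    """
    if geom.shape is NeckShape.SPHERICAL:
        b = model.bundle_properties(params, n)
        cp = geom.c_par.per_nm
        cq = geom.c_perp.per_nm
        gap = 0.5 * params.kT * b.Lp_n_nm * (cp * cp - cq * cq)
    else:
        dg_par, dg_perp = neck_free_energies(params, n, geom)
        gap = dg_par - dg_perp
    if gap > 0.0:
        return OrientationPreference(Preference.PERPENDICULAR, gap)
    if gap < 0.0:
        return OrientationPreference(Preference.PARALLEL, gap)
    return OrientationPreference(Preference.DEGENERATE, 0.0)


def transition_condition(
    params: SeptinModelParams, n: int, c_par: Curvature, c_perp: Curvature
) -> bool:
    """Closed-form parallel-to-circumferential transition test for oblong
    shapes: true iff (c_perp + c_par - c_n)(c_par - c_perp) > 0, with
    c_n the curved-over-flat threshold of an n-bundle.  Equivalent to
    the sign of the direct oblong energy gap."""
    c_n = model.threshold_curvature(params, n).per_nm
    cp = c_par.per_nm
    cq = c_perp.per_nm
    return (cq + cp - c_n) * (cp - cq) > 0.0


def _oblong_stage(
    params: SeptinModelParams,
    geom: NeckGeometry,
    n_list: Sequence[int],
    bundle_n: int,
) -> StageLabel:
    per_n = {
        n: preferred_orientation(params, n, geom).preferred for n in n_list
    }
    c_max, _ = model.max_curvature_and_min_radius(params, bundle_n)
    if abs(geom.c_perp.per_nm) > c_max.per_nm:
        return StageLabel(Stage.SPLIT_DOUBLE_RING, per_n)
    if all(p is Preference.PERPENDICULAR for p in per_n.values()):
        return StageLabel(Stage.NECK_CIRCUMFERENTIAL, per_n)
    return StageLabel(Stage.CYLINDER_MIXED, per_n)


def stage_sequence(
    params: SeptinModelParams,
    geometry_path: Sequence[NeckGeometry],
    n_list: Sequence[int] = (1, 2),
    bundle_n: int = 50,
) -> list[StageLabel]:
    """Label each point of a progressive-constriction path with its
    cytokinesis stage.

    The path must be ordered by constriction, i.e. non-decreasing total
    curvature c_perp + c_par for the oblong segment (the sharpening
    saddle's positive meridian curvature outgrows the deepening negative
    circumferential one).  Spherical points are labelled SPHERE_RADIAL;
    oblong points are CYLINDER_MIXED while any n in ``n_list`` still
    prefers the parallel orientation, NECK_CIRCUMFERENTIAL once all are
    circumferential, and SPLIT_DOUBLE_RING once the circumferential
    curvature magnitude exceeds the maximum curvature of a
    ``bundle_n``-filament bundle (ring splitting; bundling itself
    requires additional molecular players, so ``bundle_n`` is supplied
    by the caller, default 50).
    """
    if not geometry_path:
        raise ValidationError("geometry_path is empty")
    if not n_list:
        raise ValidationError("n_list is empty")
    sums = [
        g.c_par.per_nm + g.c_perp.per_nm
        for g in geometry_path
        if g.shape is NeckShape.OBLONG
    ]
    if any(b < a - 1e-15 for a, b in zip(sums, sums[1:])):
        raise ValidationError(
            "geometry_path is not ordered by progressive constriction "
            "(c_par + c_perp must be non-decreasing over oblong points)"
        )
    labels: list[StageLabel] = []
    for geom in geometry_path:
        if geom.shape is NeckShape.SPHERICAL:
            per_n = {n: Preference.PARALLEL for n in n_list}
            labels.append(StageLabel(Stage.SPHERE_RADIAL, per_n))
        else:
            labels.append(_oblong_stage(params, geom, n_list, bundle_n))
    return labels


def phase_diagram(
    params: SeptinModelParams,
    c_par_grid_per_um: Iterable[float],
    c_perp_grid_per_um: Iterable[float],
    n: int,
) -> pd.DataFrame:
    """Evaluate the oblong orientation preference on a curvature grid.

    Returns one row per (c_par, c_perp) cell with columns
    ``c_par_per_um``, ``c_perp_per_um``, ``n``, ``preferred`` and
    ``gap_kT_per_nm``.  Deterministic.
    """
    c_par_grid = np.asarray(list(c_par_grid_per_um), dtype=float)
    c_perp_grid = np.asarray(list(c_perp_grid_per_um), dtype=float)
    if c_par_grid.size == 0 or c_perp_grid.size == 0:
        raise ValidationError("phase_diagram grids must be non-empty")
    b = model.bundle_properties(params, n)
    rows = []
    for cp in c_par_grid:
        for cq in c_perp_grid:
            # direct oblong gap in internal units; handles zero curvatures
            cpn, cqn = cp * 1e-3, cq * 1e-3
            gap = (
                -0.5 * b.dg_n_flat * b.a_n_nm * (cpn - cqn)
                + 0.5 * params.kT * b.Lp_n_nm * (cpn * cpn - cqn * cqn)
            )
            if gap > 0.0:
                pref = Preference.PERPENDICULAR
            elif gap < 0.0:
                pref = Preference.PARALLEL
            else:
                pref = Preference.DEGENERATE
            rows.append(
                {
                    "c_par_per_um": cp,
                    "c_perp_per_um": cq,
                    "n": n,
                    "preferred": pref.value,
                    "gap_kT_per_nm": gap,
                }
            )
    return pd.DataFrame(rows)
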