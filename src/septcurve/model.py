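"""Adsorption free-energy model for filaments and bundles on curved membranes.

Model
-----
A filament of width ``a_n``, persistence length ``Lp_n`` and flat-membrane
binding energy per unit length ``dg_n0 < 0`` adsorbed on a substrate of
signed curvature ``c`` has free energy per unit length (kT = 1)

    dg_n(c) = dg_n0 * (1 - a_n * c / 2) + Lp_n * c**2 / 2

The linear term is the curvature-induced change of membrane-contact area
(an incompressible filament presents more contact surface on a concave
substrate), the quadratic term is the bending energy.  Since dg_n0 < 0
and Lp_n > 0 the energy is strictly convex in c with a minimum at a
negative (concave) optimal curvature

    c_n* = dg_n0 * a_n / (2 * Lp_n)

Curved beats flat exactly on the band c_n < c < 0 with threshold
c_n = 2 c_n*, and adsorption remains favorable at all only up to a
maximum curvature magnitude c_n_max = sqrt(-2 dg_n0 / Lp_n), i.e. down
to a minimum radius R_n_min = 1/c_n_max.  With the bundle scalings
(a_n ~ n^1/2, Lp_n ~ n^2, dg_n0 ~ n^1/2) these obey c_n*/c_1* = 1/n and
R_n_min/R_1_min = n^(3/4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import DomainError, ModelViolationError
from .params import BundleProperties, Curvature, SeptinModelParams

__all__ = [
    "OrientationRegime",
    "Orientation",
    "dg_flat_from_kd",
    "bundle_properties",
    "free_energy_per_length",
    "optimal_curvature",
    "threshold_curvature",
    "max_curvature_and_min_radius",
    "curved_vs_flat_gap",
    "classify_substrate_orientation",
]


class Orientation(Enum):
    """Filament orientation on a uniaxially wavy substrate."""

    ALONG_AXIS = "along_axis"
    TILTED = "tilted"
    ACROSS_GROOVE = "across_groove"


@dataclass(frozen=True)
class OrientationRegime:
    """Orientation regime plus tilt angle (degrees from the wave axis).

    0 deg = straight along the zero-curvature wave axis, 90 deg = bent
    across the groove, following the full substrate curvature.
    """

    regime: Orientation
    tilt_angle_deg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt_angle_deg <= 90.0:
            raise DomainError(
                f"tilt angle must be in [0, 90], got {self.tilt_angle_deg}"
            )
        if self.regime is Orientation.ALONG_AXIS and self.tilt_angle_deg != 0.0:
            raise DomainError("ALONG_AXIS requires tilt angle 0")
        if self.regime is Orientation.ACROSS_GROOVE and self.tilt_angle_deg != 90.0:
            raise DomainError("ACROSS_GROOVE requires tilt angle 90")


def dg_flat_from_kd(params: SeptinModelParams) -> float:
    """Flat binding free energy per unit length from the dissociation
    constant: ln(Kd / c_ref) / (8 * a1), in k_bT nm^-1.

    An octamer (8 monomers of size a1) bound with dissociation constant
    Kd contributes kT ln(Kd/c_ref) of binding energy over length 8*a1.
    Negative whenever Kd < c_ref.  Note this standard-state estimate is
    not used as the package default (see :class:`SeptinModelParams`).
    """
    kd_M = params.Kd_nM * 1e-9
    return params.kT * math.log(kd_M / params.ref_conc_M) / (8.0 * params.a1_nm)


def bundle_properties(params: SeptinModelParams, n: int) -> BundleProperties:
    """Width, persistence length and flat binding energy of an n-bundle."""
    if isinstance(n, bool) or not isinstance(n, int):
        raise DomainError(f"filament count n must be an integer, got {n!r}")
    if n < 1:
        raise DomainError(f"filament count n must be >= 1, got {n}")
    root_n = math.sqrt(n)
    return BundleProperties(
        n=n,
        a_n_nm=params.a1_nm * root_n,
        Lp_n_nm=params.Lp1_nm * n * n,
        dg_n_flat=params.dg1_flat * root_n,
    )


def free_energy_per_length(
    params: SeptinModelParams, n: int, c: Curvature
) -> float:
    """Adsorption free energy per unit length dg_n(c), k_bT nm^-1."""
    b = bundle_properties(params, n)
    cc = c.per_nm
    return (
        b.dg_n_flat * (1.0 - 0.5 * b.a_n_nm * cc)
        + 0.5 * params.kT * b.Lp_n_nm * cc * cc
    )


def optimal_curvature(params: SeptinModelParams, n: int) -> Curvature:
    """Curvature minimizing dg_n: c_n* = dg_n0 a_n / (2 Lp_n) < 0."""
    b = bundle_properties(params, n)
    if b.dg_n_flat >= 0:
        raise ModelViolationError(
            "no bound-state optimum: flat binding energy must be negative"
        )
    return Curvature(b.dg_n_flat * b.a_n_nm / (2.0 * params.kT * b.Lp_n_nm))


def threshold_curvature(params: SeptinModelParams, n: int) -> Curvature:
    """Curvature where curved and flat adsorption are equally favorable:
    c_n = 2 c_n*; curved beats flat exactly on c_n < c < 0."""
    return Curvature(2.0 * optimal_curvature(params, n).per_nm)


def max_curvature_and_min_radius(
    params: SeptinModelParams, n: int
) -> tuple[Curvature, float]:
    """Maximum curvature magnitude at which adsorption stays favorable,
    and the corresponding minimum radius of curvature.

    Neglecting the contact-area term (|c a_n| << 1), adsorption is
    favorable while Lp_n c^2 / 2 + dg_n0 < 0, i.e. up to
    c_n_max = sqrt(-2 dg_n0 / Lp_n).  Returns (c_n_max, R_n_min_nm);
    R_n_min = R_1_min * n^(3/4).
    """
    b = bundle_properties(params, n)
    if b.dg_n_flat >= 0:
        raise ModelViolationError(
            "maximum curvature undefined: flat binding energy must be negative"
        )
    c_max = math.sqrt(-2.0 * b.dg_n_flat / (params.kT * b.Lp_n_nm))
    return Curvature(c_max), 1.0 / c_max


def curved_vs_flat_gap(params: SeptinModelParams, n: int, c: Curvature) -> float:
    """dg_n(c) - dg_n(0) = -dg_n0 a_n c / 2 + Lp_n c^2 / 2, k_bT nm^-1.

    Zero at c = 0 and at the threshold c_n; minimal at the optimum c_n*.
    Negative values mean curved adsorption beats flat.
    """
    b = bundle_properties(params, n)
    cc = c.per_nm
    return -0.5 * b.dg_n_flat * b.a_n_nm * cc + 0.5 * params.kT * b.Lp_n_nm * cc * cc


def classify_substrate_orientation(
    params: SeptinModelParams, n: int, groove_curvature: Curvature
) -> OrientationRegime:
    """Predict filament orientation on a uniaxially wavy substrate.

    ``groove_curvature`` is the extremal signed curvature across the
    wave at the adsorption site (valley negative, hill positive); the
    principal curvatures of the substrate there are (c, 0) with 0 along
    the wave axis.  A filament tilted by angle phi from the axis samples
    the normal curvature c_eff(phi) = c * sin(phi)**2 (Euler's formula).

    Bands (c_n = 2 c_n* < c_n* < 0):

    * c >= 0: positive curvature is always unfavorable; filaments stay
      straight along the zero-curvature axis (ALONG_AXIS).
    * c_n* <= c < 0: the full substrate curvature is within the
      favorable range up to the optimum; filaments bend fully across
      the groove (ACROSS_GROOVE, 90 deg).
    * c_n < c < c_n*: the substrate over-curves past the optimum; the
      filament tilts so its sampled normal curvature equals the optimum,
      sin(phi)**2 = c_n* / c (TILTED).
    * c <= c_n: even the optimal tilt cannot beat flat adsorption along
      the axis within the curved-over-flat band; ALONG_AXIS.

    Ties at band edges resolve toward the lower-|tilt| regime.
    """
    c = groove_curvature.per_nm
    c_star = optimal_curvature(params, n).per_nm
    c_thr = 2.0 * c_star
    if c >= 0.0 or c <= c_thr:
        return OrientationRegime(Orientation.ALONG_AXIS, 0.0)
    if c >= c_star:  # c_n* <= c < 0
        return OrientationRegime(Orientation.ACROSS_GROOVE, 90.0)
    # c_n < c < c_n*: optimal tilt from Euler's normal-curvature formula
    sin2 = c_star / c  # both negative, ratio in (0, 1)
    phi = math.degrees(math.asin(math.sqrt(sin2)))
    return OrientationRegime(Orientation.TILTED, phi)
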