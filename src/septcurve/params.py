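"""Model parameters and elementary geometric value types.

Conventions
-----------
* Internal units: lengths in nm, curvatures in nm^-1, energies in k_bT
  (the thermal energy scale ``kT`` is fixed at 1, so "energy per unit
  length" is k_bT nm^-1).
* Curvature sign: measured on the face the filament binds; the outside
  of a sphere (a convex hill) is positive, the inside of a sphere (a
  concave valley, or the circumference of a constricted neck seen from
  the cytosolic face) is negative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import DomainError, ValidationError

#: nm per µm; the only unit conversion in the package, exact.
NM_PER_UM = 1.0e3


@dataclass(frozen=True)
class Curvature:
    """Signed curvature, stored in nm^-1.

    Positive = convex substrate (outside of a sphere, hill crest);
    negative = concave (valley, neck circumference).
    """

    per_nm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.per_nm):
            raise DomainError(f"curvature must be finite, got {self.per_nm}")

    @classmethod
    def from_per_um(cls, c_per_um: float) -> "Curvature":
        return cls(c_per_um / NM_PER_UM)

    @classmethod
    def from_radius_um(cls, radius_um: float) -> "Curvature":
        if radius_um == 0.0:
            raise DomainError("radius of curvature cannot be zero")
        return cls(1.0 / (radius_um * NM_PER_UM))

    @property
    def per_um(self) -> float:
        return self.per_nm * NM_PER_UM

    @property
    def radius_nm(self) -> float:
        """Signed radius of curvature in nm (infinite for a flat substrate)."""
        if self.per_nm == 0.0:
            return math.inf
        return 1.0 / self.per_nm

    @property
    def radius_um(self) -> float:
        return self.radius_nm / NM_PER_UM


@dataclass(frozen=True)
class SeptinModelParams:
    """Single-filament parameters of the adsorption free-energy model.

    Parameters
    ----------
    a1_nm:
        Size of a septin monomer (filament width), nm.  Default 4 nm.
    Lp1_nm:
        Persistence length of a single filament, nm.  Default 2000 nm,
        one quarter of the measured paired-filament value of 8 µm
        (persistence length scales with the square of filament number).
    dg1_flat:
        Flat-membrane binding free energy per unit length of a single
        filament, k_bT nm^-1; must be negative (binding is favorable).
        The default -0.7305 is calibrated so that the model's minimum
        adsorption radius is 37 nm and its curved-over-flat threshold
        radius is ~ -0.7 µm with the default a1 and Lp1.  The
        alternative estimate from the measured dissociation constant is
        available via :func:`septcurve.model.dg_flat_from_kd`.
    Kd_nM:
        Dissociation constant per octamer on a flat bilayer, nM
        (informational; default 88 nM).
    ref_conc_M:
        Reference (standard-state) concentration for the logarithm in
        the Kd-to-energy conversion, mol/L.  Default 1 M.
    kT:
        Thermal energy scale; fixed to 1 (all energies in k_bT).
    """

    a1_nm: float = 4.0
    Lp1_nm: float = 2000.0
    dg1_flat: float = -0.7305
    Kd_nM: float = 88.0
    ref_conc_M: float = 1.0
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.a1_nm <= 0:
            raise DomainError(f"a1_nm must be > 0, got {self.a1_nm}")
        if self.Lp1_nm <= 0:
            raise DomainError(f"Lp1_nm must be > 0, got {self.Lp1_nm}")
        if self.dg1_flat >= 0:
            raise DomainError(
                f"dg1_flat must be < 0 (binding), got {self.dg1_flat}"
            )
        if self.Kd_nM <= 0:
            raise DomainError(f"Kd_nM must be > 0, got {self.Kd_nM}")
        if self.ref_conc_M <= 0:
            raise DomainError(f"ref_conc_M must be > 0, got {self.ref_conc_M}")
        if self.kT != 1.0:
            raise DomainError("kT is fixed to 1 (all energies in k_bT)")

    @classmethod
    def from_threshold_radius(
        cls,
        R1_um: float,
        a1_nm: float = 4.0,
        Lp1_nm: float = 2000.0,
        **kwargs: float,
    ) -> "SeptinModelParams":
        """Calibrate the flat binding energy from an observed single-filament
        curved-over-flat threshold radius (negative, µm).

        The threshold curvature is c1 = dg1_flat * a1 / Lp1, so
        dg1_flat = Lp1 / (R1 * a1) with R1 in nm.
        """
        if R1_um >= 0:
            raise DomainError(
                f"threshold radius must be negative (concave), got {R1_um}"
            )
        dg1 = Lp1_nm / (R1_um * NM_PER_UM * a1_nm)
        return cls(a1_nm=a1_nm, Lp1_nm=Lp1_nm, dg1_flat=dg1, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SeptinModelParams":
        """Build from the JSON-config key set (lengths in µm where noted)."""
        known = {
            "a1_nm",
            "Lp1_um",
            "dg1_flat_kT_per_nm",
            "Kd_nM",
            "ref_conc_M",
        }
        unknown = set(d) - known
        if unknown:
            raise ValidationError(
                f"unknown parameter keys: {sorted(unknown)}; expected subset "
                f"of {sorted(known)}"
            )
        kwargs = {}
        if "a1_nm" in d:
            kwargs["a1_nm"] = float(d["a1_nm"])
        if "Lp1_um" in d:
            kwargs["Lp1_nm"] = float(d["Lp1_um"]) * NM_PER_UM
        if "dg1_flat_kT_per_nm" in d:
            kwargs["dg1_flat"] = float(d["dg1_flat_kT_per_nm"])
        if "Kd_nM" in d:
            kwargs["Kd_nM"] = float(d["Kd_nM"])
        if "ref_conc_M" in d:
            kwargs["ref_conc_M"] = float(d["ref_conc_M"])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "SeptinModelParams":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"invalid JSON in {path}: {exc}") from exc
        if not isinstance(d, dict):
            raise ValidationError(f"{path}: expected a JSON object")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "a1_nm": self.a1_nm,
            "Lp1_um": self.Lp1_nm / NM_PER_UM,
            "dg1_flat_kT_per_nm": self.dg1_flat,
            "Kd_nM": self.Kd_nM,
            "ref_conc_M": self.ref_conc_M,
        }


@dataclass(frozen=True)
class BundleProperties:
    """Derived properties of an n-filament bundle.

    Assuming a roughly circular bundle cross-section the width grows as
    n^(1/2), the persistence length as n^2, and the flat binding energy
    per unit length (set by the membrane-contact width) as n^(1/2).
    These scalings are treated as exact definitions.
    """

    n: int
    a_n_nm: float
    Lp_n_nm: float
    dg_n_flat: float

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int,)) or isinstance(self.n, bool):
            raise DomainError(f"n must be an integer, got {self.n!r}")
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")
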