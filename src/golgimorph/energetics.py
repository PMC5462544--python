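"""Free-energy functional of a cisterna.

Three additive contributions, all in units of kBT:

* ``F_part`` — mean-field mixing (partitioning) entropy of rigid
  liquid-ordered nanodomains distributed between the rim and the sheet,
  with region-wise constant area fractions ``Phi_rim`` / ``Phi_mid``.
* ``F_bend_mid`` — Helfrich bending of the two spherical sheet caps
  (total curvature ±2/R; the cross terms of the two leaflet signs cancel,
  leaving ``4/R² + Js_mid²``).
* ``F_bend_rim`` — Helfrich bending of the toroidal rim, integrated
  numerically over the toroidal angle.

The local bending modulus interpolates harmonically between the
liquid-disordered and liquid-ordered moduli as a function of the local
nanodomain fraction; the Gaussian modulus is a fixed (negative) multiple
of the local bending modulus, so Gauss–Bonnet does not apply and the
Gaussian term is kept explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .geometry import ShapeState

__all__ = [
    "NanodomainField",
    "ElasticParams",
    "BuddingParams",
    "EnergyBreakdown",
    "PartitionConstraintError",
    "local_bending_modulus",
    "js_from_budding",
    "mid_fraction",
    "admissible_phi_rim",
    "partition_entropy_energy",
    "mid_bending_energy",
    "rim_bending_energy",
    "total_energy",
]


class PartitionConstraintError(ValueError):
    """Nanodomain conservation pushed a region fraction outside [0, 1]."""


@dataclass(frozen=True)
class NanodomainField:
    """Rigid nanodomain population: domain radius and global area fraction."""

    Rd: float = 5.0
    Phi: float = 0.2
    a_dom: float = field(init=False)

    def __post_init__(self) -> None:
        if self.Rd <= 0:
            raise ValueError("nanodomain radius must be positive")
        if not 0.0 <= self.Phi <= 1.0:
            raise ValueError("nanodomain area fraction must lie in [0, 1]")
        object.__setattr__(self, "a_dom", math.pi * self.Rd**2)


@dataclass(frozen=True)
class ElasticParams:
    """Elastic moduli (kBT) and spontaneous curvatures (nm^-1).

    ``alpha_kbar`` is the ratio of Gaussian to bending modulus,
    negative for stable bilayers.  ``Js_rim``/``Js_mid`` are the
    spontaneous curvatures of the rim and sheet regions; the default
    scenario concentrates curvature generators at the rim (Js_mid = 0).
    """

    kappa_ld: float = 20.0
    kappa_lo: float = 80.0
    alpha_kbar: float = -0.83
    Js_rim: float = 0.0
    Js_mid: float = 0.0

    def __post_init__(self) -> None:
        if not self.kappa_lo >= self.kappa_ld > 0:
            raise ValueError("require kappa_lo >= kappa_ld > 0")


@dataclass(frozen=True)
class BuddingParams:
    """Curvature-generating (budding) proteins on the cytosolic leaflet."""

    phi_budding: float
    zeta_budding: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_budding <= 1.0:
            raise ValueError("phi_budding must lie in [0, 1]")
        if self.zeta_budding <= 0:
            raise ValueError("zeta_budding must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    F_part: float
    F_bend_mid: float
    F_bend_rim: float

    @property
    def F_total(self) -> float:
        return self.F_part + self.F_bend_mid + self.F_bend_rim


def local_bending_modulus(phi: float, params: ElasticParams) -> float:
    """Harmonic interpolation of the bending modulus at local lo-fraction phi:
    1/κ = φ/κ_lo + (1 − φ)/κ_ld.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phase fraction {phi} outside [0, 1]")
    return 1.0 / (phi / params.kappa_lo + (1.0 - phi) / params.kappa_ld)


def js_from_budding(b: BuddingParams) -> float:
    """Membrane spontaneous curvature from budding-protein coverage,
    Js = ½ φ_budding ζ_budding (the ½ accounts for the resistance of the
    opposing monolayer)."""
    return 0.5 * b.phi_budding * b.zeta_budding


def mid_fraction(Phi: float, Phi_rim: float, shape: ShapeState) -> float:
    """Sheet-region nanodomain fraction implied by conservation:
    Φ_mid = Φ + (Φ − Φ_rim) · A_rim / A_mid."""
    if not (0.0 <= Phi <= 1.0 and 0.0 <= Phi_rim <= 1.0):
        raise PartitionConstraintError("area fractions must lie in [0, 1]")
    phi_mid = Phi + (Phi - Phi_rim) * shape.A_rim / shape.A_mid
    if not -1e-12 <= phi_mid <= 1.0 + 1e-12:
        raise PartitionConstraintError(
            f"Phi_mid={phi_mid} outside [0, 1] for Phi={Phi}, Phi_rim={Phi_rim}"
        )
    return min(max(phi_mid, 0.0), 1.0)


def admissible_phi_rim(Phi: float, shape: ShapeState) -> tuple[float, float]:
    """Interval of rim fractions compatible with Φ_mid ∈ [0, 1] and Φ_rim ∈ [0, 1]."""
    ratio = shape.A_mid / shape.A_rim
    lo = max(0.0, Phi - (1.0 - Phi) * ratio)
    hi = min(1.0, Phi * (1.0 + ratio))
    return lo, hi


def _mixing(x: float) -> float:
    """x ln x + (1−x) ln(1−x), with the exact 0·ln0 = 0 limits."""
    s = 0.0
    if x > 0.0:
        s += x * math.log(x)
    if x < 1.0:
        s += (1.0 - x) * math.log(1.0 - x)
    return s


def partition_entropy_energy(
    Phi_rim: float, Phi: float, nano: NanodomainField, shape: ShapeState
) -> float:
    """Mean-field partitioning free energy −T·S_part in kBT:
    (1/πRd²) Σ_regions A_region [Φ ln Φ + (1−Φ) ln(1−Φ)]."""
    phi_mid = mid_fraction(Phi, Phi_rim, shape)
    return (shape.A_mid * _mixing(phi_mid) + shape.A_rim * _mixing(Phi_rim)) / nano.a_dom


def mid_bending_energy(
    shape: ShapeState, Phi_rim: float, nano: NanodomainField, el: ElasticParams
) -> float:
    """Bending energy of the sheet caps:
    (κ_mid/2)(4/R² + Js_mid²) A_mid + ᾱ_κ κ_mid A_mid / R².

    The ±2/R leaflet signs of the two parallel caps average to the
    4/R² + Js_mid² form (the odd cross terms cancel); the flat state with
    Js_mid = 0 is exactly zero.
    """
    phi_mid = mid_fraction(nano.Phi, Phi_rim, shape)
    kappa_mid = local_bending_modulus(phi_mid, el)
    inv_R2 = 0.0 if shape.is_flat else 1.0 / (shape.R * shape.R)
    bend = 0.5 * kappa_mid * (4.0 * inv_R2 + el.Js_mid**2) * shape.A_mid
    gauss = el.alpha_kbar * kappa_mid * shape.A_mid * inv_R2
    return bend + gauss


def rim_bending_energy(shape: ShapeState, Phi_rim: float, el: ElasticParams) -> float:
    """Bending energy of the toroidal rim.

    Expanding (J − Js_rim)² reduces the surface integral to the
    precomputed rim curvature moments:
    κ_rim/2 (I2 − 2 Js_rim I1 + Js_rim² A_rim) + ᾱ_κ κ_rim IK.
    """
    kappa_rim = local_bending_modulus(Phi_rim, el)
    js = el.Js_rim
    bend = 0.5 * kappa_rim * (shape.I2 - 2.0 * js * shape.I1 + js * js * shape.A_rim)
    return bend + el.alpha_kbar * kappa_rim * shape.IK


def total_energy(
    shape: ShapeState, Phi_rim: float, nano: NanodomainField, el: ElasticParams
) -> EnergyBreakdown:
    """Total free energy F = F_part + F_bend_mid + F_bend_rim (kBT)."""
    return EnergyBreakdown(
        F_part=partition_entropy_energy(Phi_rim, nano.Phi, nano, shape),
        F_bend_mid=mid_bending_energy(shape, Phi_rim, nano, el),
        F_bend_rim=rim_bending_energy(shape, Phi_rim, el),
    )
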