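"""Geometry of the flat <-> curled cisterna shape family.

A Golgi cisterna is modelled as two parallel circular membrane sheets
(lumenal half-thickness ``h``) closed by an open-toroidal rim of
cross-sectional radius ``rrim``.  Curling bends the sheet pair into
spherical caps of radius ``R`` while the rim centre-line circle shrinks
from ``rflat`` down towards ``rrim``; its radius ``rgap`` is the single
scalar "degree of curling" coordinate.  Total membrane area is conserved
along the whole family, which ties ``R`` to ``rgap``.

All lengths are in nm, areas in nm^2, curvatures in nm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "GeometryParams",
    "ShapeState",
    "InvalidGeometryError",
    "rim_area",
    "flat_total_area",
    "rim_phi_limits",
    "rim_curvatures",
    "rim_moments",
    "solve_shape",
    "ShapeFamily",
]


class InvalidGeometryError(ValueError):
    """Raised for geometrically inconsistent parameters or coordinates."""


@dataclass(frozen=True)
class GeometryParams:
    """Fixed lengths of the cisterna: sheet radius, rim radius, half-thickness.

    ``alpha = arcsin(h / rrim)`` is the half-opening angle at which the
    toroidal rim meets the sheet; ``A_total`` is the conserved membrane
    area, evaluated in the flat configuration.
    """

    rflat: float = 500.0
    rrim: float = 30.0
    h: float = 15.0
    alpha: float = field(init=False)
    A_total: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.rflat > self.rrim > self.h > 0):
            raise InvalidGeometryError(
                f"require rflat > rrim > h > 0, got "
                f"rflat={self.rflat}, rrim={self.rrim}, h={self.h}"
            )
        object.__setattr__(self, "alpha", math.asin(self.h / self.rrim))
        object.__setattr__(self, "A_total", flat_total_area(self))


@dataclass(frozen=True)
class ShapeState:
    """One member of the area-conserving shape family at a given ``rgap``.

    ``theta_cap`` is the polar cap angle of the spherical sheet
    (``rgap = R sin(theta_cap)``); the flat state is represented exactly
    with ``theta_cap = 0`` and ``R = inf``.  Rim curvature moments
    ``I1 = ∮J dA``, ``I2 = ∮J^2 dA``, ``IK = ∮K dA`` are precomputed so
    that rim bending energies are closed-form in the elastic parameters.
    """

    rgap: float
    theta_cap: float
    R: float
    A_rim: float
    A_mid: float
    geometry: GeometryParams
    I1: float
    I2: float
    IK: float

    @property
    def is_flat(self) -> bool:
        return math.isinf(self.R)

    @property
    def mid_total_curvature(self) -> float:
        """Magnitude of the sheet total curvature, 2/R (0 when flat)."""
        return 0.0 if self.is_flat else 2.0 / self.R


def _phi0(rgap: float, rflat: float) -> float:
    return math.asin(1.0 - 2.0 * rgap * rgap / (rflat * rflat))


def rim_phi_limits(rgap: float, geom: GeometryParams) -> tuple[float, float]:
    """Integration limits of the toroidal angle phi along the rim cross-section."""
    p0 = _phi0(rgap, geom.rflat)
    return p0 - math.pi / 2 + geom.alpha, p0 + 3 * math.pi / 2 - geom.alpha


def _check_rgap(rgap: float, geom: GeometryParams) -> None:
    if not (geom.rrim < rgap <= geom.rflat):
        raise InvalidGeometryError(
            f"rgap={rgap} outside admissible interval ({geom.rrim}, {geom.rflat}]"
        )


def rim_area(rgap: float, geom: GeometryParams) -> float:
    """Rim surface area at curling coordinate ``rgap``.

    Closed form of the toroidal area integral:
    ``4π rrim [rgap (π − α) − rrim sin α sin φ0]`` with
    ``φ0 = arcsin(1 − 2 rgap²/rflat²)``.
    """
    _check_rgap(rgap, geom)
    p0 = _phi0(rgap, geom.rflat)
    return (
        4.0
        * math.pi
        * geom.rrim
        * (rgap * (math.pi - geom.alpha) - geom.rrim * math.sin(geom.alpha) * math.sin(p0))
    )


def flat_total_area(geom: GeometryParams) -> float:
    """Conserved total membrane area, evaluated for the flat configuration:
    ``2π rflat² + 4π rrim [h + rflat (π − α)]``.
    """
    alpha = math.asin(geom.h / geom.rrim)
    return 2.0 * math.pi * geom.rflat**2 + 4.0 * math.pi * geom.rrim * (
        geom.h + geom.rflat * (math.pi - alpha)
    )


def rim_curvatures(phi: float, rgap: float, rrim: float):
    """Total and Gaussian curvature at toroidal angle ``phi`` on the rim.

    J = (rgap + 2 rrim cos φ) / (rrim (rgap + rrim cos φ)),
    K = cos φ / (rrim (rgap + rrim cos φ)).
    Vectorised over ``phi``.
    """
    if rgap <= rrim:
        raise InvalidGeometryError(f"rgap={rgap} must exceed rrim={rrim}")
    c = np.cos(phi)
    denom = rrim * (rgap + rrim * c)
    return (rgap + 2.0 * rrim * c) / denom, c / denom


def rim_moments(rgap: float, geom: GeometryParams, rel_tol: float = 1e-10):
    """Rim curvature moments (I1, I2, IK) over the toroidal surface patch.

    I1 = ∮ J dA and IK = ∮ K dA are analytic; I2 = ∮ J² dA requires
    adaptive quadrature (there is no closed form).  The θ integral
    contributes a flat 2π factor.
    """
    _check_rgap(rgap, geom)
    lo, hi = rim_phi_limits(rgap, geom)
    rr = geom.rrim
    # J dA = (rgap + 2 rrim cos φ) dφ dθ ;  K dA = cos φ dφ dθ
    dsin = math.sin(hi) - math.sin(lo)
    I1 = 2.0 * math.pi * (rgap * (hi - lo) + 2.0 * rr * dsin)
    IK = 2.0 * math.pi * dsin

    def j2_element(phi: float) -> float:
        c = math.cos(phi)
        return (rgap + 2.0 * rr * c) ** 2 / (rr * (rgap + rr * c))

    val, _ = integrate.quad(j2_element, lo, hi, epsrel=rel_tol, epsabs=0.0, limit=200)
    I2 = 2.0 * math.pi * val
    return I1, I2, IK


def solve_shape(rgap: float, geom: GeometryParams) -> ShapeState:
    """Solve the area-conservation constraint for the sheet cap at ``rgap``.

    Given the rim area, conservation fixes the sheet area
    ``A_mid = A_total − A_rim``.  Writing the two sheet caps as spherical
    caps of angle θ (``rgap = R sin θ``, ``A_mid = 4π R²(1 − cos θ)``)
    gives the exact solution ``cos θ = 4π rgap² / A_mid − 1`` on the
    single branch continuous with the flat limit (θ → 0 at
    ``rgap = rflat``); the spec's ± branches of the cap area correspond
    to θ below/above π/2.  The flat state is returned exactly with
    R = inf.
    """
    _check_rgap(rgap, geom)
    A_rim = rim_area(rgap, geom)
    I1, I2, IK = rim_moments(rgap, geom)
    if rgap == geom.rflat:
        A_mid = 2.0 * math.pi * geom.rflat**2
        return ShapeState(rgap, 0.0, math.inf, A_rim, A_mid, geom, I1, I2, IK)
    A_mid = geom.A_total - A_rim
    cos_theta = 4.0 * math.pi * rgap * rgap / A_mid - 1.0
    if not (-1.0 < cos_theta < 1.0):
        raise InvalidGeometryError(
            f"area conservation unsolvable at rgap={rgap} (cos theta={cos_theta})"
        )
    theta = math.acos(cos_theta)
    R = rgap / math.sin(theta)
    return ShapeState(rgap, theta, R, A_rim, A_mid, geom, I1, I2, IK)


class ShapeFamily:
    """Cached shape family on an rgap grid for a fixed geometry.

    Profile and diagram scans re-solve the same geometry for many
    elastic parameter sets; caching the solved states (and their rim
    quadrature moments) makes those scans cheap.
    """

    def __init__(self, geom: GeometryParams, rgap_grid: np.ndarray):
        self.geometry = geom
        self.rgap_grid = np.asarray(rgap_grid, dtype=float)
        self.states = [solve_shape(r, geom) for r in self.rgap_grid]
        self._cache: dict[float, ShapeState] = {s.rgap: s for s in self.states}

    def state_at(self, rgap: float) -> ShapeState:
        st = self._cache.get(rgap)
        if st is None:
            st = solve_shape(rgap, self.geometry)
            self._cache[rgap] = st
        return st


def default_rgap_grid(geom: GeometryParams, n: int = 200) -> np.ndarray:
    """Geometrically spaced rgap grid, dense near the rim, ending at rflat."""
    lo = geom.rrim * 1.02
    grid = np.geomspace(lo, geom.rflat, n)
    grid[-1] = geom.rflat
    return grid
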