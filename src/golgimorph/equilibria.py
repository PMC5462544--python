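"""Equilibrium shapes: partition-optimized energy profiles and their minima.

For every degree of curling ``rgap`` the rim nanodomain fraction is
optimized first (a bounded one-dimensional minimization), yielding the
partition-optimized profile F(rgap).  Local minima of that profile are
the locally stable cisterna configurations: an interior minimum is a
curled cisterna, the boundary point ``rgap = rflat`` is the flat one.
Energies are always reported relative to the flat configuration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .energetics import (
    ElasticParams,
    NanodomainField,
    admissible_phi_rim,
    mid_fraction,
    total_energy,
)
from .geometry import GeometryParams, ShapeFamily, ShapeState, default_rgap_grid

__all__ = [
    "StateKind",
    "StateClass",
    "EnergyProfile",
    "optimize_partition",
    "energy_profile",
    "classify_state",
    "enrichment_ratio",
]

#: two minima closer than this (kBT) are reported as degenerate
DEGENERACY_TOL = 1e-3

#: finite step (nm) for the one-sided stability test of the flat boundary point
_FLAT_TEST_STEP = 0.5

#: refinement tolerance for extremum locations (nm)
_RGAP_XATOL = 1e-3


class StateKind(enum.Enum):
    FLAT_ONLY = "flat_only"
    CURLED_ONLY = "curled_only"
    BISTABLE_CURLED_GLOBAL = "bistable_curled_global"
    BISTABLE_FLAT_GLOBAL = "bistable_flat_global"

    @property
    def bistable(self) -> bool:
        return self in (StateKind.BISTABLE_CURLED_GLOBAL, StateKind.BISTABLE_FLAT_GLOBAL)


@dataclass(frozen=True)
class StateClass:
    kind: StateKind
    degenerate: bool = False

    def __str__(self) -> str:
        return self.kind.value + (" (degenerate)" if self.degenerate else "")


@dataclass
class EnergyProfile:
    """Partition-optimized energy landscape F(rgap), relative to the flat state."""

    rgap_grid: np.ndarray
    F_opt: np.ndarray
    Phi_rim_opt: np.ndarray
    Phi_mid_opt: np.ndarray
    has_flat_min: bool
    has_curled_min: bool
    F_flat: float
    F_curl: float | None
    F_max: float | None
    rgap_curl: float | None
    rgap_max: float | None
    Phi_rim_curl: float | None
    Phi_rim_flat: float
    geometry: GeometryParams

    @property
    def dF_flat_to_curl(self) -> float | None:
        if self.F_max is None or not self.has_flat_min:
            return None
        return self.F_max - self.F_flat

    @property
    def dF_curl_to_flat(self) -> float | None:
        if self.F_max is None or self.F_curl is None:
            return None
        return self.F_max - self.F_curl

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rgap_nm": self.rgap_grid,
                "F_kBT": self.F_opt,
                "Phi_rim_opt": self.Phi_rim_opt,
                "Phi_mid_opt": self.Phi_mid_opt,
            }
        )


def optimize_partition(
    shape: ShapeState,
    nano: NanodomainField,
    el: ElasticParams,
    xatol: float = 1e-6,
) -> tuple[float, float]:
    """Minimize the total free energy over the rim nanodomain fraction.

    Returns ``(Phi_rim_opt, F_opt)`` with the search restricted to the
    interval where conservation keeps both region fractions in [0, 1].
    Rigid nanodomains always deplete from the curved rim, so the
    minimizer satisfies ``Phi_rim_opt <= Phi``.
    """
    if nano.Phi == 0.0:
        return 0.0, total_energy(shape, 0.0, nano, el).F_total
    lo, hi = admissible_phi_rim(nano.Phi, shape)
    if hi - lo < xatol:
        x = 0.5 * (lo + hi)
        return x, total_energy(shape, x, nano, el).F_total

    def objective(phi_rim: float) -> float:
        return total_energy(shape, phi_rim, nano, el).F_total

    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    if not res.success:
        raise RuntimeError(f"partition optimization failed at rgap={shape.rgap}")
    return float(res.x), float(res.fun)


def _optimized_F(rgap: float, family: ShapeFamily, nano: NanodomainField,
                 el: ElasticParams) -> float:
    return optimize_partition(family.state_at(rgap), nano, el)[1]


def _refine_extremum(
    a: float, b: float, family: ShapeFamily, nano: NanodomainField,
    el: ElasticParams, maximize: bool = False,
) -> tuple[float, float]:
    sign = -1.0 if maximize else 1.0
    res = minimize_scalar(
        lambda r: sign * _optimized_F(r, family, nano, el),
        bounds=(a, b), method="bounded", options={"xatol": _RGAP_XATOL},
    )
    return float(res.x), sign * float(res.fun)


def energy_profile(
    nano: NanodomainField,
    el: ElasticParams,
    geom: GeometryParams | None = None,
    n_grid: int = 200,
    family: ShapeFamily | None = None,
) -> EnergyProfile:
    """Partition-optimized profile F(rgap) with refined minima and barrier.

    The grid is geometrically spaced (dense near the rim) and includes
    the flat endpoint ``rgap = rflat`` exactly; grid extrema are refined
    by bounded scalar search to 1e-3 nm.  A precomputed ``ShapeFamily``
    may be passed to amortize the geometry solve across parameter scans.
    """
    if family is None:
        if geom is None:
            geom = GeometryParams()
        family = ShapeFamily(geom, default_rgap_grid(geom, n_grid))
    geom = family.geometry
    grid = family.rgap_grid
    n = len(grid)
    if n < 100:
        raise ValueError("n_grid must be at least 100")

    F_raw = np.empty(n)
    phi_rim = np.empty(n)
    for i, state in enumerate(family.states):
        phi_rim[i], F_raw[i] = optimize_partition(state, nano, el)
    F_flat_raw = F_raw[-1]
    F = F_raw - F_flat_raw
    phi_mid = np.array(
        [mid_fraction(nano.Phi, p, s) for p, s in zip(phi_rim, family.states)]
    )

    # interior curled minimum: 3-point stencil, lowest candidate, refined
    has_curled = False
    rgap_curl = F_curl = phi_rim_curl = None
    interior = [
        i for i in range(1, n - 1) if F[i] < F[i - 1] and F[i] <= F[i + 1]
    ]
    if interior:
        i0 = min(interior, key=lambda i: F[i])
        rgap_curl, F_curl_raw = _refine_extremum(
            grid[i0 - 1], grid[i0 + 1], family, nano, el
        )
        F_curl = F_curl_raw - F_flat_raw
        phi_rim_curl = optimize_partition(family.state_at(rgap_curl), nano, el)[0]
        has_curled = True

    # flat boundary minimum: one-sided slope test at rgap = rflat
    F_near_flat = _optimized_F(geom.rflat - _FLAT_TEST_STEP, family, nano, el) - F_flat_raw
    has_flat = F_near_flat > 0.0

    # barrier between the curled minimum and the flat endpoint
    F_max = rgap_max = None
    if has_curled:
        sel = grid >= rgap_curl
        idx = np.flatnonzero(sel)
        j = idx[np.argmax(F[idx])]
        a = grid[max(j - 1, 0)] if grid[max(j - 1, 0)] >= rgap_curl else rgap_curl
        b = grid[min(j + 1, n - 1)]
        rgap_max, F_max_raw = _refine_extremum(a, b, family, nano, el, maximize=True)
        F_max = F_max_raw - F_flat_raw

    return EnergyProfile(
        rgap_grid=grid,
        F_opt=F,
        Phi_rim_opt=phi_rim,
        Phi_mid_opt=phi_mid,
        has_flat_min=has_flat,
        has_curled_min=has_curled,
        F_flat=0.0,
        F_curl=F_curl,
        F_max=F_max,
        rgap_curl=rgap_curl,
        rgap_max=rgap_max,
        Phi_rim_curl=phi_rim_curl,
        Phi_rim_flat=float(phi_rim[-1]),
        geometry=geom,
    )


def classify_state(profile: EnergyProfile) -> StateClass:
    """Classify the landscape into the four stability regions.

    The flat endpoint counts as a local minimum iff the energy decreases
    towards ``rflat``; when both minima exist the global one is the lower,
    with a degeneracy flag when they agree within 1e-3 kBT.
    """
    if profile.has_curled_min and profile.has_flat_min:
        degenerate = abs(profile.F_curl - profile.F_flat) < DEGENERACY_TOL
        if profile.F_curl < profile.F_flat:
            return StateClass(StateKind.BISTABLE_CURLED_GLOBAL, degenerate)
        return StateClass(StateKind.BISTABLE_FLAT_GLOBAL, degenerate)
    if profile.has_curled_min:
        return StateClass(StateKind.CURLED_ONLY)
    return StateClass(StateKind.FLAT_ONLY)


def enrichment_ratio(
    profile: EnergyProfile, nano: NanodomainField, el: ElasticParams | None = None
) -> dict[str, float]:
    """Sheet-to-rim nanodomain enrichment Φ_mid*/Φ_rim* per stable branch.

    Always >= 1 (domains deplete from the rim); returns ``inf`` when the
    rim is completely depleted.  Keys: ``"flat"`` and/or ``"curled"``.
    """
    from .geometry import solve_shape

    out: dict[str, float] = {}

    def ratio(phi_rim: float, shape: ShapeState) -> float:
        phi_mid = mid_fraction(nano.Phi, phi_rim, shape)
        if phi_rim == 0.0:
            return math.inf
        return phi_mid / phi_rim

    if profile.has_flat_min:
        out["flat"] = ratio(
            profile.Phi_rim_flat, solve_shape(profile.geometry.rflat, profile.geometry)
        )
    if profile.has_curled_min:
        out["curled"] = ratio(
            profile.Phi_rim_curl, solve_shape(profile.rgap_curl, profile.geometry)
        )
    return out
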