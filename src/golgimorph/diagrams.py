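"""Shape diagrams in the (Phi, Js) plane and their boundary curves.

Three boundaries organize the diagram at each nanodomain fraction Phi:

* the *flat spinodal* — the Js below which the flat configuration stops
  being a local minimum (only curled shapes below it);
* the *curled spinodal* — the Js above which the curled local minimum
  disappears (only flat shapes above it);
* the *equal-energy locus* between them, where the two minima swap
  global stability.

Boundaries are located by per-Phi bisection in Js on the existence (or
energy-ordering) predicate, which is sharper than contouring cell
states.  Everything here is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import ElasticParams, NanodomainField
from .equilibria import EnergyProfile, StateClass, classify_state, energy_profile
from .geometry import GeometryParams, ShapeFamily, default_rgap_grid

__all__ = [
    "Boundaries",
    "PhaseDiagram",
    "find_boundaries",
    "scan_diagram",
    "scan_variant_homogeneous_js",
    "scan_sensitivity",
]

JS_MAX_DEFAULT = 0.033
BARRIER_DISPLAY_CAP = 40.0


@dataclass(frozen=True)
class Boundaries:
    """Boundary Js values at one Phi (any may be None if outside range)."""

    flat_spinodal: float | None
    curled_spinodal: float | None
    equal_energy: float | None


@dataclass
class PhaseDiagram:
    Phi_grid: np.ndarray
    Js_grid: np.ndarray
    state: list[list[StateClass]]
    dF_flat_to_curl: np.ndarray
    dF_curl_to_flat: np.ndarray
    boundaries: dict[float, Boundaries]
    js_mid_mode: str
    geometry: GeometryParams
    Rd: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (Phi, Js) cell."""
        rows = []
        for i, phi in enumerate(self.Phi_grid):
            for j, js in enumerate(self.Js_grid):
                dfc = self.dF_flat_to_curl[i, j]
                dcf = self.dF_curl_to_flat[i, j]
                rows.append(
                    {
                        "Phi": phi,
                        "Js": js,
                        "state": self.state[i][j].kind.value,
                        "dF_fc_kBT": dfc,
                        "dF_cf_kBT": dcf,
                        "barrier_above_display_cap": bool(
                            np.nanmax([dfc, dcf]) > BARRIER_DISPLAY_CAP
                        )
                        if not (math.isnan(dfc) and math.isnan(dcf))
                        else False,
                    }
                )
        return pd.DataFrame(rows)

    def boundaries_dict(self) -> dict:
        return {
            "Phi": list(map(float, self.boundaries.keys())),
            "flat_spinodal_Js": [b.flat_spinodal for b in self.boundaries.values()],
            "curled_spinodal_Js": [b.curled_spinodal for b in self.boundaries.values()],
            "equal_energy_Js": [b.equal_energy for b in self.boundaries.values()],
        }


@dataclass
class _Scanner:
    """Profile evaluator for one Phi with a shared shape-family cache."""

    nano: NanodomainField
    el_base: ElasticParams
    family: ShapeFamily
    js_mid_mode: str = "rim_only"
    _cache: dict[float, EnergyProfile] = field(default_factory=dict)

    def elastic_at(self, js: float) -> ElasticParams:
        js_mid = js if self.js_mid_mode == "homogeneous" else self.el_base.Js_mid
        return ElasticParams(
            kappa_ld=self.el_base.kappa_ld,
            kappa_lo=self.el_base.kappa_lo,
            alpha_kbar=self.el_base.alpha_kbar,
            Js_rim=js,
            Js_mid=js_mid,
        )

    def profile(self, js: float) -> EnergyProfile:
        p = self._cache.get(js)
        if p is None:
            p = energy_profile(self.nano, self.elastic_at(js), family=self.family)
            self._cache[js] = p
        return p


def _bisect(pred, lo: float, hi: float, tol: float) -> float:
    """Bisect for the crossing of a boolean predicate, pred(lo) != pred(hi)."""
    flo = pred(lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pred(mid) == flo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_boundaries(
    Phi: float,
    el_base: ElasticParams | None = None,
    geom: GeometryParams | None = None,
    Rd: float = 5.0,
    js_lo: float = 0.0,
    js_hi: float = JS_MAX_DEFAULT,
    tol: float = 1e-4,
    js_mid_mode: str = "rim_only",
    n_grid: int = 200,
    family: ShapeFamily | None = None,
) -> Boundaries:
    """Locate the three boundary Js values at a fixed Phi by bisection.

    Returns None for a boundary lying outside [js_lo, js_hi].
    """
    geom = geom or GeometryParams()
    el_base = el_base or ElasticParams()
    if family is None:
        family = ShapeFamily(geom, default_rgap_grid(geom, n_grid))
    nano = NanodomainField(Rd=Rd, Phi=Phi)
    sc = _Scanner(nano, el_base, family, js_mid_mode)

    p_lo, p_hi = sc.profile(js_lo), sc.profile(js_hi)

    flat_sp = None
    if p_lo.has_flat_min != p_hi.has_flat_min:
        flat_sp = _bisect(lambda js: sc.profile(js).has_flat_min, js_lo, js_hi, tol)
    curled_sp = None
    if p_lo.has_curled_min != p_hi.has_curled_min:
        curled_sp = _bisect(lambda js: sc.profile(js).has_curled_min, js_lo, js_hi, tol)

    equal = None

    def curl_lower(js: float) -> bool:
        p = sc.profile(js)
        if not p.has_curled_min:
            return False
        return p.F_curl < p.F_flat

    lo = flat_sp if flat_sp is not None else js_lo
    hi = curled_sp if curled_sp is not None else js_hi
    if lo < hi and curl_lower(lo) != curl_lower(hi):
        equal = _bisect(curl_lower, lo, hi, tol)
    return Boundaries(flat_sp, curled_sp, equal)


def js_matching_barrier(
    target_dF: float,
    Phi: float = 0.2,
    direction: str = "curl_to_flat",
    el_base: ElasticParams | None = None,
    geom: GeometryParams | None = None,
    Rd: float = 5.0,
    js_mid_mode: str = "rim_only",
    family: ShapeFamily | None = None,
    boundaries: Boundaries | None = None,
    tol: float = 1e-6,
) -> float:
    """Solve for the Js inside the bistable band whose transition barrier
    equals ``target_dF`` (kBT).

    The curl->flat barrier decreases monotonically with Js (vanishing at
    the curled spinodal); the flat->curl barrier increases.  Uses Brent
    root finding on the refined barrier within the bistable band.
    """
    from scipy.optimize import brentq

    geom = geom or GeometryParams()
    el_base = el_base or ElasticParams()
    if family is None:
        family = ShapeFamily(geom, default_rgap_grid(geom, 200))
    if boundaries is None:
        boundaries = find_boundaries(
            Phi, el_base, geom, Rd, js_mid_mode=js_mid_mode, family=family
        )
    if boundaries.flat_spinodal is None or boundaries.curled_spinodal is None:
        raise ValueError("no bistable band in the scanned Js range")
    nano = NanodomainField(Rd=Rd, Phi=Phi)
    sc = _Scanner(nano, el_base, family, js_mid_mode)

    def barrier(js: float) -> float:
        p = sc.profile(js)
        dF = p.dF_curl_to_flat if direction == "curl_to_flat" else p.dF_flat_to_curl
        if dF is None:
            raise ValueError(f"barrier undefined at Js={js} (outside band)")
        return dF - target_dF

    margin = 2e-4
    lo = boundaries.flat_spinodal + margin
    hi = boundaries.curled_spinodal - margin
    return float(brentq(barrier, lo, hi, xtol=tol))


def scan_diagram(
    Phi_range=None,
    Js_range=None,
    geom: GeometryParams | None = None,
    el_base: ElasticParams | None = None,
    Rd: float = 5.0,
    js_mid_mode: str = "rim_only",
    n_grid: int = 200,
    boundary_tol: float = 1e-4,
) -> PhaseDiagram:
    """Classify every (Phi, Js) cell and refine the three boundary curves.

    Default grid: 21 Phi values on [0, 0.4] x 34 Js values on [0, 0.033].
    Barriers are recorded where the cell is bistable; values above
    40 kBT are flagged in the exported table (kinetically frozen).
    """
    geom = geom or GeometryParams()
    el_base = el_base or ElasticParams()
    Phi_grid = np.asarray(
        Phi_range if Phi_range is not None else np.linspace(0.0, 0.4, 21), dtype=float
    )
    Js_grid = np.asarray(
        Js_range if Js_range is not None else np.linspace(0.0, JS_MAX_DEFAULT, 34),
        dtype=float,
    )
    family = ShapeFamily(geom, default_rgap_grid(geom, n_grid))

    states: list[list[StateClass]] = []
    dF_fc = np.full((len(Phi_grid), len(Js_grid)), np.nan)
    dF_cf = np.full((len(Phi_grid), len(Js_grid)), np.nan)
    boundaries: dict[float, Boundaries] = {}
    for i, phi in enumerate(Phi_grid):
        nano = NanodomainField(Rd=Rd, Phi=phi)
        sc = _Scanner(nano, el_base, family, js_mid_mode)
        row = []
        for j, js in enumerate(Js_grid):
            p = sc.profile(js)
            row.append(classify_state(p))
            if p.dF_flat_to_curl is not None:
                dF_fc[i, j] = p.dF_flat_to_curl
            if p.dF_curl_to_flat is not None:
                dF_cf[i, j] = p.dF_curl_to_flat
        states.append(row)
        boundaries[float(phi)] = find_boundaries(
            phi, el_base, geom, Rd,
            js_lo=float(Js_grid[0]), js_hi=float(Js_grid[-1]),
            tol=boundary_tol, js_mid_mode=js_mid_mode, family=family,
        )
    return PhaseDiagram(
        Phi_grid, Js_grid, states, dF_fc, dF_cf, boundaries, js_mid_mode, geom, Rd
    )


def scan_variant_homogeneous_js(**kwargs) -> PhaseDiagram:
    """Diagram variant with curvature generators spread over the whole
    cisterna (Js_mid = Js_rim = Js); boundaries shift to lower Js and the
    bistable band narrows relative to the rim-only scenario."""
    kwargs.pop("js_mid_mode", None)
    return scan_diagram(js_mid_mode="homogeneous", **kwargs)


def scan_sensitivity(
    Rd: float | None = None, rflat: float | None = None, **kwargs
) -> PhaseDiagram:
    """Diagram for an alternative nanodomain radius (Rd = 2 or 20 nm) or
    sheet radius (rflat = 1000 nm); larger cisternae shift both boundaries
    to higher Js, while Rd mainly rescales the partition-entropy prefactor."""
    if rflat is not None:
        base = kwargs.pop("geom", None) or GeometryParams()
        kwargs["geom"] = GeometryParams(rflat=rflat, rrim=base.rrim, h=base.h)
    if Rd is not None:
        kwargs["Rd"] = Rd
    return scan_diagram(**kwargs)
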