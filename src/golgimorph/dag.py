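"""Diacylglycerol (DAG) redistribution null-model.

Tests whether lateral/inter-leaflet redistribution of the conical lipid
DAG (molecular spontaneous curvature ~ -1 nm^-1, fast flip-flop) could
by itself drive cisterna curling.  Six DAG area fractions — one per
leaflet (cytosolic/luminal) of the three bilayer regions (top sheet cap,
bottom sheet cap, rim) — shift each region's effective spontaneous
curvature by 1/2 (phi_cyt - phi_lum) * zeta_DAG and pay an ideal-mixing
entropy with prefactor kBT / a_DAG per leaflet.  The total DAG content
of each leaflet is conserved (fast flip-flop keeps the two leaflets'
totals equal), which eliminates the rim fractions.

This sub-model runs on a uniform liquid-disordered membrane (kappa_ld,
no nanodomain terms, no Gaussian term — with a uniform modulus the
Gaussian energy is a topological constant).  Sheet-cap curvature signs
follow the convention J_top = -2/R, J_bottom = +2/R, under which the
cytosolic leaflet of the top cap enriches in DAG upon curling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .energetics import ElasticParams
from .geometry import GeometryParams, ShapeFamily, ShapeState, default_rgap_grid

__all__ = [
    "DagParams",
    "DagState",
    "dag_free_energy",
    "optimize_dag_fractions",
    "optimize_dag",
    "dag_shape_diagram",
]

REGIONS = ("top", "bottom", "rim")
LEAFLETS = ("cyt", "lum")

CONSTRAINT_TOL = 1e-9


@dataclass(frozen=True)
class DagParams:
    """Total DAG area fraction, molecular spontaneous curvature (nm^-1)
    and area per molecule (nm^2)."""

    phi_DAG: float
    zeta_DAG: float = -1.0
    a_DAG: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_DAG <= 0.05:
            raise ValueError("phi_DAG outside the modelled range [0, 0.05]")
        if self.zeta_DAG > 0:
            raise ValueError("zeta_DAG must be non-positive (conical lipid)")


@dataclass
class DagState:
    """Per-leaflet, per-region DAG fractions on a given shape."""

    phi: dict[str, dict[str, float]]  # phi[region][leaflet]
    areas: dict[str, float]
    Js: dict[str, float]
    J: dict[str, float]

    def leaflet_totals(self) -> dict[str, float]:
        return {
            leaf: sum(self.phi[reg][leaf] * self.areas[reg] for reg in REGIONS)
            for leaf in LEAFLETS
        }

    def constraint_residual(self, p: DagParams) -> float:
        """Max relative violation of the leaflet-total conservation."""
        A = sum(self.areas.values())
        target = p.phi_DAG * A
        tot = self.leaflet_totals()
        return max(abs(tot[leaf] - target) for leaf in LEAFLETS) / max(target, 1e-300)

    def to_dict(self) -> dict:
        return {
            "fractions": self.phi,
            "areas_nm2": self.areas,
            "Js_nm_inv": self.Js,
            "J_nm_inv": self.J,
        }


def _region_geometry(shape: ShapeState, el: ElasticParams):
    """Areas, mean curvatures and spontaneous curvatures of the 3 regions."""
    Jmid = shape.mid_total_curvature
    areas = {"top": 0.5 * shape.A_mid, "bottom": 0.5 * shape.A_mid, "rim": shape.A_rim}
    J = {"top": -Jmid, "bottom": +Jmid, "rim": math.nan}  # rim handled via moments
    Js = {"top": el.Js_mid, "bottom": el.Js_mid, "rim": el.Js_rim}
    return areas, J, Js


def _mix(x: float) -> float:
    s = 0.0
    if x > 0.0:
        s += x * math.log(x)
    if x < 1.0:
        s += (1.0 - x) * math.log(1.0 - x)
    return s


def dag_free_energy(
    shape: ShapeState, d: DagState, p: DagParams, el: ElasticParams
) -> float:
    """Bending + DAG mixing free energy (kBT) of a shape with given fractions.

    Bending per region uses the effective spontaneous-curvature shift
    1/2 (phi_cyt - phi_lum) zeta_DAG; the rim integral is exact via the
    precomputed curvature moments.  Raises if the leaflet conservation
    constraint is violated beyond 1e-9 relative.
    """
    if d.constraint_residual(p) > CONSTRAINT_TOL:
        raise ValueError("DAG leaflet-conservation constraint violated")
    kappa = el.kappa_ld
    F = 0.0
    for reg in ("top", "bottom"):
        shift = 0.5 * (d.phi[reg]["cyt"] - d.phi[reg]["lum"]) * p.zeta_DAG
        F += 0.5 * kappa * d.areas[reg] * (d.J[reg] - shift - d.Js[reg]) ** 2
    c = 0.5 * (d.phi["rim"]["cyt"] - d.phi["rim"]["lum"]) * p.zeta_DAG + d.Js["rim"]
    F += 0.5 * kappa * (shape.I2 - 2.0 * c * shape.I1 + c * c * shape.A_rim)
    for reg in REGIONS:
        for leaf in LEAFLETS:
            F += d.areas[reg] * _mix(d.phi[reg][leaf]) / p.a_DAG
    return F


def _build_state(shape: ShapeState, el: ElasticParams, fractions) -> DagState:
    areas, J, Js = _region_geometry(shape, el)
    tc, bc, tl, bl, rc, rl = fractions
    phi = {
        "top": {"cyt": tc, "lum": tl},
        "bottom": {"cyt": bc, "lum": bl},
        "rim": {"cyt": rc, "lum": rl},
    }
    return DagState(phi, areas, Js, J)


def optimize_dag_fractions(
    shape: ShapeState, p: DagParams, el: ElasticParams
) -> tuple[DagState, float]:
    """Minimize the DAG free energy over the six fractions at fixed shape.

    The two rim fractions are eliminated by leaflet conservation; the
    remaining four are searched by bounded quasi-Newton seeded at the
    homogeneous distribution (which is the exact optimum for zeta = 0).
    """
    areas, J, Js = _region_geometry(shape, el)
    At, Ab, Ar = areas["top"], areas["bottom"], areas["rim"]
    A = At + Ab + Ar
    target = p.phi_DAG * A
    kappa = el.kappa_ld
    zeta = p.zeta_DAG

    def rim_of(tx: float, bx: float) -> float:
        return (target - tx * At - bx * Ab) / Ar

    inv_a = 1.0 / p.a_DAG
    tiny = 1e-12  # keeps the entropy gradient finite at the box edges

    def objective(x):
        """Energy and analytic gradient; the entropy offset is O(1e5) kBT,
        so a finite-difference gradient would drown the kBT-scale
        curvature signal in cancellation noise."""
        tc, bc, tl, bl = x
        rc, rl = rim_of(tc, bc), rim_of(tl, bl)
        F = 0.0
        g = np.zeros(4)
        # quadratic penalty keeps the eliminated rim fractions in [0, 1]
        for r, cols in ((rc, (0, 1)), (rl, (2, 3))):
            if r < tiny or r > 1.0 - tiny:
                viol = r - tiny if r < tiny else r - (1.0 - tiny)
                F += 1e10 * viol * viol
                g[cols[0]] += 2e10 * viol * (-At / Ar)
                g[cols[1]] += 2e10 * viol * (-Ab / Ar)
        rc = min(max(rc, tiny), 1.0 - tiny)
        rl = min(max(rl, tiny), 1.0 - tiny)

        dev_t = J["top"] - 0.5 * (tc - tl) * zeta - Js["top"]
        dev_b = J["bottom"] - 0.5 * (bc - bl) * zeta - Js["bottom"]
        F += 0.5 * kappa * (At * dev_t**2 + Ab * dev_b**2)
        g[0] += -0.5 * zeta * kappa * At * dev_t
        g[2] += +0.5 * zeta * kappa * At * dev_t
        g[1] += -0.5 * zeta * kappa * Ab * dev_b
        g[3] += +0.5 * zeta * kappa * Ab * dev_b

        c = 0.5 * (rc - rl) * zeta + Js["rim"]
        F += 0.5 * kappa * (shape.I2 - 2.0 * c * shape.I1 + c * c * Ar)
        dF_dc = kappa * (c * Ar - shape.I1)
        g[0] += dF_dc * (-0.5 * zeta * At / Ar)
        g[1] += dF_dc * (-0.5 * zeta * Ab / Ar)
        g[2] += dF_dc * (+0.5 * zeta * At / Ar)
        g[3] += dF_dc * (+0.5 * zeta * Ab / Ar)

        F += (At * (_mix(tc) + _mix(tl)) + Ab * (_mix(bc) + _mix(bl))
              + Ar * (_mix(rc) + _mix(rl))) * inv_a

        def dlog(xv: float) -> float:
            xv = min(max(xv, tiny), 1.0 - tiny)
            return math.log(xv / (1.0 - xv))

        g[0] += inv_a * (At * dlog(tc) + Ar * dlog(rc) * (-At / Ar))
        g[1] += inv_a * (Ab * dlog(bc) + Ar * dlog(rc) * (-Ab / Ar))
        g[2] += inv_a * (At * dlog(tl) + Ar * dlog(rl) * (-At / Ar))
        g[3] += inv_a * (Ab * dlog(bl) + Ar * dlog(rl) * (-Ab / Ar))
        return F, g

    x0 = np.full(4, p.phi_DAG)
    if p.phi_DAG == 0.0 or zeta == 0.0:
        # without a curvature incentive the mixing entropy is minimized by
        # the exactly homogeneous distribution (analytic optimum)
        st = _build_state(shape, el, (p.phi_DAG,) * 6)
        return st, dag_free_energy(shape, st, p, el)
    res = minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        bounds=[(tiny, 1.0 - tiny)] * 4,
        options={"ftol": 1e-16, "gtol": 1e-8, "maxiter": 500},
    )
    if not res.success and res.status != 2:  # status 2: precision loss at optimum
        raise RuntimeError(f"DAG fraction optimization failed: {res.message}")
    tc, bc, tl, bl = res.x
    st = _build_state(shape, el, (tc, bc, tl, bl, rim_of(tc, bc), rim_of(tl, bl)))
    return st, float(res.fun)


def _dag_profile(family: ShapeFamily, p: DagParams, el: ElasticParams) -> np.ndarray:
    return np.array(
        [optimize_dag_fractions(s, p, el)[1] for s in family.states]
    )


def optimize_dag(
    p: DagParams,
    el: ElasticParams,
    geom: GeometryParams | None = None,
    n_grid: int = 120,
    family: ShapeFamily | None = None,
) -> tuple[DagState, ShapeState]:
    """Joint minimization over the shape coordinate and the six fractions.

    Scans the rgap family (flat endpoint included), optimizing fractions
    at each shape, and returns the global optimum.
    """
    if family is None:
        geom = geom or GeometryParams()
        family = ShapeFamily(geom, default_rgap_grid(geom, n_grid))
    F = _dag_profile(family, p, el)
    i = int(np.argmin(F))
    shape = family.states[i]
    state, _ = optimize_dag_fractions(shape, p, el)
    return state, shape


def dag_shape_diagram(
    phi_DAG_range=None,
    Js_range=None,
    geom: GeometryParams | None = None,
    el_base: ElasticParams | None = None,
    n_grid: int = 120,
    boundary_tol: float = 1e-4,
) -> pd.DataFrame:
    """Globally stable configuration (flat vs curled) per (phi_DAG, Js) cell.

    Returns a long-format frame with columns phi_DAG, Js, state, and the
    per-phi_DAG equal-energy boundary Js (bisected to ``boundary_tol``)
    in the frame attribute ``attrs['boundary']``.  The boundary depends
    only very weakly on phi_DAG: DAG redistribution is not a shape driver.
    """
    geom = geom or GeometryParams()
    el_base = el_base or ElasticParams()
    phis = np.asarray(
        phi_DAG_range if phi_DAG_range is not None else np.linspace(0.0, 0.05, 6)
    )
    jss = np.asarray(
        Js_range if Js_range is not None else np.linspace(0.0, 0.033, 12)
    )
    family = ShapeFamily(geom, default_rgap_grid(geom, n_grid))

    _memo: dict[tuple[float, float], bool] = {}

    def curled_is_global(phi_dag: float, js: float) -> bool:
        key = (float(phi_dag), float(js))
        if key in _memo:
            return _memo[key]
        el = ElasticParams(
            kappa_ld=el_base.kappa_ld, kappa_lo=el_base.kappa_lo,
            alpha_kbar=el_base.alpha_kbar, Js_rim=js, Js_mid=el_base.Js_mid,
        )
        F = _dag_profile(family, DagParams(phi_DAG=float(phi_dag)), el)
        result = bool(np.min(F[:-1]) < F[-1])
        _memo[key] = result
        return result

    rows = []
    boundary = {}
    for phi_dag in phis:
        for js in jss:
            rows.append(
                {
                    "phi_DAG": float(phi_dag),
                    "Js": float(js),
                    "state": "curled" if curled_is_global(phi_dag, js) else "flat",
                }
            )
        lo, hi = float(jss[0]), float(jss[-1])
        if curled_is_global(phi_dag, lo) != curled_is_global(phi_dag, hi):
            a, b = lo, hi
            ref = curled_is_global(phi_dag, a)
            while b - a > boundary_tol:
                mid = 0.5 * (a + b)
                if curled_is_global(phi_dag, mid) == ref:
                    a = mid
                else:
                    b = mid
            boundary[float(phi_dag)] = 0.5 * (a + b)
        else:
            boundary[float(phi_dag)] = None
    frame = pd.DataFrame(rows)
    frame.attrs["boundary"] = boundary
    return frame
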