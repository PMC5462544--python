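"""Arrhenius barrier-crossing kinetics and quasi-static hysteresis sweeps.

Shape transitions between the flat and curled minima are thermally
activated: the mean transition time over a barrier dF (kBT) is
``tau = t0 * exp(dF)`` with an attempt time ``t0 ~ 1 ms`` set by the
mechanical relaxation of the cisterna (eta R^3 / kappa).  Sweeping the
rim spontaneous curvature Js through the bistable band quasi-statically
produces hysteresis: the system follows its current branch until that
branch either loses its minimum (spinodal) or its exit barrier drops
below a configurable feasibility threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .energetics import ElasticParams, NanodomainField
from .equilibria import energy_profile
from .geometry import GeometryParams, ShapeFamily, default_rgap_grid

__all__ = [
    "KineticsParams",
    "HysteresisTrace",
    "arrhenius_time",
    "barrier_from_time",
    "mech_relaxation_time",
    "hysteresis_trajectory",
]

KBT_J = 1.380649e-23 * 300.0  # thermal energy at 300 K, joules

#: barriers above this return an infinite Arrhenius time (exp overflow guard)
_OVERFLOW_BARRIER = 700.0


@dataclass(frozen=True)
class KineticsParams:
    """Attempt time t0 (ms) and the barrier (kBT) below which a thermally
    activated jump is considered kinetically feasible on observation
    time scales (ln(hours / ms) ~ 17-25)."""

    t0_ms: float = 1.0
    feasibility_barrier: float = 25.0
    tau_flux_s: float = 100.0

    def __post_init__(self) -> None:
        if self.t0_ms <= 0 or self.feasibility_barrier <= 0:
            raise ValueError("t0 and feasibility_barrier must be positive")


def arrhenius_time(dF: float, k: KineticsParams = KineticsParams()) -> float:
    """Mean barrier-crossing time tau = t0 exp(dF), in ms (dF in kBT)."""
    if dF < 0:
        raise ValueError("barrier must be non-negative")
    if dF > _OVERFLOW_BARRIER:
        return math.inf
    return k.t0_ms * math.exp(dF)


def barrier_from_time(tau_ms: float, k: KineticsParams = KineticsParams()) -> float:
    """Barrier height dF = ln(tau / t0) (kBT) implied by a transition time."""
    if tau_ms < k.t0_ms:
        raise ValueError("transition time below the attempt time")
    return math.log(tau_ms / k.t0_ms)


def mech_relaxation_time(eta_pa_s: float, R_nm: float, kappa_kbt: float) -> float:
    """Mechanical shape-relaxation time eta R^3 / kappa, in ms.

    Order ~1 ms for physiological inputs (eta ~ 1 Pa s, R ~ 500 nm,
    kappa ~ 20 kBT), far below the ~100 s compositional flux time — the
    justification for treating the shape as mechanically equilibrated.
    """
    if eta_pa_s <= 0 or R_nm <= 0 or kappa_kbt <= 0:
        raise ValueError("inputs must be positive")
    return eta_pa_s * (R_nm * 1e-9) ** 3 / (kappa_kbt * KBT_J) * 1e3


@dataclass
class HysteresisTrace:
    """Branch occupation along a Js sweep, with recorded jump events."""

    Js_path: list[float]
    branch_path: list[str]
    F_branch: list[float]
    exit_barrier: list[float]
    transition_events: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        events = {e["Js"]: e for e in self.transition_events}
        return pd.DataFrame(
            {
                "Js": self.Js_path,
                "branch": self.branch_path,
                "F_branch_kBT": self.F_branch,
                "barrier_kBT": self.exit_barrier,
                "event": [
                    events[js]["direction"] if js in events else "" for js in self.Js_path
                ],
            }
        )

    @property
    def loop_width(self) -> float:
        """|Js(flat->curled jump) - Js(curled->flat jump)|; 0 if either is absent."""
        fwd = [e["Js"] for e in self.transition_events if e["direction"] == "flat_to_curled"]
        rev = [e["Js"] for e in self.transition_events if e["direction"] == "curled_to_flat"]
        if not fwd or not rev:
            return 0.0
        return abs(fwd[0] - rev[0])


def hysteresis_trajectory(
    Js_path,
    Phi: float = 0.2,
    k: KineticsParams = KineticsParams(),
    geom: GeometryParams | None = None,
    el_base: ElasticParams | None = None,
    Rd: float = 5.0,
    n_grid: int = 200,
    family: ShapeFamily | None = None,
) -> HysteresisTrace:
    """Quasi-static branch following along a Js sweep at fixed Phi.

    At each Js the partition-optimized profile is classified.  The system
    stays on its current branch while that branch exists and its exit
    barrier exceeds ``k.feasibility_barrier``; it jumps to the other
    branch when the current minimum disappears (spinodal) or when the
    barrier to a *lower* minimum becomes feasible.  Trajectories are
    deterministic; the stochastic trigger of a real cisterna is
    represented by the interval between the feasibility and spinodal
    jump points, not by sampling.
    """
    geom = geom or GeometryParams()
    el_base = el_base or ElasticParams()
    if family is None:
        family = ShapeFamily(geom, default_rgap_grid(geom, n_grid))
    nano = NanodomainField(Rd=Rd, Phi=Phi)
    prof_cache: dict[float, object] = {}

    def profile_at(js: float):
        p = prof_cache.get(js)
        if p is None:
            el = ElasticParams(
                kappa_ld=el_base.kappa_ld, kappa_lo=el_base.kappa_lo,
                alpha_kbar=el_base.alpha_kbar, Js_rim=js, Js_mid=el_base.Js_mid,
            )
            p = energy_profile(nano, el, family=family)
            prof_cache[js] = p
        return p

    Js_path = [float(j) for j in Js_path]
    p0 = profile_at(Js_path[0])
    branch = "flat" if p0.has_flat_min and (
        not p0.has_curled_min or p0.F_flat <= p0.F_curl
    ) else "curled"

    branches, energies, barriers, events = [], [], [], []
    for js in Js_path:
        p = profile_at(js)
        exists = p.has_flat_min if branch == "flat" else p.has_curled_min
        if not exists:
            new = "curled" if branch == "flat" else "flat"
            events.append({"Js": js, "direction": f"{branch}_to_{new}",
                           "reason": "spinodal"})
            branch = new
        else:
            barrier = p.dF_flat_to_curl if branch == "flat" else p.dF_curl_to_flat
            other_F = p.F_curl if branch == "flat" else p.F_flat
            own_F = p.F_flat if branch == "flat" else p.F_curl
            if (
                barrier is not None
                and other_F is not None
                and other_F < own_F
                and barrier < k.feasibility_barrier
            ):
                new = "curled" if branch == "flat" else "flat"
                events.append({"Js": js, "direction": f"{branch}_to_{new}",
                               "reason": "thermal"})
                branch = new
        own_F = p.F_flat if branch == "flat" else p.F_curl
        barrier = p.dF_flat_to_curl if branch == "flat" else p.dF_curl_to_flat
        branches.append(branch)
        energies.append(own_F if own_F is not None else math.nan)
        barriers.append(barrier if barrier is not None else math.inf)

    return HysteresisTrace(Js_path, branches, energies, barriers, events)
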