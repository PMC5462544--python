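"""High-level modelling interface.

``CisternaModel`` bundles the geometry, elastic and nanodomain
parameters of one cisterna; ``fit()`` carries out the two-variable free
energy minimization (rim partitioning at every degree of curling,
followed by extremum analysis of the optimized profile) and returns a
``CisternaResults`` object holding the stable configurations, the
barriers between them and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .energetics import ElasticParams, NanodomainField
from .equilibria import (
    EnergyProfile,
    StateClass,
    classify_state,
    energy_profile,
    enrichment_ratio,
)
from .geometry import GeometryParams, ShapeFamily, default_rgap_grid

__all__ = ["CisternaModel", "CisternaResults"]


class CisternaModel:
    """Free-energy model of a single Golgi cisterna.

    Parameters
    ----------
    phi : float
        Global area fraction covered by rigid nanodomains (0-0.4).
    js : float
        Spontaneous curvature of the rim membrane, nm^-1 (0-0.033).
    js_mid_mode : {"rim_only", "homogeneous"}
        Whether curvature generators sit only at the rim (Js_mid = 0) or
        cover the whole cisterna (Js_mid = Js).
    geometry, elastic, Rd
        Geometry lengths, elastic moduli and nanodomain radius; defaults
        are the reference parameter set (rflat 500 nm, rrim 30 nm,
        h 15 nm, Rd 5 nm, kappa_ld 20 kBT, kappa_lo 80 kBT,
        alpha_kbar -0.83).
    """

    def __init__(
        self,
        phi: float = 0.2,
        js: float = 0.02,
        js_mid_mode: str = "rim_only",
        geometry: GeometryParams | None = None,
        elastic: ElasticParams | None = None,
        Rd: float = 5.0,
        n_grid: int = 200,
    ):
        if js_mid_mode not in ("rim_only", "homogeneous"):
            raise ValueError("js_mid_mode must be 'rim_only' or 'homogeneous'")
        base = elastic or ElasticParams()
        js_mid = js if js_mid_mode == "homogeneous" else 0.0
        self.geometry = geometry or GeometryParams()
        self.elastic = ElasticParams(
            kappa_ld=base.kappa_ld, kappa_lo=base.kappa_lo,
            alpha_kbar=base.alpha_kbar, Js_rim=js, Js_mid=js_mid,
        )
        self.nanodomains = NanodomainField(Rd=Rd, Phi=phi)
        self.js_mid_mode = js_mid_mode
        self.n_grid = n_grid
        self._family: ShapeFamily | None = None

    @classmethod
    def from_config(cls, cfg) -> "CisternaModel":
        """Build a model from a ``RunConfig`` (see :mod:`golgimorph.config`)."""
        return cls(
            phi=cfg.Phi, js=cfg.Js, js_mid_mode=cfg.js_mid_mode,
            geometry=GeometryParams(rflat=cfg.rflat, rrim=cfg.rrim, h=cfg.h),
            elastic=ElasticParams(
                kappa_ld=cfg.kappa_ld, kappa_lo=cfg.kappa_lo,
                alpha_kbar=cfg.alpha_kbar,
            ),
            Rd=cfg.Rd, n_grid=cfg.n_grid,
        )

    @property
    def family(self) -> ShapeFamily:
        if self._family is None:
            self._family = ShapeFamily(
                self.geometry, default_rgap_grid(self.geometry, self.n_grid)
            )
        return self._family

    def fit(self) -> "CisternaResults":
        """Minimize the free energy and analyse the optimized landscape."""
        profile = energy_profile(self.nanodomains, self.elastic, family=self.family)
        return CisternaResults(self, profile)


@dataclass
class CisternaResults:
    """Optimized energy landscape of a fitted :class:`CisternaModel`."""

    model: CisternaModel
    profile: EnergyProfile

    @property
    def state(self) -> StateClass:
        return classify_state(self.profile)

    @property
    def enrichment(self) -> dict[str, float]:
        return enrichment_ratio(self.profile, self.model.nanodomains)

    def profile_frame(self) -> pd.DataFrame:
        return self.profile.to_frame()

    def summary(self) -> str:
        p = self.profile
        m = self.model
        lines = [
            "Cisterna free-energy minimization",
            "=" * 48,
            f"geometry          rflat={m.geometry.rflat:g} nm, "
            f"rrim={m.geometry.rrim:g} nm, h={m.geometry.h:g} nm",
            f"nanodomains       Rd={m.nanodomains.Rd:g} nm, Phi={m.nanodomains.Phi:g}",
            f"elastic           kld={m.elastic.kappa_ld:g} kBT, "
            f"klo={m.elastic.kappa_lo:g} kBT, a_kbar={m.elastic.alpha_kbar:g}",
            f"spont. curvature  Js_rim={m.elastic.Js_rim:g} nm^-1, "
            f"Js_mid={m.elastic.Js_mid:g} nm^-1 ({m.js_mid_mode})",
            "-" * 48,
            f"state             {self.state}",
            f"flat minimum      {'yes' if p.has_flat_min else 'no'} "
            f"(F = 0 by reference)",
        ]
        if p.has_curled_min:
            lines.append(
                f"curled minimum    rgap = {p.rgap_curl:.2f} nm, "
                f"F = {p.F_curl:+.2f} kBT"
            )
        else:
            lines.append("curled minimum    none")
        if p.dF_flat_to_curl is not None:
            lines.append(f"barrier flat->curl  {p.dF_flat_to_curl:.2f} kBT")
        if p.dF_curl_to_flat is not None:
            lines.append(f"barrier curl->flat  {p.dF_curl_to_flat:.2f} kBT")
        for branch, ratio in self.enrichment.items():
            lines.append(f"enrichment mid/rim ({branch})  {ratio:.3f}")
        return "\n".join(lines)
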