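"""DAG redistribution null-model: constraints, optimum, shape diagram."""

import math

import numpy as np
import pytest

from golgimorph.dag import (
    DagParams,
    dag_free_energy,
    dag_shape_diagram,
    optimize_dag,
    optimize_dag_fractions,
    _build_state,
)
from golgimorph.energetics import (
    ElasticParams,
    NanodomainField,
    mid_bending_energy,
    rim_bending_energy,
)
from golgimorph.geometry import GeometryParams, ShapeFamily, default_rgap_grid, solve_shape


@pytest.fixture(scope="module")
def geom_m():
    return GeometryParams()


@pytest.fixture(scope="module")
def curled(geom_m):
    return solve_shape(70.0, geom_m)


@pytest.fixture(scope="module")
def el():
    return ElasticParams(Js_rim=0.02, Js_mid=0.0)


class TestFreeEnergy:
    def test_no_dag_reduces_to_bare_bending(self, curled, el):
        # phi_DAG = 0 must equal the nanodomain-free bending energy of the
        # same shape without the Gaussian term (uniform kappa_ld membrane)
        p = DagParams(phi_DAG=0.0)
        st, F = optimize_dag_fractions(curled, p, el)
        el0 = ElasticParams(
            kappa_ld=el.kappa_ld, kappa_lo=el.kappa_lo, alpha_kbar=0.0,
            Js_rim=el.Js_rim, Js_mid=el.Js_mid,
        )
        nano0 = NanodomainField(Phi=0.0)
        expected = mid_bending_energy(curled, 0.0, nano0, el0) + rim_bending_energy(
            curled, 0.0, el0
        )
        assert F == pytest.approx(expected, rel=1e-12)

    def test_homogeneous_has_no_curvature_shift(self, curled, el):
        p = DagParams(phi_DAG=0.02)
        homog = _build_state(curled, el, (0.02,) * 6)
        none = _build_state(curled, el, (0.0,) * 6)
        dF = dag_free_energy(curled, homog, p, el) - dag_free_energy(
            curled, none, DagParams(phi_DAG=0.0), el
        )
        # difference is pure mixing entropy: (A/a_DAG) * 2 * s(phi)
        A = sum(homog.areas.values())
        s = 0.02 * math.log(0.02) + 0.98 * math.log(0.98)
        assert dF == pytest.approx(2 * A * s / p.a_DAG, rel=1e-12)

    def test_constraint_violation_raises(self, curled, el):
        p = DagParams(phi_DAG=0.02)
        bad = _build_state(curled, el, (0.05, 0.02, 0.02, 0.02, 0.02, 0.02))
        with pytest.raises(ValueError, match="constraint"):
            dag_free_energy(curled, bad, p, el)

    def test_leaflet_antisymmetric_perturbation_closed_form(self, curled, el):
        # +delta on the top-cytosolic leaflet compensated in the rim,
        # -delta on the top-luminal leaflet compensated in the rim; the
        # energy change must match the term-by-term analytic expression
        p = DagParams(phi_DAG=0.02)
        phi0, delta = 0.02, 5e-4  # rim compensation scales delta by A_top/A_rim
        st0 = _build_state(curled, el, (phi0,) * 6)
        At, Ar = st0.areas["top"], st0.areas["rim"]
        eps = delta * At / Ar
        st1 = _build_state(
            curled, el,
            (phi0 + delta, phi0, phi0 - delta, phi0, phi0 - eps, phi0 + eps),
        )
        dF = dag_free_energy(curled, st1, p, el) - dag_free_energy(curled, st0, p, el)

        kappa, zeta = el.kappa_ld, p.zeta_DAG
        J_top = st0.J["top"]
        bend_top = 0.5 * kappa * At * (
            (J_top - delta * zeta - el.Js_mid) ** 2 - (J_top - el.Js_mid) ** 2
        )
        c0, c1 = el.Js_rim, -eps * zeta + el.Js_rim
        bend_rim = 0.5 * kappa * (
            (curled.I2 - 2 * c1 * curled.I1 + c1**2 * Ar)
            - (curled.I2 - 2 * c0 * curled.I1 + c0**2 * Ar)
        )

        def s(x):
            return x * math.log(x) + (1 - x) * math.log(1 - x)

        ent = (
            At * (s(phi0 + delta) + s(phi0 - delta) - 2 * s(phi0))
            + Ar * (s(phi0 - eps) + s(phi0 + eps) - 2 * s(phi0))
        ) / p.a_DAG
        assert dF == pytest.approx(bend_top + bend_rim + ent, rel=1e-10)


class TestOptimum:
    def test_constraint_satisfied_exactly(self, curled, el):
        p = DagParams(phi_DAG=0.016)
        st, _ = optimize_dag_fractions(curled, p, el)
        assert st.constraint_residual(p) < 1e-9

    def test_zeta_zero_exactly_homogeneous(self, curled, el):
        p = DagParams(phi_DAG=0.016, zeta_DAG=0.0)
        st, _ = optimize_dag_fractions(curled, p, el)
        for reg in st.phi.values():
            for v in reg.values():
                assert v == 0.016

    def test_curled_enrichment_sign_and_magnitude(self, curled, el):
        # on a curled shape the cytosolic leaflet of the top cap enriches
        # (and the luminal depletes), mirrored on the bottom cap; the
        # deviation from homogeneity stays small
        p = DagParams(phi_DAG=0.016)
        st, _ = optimize_dag_fractions(curled, p, el)
        assert st.phi["top"]["cyt"] > p.phi_DAG > st.phi["top"]["lum"]
        assert st.phi["bottom"]["lum"] > p.phi_DAG > st.phi["bottom"]["cyt"]
        for reg in st.phi.values():
            for v in reg.values():
                assert abs(v - p.phi_DAG) / p.phi_DAG < 0.10

    def test_smaller_molecules_more_homogeneous(self, curled, el):
        devs = []
        for a_dag in (0.6, 0.15):
            p = DagParams(phi_DAG=0.016, a_DAG=a_dag)
            st, _ = optimize_dag_fractions(curled, p, el)
            devs.append(abs(st.phi["top"]["cyt"] - p.phi_DAG))
        assert devs[1] < devs[0]

    def test_joint_optimum_shape(self, geom_m):
        # at low Js the global optimum is a curled shape; the optimizer
        # must return it with a consistent DagState
        el_low = ElasticParams(Js_rim=0.005, Js_mid=0.0)
        p = DagParams(phi_DAG=0.016)
        st, shape = optimize_dag(p, el_low, geom=geom_m, n_grid=120)
        assert shape.rgap < geom_m.rflat / 2
        assert st.constraint_residual(p) < 1e-9


@pytest.fixture(scope="module")
def diagram(geom_m):
    return dag_shape_diagram(
        phi_DAG_range=[0.0, 0.014, 0.018, 0.05],
        Js_range=np.linspace(0.0, 0.033, 6),
        geom=geom_m, n_grid=100, boundary_tol=2e-4,
    )


class TestDiagram:
    def test_weak_dag_dependence(self, diagram):
        # the global-stability boundary barely moves across the full DAG range
        boundary = diagram.attrs["boundary"]
        vals = [v for v in boundary.values() if v is not None]
        assert len(vals) == 4
        assert max(vals) - min(vals) < 0.0033 / 5  # below the Js grid step

    def test_no_transition_in_observed_dag_window(self, diagram):
        # raising DAG from 1.4 to 1.8 mol% flips no cell where flat is stable
        sub = diagram[diagram.phi_DAG.isin([0.014, 0.018])]
        states = sub.pivot(index="Js", columns="phi_DAG", values="state")
        assert (states[0.014] == states[0.018]).all()

    def test_zero_dag_matches_base_model_boundary(self, diagram, geom_m):
        # without DAG the sub-model is the uniform-kappa_ld membrane; its
        # equal-energy boundary must match the base model with Phi = 0 and
        # no Gaussian contribution
        from golgimorph.diagrams import find_boundaries

        b = find_boundaries(
            0.0, el_base=ElasticParams(alpha_kbar=-1e-15), geom=geom_m, n_grid=120
        )
        assert diagram.attrs["boundary"][0.0] == pytest.approx(
            b.equal_energy, abs=5e-4
        )
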