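"""Free-energy terms: moduli, partitioning entropy, sheet and rim bending."""

import math

import numpy as np
import pytest

from golgimorph.energetics import (
    BuddingParams,
    ElasticParams,
    NanodomainField,
    PartitionConstraintError,
    js_from_budding,
    local_bending_modulus,
    mid_bending_energy,
    mid_fraction,
    partition_entropy_energy,
    rim_bending_energy,
    total_energy,
)
from golgimorph.geometry import rim_curvatures, rim_phi_limits, solve_shape


@pytest.fixture(scope="module")
def flat():
    from golgimorph.geometry import GeometryParams

    g = GeometryParams()
    return solve_shape(g.rflat, g)


@pytest.fixture(scope="module")
def curled():
    from golgimorph.geometry import GeometryParams

    return solve_shape(70.0, GeometryParams())


class TestModulus:
    @pytest.mark.parametrize(
        "phi,expected", [(0.0, 20.0), (1.0, 80.0), (0.5, 32.0)]
    )
    def test_harmonic_interpolation(self, phi, expected):
        assert local_bending_modulus(phi, ElasticParams()) == pytest.approx(expected)

    def test_monotone_and_bounded(self):
        el = ElasticParams()
        ks = [local_bending_modulus(p, el) for p in np.linspace(0, 1, 21)]
        assert all(b > a for a, b in zip(ks, ks[1:]))
        assert min(ks) >= 20.0 and max(ks) <= 80.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            local_bending_modulus(1.2, ElasticParams())


class TestBudding:
    def test_spontaneous_curvature_from_coverage(self):
        assert js_from_budding(BuddingParams(0.09, 0.5)) == pytest.approx(0.0225)
        assert js_from_budding(BuddingParams(0.10, 0.66)) == pytest.approx(0.033)
        assert js_from_budding(BuddingParams(0.0, 0.5)) == 0.0


class TestPartitioning:
    def test_homogeneous_cases(self, flat):
        assert mid_fraction(0.2, 0.2, flat) == pytest.approx(0.2, rel=1e-14)
        assert mid_fraction(0.0, 0.0, flat) == 0.0

    def test_depleted_rim_enriches_sheet(self, flat):
        ratio = flat.A_rim / flat.A_mid
        assert ratio == pytest.approx(0.3177, rel=1e-3)
        assert mid_fraction(0.2, 0.0, flat) == pytest.approx(0.2 * (1 + ratio), rel=1e-12)

    def test_constraint_error(self, flat):
        with pytest.raises(PartitionConstraintError):
            mid_fraction(0.9, 0.0, flat)  # sheet fraction would exceed 1

    def test_entropy_reference_value(self, flat):
        # homogeneous Phi = 0.2: (A / pi Rd^2) (0.2 ln 0.2 + 0.8 ln 0.8)
        nano = NanodomainField(Rd=5.0, Phi=0.2)
        F = partition_entropy_energy(0.2, 0.2, nano, flat)
        A = flat.A_mid + flat.A_rim
        expected = A / (math.pi * 25.0) * (0.2 * math.log(0.2) + 0.8 * math.log(0.8))
        assert F == pytest.approx(expected, rel=1e-14)
        assert F == pytest.approx(-1.319e4, rel=1e-3)

    def test_zero_fraction_zero_entropy(self, flat):
        nano = NanodomainField(Rd=5.0, Phi=0.0)
        assert partition_entropy_energy(0.0, 0.0, nano, flat) == 0.0

    def test_entropy_alone_favors_homogeneity(self, curled):
        nano = NanodomainField(Rd=5.0, Phi=0.2)
        grid = np.linspace(0.0, 0.6, 601)
        vals = [partition_entropy_energy(p, 0.2, nano, curled) for p in grid]
        assert grid[int(np.argmin(vals))] == pytest.approx(0.2, abs=2e-3)

    def test_entropy_prefactor_scales_with_domain_area(self, flat):
        # halving Rd quadruples the entropy (a_dom = pi Rd^2)
        f5 = partition_entropy_energy(0.1, 0.2, NanodomainField(Rd=5, Phi=0.2), flat)
        f25 = partition_entropy_energy(0.1, 0.2, NanodomainField(Rd=2.5, Phi=0.2), flat)
        assert f25 == pytest.approx(4 * f5, rel=1e-14)


class TestMidBending:
    def test_flat_zero(self, flat):
        el = ElasticParams(Js_mid=0.0)
        assert mid_bending_energy(flat, 0.2, NanodomainField(Phi=0.2), el) == 0.0

    def test_flat_spontaneous_penalty(self, flat):
        el = ElasticParams(Js_mid=0.01)
        nano = NanodomainField(Phi=0.2)
        kappa = local_bending_modulus(0.2, el)
        expected = 0.5 * kappa * 0.01**2 * flat.A_mid
        assert mid_bending_energy(flat, 0.2, nano, el) == pytest.approx(expected)

    def test_curled_closed_form(self, curled):
        # homogeneous composition, Js_mid = 0:
        # F = kappa (2 + alpha_kbar) A_mid / R^2
        el = ElasticParams()
        nano = NanodomainField(Phi=0.2)
        kappa = local_bending_modulus(0.2, el)
        expected = kappa * (2.0 + el.alpha_kbar) * curled.A_mid / curled.R**2
        assert mid_bending_energy(curled, 0.2, nano, el) == pytest.approx(
            expected, rel=1e-12
        )


class TestRimBending:
    def _riemann(self, shape, phi_rim, el, n=100_000):
        geom = shape.geometry
        lo, hi = rim_phi_limits(shape.rgap, geom)
        phi = lo + (np.arange(n) + 0.5) * (hi - lo) / n
        J, K = rim_curvatures(phi, shape.rgap, geom.rrim)
        kappa = local_bending_modulus(phi_rim, el)
        f = 0.5 * kappa * (J - el.Js_rim) ** 2 + el.alpha_kbar * kappa * K
        dA = geom.rrim * (shape.rgap + geom.rrim * np.cos(phi)) * (hi - lo) / n
        return 2 * math.pi * float(np.sum(f * dA))

    def test_matches_riemann_oracle(self, rng):
        from golgimorph.geometry import GeometryParams

        g = GeometryParams()
        for _ in range(10):
            rgap = float(rng.uniform(g.rrim * 1.05, g.rflat))
            phi_rim = float(rng.uniform(0.0, 0.6))
            el = ElasticParams(
                Js_rim=float(rng.uniform(0, 0.033)),
                alpha_kbar=float(rng.uniform(-0.83, -0.2)),
            )
            shape = solve_shape(rgap, g)
            assert rim_bending_energy(shape, phi_rim, el) == pytest.approx(
                self._riemann(shape, phi_rim, el), rel=1e-6
            )

    def test_modulus_linearity(self, curled):
        # Js = 0: energy scales exactly by kappa_lo/kappa_ld between pure phases
        el = ElasticParams(Js_rim=0.0)
        e0 = rim_bending_energy(curled, 0.0, el)
        e1 = rim_bending_energy(curled, 1.0, el)
        assert e1 == pytest.approx(4.0 * e0, rel=1e-14)

    def test_near_spontaneous_tube_is_cheap(self):
        # a barely curled rim with matched spontaneous curvature costs much
        # less than a mismatched one
        from golgimorph.geometry import GeometryParams

        g = GeometryParams()
        shape = solve_shape(g.rflat, g)
        matched = ElasticParams(Js_rim=1.0 / g.rrim, alpha_kbar=-1e-12)
        mismatched = ElasticParams(Js_rim=0.0, alpha_kbar=-1e-12)
        assert rim_bending_energy(shape, 0.0, matched) < 0.05 * rim_bending_energy(
            shape, 0.0, mismatched
        )


class TestTotal:
    def test_additivity(self, curled):
        nano = NanodomainField(Phi=0.2)
        el = ElasticParams(Js_rim=0.02)
        br = total_energy(curled, 0.15, nano, el)
        assert br.F_total == br.F_part + br.F_bend_mid + br.F_bend_rim
        assert br.F_part == partition_entropy_energy(0.15, 0.2, nano, curled)
        assert br.F_bend_mid == mid_bending_energy(curled, 0.15, nano, el)
        assert br.F_bend_rim == rim_bending_energy(curled, 0.15, el)

    def test_no_nanodomains_pure_rim_bending(self, flat):
        nano = NanodomainField(Phi=0.0)
        el = ElasticParams(Js_rim=0.0, Js_mid=0.0)
        br = total_energy(flat, 0.0, nano, el)
        assert br.F_part == 0.0
        assert br.F_bend_mid == 0.0
        assert br.F_total == br.F_bend_rim
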