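"""Forward-model tests: buoyancy coefficient, radial profile, Kd conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aucbind import (
    ComplexModelParams,
    RadialProfile,
    RunConditions,
    Species,
    association_from_kd,
    buoyancy_coefficient,
    kd_from_association,
    predict_profile,
)
from aucbind.errors import ValidationError


def make_conditions(rpm=15_000.0, temp=298.15, density=1.002, r0=6.9):
    return RunConditions(
        rotor_speed_rpm=rpm,
        temperature_K=temp,
        solvent_density=density,
        path_length_cm=1.2,
        reference_radius_cm=r0,
        radial_window_cm=(5.9, 7.2),
    )


def scalar_profile_oracle(params, ho1, cpr, cond, r):
    """Independent per-point evaluation: H recomputed from first principles."""
    omega = cond.rotor_speed_rpm * 2 * math.pi / 60
    out = []
    mh = []
    for sp in (ho1, cpr):
        h_si = (
            (1 - sp.partial_specific_volume * cond.solvent_density)
            * omega**2
            / (2 * 8.314462618 * cond.temperature_K)
        )
        mh.append(sp.molar_mass * h_si * 1e-7)  # cm^-2
    for ri in np.atleast_1d(r):
        xi = ri**2 - cond.reference_radius_cm**2
        a = (
            params.a_ho1_ref * math.exp(mh[0] * xi)
            + params.a_cpr_ref * math.exp(mh[1] * xi)
            + params.k_assoc
            * params.a_ho1_ref
            * params.a_cpr_ref
            * math.exp((mh[0] + mh[1]) * xi)
            + params.baseline
        )
        out.append(a)
    return np.array(out)


class TestBuoyancyCoefficient:
    def test_neutral_buoyancy_gives_flat_profile(self):
        sp = Species("x", 70_000, 1.0, {455.0: 20_000.0})
        cond = make_conditions(density=1.0)
        assert buoyancy_coefficient(sp, cond) == 0.0
        p = ComplexModelParams(0.2, 0.3, 0.0, 0.05)
        prof = predict_profile(p, sp, sp, cond, np.linspace(6.0, 7.2, 20))
        assert np.allclose(prof, 0.2 + 0.3 + 0.05)

    def test_resting_rotor(self):
        sp = Species("x", 70_000, 0.73, {})
        assert buoyancy_coefficient(sp, make_conditions(rpm=0.0)) == 0.0

    def test_reference_value(self):
        # frozen from a hand evaluation of (1 - vbar*rho) w^2 / 2RT in SI,
        # converted to cm^-2 per g/mol and scaled by M = 70,000 g/mol
        sp = Species("x", 70_000, 0.73, {})
        mh = sp.molar_mass * buoyancy_coefficient(sp, make_conditions())
        assert mh == pytest.approx(0.9355086, rel=1e-6)

    def test_flotation_allowed(self):
        sp = Species("lipid", 50_000, 1.1, {})
        assert buoyancy_coefficient(sp, make_conditions(density=1.05)) < 0

    def test_invalid_species_rejected(self):
        with pytest.raises(ValidationError):
            Species("bad", -1.0, 0.73, {})
        with pytest.raises(ValidationError):
            Species("bad", 70_000, 2.5, {})
        with pytest.raises(ValidationError):
            Species("bad", 70_000, 0.73, {455.0: -3.0})


class TestPredictProfile:
    def setup_method(self):
        self.ho1 = Species("ho1", 30_000, 0.73, {})
        self.cpr = Species("cpr", 70_000, 0.73, {})
        self.cond = make_conditions()

    def test_reference_radius_collapse(self):
        p = ComplexModelParams(0.2, 0.3, 1.5, 0.01)
        val = predict_profile(p, self.ho1, self.cpr, self.cond, [6.9])[0]
        assert val == pytest.approx(0.2 + 0.3 + 1.5 * 0.2 * 0.3 + 0.01, rel=1e-14)

    def test_zero_association_equals_non_complexed(self):
        r = np.linspace(6.0, 7.2, 57)
        with_k = ComplexModelParams(0.2, 0.3, 0.0, 0.02)
        # non-complexed = monomer terms evaluated independently
        a1 = predict_profile(
            ComplexModelParams(0.2, 0.0, 0.0, 0.0), self.ho1, self.cpr, self.cond, r
        )
        a2 = predict_profile(
            ComplexModelParams(0.0, 0.3, 0.0, 0.0), self.ho1, self.cpr, self.cond, r
        )
        full = predict_profile(with_k, self.ho1, self.cpr, self.cond, r)
        np.testing.assert_allclose(full, a1 + a2 + 0.02, rtol=1e-12)

    def test_hand_evaluated_point(self):
        # both M*H forced to exactly 1.0 cm^-2 by choosing M = 1/H
        cond = make_conditions(r0=6.9)
        h = buoyancy_coefficient(Species("u", 1.0, 0.73, {}), cond)
        sp = Species("unit", 1.0 / h, 0.73, {})
        p = ComplexModelParams(0.2, 0.3, 1.0, 0.0)
        val = predict_profile(p, sp, sp, cond, [7.0])[0]
        # frozen: 0.2 e^1.39 + 0.3 e^1.39 + 0.06 e^2.78, xi = 7^2 - 6.9^2
        assert val == pytest.approx(2.974566283, rel=1e-9)

    def test_monotone_increasing_beyond_reference(self):
        p = ComplexModelParams(0.1, 0.1, 2.0, 0.0)
        r = np.linspace(6.9, 7.2, 100)
        prof = predict_profile(p, self.ho1, self.cpr, self.cond, r)
        assert np.all(np.diff(prof) > 0)

    def test_exponent_cap_names_radius(self):
        heavy = Species("huge", 5e6, 0.73, {})
        with pytest.raises(ValidationError, match="r = "):
            predict_profile(
                ComplexModelParams(0.1, 0.1, 0.0, 0.0),
                heavy, self.cpr, self.cond, [6.0, 7.2],
            )

    def test_matches_scalar_oracle_on_random_draws(self):
        rng = np.random.default_rng(2024)
        r = np.linspace(6.7, 7.2, 31)
        for _ in range(50):
            p = ComplexModelParams(
                rng.uniform(0.01, 0.5),
                rng.uniform(0.01, 0.5),
                rng.uniform(0.0, 50.0),
                rng.uniform(-0.05, 0.05),
            )
            ho1 = Species("a", rng.uniform(10_000, 40_000), 0.72, {})
            cpr = Species("b", rng.uniform(40_000, 90_000), 0.74, {})
            got = predict_profile(p, ho1, cpr, self.cond, r)
            want = scalar_profile_oracle(p, ho1, cpr, self.cond, r)
            np.testing.assert_allclose(got, want, rtol=1e-12)


class TestKdConversion:
    def test_reference_value(self):
        # frozen hand evaluation: (eps1+eps2)/(eps1*eps2*l)/K
        kd = kd_from_association(1.448, 15_100.0, 24_000.0, 1.2)
        assert kd * 1e6 == pytest.approx(62.09244, rel=1e-6)

    def test_path_length_scaling(self):
        kd1 = kd_from_association(2.0, 15_100.0, 24_000.0, 1.0)
        kd2 = kd_from_association(2.0, 15_100.0, 24_000.0, 2.0)
        assert kd2 == pytest.approx(kd1 / 2, rel=1e-14)

    def test_zero_association_is_infinite_not_overflow(self):
        assert math.isinf(kd_from_association(0.0, 15_100.0, 24_000.0, 1.2))
        assert association_from_kd(math.inf, 15_100.0, 24_000.0, 1.2) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        k=st.floats(1e-4, 1e4),
        e1=st.floats(1e3, 1e6),
        e2=st.floats(1e3, 1e6),
        path=st.floats(0.1, 3.0),
    )
    def test_round_trip(self, k, e1, e2, path):
        kd = kd_from_association(k, e1, e2, path)
        assert association_from_kd(kd, e1, e2, path) == pytest.approx(k, rel=1e-10)

    @settings(derandomize=True, max_examples=30)
    @given(c=st.floats(0.5, 5.0))
    def test_extinction_scaling_matches_closed_form(self, c):
        base = kd_from_association(1.0, 15_100.0, 24_000.0, 1.2)
        scaled = kd_from_association(1.0, c * 15_100.0, c * 24_000.0, 1.2)
        assert scaled == pytest.approx(base / c, rel=1e-12)

    def test_monotone_decreasing_in_k(self):
        kds = [kd_from_association(k, 15_100.0, 24_000.0, 1.2) for k in (0.1, 1, 10)]
        assert kds[0] > kds[1] > kds[2]


class TestRadialProfile:
    def test_sorts_and_rejects_duplicates(self):
        p = RadialProfile([7.0, 6.9, 7.1], [3.0, 1.0, 2.0], 455.0)
        np.testing.assert_array_equal(p.radii, [6.9, 7.0, 7.1])
        np.testing.assert_array_equal(p.absorbances, [1.0, 3.0, 2.0])
        with pytest.raises(ValidationError):
            RadialProfile([6.9, 6.9, 7.0], [1, 2, 3], 455.0)
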