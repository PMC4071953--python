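"""Unit and property tests for the model core: damage hazard, derived
sources, right-hand side and parameter containers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import lognorm

from mdximmune.model import (DamageParameters, InvalidParameterError,
                             ModelParameters, StateVector, damage_rate,
                             derivatives, derived_sources, make_rhs,
                             mdx_parameters, wild_type_parameters)


class TestDamageRate:
    def test_zero_amplitude_annihilates_hazard(self):
        p = DamageParameters(h=0.0, m=1.0, sigma=1.0)
        assert damage_rate(3.7, p) == 0.0
        assert np.all(damage_rate(np.linspace(0, 10, 7), p) == 0.0)

    def test_zero_time_limit(self, mdx):
        assert damage_rate(0.0, mdx.damage) == 0.0

    def test_value_at_one_week(self, mdx):
        # direct arithmetic evaluation of the scaled lognormal density
        assert damage_rate(1.0, mdx.damage) == pytest.approx(0.0246, abs=1e-4)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            DamageParameters(h=1.0, m=0.0, sigma=0.0)
        with pytest.raises(InvalidParameterError):
            DamageParameters(h=1.0, m=0.0, sigma=-1.0)

    @given(
        t=st.floats(0.01, 200.0),
        h=st.floats(0.0, 5.0),
        m=st.floats(-2.0, 5.0),
        sigma=st.floats(0.1, 4.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_scaled_lognormal_density(self, t, h, m, sigma):
        """The hazard is h times the lognormal(m, sigma) density in t —
        cross-checked against the scipy.stats parameterization."""
        p = DamageParameters(h=h, m=m, sigma=sigma)
        expected = h * lognorm.pdf(t, s=sigma, scale=math.exp(m))
        assert damage_rate(t, p) == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_total_hazard_mass_equals_amplitude(self, mdx):
        """Integrating alpha over (0, inf) recovers the amplitude h."""
        d = mdx.damage
        mass, _ = quad(lambda t: damage_rate(t, d), 0, np.inf, limit=400)
        assert mass == pytest.approx(d.h, rel=1e-6)


class TestParameters:
    def test_derived_sources_are_products_of_table_entries(self, mdx):
        bH, bC, bM = derived_sources(mdx)
        assert bH == 0.0  # H0 = 0 leaves CD4+ cells with no constant source
        assert bC == pytest.approx(6.46044, rel=1e-5)
        assert bM == pytest.approx(312.462, rel=1e-5)

    def test_negative_rate_rejected(self, mdx):
        with pytest.raises(InvalidParameterError):
            mdx.with_values(k4=-0.1)

    def test_flat_dict_round_trip(self, mdx):
        d = mdx.to_dict()
        assert set(d) == {"k1", "k2", "k3", "k4", "k5", "k6", "dH", "dC",
                          "dM", "dD", "h", "m", "sigma", "H0", "C0", "M0"}
        assert ModelParameters.from_dict(d) == mdx

    def test_wild_type_h_is_one_tenth_of_mdx(self, mdx):
        wt = wild_type_parameters()
        assert wt.damage.h == pytest.approx(mdx.damage.h / 10.0)
        assert wt.damage.h == pytest.approx(0.0511657)
        # everything else identical
        assert wt.with_values(h=mdx.damage.h) == mdx


admissible_states = st.builds(
    StateVector,
    H=st.floats(0, 1e6), C=st.floats(0, 1e5), M=st.floats(0, 1e6),
    N=st.floats(0, 100), D=st.floats(0, 100), R=st.floats(0, 100),
)


class TestDerivatives:
    def test_all_zero_fixed_point(self):
        """With no damage input and all baselines zero, the undamaged state
        is an exact fixed point."""
        p = mdx_parameters().with_values(h=0.0, H0=0.0, C0=0.0, M0=0.0)
        s = StateVector(H=0, C=0, M=0, N=100, D=0, R=0)
        d = derivatives(5.0, s, p)
        assert np.all(d.as_array() == 0.0)

    def test_immune_baseline_is_fixed_point_without_damage(self, mdx):
        """With D = 0 the immune populations rest at (H0, C0, M0)."""
        s = StateVector(H=mdx.H0, C=mdx.C0, M=mdx.M0, N=100, D=0, R=0)
        d = derivatives(0.0, s, mdx)
        assert d.dH == 0.0 and d.dC == 0.0 and d.dM == 0.0

    @given(s=admissible_states, t=st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_fiber_flows_sum_to_zero_exactly(self, mdx, s, t):
        d = derivatives(t, s, mdx)
        assert d.dN + d.dD + d.dR == 0.0

    @given(s=admissible_states, t=st.floats(0, 100))
    @settings(max_examples=60, deadline=None)
    def test_zeroed_immune_components_never_driven_negative(self, mdx, s, t):
        """Each immune equation's negative terms are proportional to the
        component itself, so a zeroed component cannot go negative."""
        for name in ("H", "C", "M"):
            zeroed = StateVector(**{**s.__dict__, name: 0.0})
            d = derivatives(t, zeroed, mdx)
            assert getattr(d, "d" + name) >= 0.0

    @given(s=admissible_states, t=st.floats(0.0, 100.0))
    @settings(max_examples=60, deadline=None)
    def test_fast_rhs_agrees_with_reference_derivatives(self, mdx, s, t):
        slow = derivatives(t, s, mdx).as_array()
        fast = make_rhs(mdx)(t, s.as_array())
        np.testing.assert_allclose(fast, slow, rtol=1e-12, atol=1e-9)
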