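"""Unit handling, parameter validation and the derived scale quantities."""

import math

import pytest
from hypothesis import given, strategies as st

import cleftflow as cf
from cleftflow.params import (
    MM_TO_CGS, NM_TO_CM, UM_TO_CM, ParameterError,
    classify_regime, compute_chom, compute_faq, compute_ktj, compute_yinh,
    derived_scales, load_parameters,
)


class TestLoadParameters:
    def test_mM_conversion(self):
        p = load_parameters({"c1": "600 mM"})
        assert p.c1 == pytest.approx(6.0e-4, rel=1e-15)

    def test_nm_conversion(self):
        p = load_parameters({"b": "40 nm"})
        assert p.b == pytest.approx(4e-6, rel=1e-15)

    def test_defaults_are_baseline_constants(self):
        p = load_parameters({})
        assert p.D == 1e-5
        assert p.j == 18.5e-9
        assert p.RT == pytest.approx(310.15 * 8.314e7)
        assert p.V_wat == 18.0
        assert p.P_f == 13.1e-3

    def test_overrides_take_precedence(self):
        p = load_parameters({"c1": "600 mM"}, {"c1": "300 mM"})
        assert p.c1 == pytest.approx(3.0e-4)

    @pytest.mark.parametrize(
        "config, match",
        [
            ({"unknown_key": "1 mM"}, "unknown parameter"),
            ({"b": "-40 nm"}, "positive"),
            ({"b": "40"}, "value unit"),
            ({"b": 40}, "bare number"),
            ({"c1": "600 furlongs"}, "unknown unit"),
            ({"c1": "20000 mM"}, "unit-conversion"),
        ],
    )
    def test_rejects_bad_input(self, config, match):
        with pytest.raises(ParameterError, match=match):
            load_parameters(config)

    def test_geometry_sanity(self):
        with pytest.raises(ParameterError, match="narrow-channel"):
            load_parameters({"b": "2 um", "L": "1 um"})

    @given(st.floats(min_value=1.0, max_value=9000.0))
    def test_unit_round_trip_identity(self, c_mM):
        cgs = c_mM * MM_TO_CGS
        assert cgs / MM_TO_CGS == pytest.approx(c_mM, rel=1e-12)


class TestAquaporinCoefficient:
    def test_table_values_give_009(self):
        assert compute_faq(5e-14, 18.0, 1e11) == pytest.approx(0.09, rel=1e-12)

    def test_no_aquaporins_no_flux(self):
        assert compute_faq(5e-14, 18.0, 0.0) == 0.0

    def test_linearity_in_density(self):
        assert compute_faq(5e-14, 18.0, 2e11) == pytest.approx(
            2 * compute_faq(5e-14, 18.0, 1e11)
        )


class TestTJConductance:
    RT = 310.15 * 8.314e7

    def test_narrow_cleft_value(self):
        # hand evaluation: 13.1e-3 * 18 * 2e-7 / (2.5786e10 * 4e-6)
        k = compute_ktj(13.1e-3, 18.0, 2e-7, self.RT, 40 * NM_TO_CM)
        assert k == pytest.approx(4.57e-13, rel=5e-3)

    def test_inverse_width_scaling(self):
        k40 = compute_ktj(13.1e-3, 18.0, 2e-7, self.RT, 40 * NM_TO_CM)
        k400 = compute_ktj(13.1e-3, 18.0, 2e-7, self.RT, 400 * NM_TO_CM)
        assert k400 == pytest.approx(k40 / 10.0, rel=1e-12)
        # k_TJ * b is a geometry-free combination
        assert k40 * 40 * NM_TO_CM == pytest.approx(k400 * 400 * NM_TO_CM, rel=1e-12)

    def test_tj_velocity_order_of_magnitude(self, table1):
        # osmotic TJ velocities sit in the 1e-7..1e-6 cm/s range at
        # physiological concentration differences
        for dc_mM in (100, 200, 400):
            v = table1.k_TJ * table1.RT * dc_mM * MM_TO_CGS
            assert 1e-7 < v < 1e-5


class TestHomogeneousConcentration:
    def test_reference_value_620mM(self):
        c = compute_chom(290 * MM_TO_CGS, 18.5e-9, 0.09)
        assert c / MM_TO_CGS == pytest.approx(620.0, rel=0.01)

    def test_closed_form_at_300mM(self):
        c = compute_chom(300 * MM_TO_CGS, 18.5e-9, 0.09)
        assert c / MM_TO_CGS == pytest.approx(627.6, rel=1e-3)

    def test_no_pumping_limit(self):
        assert compute_chom(3e-4, 0.0, 0.09) == 3e-4

    def test_faq_zero_with_pumping_is_error(self):
        with pytest.raises(ParameterError):
            compute_chom(3e-4, 1e-9, 0.0)

    @given(
        c3=st.floats(min_value=1e-4, max_value=1e-3),
        j=st.floats(min_value=1e-10, max_value=1e-7),
        f_aq=st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_satisfies_defining_quadratic(self, c3, j, f_aq):
        c = compute_chom(c3, j, f_aq)
        residual = c * c - c3 * c - j / f_aq
        assert abs(residual) <= 1e-12 * c * c
        assert c > c3

    def test_monotone_in_inputs(self):
        base = compute_chom(3e-4, 1.85e-8, 0.09)
        assert compute_chom(3e-4, 3e-8, 0.09) > base        # more pumping
        assert compute_chom(4e-4, 1.85e-8, 0.09) > base     # saltier cytosol
        assert compute_chom(3e-4, 1.85e-8, 0.2) < base      # more aquaporins


class TestInhomogeneityLength:
    def test_wide_cleft_value(self):
        c_hom = compute_chom(290 * MM_TO_CGS, 18.5e-9, 0.09)
        y = compute_yinh(1e-5, 400 * NM_TO_CM, c_hom, 18.5e-9)
        assert y / UM_TO_CM == pytest.approx(36.6, rel=5e-3)

    def test_sqrt_width_scaling_exact(self):
        c_hom = compute_chom(290 * MM_TO_CGS, 18.5e-9, 0.09)
        y1 = compute_yinh(1e-5, 4e-6, c_hom, 18.5e-9)
        y10 = compute_yinh(1e-5, 4e-5, c_hom, 18.5e-9)
        assert y10 / y1 == pytest.approx(math.sqrt(10.0), rel=1e-12)

    def test_vanishing_diffusion(self):
        assert compute_yinh(0.0, 4e-6, 6e-4, 1.85e-8) == 0.0

    def test_no_pumping_is_error(self):
        with pytest.raises(ParameterError):
            compute_yinh(1e-5, 4e-6, 6e-4, 0.0)


class TestRegime:
    def test_fig3_lengths(self, fig3_params):
        assert derived_scales(fig3_params.replace(L=100 * UM_TO_CM)).regime == "long"
        assert derived_scales(fig3_params.replace(L=20 * UM_TO_CM)).regime == "short"

    def test_boundary_belongs_to_long(self):
        assert classify_regime(10.0, 10.0, 20.0) == "long"
        assert classify_regime(9.999, 10.0, 19.0) == "intermediate"

    def test_no_pumping_is_short(self):
        assert classify_regime(10.0, math.inf, math.inf) == "short"


class TestDerivedScales:
    def test_velocity_slope_consistency(self, fig3_params):
        s = derived_scales(fig3_params)
        assert s.A * fig3_params.L == s.v_hom_L
        assert s.A == pytest.approx(
            2 * fig3_params.j / (fig3_params.b * s.c_hom), rel=1e-14
        )

    def test_chom_exceeds_c3(self, fig3_params):
        s = derived_scales(fig3_params)
        assert s.c_hom > fig3_params.c3
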