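"""Flux partitioning, parameter sweeps and volume estimates."""

import numpy as np
import pytest

import cleftflow as cf
from cleftflow.params import MM_TO_CGS, NM_TO_CM, UM_TO_CM, derived_scales
from cleftflow.scenarios import (
    DEFAULT_CLEFT_LINE_DENSITY, flux_summary, linked_c3, sweep, volume_per_area,
)
from cleftflow.solvers import solve


class TestFluxSummary:
    def test_homogeneous_efflux_is_chom(self, homogeneous_params):
        """For the homogeneous state v(L) = 2jL/(b c_hom), so c_e = c_hom."""
        p = homogeneous_params
        s = derived_scales(p)
        prof = solve(p)
        fs = flux_summary(prof, p)
        assert fs.c_e == pytest.approx(s.c_hom, rel=1e-8)

    def test_volume_budget_closes(self, fig3_params):
        for L_um in (20, 60, 100):
            p = fig3_params.replace(L=L_um * UM_TO_CM)
            fs = flux_summary(solve(p), p)
            assert fs.Q_tj + fs.Q_lateral == pytest.approx(fs.Q_out, rel=1e-6)

    def test_efflux_range_over_widths(self, fig3_params):
        """c_e stays within 600-700 mM as the cleft narrows (L = 100 um)."""
        for b_nm in (40, 100, 200, 400):
            p = fig3_params.replace(b=b_nm * NM_TO_CM)
            fs = flux_summary(solve(p), p)
            assert 600.0 <= fs.c_e_mM <= 700.0

    def test_tj_fraction_is_tiny(self, fig3_params):
        """TJ water is a sub-percent share of the total efflux for the
        baseline TJ permeability."""
        for b_nm in (40, 400):
            for L_um in (20, 100):
                p = fig3_params.replace(b=b_nm * NM_TO_CM, L=L_um * UM_TO_CM)
                fs = flux_summary(solve(p), p)
                assert abs(fs.tj_fraction) < 0.01

    def test_elevated_cytosol_reverses_lateral_flow(self, fig3_params):
        """With c3 between c(0) and c4, the lateral aquaporin flow changes
        direction inside the cleft (c crosses c3) and the open-end flux
        weakens relative to the baseline."""
        p0 = fig3_params.replace(L=30 * UM_TO_CM)
        base = flux_summary(solve(p0), p0)
        p = p0.replace(c3=500 * MM_TO_CGS)
        fs = flux_summary(solve(p), p)
        assert fs.lateral_sign_switch_y is not None
        assert 0.0 < fs.lateral_sign_switch_y < p.L
        assert fs.Q_lateral < base.Q_lateral

    def test_negative_outflow_has_no_efflux_concentration(self, fig3_params):
        # strongly elevated cytosol sucks water out of the cleft: v(L) < 0
        p = fig3_params.replace(L=30 * UM_TO_CM, c3=900 * MM_TO_CGS)
        fs = flux_summary(solve(p), p)
        assert fs.vL < 0
        assert fs.c_e is None


class TestSweep:
    def test_length_sweep_sign_pattern(self, fig3_params):
        res = sweep(fig3_params, "L", [L * UM_TO_CM for L in (20, 30, 80, 100)])
        assert all(res.converged)
        signs = [np.sign(s.v0) for s in res.summaries]
        assert signs == [-1, -1, 1, 1]

    def test_width_sweep_short_cleft_inlet_rises(self, fig3_params):
        """Narrowing a short cleft pushes c(0) up toward c_hom."""
        p = fig3_params.replace(L=20 * UM_TO_CM)
        s = derived_scales(p)
        c0s = [solve(p.replace(b=b_nm * NM_TO_CM)).c0
               for b_nm in (400, 200, 100, 40)]
        assert all(a < b for a, b in zip(c0s, c0s[1:]))
        assert c0s[-1] < s.c_hom

    def test_width_sweep_total_flux_rises(self, fig3_params):
        """Narrowing the cleft increases the open-end volumetric flux."""
        p = fig3_params.replace(L=60 * UM_TO_CM)
        res = sweep(p, "b", [b_nm * NM_TO_CM for b_nm in (400, 200, 100, 40)])
        qouts = [s.Q_out for s in res.summaries]
        assert all(a < b for a, b in zip(qouts, qouts[1:]))

    def test_tj_velocity_monotone_in_lumen_osmolarity(self, fig3_params):
        res = sweep(fig3_params, "c1",
                    [c * MM_TO_CGS for c in np.linspace(200, 1000, 9)])
        v0s = [s.v0 for s in res.summaries]
        assert all(a > b for a, b in zip(v0s, v0s[1:]))

    def test_width_change_flips_volume_flux_under_hypertonic_lumen(self, fig3_params):
        """Narrowing shrinks the TJ backflow under strong lumen hypertonicity
        and keeps absorption positive without a gradient."""
        p = fig3_params.replace(L=20 * UM_TO_CM, c4=300 * MM_TO_CGS)
        # dc = c1 - c4 = 600 mM
        hyper = {b: flux_summary(
            solve(p.replace(c1=900 * MM_TO_CGS, b=b * NM_TO_CM)),
            p.replace(c1=900 * MM_TO_CGS, b=b * NM_TO_CM))
            for b in (400, 40)}
        assert hyper[400].Q_tj < 0
        assert abs(hyper[40].Q_tj) < abs(hyper[400].Q_tj)
        # dc = 0: absorption through the TJ for both widths
        iso = {b: flux_summary(
            solve(p.replace(c1=300 * MM_TO_CGS, b=b * NM_TO_CM)),
            p.replace(c1=300 * MM_TO_CGS, b=b * NM_TO_CM))
            for b in (400, 40)}
        assert iso[400].Q_tj > 0 and iso[40].Q_tj > 0

    def test_failures_recorded_not_raised(self, fig3_params):
        # width larger than the cleft length violates validation at that point
        res = sweep(fig3_params.replace(L=2 * UM_TO_CM),
                    "b", [400 * NM_TO_CM, 3 * UM_TO_CM])
        assert res.converged == [True, False]
        assert res.errors[1] is not None
        df = res.to_dataframe()
        assert len(df) == 2 and not df["converged"].iloc[1]

    def test_dataframe_is_tidy(self, fig3_params):
        res = sweep(fig3_params, "b", [b * NM_TO_CM for b in (100, 400)])
        df = res.to_dataframe()
        assert list(df["b_nm"]) == [100, 400]
        assert {"v0_cm_per_s", "c_e_mM", "tj_fraction"} <= set(df.columns)


class TestVolumePerArea:
    def test_zero_flux_zero_volume(self, fig3_params):
        fs = flux_summary(solve(fig3_params.replace(j=0.0, n_aq=0.0, P_f=0.0)),
                          fig3_params.replace(j=0.0, n_aq=0.0, P_f=0.0))
        assert volume_per_area(fs) == 0.0

    def test_linearity_in_geometry(self, fig3_params):
        fs = flux_summary(solve(fig3_params), fig3_params)
        v1 = volume_per_area(fs, geometry=DEFAULT_CLEFT_LINE_DENSITY)
        v2 = volume_per_area(fs, geometry=2 * DEFAULT_CLEFT_LINE_DENSITY)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_reverse_flux_daily_magnitude(self, fig3_params):
        """A strongly hypertonic lumen over a short epithelium drives a TJ
        backflow amounting to a mL-scale volume per m^2 and day."""
        p = fig3_params.replace(L=30 * UM_TO_CM, c1=1000 * MM_TO_CGS)
        fs = flux_summary(solve(p), p)
        assert fs.v0 < 0
        vol_mL_per_m2_day = volume_per_area(fs, pathway="tj") * 1e4
        assert 1e-2 < vol_mL_per_m2_day < 1e3

    def test_pathway_and_geometry_validation(self, fig3_params):
        fs = flux_summary(solve(fig3_params), fig3_params)
        with pytest.raises(ValueError):
            volume_per_area(fs, geometry=-1.0)
        with pytest.raises(ValueError):
            volume_per_area(fs, pathway="apical")


class TestLinkedCytosol:
    def test_linear_coupling(self):
        c3 = linked_c3(900 * MM_TO_CGS, slope=0.5)
        assert c3 / MM_TO_CGS == pytest.approx(600.0)
        assert linked_c3(300 * MM_TO_CGS) / MM_TO_CGS == pytest.approx(300.0)
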