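import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sasri.constants import N_A
from sasri.exceptions import FitError, ValidationError
from sasri.interaction import (
    analyze_series,
    convert_b22,
    fit_interaction,
    fit_virial,
    number_density,
    s_zero,
    volume_fraction,
    xi,
    xi_dilute,
)
from sasri.synthetic import SimulationConfig, simulate_series
from tests.conftest import (
    B22_REF_ML,
    LYSOZYME_MW,
    LYSOZYME_RHO,
    RG0_REF,
    RI_REF,
    SERIES_CONCENTRATIONS,
)

#: Number densities (1/mL) matching the six series concentrations.
SERIES_N = [number_density(c, LYSOZYME_MW) for c in SERIES_CONCENTRATIONS]


class TestConcentrationUtilities:
    def test_number_density_reference_cell(self):
        # 4.91 mg/mL of a 14.3 kDa protein → 2.068e17 particles/mL
        assert number_density(4.91, LYSOZYME_MW) / 1e17 == pytest.approx(
            2.068, abs=5e-4
        )

    @pytest.mark.parametrize(
        "c,expected_1e17",
        [(2.45, 1.030), (7.40, 3.117), (9.94, 4.187),
         (14.21, 5.985), (18.56, 7.818)],
    )
    def test_number_density_full_series(self, c, expected_1e17):
        # remaining cells agree to the rounding of the published table
        assert number_density(c, LYSOZYME_MW) / 1e17 == pytest.approx(
            expected_1e17, rel=2.5e-3
        )

    def test_number_density_linearity(self):
        assert number_density(9.82, LYSOZYME_MW) == pytest.approx(
            2.0 * number_density(4.91, LYSOZYME_MW), rel=1e-14
        )

    def test_number_density_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            number_density(0.0, LYSOZYME_MW)

    def test_volume_fraction_reference_value(self):
        assert 100 * volume_fraction(2.45, LYSOZYME_RHO) == pytest.approx(
            0.168, abs=5e-4
        )

    def test_volume_fraction_identity_scale(self):
        assert volume_fraction(1460.0, LYSOZYME_RHO) == pytest.approx(1.0)

    def test_volume_fraction_rejects_zero_density(self):
        with pytest.raises(ValidationError):
            volume_fraction(2.45, 0.0)


class TestConvertB22:
    def test_per_mol_value(self):
        per_mol, _ = convert_b22(B22_REF_ML, LYSOZYME_MW)
        assert per_mol == pytest.approx(-22900, rel=5e-3)

    def test_per_mass_value(self):
        _, per_mass = convert_b22(B22_REF_ML, LYSOZYME_MW)
        assert per_mass == pytest.approx(-1.12e-4, rel=5e-3)

    def test_zero_maps_to_zero(self):
        assert convert_b22(0.0, LYSOZYME_MW) == (0.0, 0.0)

    @given(st.floats(-1e-18, 1e-18, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, b22):
        per_mol, _ = convert_b22(b22, LYSOZYME_MW)
        assert per_mol / N_A == pytest.approx(b22, rel=1e-12, abs=1e-30)


class TestStructureFactorZero:
    def test_reference_value_at_largest_n(self):
        assert s_zero(7.818e17, B22_REF_ML) == pytest.approx(1.0594, abs=1e-4)

    def test_ideal_solution(self):
        assert s_zero(1e17, 0.0) == 1.0

    def test_beyond_validity_raises(self):
        with pytest.raises(ValidationError, match="dilute-expansion"):
            s_zero(1e20, 1e-20)


class TestXi:
    def test_ideal_gas_is_zero(self):
        assert xi(1.0) == 0.0

    @given(
        st.floats(1e16, 1e18),
        st.floats(-5e-20, 4e-21, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_identity_with_s_zero(self, n, b22):
        # ξ(S(0)) ≡ −nB22/(1 − 2nB22) for every valid pair
        assert xi(s_zero(n, b22)) == pytest.approx(
            xi_dilute(n, b22, "exact"), rel=1e-12, abs=1e-15
        )

    def test_first_order_close_to_exact_when_dilute(self):
        # attractive case with n·|B22| = 0.03: difference is 0.03/1.06 vs 0.03
        n, b22 = 1e18, -3e-20
        first = xi_dilute(n, b22, "first")
        exact = xi_dilute(n, b22, "exact")
        assert abs(first - exact) / abs(exact) < 0.07

    def test_invalid_s0_raises(self):
        with pytest.raises(ValidationError):
            xi(0.0)


class TestFitVirial:
    def test_exact_line_recovery(self):
        b = 0.37
        pts = [
            (n, n * b * (1.0 - 2.0 * B22_REF_ML * n), 0.0) for n in SERIES_N
        ]
        res = fit_virial(pts, mw=LYSOZYME_MW)
        assert res.b22_mL == pytest.approx(B22_REF_ML, rel=1e-10)
        assert res.intercept_b == pytest.approx(b, rel=1e-10)

    def test_flat_line_gives_zero_b22(self):
        pts = [(n, 0.5 * n, 0.0) for n in SERIES_N]
        res = fit_virial(pts, mw=LYSOZYME_MW)
        assert res.b22_mL == pytest.approx(0.0, abs=1e-30)
        assert res.s_zero(SERIES_N[-1]) == pytest.approx(1.0)

    def test_two_points_rejected(self):
        with pytest.raises(ValidationError, match="≥ 3 required"):
            fit_virial([(1e17, 1.0, 0.1), (2e17, 2.0, 0.1)])

    def test_all_n_equal_rejected(self):
        with pytest.raises(FitError):
            fit_virial([(1e17, 1.0, 0.1)] * 4)

    def test_negative_intercept_unphysical(self):
        # I(0)/n rising through a negative intercept: every I(0) positive
        # but the extrapolated b is not
        pts = [(n, n * (1e-18 * n - 0.05), 0.0) for n in SERIES_N]
        with pytest.raises(FitError, match="unphysical intercept"):
            fit_virial(pts)


class TestFitInteraction:
    def test_exact_line_recovery(self):
        x = [-n * B22_REF_ML for n in SERIES_N]
        pts = [(xi_, 168.0 + 1431.0 * xi_, 0.0) for xi_ in x]
        res = fit_interaction(pts)
        assert res.ri2 == pytest.approx(1431.0, rel=1e-10)
        assert res.rg0_2 == pytest.approx(168.0, rel=1e-10)
        assert res.rg0 == pytest.approx(math.sqrt(168.0), rel=1e-10)
        assert res.ratio == pytest.approx(math.sqrt(1431.0 / 168.0), rel=1e-10)

    def test_constant_rg_means_no_interaction_signal(self):
        x = [-n * B22_REF_ML for n in SERIES_N]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_interaction([(xi_, 169.0, 0.0) for xi_ in x])
        assert res.ri2 == pytest.approx(0.0, abs=1e-8)
        assert res.rg0_2 == pytest.approx(169.0, rel=1e-10)

    def test_negative_slope_flagged_not_hidden(self):
        x = np.linspace(0.001, 0.03, 6)
        with pytest.warns(UserWarning, match="undefined"):
            res = fit_interaction([(xi_, 169.0 - 500.0 * xi_, 0.0) for xi_ in x])
        assert not res.ri_defined
        assert math.isnan(res.ri)
        assert res.ri2 < 0  # reported, not clipped

    def test_unphysical_intercept_raises(self):
        x = np.linspace(0.01, 0.05, 5)
        with pytest.raises(FitError, match="intercept"):
            fit_interaction([(xi_, -10.0 + 100.0 * xi_, 0.0) for xi_ in x])

    def test_equal_x_rejected(self):
        with pytest.raises(FitError):
            fit_interaction([(0.01, 170.0, 1.0)] * 4)

    def test_confidence_band_shrinks_at_data_center(self):
        rng = np.random.default_rng(11)
        x = np.linspace(0.0, 0.03, 8)
        y = 168.0 + 1431.0 * x + rng.normal(0, 0.5, x.size)
        res = fit_interaction([(a, b, 0.5) for a, b in zip(x, y)])
        assert res.ci95_band(0.015) < res.ci95_band(0.10)


class TestAnalyzeSeries:
    def test_noiseless_round_trip_recovers_truth(self):
        cfg = SimulationConfig(noise_frac=0.0)
        series = simulate_series(cfg)
        res = analyze_series(series, mw=cfg.mw, x_mode="xi_exact")
        assert res.virial.b22_mL == pytest.approx(B22_REF_ML, rel=1e-3)
        assert res.interaction.ri == pytest.approx(RI_REF, rel=1e-3)
        assert res.interaction.rg0 == pytest.approx(RG0_REF, rel=1e-3)

    def test_no_interaction_flags_ri_undefined(self):
        cfg = SimulationConfig(b22_mL=0.0, noise_frac=0.0)
        series = simulate_series(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = analyze_series(series, mw=cfg.mw)
        # with B22 = 0 every profile shows the bare Rg and ri carries no signal
        for g in res.guinier:
            assert g.rg_obs == pytest.approx(RG0_REF, rel=1e-6)
        assert not res.interaction.ri_defined or abs(res.interaction.ri2) < 1e-4

    @pytest.mark.parametrize("b22,increasing", [(-3.8e-20, True),
                                                (+3.8e-20, False)])
    def test_sign_law_of_apparent_rg(self, b22, increasing):
        # attraction raises Rg,obs with concentration, repulsion lowers it
        cfg = SimulationConfig(b22_mL=b22, noise_frac=0.0)
        series = simulate_series(cfg)
        res = analyze_series(series, mw=cfg.mw)
        rg = np.array([g.rg_obs for g in res.guinier])
        diffs = np.diff(rg)
        assert np.all(diffs > 0) if increasing else np.all(diffs < 0)

    def test_short_series_rejected(self):
        cfg = SimulationConfig(concentrations=(2.45, 4.91, 7.40),
                               noise_frac=0.0)
        series = simulate_series(cfg)[:2]
        with pytest.raises(ValidationError):
            analyze_series(series, mw=cfg.mw)

    def test_stage_failure_names_stage(self):
        cfg = SimulationConfig(noise_frac=0.0)
        series = simulate_series(cfg)
        with pytest.raises(FitError, match="guinier stage"):
            analyze_series(series, mw=cfg.mw, q_lo=0.9, q_hi=1.0)
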