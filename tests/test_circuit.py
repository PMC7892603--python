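"""Excitations, opponency, rod shunting, the piecewise response, calibration."""

import math

import numpy as np
import pytest

from circphot import (
    CircuitParams,
    ValidationError,
    calibrate_cross_point,
    calibrate_gains,
    circadian_response,
    excitations,
    make_blackbody,
    make_gaussian_band,
    make_monochromatic,
    mix,
    opponent_by,
    rod_shunt,
)
from circphot.circuit import (
    corneal_sensitivities,
    load_params,
    response_from_excitations,
    save_params,
)


@pytest.fixture(scope="module")
def sens(bundled_lens):
    return corneal_sensitivities(lens=bundled_lens)


class TestExcitations:
    def test_zero_spd_gives_zero_excitations(self):
        exc = excitations(make_monochromatic(500.0, 0.0))
        assert (exc.X_S, exc.X_M, exc.X_L, exc.X_rod, exc.X_mel, exc.V_ach) == (
            0.0,
        ) * 6

    def test_excitations_are_additive_fieldwise(self):
        e1 = make_gaussian_band(460.0, 25.0, 0.8)
        e2 = make_monochromatic(590.0, 0.4)
        a, b = excitations(e1), excitations(e2)
        both = excitations(mix([e1, e2], [1.0, 1.0]))
        for name in ("X_S", "X_M", "X_L", "X_rod", "X_mel"):
            assert getattr(both, name) == pytest.approx(
                getattr(a, name) + getattr(b, name), rel=1e-12
            )

    def test_430nm_line_drives_s_cones_more_than_l_cones(self, sens):
        exc = excitations(make_monochromatic(430.0, 1.0))
        assert exc.X_S > exc.X_L
        # direct-evaluation oracle: the integrals of a unit line are the
        # corneal sensitivities at 430 nm
        assert exc.X_S == pytest.approx(sens["S"].value_at(430.0))
        assert exc.X_L == pytest.approx(sens["L"].value_at(430.0))

    def test_achromatic_channel_is_l_plus_m(self):
        exc = excitations(make_gaussian_band(540.0, 30.0, 1.0))
        assert exc.V_ach == exc.X_L + exc.X_M


class TestOpponentChannel:
    def test_cross_point_line_is_balanced_and_yellow(self, params):
        exc = excitations(make_monochromatic(500.0, 1.0))
        signal = opponent_by(exc, params.k)
        assert signal.b_minus_y == pytest.approx(0.0, abs=1e-12)
        assert signal.branch == "yellow"

    @pytest.mark.parametrize("nm,branch", [(450.0, "blue"), (580.0, "yellow")])
    def test_branch_sign_matches_template_evaluation(self, nm, branch, params, sens):
        exc = excitations(make_monochromatic(nm, 1.0))
        assert opponent_by(exc, params.k).branch == branch
        oracle = sens["S"].value_at(nm) - params.k * (
            sens["L"].value_at(nm) + sens["M"].value_at(nm)
        )
        assert (oracle > 0) == (branch == "blue")

    def test_nonpositive_gain_rejected(self):
        exc = excitations(make_monochromatic(450.0, 1.0))
        with pytest.raises(ValidationError):
            opponent_by(exc, 0.0)


class TestRodShunt:
    def test_no_rod_drive_no_shunt(self, params):
        exc = excitations(make_monochromatic(500.0, 0.0))
        assert rod_shunt(exc, params) == 0.0

    def test_shunt_saturates_to_a2_without_cone_release(self, params):
        from circphot.circuit import PhotoreceptorExcitations

        shunts = [
            rod_shunt(PhotoreceptorExcitations(0.0, 0.0, 0.0, x_rod, 0.0), params)
            for x_rod in np.logspace(-3, 0, 30)
        ]
        assert np.all(np.diff(shunts) >= 0)
        assert np.all(np.asarray(shunts) < params.a2)
        assert shunts[-1] == pytest.approx(params.a2, rel=1e-6)

    def test_cone_drive_strictly_releases_the_shunt(self, params):
        # fixed rod excitation, achromatic drive doubled across a sweep
        from circphot.circuit import PhotoreceptorExcitations

        for v_ach in np.linspace(0.01, 2.0, 20):
            lo = PhotoreceptorExcitations(0.0, v_ach / 2, v_ach / 2, 0.3, 0.1)
            hi = PhotoreceptorExcitations(0.0, v_ach, v_ach, 0.3, 0.1)
            assert rod_shunt(hi, params) < rod_shunt(lo, params)


class TestCircadianResponse:
    def test_zero_spd_gives_zero_drive(self, params):
        assert circadian_response(make_monochromatic(500.0, 0.0), params) == 0.0

    @pytest.mark.parametrize("power", [1e-4, 1e-1, 10.0])
    def test_warm_line_response_is_exactly_melanopic(self, power, params):
        spd = make_monochromatic(600.0, power)
        assert circadian_response(spd, params) == excitations(spd).X_mel

    def test_yellow_branch_is_independent_of_shunt_and_sb_gains(self, params):
        warm_sources = [
            make_monochromatic(600.0, 0.5),
            make_blackbody(2700.0, scale=0.3),
        ]
        altered = CircuitParams(
            k=params.k,
            a1=7 * params.a1,
            a2=5 * params.a2,
            a3=0.1 * params.a3,
            rod_sat=3 * params.rod_sat,
        )
        for spd in warm_sources:
            assert opponent_by(excitations(spd), params.k).branch == "yellow"
            assert circadian_response(spd, params) == circadian_response(spd, altered)

    def test_dim_blue_stimulus_is_clamped_to_zero(self, params):
        band = make_gaussian_band(470.0, 30.0, 1e-3)
        assert opponent_by(excitations(band), params.k).branch == "blue"
        assert circadian_response(band, params) == 0.0

    def test_threshold_is_spectral_not_just_radiometric(self, params):
        # same corneal power: the blue-branch band is shunted to zero while
        # the warm line, with the shunt decoupled, still drives the ipRGC
        power = 1e-3
        band = make_gaussian_band(470.0, 30.0, power)
        line = make_monochromatic(600.0, power)
        assert circadian_response(band, params) == 0.0
        assert circadian_response(line, params) > 0.0

    def test_response_monotone_in_intensity_on_both_branches(self, params):
        for spd in (make_gaussian_band(470.0, 30.0, 1.0), make_monochromatic(600.0, 1.0)):
            scales = np.logspace(-5, 2, 120)
            responses = [circadian_response(spd.scaled(c), params) for c in scales]
            assert np.all(np.diff(responses) >= -1e-12)

    def test_balanced_mixture_responds_subadditively(self, params):
        # two-line mixture scaled so b-y = 0: the mixture drive is purely
        # melanopic and strictly below the sum of the component drives
        blue = make_monochromatic(450.0, 0.3)
        by_blue = opponent_by(excitations(blue), params.k).b_minus_y
        yellow_unit = make_monochromatic(570.0, 1.0)
        by_yellow = opponent_by(excitations(yellow_unit), params.k).b_minus_y
        yellow = yellow_unit.scaled(by_blue / -by_yellow)
        mixture = mix([blue, yellow], [1.0, 1.0])
        exc = excitations(mixture)
        assert opponent_by(exc, params.k).b_minus_y == pytest.approx(0.0, abs=1e-12)
        r_mix = circadian_response(mixture, params)
        assert r_mix == exc.X_mel
        r_sum = circadian_response(blue, params) + circadian_response(yellow, params)
        assert r_mix < r_sum

    def test_pipeline_matches_direct_formula(self, params):
        # independent one-line re-derivation of the piecewise response
        for spd in (
            make_gaussian_band(460.0, 30.0, 0.5),
            make_monochromatic(490.0, 0.2),
            make_blackbody(6500.0, scale=0.2),
            make_monochromatic(600.0, 1.0),
        ):
            exc = excitations(spd)
            b_y = exc.X_S - params.k * (exc.X_L + exc.X_M)
            if b_y > 0:
                shunt = params.a2 * (
                    1.0
                    - math.exp(
                        -exc.X_rod
                        / (1.0 + params.a3 * (exc.X_L + exc.X_M))
                        / params.rod_sat
                    )
                )
                expected = max(0.0, exc.X_mel + params.a1 * b_y - shunt)
            else:
                expected = exc.X_mel
            assert circadian_response(spd, params) == pytest.approx(
                expected, rel=1e-12, abs=1e-300
            )
            assert response_from_excitations(exc, params) == circadian_response(
                spd, params
            )


class TestCalibration:
    def test_cross_point_gain_matches_closed_form(self, params, sens):
        k = calibrate_cross_point()
        ratio = sens["S"].value_at(500.0) / (
            sens["L"].value_at(500.0) + sens["M"].value_at(500.0)
        )
        assert k == pytest.approx(ratio, rel=1e-12)
        assert k > 0
        assert params.k == k

    def test_calibrated_gains_hit_target_half_bandwidth(self, params):
        from circphot import fwhm, spectral_sensitivity_curve

        curve = spectral_sensitivity_curve(params)
        assert fwhm(curve) == pytest.approx(100.0, abs=10.0)

    def test_disabling_sb_and_shunt_reduces_to_melanopsin_alone(self, params, unity_lens):
        from circphot import fwhm, spectral_sensitivity_curve

        ablated = CircuitParams(
            k=params.k, a1=0.0, a2=0.0, a3=params.a3, rod_sat=params.rod_sat
        )
        full = spectral_sensitivity_curve(ablated, lens=unity_lens)
        mel = spectral_sensitivity_curve(
            ablated, lens=unity_lens, variant="melanopsin_only"
        )
        np.testing.assert_allclose(full.values, mel.values, rtol=1e-12)
        assert fwhm(full) == pytest.approx(80.0, abs=1.0)

    def test_calibration_is_deterministic(self, params):
        assert calibrate_gains() == calibrate_gains() == params

    def test_target_below_opsin_width_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_gains(target_fwhm=60.0)


class TestParamsIO:
    def test_round_trip_and_byte_identical_files(self, params, tmp_path):
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        save_params(p1, params, extra={"cross_point_nm": "500"})
        save_params(p2, params, extra={"cross_point_nm": "500"})
        assert p1.read_bytes() == p2.read_bytes()
        loaded, extra = load_params(p1)
        assert loaded == params
        assert extra["cross_point_nm"] == "500"

    def test_missing_parameter_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("k = 0.5\na1 = 1.0\n")
        with pytest.raises(ValidationError):
            load_params(path)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            CircuitParams(k=0.0, a1=1.0, a2=0.1, a3=1.0, rod_sat=0.05)
        with pytest.raises(ValidationError):
            CircuitParams(k=0.5, a1=-1.0, a2=0.1, a3=1.0, rod_sat=0.05)
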