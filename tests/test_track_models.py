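import math

import numpy as np
import pytest
from scipy import integrate

from cordrbe.rbe_stats import RBEResult
from cordrbe.track_models import (
    IonBeam,
    LEMParams,
    MKMParams,
    PhotonLQ,
    energy_from_let,
    lem1_alpha_beta,
    let_from_energy,
    mixed_field,
    mkm_alpha_beta,
    mkm_zstar,
    model_comparison,
    predict_rbe,
    radial_dose,
)
from cordrbe.track_models.mkm import specific_energy_profile
from cordrbe.track_models.stopping import KEV_PER_UM_TO_GY_UM2, load_let_table

PHOTON = PhotonLQ(alpha_x=0.1, beta_x=0.05, d_t=30.0)
STUDY_LETS = (26.0, 66.0, 98.0, 141.0)


class TestStopping:
    def test_table_matches_formula(self):
        energy, let = load_let_table()
        sampled = energy[::40]
        for e in sampled:
            assert let_from_energy(float(e)) == pytest.approx(
                float(np.interp(e, energy, let)), rel=1e-3)

    def test_energy_let_roundtrip(self):
        for let in STUDY_LETS:
            e = energy_from_let(let)
            assert let_from_energy(e) == pytest.approx(let, rel=1e-3)

    def test_beam_derivation(self):
        beam = IonBeam(let_value=98.0)
        assert 30.0 < beam.energy < 50.0
        assert 0.0 < beam.beta_v < 1.0
        with pytest.raises(ValueError):
            IonBeam()

    def test_out_of_range_let(self):
        with pytest.raises(ValueError, match="outside"):
            energy_from_let(5.0)


class TestRadialDose:
    @pytest.mark.parametrize("let", STUDY_LETS)
    def test_normalization(self, let):
        beam = IonBeam(let_value=let)
        params = LEMParams()
        r_max = params.r_max(beam.energy)
        val, _ = integrate.quad(
            lambda r: radial_dose(r, beam, params) * 2.0 * math.pi * r,
            0.0, r_max, points=[params.r_min], limit=400)
        assert val == pytest.approx(KEV_PER_UM_TO_GY_UM2 * let, rel=5e-3)

    def test_linear_in_let_at_fixed_energy(self):
        params = LEMParams()
        e = energy_from_let(66.0)
        b1 = IonBeam(energy=e)

        class Doubled:
            energy = e
            let_value = 2.0 * b1.let_value

        r = np.array([0.1, 0.5, 2.0, 10.0])
        assert np.allclose(radial_dose(r, Doubled(), params),
                           2.0 * radial_dose(r, b1, params))

    def test_inverse_square_law(self):
        beam = IonBeam(let_value=98.0)
        params = LEMParams()
        r1, r2 = params.r_min * 1.5, params.r_min * 3.0
        d1, d2 = radial_dose(r1, beam, params), radial_dose(r2, beam, params)
        assert d1 * r1 ** 2 == pytest.approx(d2 * r2 ** 2, rel=1e-12)

    def test_core_is_flat(self):
        beam = IonBeam(let_value=98.0)
        params = LEMParams()
        assert radial_dose(0.0, beam, params) == radial_dose(params.r_min, beam, params)

    def test_zero_beyond_rmax(self):
        beam = IonBeam(let_value=98.0)
        params = LEMParams()
        assert radial_dose(params.r_max(beam.energy) * 1.01, beam, params) == 0.0


class TestLemAlphaBeta:
    def test_smax_arithmetic(self):
        assert PHOTON.s_max == pytest.approx(3.1)

    def test_low_let_limit_approaches_photon_alpha(self):
        class ThinBeam:
            let_value = 0.1
            energy = 300.0

        alpha, _ = lem1_alpha_beta(ThinBeam(), PHOTON)
        assert alpha == pytest.approx(PHOTON.alpha_x, rel=0.20)

    def test_alpha_rises_over_study_range(self):
        alphas = [lem1_alpha_beta(IonBeam(let_value=l), PHOTON)[0]
                  for l in STUDY_LETS]
        assert all(b > a for a, b in zip(alphas, alphas[1:]))

    def test_overkill_turnover_full_scan(self):
        # the Poisson single-track form must rise then fall somewhere on
        # the achievable LET range for this ion
        lets = np.linspace(15.0, 650.0, 40)
        alphas = np.array([lem1_alpha_beta(IonBeam(let_value=float(l)), PHOTON)[0]
                           for l in lets])
        peak = int(np.argmax(alphas))
        assert 0 < peak < len(lets) - 1
        assert alphas[-1] < alphas[peak]

    def test_linear_form_monotone_saturating(self):
        lets = np.linspace(15.0, 650.0, 30)
        alphas = np.array([
            lem1_alpha_beta(IonBeam(let_value=float(l)), PHOTON, form="linear")[0]
            for l in lets])
        assert np.all(np.diff(alphas) > 0)
        assert alphas[-1] < PHOTON.s_max

    def test_beta_from_slope_balance(self):
        beam = IonBeam(let_value=98.0)
        alpha, beta = lem1_alpha_beta(beam, PHOTON)
        assert beta == pytest.approx((PHOTON.s_max - alpha) / (2.0 * PHOTON.d_t))

    def test_analytic_penumbra_oracle(self):
        # below-threshold track: the radial integral has a closed form
        from cordrbe.track_models.lem import _track_lambda, single_track_yield

        beam = IonBeam(let_value=26.0)
        params = LEMParams()
        r_min, r_max = params.r_min, params.r_max(beam.energy)
        lam = _track_lambda(beam, r_min, r_max)
        assert lam / r_min ** 2 < PHOTON.d_t  # everything below threshold
        a, b = PHOTON.alpha_x, PHOTON.beta_x
        core = (a * lam / r_min ** 2 + b * (lam / r_min ** 2) ** 2) * math.pi * r_min ** 2
        pen = (2 * math.pi * a * lam * math.log(r_max / r_min)
               + math.pi * b * lam ** 2 * (1 / r_min ** 2 - 1 / r_max ** 2))
        assert single_track_yield(beam, PHOTON, params) == pytest.approx(
            core + pen, rel=1e-6)


class TestMkm:
    def test_saturation_never_increases(self):
        for let in STUDY_LETS:
            beam = IonBeam(let_value=let)
            z_sat = mkm_zstar(beam)
            z_unc = mkm_zstar(beam, saturation=False)
            assert z_sat <= z_unc + 1e-12

    def test_z0_infinite_limit(self):
        beam = IonBeam(let_value=141.0)
        params_huge = MKMParams(y_0=1e9)
        assert mkm_zstar(beam, params_huge) == pytest.approx(
            mkm_zstar(beam, saturation=False), rel=1e-6)

    def test_scan_increasing_with_strengthening_saturation(self):
        lets = np.linspace(15.0, 200.0, 12)
        beams = [IonBeam(let_value=float(l)) for l in lets]
        z_sat = np.array([mkm_zstar(b) for b in beams])
        z_unc = np.array([mkm_zstar(b, saturation=False) for b in beams])
        assert np.all(np.diff(z_sat) > 0)
        # growth relative to the uncorrected dose-mean slows monotonically,
        # with an appreciable deficit as LET approaches y_0
        ratio = z_sat / z_unc
        assert np.all(np.diff(ratio) < 0)
        assert ratio[-1] < 0.95

    def test_sublinear_beyond_saturation_parameter(self):
        # per-LET yield z*/LET eventually declines (overkill saturation)
        z300 = mkm_zstar(IonBeam(let_value=300.0)) / 300.0
        z500 = mkm_zstar(IonBeam(let_value=500.0)) / 500.0
        assert z500 < z300

    def test_saturation_bites_at_high_let(self):
        beam = IonBeam(let_value=141.0)
        assert mkm_zstar(beam) < mkm_zstar(beam, saturation=False)

    def test_profile_integral_preserves_let(self):
        # averaging over domains preserves the track's radial dose integral
        beam = IonBeam(let_value=66.0)
        params = MKMParams()
        from cordrbe.track_models.mkm import _kc_track

        _, r_p, _ = _kc_track(beam)
        b = np.unique(np.concatenate([
            np.geomspace(1e-5, params.domain_radius, 400),
            np.linspace(params.domain_radius, r_p + params.domain_radius, 2000),
        ]))
        z = specific_energy_profile(b, beam, params)
        total = np.trapezoid(z * 2.0 * math.pi * b, b)
        assert total == pytest.approx(KEV_PER_UM_TO_GY_UM2 * 66.0, rel=0.02)

    def test_alpha_beta_map(self):
        params = MKMParams()
        assert mkm_alpha_beta(0.0, params) == (params.alpha_0, params.beta_m)
        a1, _ = mkm_alpha_beta(10.0, params)
        a2, _ = mkm_alpha_beta(20.0, params)
        assert (a2 - params.alpha_0) == pytest.approx(2.0 * (a1 - params.alpha_0))

    def test_default_parameters(self):
        params = MKMParams()
        assert params.beta_m == pytest.approx(0.0015)
        assert params.alpha_0 / params.beta_m == pytest.approx(2.0)


class TestMixedField:
    def test_single_component_identity(self):
        assert mixed_field([(1.0, 0.2, 0.05)]) == pytest.approx((0.2, 0.05))

    def test_equal_components(self):
        assert mixed_field([(0.5, 0.2, 0.05), (0.5, 0.2, 0.05)]) == pytest.approx(
            (0.2, 0.05))

    def test_alpha_convexity(self):
        a, _ = mixed_field([(0.3, 0.1, 0.05), (0.7, 0.4, 0.02)])
        assert 0.1 <= a <= 0.4

    def test_weight_normalization_enforced(self):
        with pytest.raises(ValueError):
            mixed_field([(0.5, 0.1, 0.05), (0.6, 0.2, 0.05)])


class TestPredictRbe:
    def test_identity_case(self):
        pred = predict_rbe(PHOTON.alpha_x, PHOTON.beta_x, PHOTON, 10.0)
        assert pred.rbe == pytest.approx(1.0, rel=1e-12)

    def test_low_dose_limit_alpha_ratio(self):
        pred = predict_rbe(2.0 * PHOTON.alpha_x, PHOTON.beta_x, PHOTON, 1e-7)
        assert pred.rbe == pytest.approx(2.0, rel=1e-4)

    def test_decreasing_in_dose(self):
        rbes = [predict_rbe(0.3, 0.05, PHOTON, d).rbe for d in (1.0, 5.0, 10.0, 20.0)]
        assert all(a > b for a, b in zip(rbes, rbes[1:]))

    def test_schedule_independence(self):
        r1 = predict_rbe(0.3, 0.04, PHOTON, 8.0, n_fractions=1).rbe
        r2 = predict_rbe(0.3, 0.04, PHOTON, 8.0, n_fractions=2).rbe
        assert r1 == r2

    def test_invalid_dose(self):
        with pytest.raises(ValueError):
            predict_rbe(0.3, 0.04, PHOTON, 0.0)


class TestCrossModel:
    def test_continuity_in_let(self):
        lets = np.linspace(20.0, 150.0, 27)
        mkm_photon = PhotonLQ(0.003, 0.0015)
        for model in ("lem", "mkm"):
            rbes = []
            for l in lets:
                beam = IonBeam(let_value=float(l))
                if model == "lem":
                    a, b = lem1_alpha_beta(beam, PHOTON)
                    rbes.append(predict_rbe(a, b, PHOTON, 14.0).rbe)
                else:
                    a, b = mkm_alpha_beta(mkm_zstar(beam))
                    rbes.append(predict_rbe(a, b, mkm_photon, 14.0).rbe)
            jumps = np.abs(np.diff(rbes))
            assert np.max(jumps) < 0.05

    def test_lem_let_slope_below_mkm(self):
        mkm_photon = PhotonLQ(0.003, 0.0015)
        lem_rbe, mkm_rbe = [], []
        for let in STUDY_LETS:
            beam = IonBeam(let_value=let)
            d = 15.0
            a, b = lem1_alpha_beta(beam, PHOTON)
            lem_rbe.append(predict_rbe(a, b, PHOTON, d).rbe)
            a, b = mkm_alpha_beta(mkm_zstar(beam))
            mkm_rbe.append(predict_rbe(a, b, mkm_photon, d).rbe)
        slope = lambda y: np.polyfit(STUDY_LETS, y, 1)[0]
        assert slope(lem_rbe) < slope(mkm_rbe)

    def test_removing_saturation_raises_high_let_rbe(self):
        beam = IonBeam(let_value=141.0)
        params = MKMParams()
        mkm_photon = PhotonLQ(params.alpha_0, params.beta_m)
        a_sat, b_sat = mkm_alpha_beta(mkm_zstar(beam, params), params)
        a_unc, b_unc = mkm_alpha_beta(mkm_zstar(beam, params, saturation=False), params)
        r_sat = predict_rbe(a_sat, b_sat, mkm_photon, 15.0).rbe
        r_unc = predict_rbe(a_unc, b_unc, mkm_photon, 15.0).rbe
        assert r_unc > r_sat


class TestModelComparison:
    def measured(self):
        return [
            RBEResult(26.0, 1, 1.43, 0.05, (1.34, 1.51), 24.5, 24.5 / 1.43),
            RBEResult(66.0, 1, 1.71, 0.06, (1.60, 1.81), 24.5, 24.5 / 1.71),
            RBEResult(98.0, 1, 1.82, 0.08, (1.69, 1.96), 24.5, 24.5 / 1.82),
            RBEResult(141.0, 1, 1.56, 0.06, (1.45, 1.67), 24.5, 24.5 / 1.56),
        ]

    def predicted(self, values, name="LEM1"):
        from cordrbe.track_models import ModelPrediction

        return [ModelPrediction(name, let, 1, 14.0, 0.2, 0.04, v)
                for let, v in zip(STUDY_LETS, values)]

    def test_perfect_prediction(self):
        df = model_comparison(self.measured(), self.predicted([1.43, 1.71, 1.82, 1.56]))
        assert np.allclose(df.deviation, 0.0)
        assert not df.significant.any()

    def test_prediction_below_cl_flagged(self):
        df = model_comparison(self.measured(), self.predicted([1.20, 1.71, 1.82, 1.56]))
        row = df[df.let_value == 26.0].iloc[0]
        assert row.significant
        assert df[df.let_value != 26.0].significant.sum() == 0

    def test_sobp_mean_sd_hand_arithmetic(self):
        df = model_comparison(self.measured(), self.predicted([1.40, 1.60, 1.70, 1.50]))
        devs = np.array([1.60 - 1.71, 1.70 - 1.82, 1.50 - 1.56])
        row = df.iloc[0]
        assert row.plateau_dev == pytest.approx(1.40 - 1.43)
        assert row.sobp_mean == pytest.approx(devs.mean())
        assert row.sobp_sd == pytest.approx(devs.std(ddof=1))

    def test_unmatched_key_rejected(self):
        with pytest.raises(KeyError):
            model_comparison(self.measured()[:2], self.predicted([1.4, 1.7, 1.8, 1.5]))
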