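"""Spectral densities, SPM/SBM dispersion models, and NMRD profile fitting."""

import cmath

import numpy as np
import pytest

from lowfield_relax import (
    SBMParams,
    SPMParams,
    ayant_spectral_density,
    field_from_frequency,
    fit_nmrd,
    freed_spectral_density,
    larmor_frequency,
    peak_frequency,
    predict_diffusion_dependence,
    r1_at_field,
    sbm_r1,
    simulate_nmrd_profile,
    spm_params_for_agent,
    spm_r1,
    subtract_background_normalize,
    tau_d,
)
from lowfield_relax.constants import (
    BOHR_MAGNETON,
    GAMMA_PROTON,
    MU0_OVER_4PI,
    OMEGA_S_OVER_OMEGA_I,
)
from lowfield_relax.nmrd import nmrd_forward


class TestLarmor:
    def test_64mT(self):
        assert round(larmor_frequency(0.064), 2) == 2.72

    def test_zero_and_3T(self):
        assert larmor_frequency(0.0) == 0.0
        assert larmor_frequency(3.0) == pytest.approx(127.732434, abs=1e-6)

    def test_inverse(self):
        assert field_from_frequency(larmor_frequency(0.25)) == pytest.approx(0.25)

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            larmor_frequency(-1.0)


class TestTauD:
    def test_reference_value(self):
        assert tau_d(15.7, 2.3e-9) == pytest.approx(1.0716956521739132e-07, rel=1e-12)

    def test_scaling(self):
        assert tau_d(10.0, 2.3e-9) / tau_d(5.0, 2.3e-9) == pytest.approx(4.0)
        assert tau_d(10.0, 4.6e-9) / tau_d(10.0, 2.3e-9) == pytest.approx(0.5)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tau_d(0.0, 2.3e-9)


class TestSpectralDensities:
    def test_freed_limits(self):
        assert freed_spectral_density(0.0, 1e-8) == pytest.approx(1.0, abs=1e-15)
        assert freed_spectral_density(1e15, 1e-8) < 1e-3

    def test_freed_complex_oracle(self):
        # independent evaluation with scalar complex arithmetic
        tau_D, tau_N = 1.0, 10.0
        z = cmath.sqrt(1j * 1.0 * tau_D + tau_D / tau_N)
        oracle = ((1 + z / 4) / (1 + z + 4 * z**2 / 9 + z**3 / 9)).real
        assert freed_spectral_density(1.0, tau_D, tau_N) == pytest.approx(
            oracle, abs=1e-12
        )
        assert oracle == pytest.approx(0.5077168927786166, abs=1e-12)

    def test_ayant_limits_and_oracle(self):
        assert ayant_spectral_density(0.0, 1e-8) == 1.0
        # u = 1 corresponds to omega = 1/(2 tau_D)
        u = 1.0
        oracle = (1 + 5 * u / 8 + u**2 / 8) / (
            1 + u + u**2 / 2 + u**3 / 6 + 4 * u**4 / 81 + u**5 / 81 + u**6 / 648
        )
        assert ayant_spectral_density(0.5, 1.0) == pytest.approx(oracle, abs=1e-12)
        assert oracle == pytest.approx(0.6410401356698701, abs=1e-12)

    def test_ayant_strictly_decreasing(self):
        omega = np.logspace(2, 10, 60)
        vals = ayant_spectral_density(omega, 1e-8)
        assert np.all(np.diff(vals) < 0)


class TestSPMModel:
    def test_zero_amplitude(self):
        p = SPMParams(d_nm=10.0, K_scale=0.0)
        assert np.allclose(spm_r1(np.logspace(-2, 1.6, 20), p), 0.0)

    def test_low_frequency_limit_closed_form(self):
        # as x -> 0 the Langevin weights tend to (L²→0, 2L/x→2/3); the model
        # plateau is K·(c_freed/3 + 2·c_trans/3)·J_F(omega→0)
        p = SPMParams(d_nm=10.0, tau_N=1e-9, K_scale=5.0)
        jf0 = freed_spectral_density(0.0, p.tau_D, p.tau_N)
        expected = 5.0 * (p.c_freed / 3.0 + 2.0 * p.c_trans / 3.0) * jf0
        assert spm_r1(1e-7, p) == pytest.approx(expected, rel=1e-6)

    def test_no_blowup_at_tiny_x(self):
        p = SPMParams(d_nm=10.0)
        vals = spm_r1(np.array([1e-12, 1e-9, 1e-6, 1e-3]), p)
        assert np.all(np.isfinite(vals))

    def test_peaks_in_2_to_10_MHz_window(self, agents):
        for name in ("B", "C", "D"):
            p = spm_params_for_agent(agents[name], 21.5, D=2.3e-9)
            assert 2.0 <= peak_frequency(p) <= 10.0, name

    def test_peak_frequency_decreases_with_diameter(self, agents):
        peaks = [
            peak_frequency(spm_params_for_agent(agents[n], 21.5, D=2.3e-9))
            for n in ("A", "B", "C", "D")
        ]
        assert np.all(np.diff(peaks) < 0)

    def test_peak_scaling_with_diameter_at_fixed_neel_time(self):
        # in the saturated-moment regime the Langevin weight is ~1 near the
        # peak and the Ayant small-u expansion puts the maximum where the
        # L(x)² tail balances the sqrt(omega·tau_D) decay, i.e. the peak
        # drifts as tau_D^(-1/3); it must also decrease monotonically with d
        base = SPMParams(d_nm=5.0, tau_N=1e-9, mu=1e-18)
        peaks, prods = [], []
        for d in (5.0, 10.0, 15.0, 20.0):
            p = SPMParams(**{**base.__dict__, "d_nm": d})
            f = peak_frequency(p, n=8000)
            peaks.append(f)
            prods.append(f * p.tau_D ** (1.0 / 3.0))
        assert np.all(np.diff(peaks) < 0)
        prods = np.array(prods)
        assert np.max(np.abs(prods / prods[-1] - 1.0)) < 0.10


def _sbm_zero_frequency_oracle(p: SBMParams) -> float:
    """Independent omega -> 0 closed form for the SBM inner-sphere term."""
    inv_t1e0 = p.delta2 * p.tau_V  # (1/5)(1+4) at zero field
    tc = 1.0 / (1.0 / p.tau_R + 1.0 / p.tau_M + inv_t1e0)
    dip = (
        (2.0 / 15.0) * MU0_OVER_4PI**2 * GAMMA_PROTON**2
        * (2.0 * BOHR_MAGNETON) ** 2 * p.S * (p.S + 1.0) / p.r_GdH**6
    )
    inv_t1m = dip * 10.0 * tc
    return p.scale * (p.q / 55500.0) / (1.0 / inv_t1m + p.tau_M)


class TestSBMModel:
    def test_zero_hydration_and_outer(self):
        p = SBMParams(q=0.0, outer_amplitude=0.0)
        assert np.allclose(sbm_r1(np.logspace(-2, 1.6, 10), p), 0.0)

    def test_low_field_plateau_matches_oracle(self):
        p = SBMParams(outer_amplitude=0.0)
        assert sbm_r1(1e-6, p) == pytest.approx(_sbm_zero_frequency_oracle(p), rel=1e-9)

    def test_non_increasing_across_dispersions(self):
        p = SBMParams()
        vals = sbm_r1(np.logspace(-2, np.log10(40), 80), p)
        assert np.all(np.diff(vals) <= 1e-9 * vals[:-1])

    def test_electron_larmor_ratio(self):
        # the omega_S dispersion must sit 658.2x below the omega_I dispersion
        assert OMEGA_S_OVER_OMEGA_I == pytest.approx(658.2)


class TestBackgroundSubtraction:
    def test_identical_profiles_give_zero(self):
        f = np.logspace(-2, 1, 10)
        prof = subtract_background_normalize(f, np.ones(10), np.ones(10), 1.0)
        assert np.allclose(prof.r1, 0.0)
        assert not prof.negative_flagged

    def test_concentration_normalization(self):
        f = np.logspace(-2, 1, 10)
        r_a = subtract_background_normalize(f, np.full(10, 3.0), np.ones(10), 1.0)
        r_b = subtract_background_normalize(f, np.full(10, 3.0), np.ones(10), 2.0)
        assert np.allclose(r_a.r1, 2.0 * r_b.r1)

    def test_recovers_forward_model_exactly(self):
        f = np.logspace(-2, np.log10(40), 15)
        p = SPMParams(d_nm=12.0, K_scale=30.0)
        blank = 0.35 * np.ones(15)
        sample = blank + 0.5 * spm_r1(f, p)
        prof = subtract_background_normalize(f, sample, blank, 0.5)
        assert np.allclose(prof.r1, spm_r1(f, p), rtol=1e-12)

    def test_negative_values_flagged(self):
        f = np.logspace(-2, 1, 10)
        with pytest.warns(UserWarning):
            prof = subtract_background_normalize(f, np.zeros(10), np.ones(10), 1.0)
        assert prof.negative_flagged

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_background_normalize(np.logspace(-2, 1, 10), np.ones(10),
                                          np.ones(9), 1.0)


class TestFitNMRD:
    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            nmrd_forward("bogus", None, np.logspace(-2, 1, 10))

    def test_noiseless_roundtrip_within_one_percent(self, agents):
        truth = spm_params_for_agent(agents["D"], 21.5)
        prof = simulate_nmrd_profile("spm", truth, rel_noise=0.0)
        init = SPMParams(**{**truth.__dict__, "d_nm": 10.0, "tau_N": 1e-9,
                            "K_scale": float(prof.r1.max())})
        fit = fit_nmrd(prof, "spm", init=init)
        assert fit.success
        assert fit.params.d_nm == pytest.approx(truth.d_nm, rel=0.01)
        assert fit.params.tau_N == pytest.approx(truth.tau_N, rel=0.01)
        assert fit.params.K_scale == pytest.approx(truth.K_scale, rel=0.01)

    def test_spm_misfits_sbm_generated_profile(self, agents):
        sbm_truth = SBMParams()
        prof = simulate_nmrd_profile("sbm", sbm_truth, rel_noise=0.005, seed=2)
        matched = fit_nmrd(prof, "sbm", init=SBMParams(scale=0.5))
        mismatched = fit_nmrd(prof, "spm", init=SPMParams(
            d_nm=10.0, K_scale=float(prof.r1.max())))
        assert mismatched.redchi > matched.redchi

    def test_requires_enough_points_and_span(self, agents):
        p = spm_params_for_agent(agents["D"], 21.5)
        with pytest.raises(ValueError):
            fit_nmrd(simulate_nmrd_profile(
                "spm", p, freqs_MHz=np.logspace(-1, 1, 6), rel_noise=0.0))


class TestR1AtField:
    def test_evaluates_at_larmor_frequency(self, agents):
        p = spm_params_for_agent(agents["D"], 21.5)
        assert r1_at_field(("spm", p), 0.064) == pytest.approx(
            float(spm_r1(larmor_frequency(0.064), p)), rel=1e-14
        )

    def test_grid_point_consistency(self, agents):
        p = spm_params_for_agent(agents["C"], 21.5)
        f = larmor_frequency(0.25)
        assert r1_at_field(("spm", p), 0.25) == pytest.approx(float(spm_r1(f, p)))


class TestDiffusionDependence:
    def test_slower_diffusion_shifts_peak_down_and_enhances_r1(self):
        p = SPMParams(d_nm=6.5, tau_N=1e-9, mu=1e-18, K_scale=40.0)
        dense = np.logspace(-2, np.log10(40), 600)
        prof_fast, prof_slow = predict_diffusion_dependence(p, [2.3e-9, 1.15e-9], dense)
        peak_fast = dense[np.argmax(prof_fast.r1)]
        peak_slow = dense[np.argmax(prof_slow.r1)]
        assert peak_slow < peak_fast
        # relaxivity at the 64 mT frequency is enhanced in the slow medium
        j = np.argmin(np.abs(dense - 2.72))
        assert prof_slow.r1[j] > prof_fast.r1[j]

    def test_low_frequency_r1_non_increasing_in_D(self):
        p = SPMParams(d_nm=6.5, tau_N=1e-9, mu=1e-19, K_scale=40.0)
        f = np.array([0.01, 0.1, 1.0])
        profs = predict_diffusion_dependence(p, [0.5e-9, 1.0e-9, 2.0e-9, 3.0e-9], f)
        stack = np.array([q.r1 for q in profs])
        assert np.all(np.diff(stack, axis=0) <= 1e-12)

    def test_identity_when_D_unchanged(self):
        p = SPMParams(d_nm=6.5, K_scale=40.0)
        f = np.logspace(-2, 1, 20)
        (prof,) = predict_diffusion_dependence(p, [p.D], f)
        assert np.allclose(prof.r1, spm_r1(f, p), rtol=0, atol=0)
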