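"""Synthetic input generation: defaults, forward models, noise, determinism."""

import numpy as np
import pytest
from scipy import special

from lowfield_relax import (
    build_default_agents,
    circular_tube_layout,
    default_concentrations,
    default_protocol,
    ir_signal,
    larmor_frequency,
    se_signal,
    simulate_magnetization_curve,
    simulate_nmrd_profile,
    simulate_phantom_series,
    spm_params_for_agent,
    sbm_params_for_agent,
    spm_r1,
    true_rates,
)
from lowfield_relax.io import (
    read_image_series,
    read_magnetization_curve,
    read_nmrd_profile,
    write_image_series,
    write_magnetization_curve,
    write_nmrd_profile,
)
from lowfield_relax.synthetic import AcquisitionProtocol, PhantomLayout, TI_64MT


class TestDefaultAgents:
    def test_seven_unique_agents(self, agents):
        assert len(agents) == 7
        assert set(agents) == {"A", "B", "C", "D", "Ferumoxytol",
                               "Ferumoxides", "Gd-BOPTA"}

    def test_largest_particle_properties(self, agents):
        d = agents["D"]
        assert d.core_diameter_nm == 15.7
        assert d.mass_saturation_magnetization == 42.4
        assert d.r1_true_per_field[0.064] == 67.0
        assert d.r2_true_per_field[0.064] == 77.5

    def test_chelate_has_no_core(self, agents):
        gd = agents["Gd-BOPTA"]
        assert gd.agent_class == "chelate"
        assert gd.core_diameter_nm is None


class TestTrueRates:
    def test_zero_concentration_gives_background(self, agents):
        r1, r2 = true_rates(agents["D"], 0.0, 0.064, background=(0.35, 1.5))
        assert (r1, r2) == (0.35, 1.5)

    def test_hand_value(self, agents):
        r1, _ = true_rates(agents["D"], 0.06, 0.064, background=(0.5, 1.5))
        assert r1 == pytest.approx(0.5 + 67.0 * 0.06, rel=1e-14)  # 4.52

    def test_linearity(self, agents):
        bg = (0.35, 1.5)
        r1a, r2a = true_rates(agents["B"], 0.1, 0.064, bg)
        r1b, r2b = true_rates(agents["B"], 0.2, 0.064, bg)
        assert r1b - bg[0] == pytest.approx(2 * (r1a - bg[0]))
        assert r2b - bg[1] == pytest.approx(2 * (r2a - bg[1]))

    def test_missing_field_named_in_error(self, agents):
        with pytest.raises(KeyError, match="1.5"):
            true_rates(agents["A"], 0.1, 1.5)


class TestProtocolAndLayout:
    def test_published_timings(self):
        p64 = default_protocol(0.064, "inversion_recovery")
        assert p64.times_ms[0] == 100.0 and p64.times_ms[-1] == 2500.0
        assert p64.tr_ms == 3000.0 and len(p64.times_ms) == 15
        e64 = default_protocol(0.064, "echo_decay")
        assert e64.times_ms[0] == 37.0 and e64.times_ms[-1] == 702.0
        p3 = default_protocol(3.0, "inversion_recovery")
        assert p3.times_ms[0] == 50.0 and p3.tr_ms == 10000.0

    def test_3T_series_omits_blank(self):
        assert 0.0 in default_concentrations(0.064)
        assert 0.0 not in default_concentrations(3.0)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionProtocol(0.064, "inversion_recovery",
                                np.array([100.0, 50.0]), 3000.0)
        with pytest.raises(ValueError):
            AcquisitionProtocol(0.064, "inversion_recovery",
                                np.array([100.0, 4000.0]), 3000.0)

    def test_overlapping_tubes_rejected(self):
        with pytest.raises(ValueError):
            PhantomLayout(shape=(32, 32, 1), tube_centers=[(10, 10), (12, 10)],
                          tube_radius=3.0, assignments=[("A", 0.0), ("A", 0.1)])

    def test_layout_requires_assignment_per_tube(self):
        with pytest.raises(ValueError):
            PhantomLayout(shape=(32, 32, 1), tube_centers=[(10, 10)],
                          tube_radius=3.0, assignments=[])


class TestPhantomSeries:
    def _setup(self, noise=0.0, seed=None, mode="inversion_recovery"):
        agents = {a.name: a for a in build_default_agents()}
        layout = circular_tube_layout("B", [0.0, 0.06, 0.25], shape=(32, 32, 1),
                                      tube_radius=3.0)
        proto = default_protocol(0.064, mode, noise_sigma=noise, seed=seed)
        return agents["B"], layout, proto, simulate_phantom_series(
            layout, proto, [agents["B"]])

    def test_noiseless_voxels_follow_signal_models(self):
        agent, layout, proto, series = self._setup()
        for i, (_, conc) in enumerate(layout.assignments):
            r1, _ = true_rates(agent, conc, 0.064, layout.background_rates)
            expected = ir_signal(proto.times_ms, proto.tr_ms, 1000.0 / r1, 1.0, 1.0)
            tube = layout.tube_mask(i)
            got = series.data[tube, :]
            assert np.allclose(got, expected, rtol=0, atol=0), conc

    def test_noiseless_echo_decay(self):
        agent, layout, proto, series = self._setup(mode="echo_decay")
        _, r2 = true_rates(agent, 0.25, 0.064, layout.background_rates)
        tube = layout.tube_mask(2)
        expected = se_signal(proto.times_ms, 1000.0 / r2, 1.0)
        assert np.allclose(series.data[tube, :], expected, rtol=0, atol=0)

    def test_seed_determinism(self):
        *_, s1 = self._setup(noise=0.02, seed=42)
        *_, s2 = self._setup(noise=0.02, seed=42)
        *_, s3 = self._setup(noise=0.02, seed=43)
        assert np.array_equal(s1.data, s2.data)
        assert not np.array_equal(s1.data, s3.data)

    def test_roi_mean_matches_rician_expectation(self):
        # Monte-Carlo oracle: tube-ROI mean over many noise realizations
        # agrees with the analytic Rician mean of the noiseless signal
        agent, layout, proto, _ = self._setup()
        sigma = 0.01
        r1, _ = true_rates(agent, 0.06, 0.064, layout.background_rates)
        clean = ir_signal(proto.times_ms, proto.tr_ms, 1000.0 / r1, 1.0, 1.0)
        j = len(proto.times_ms) - 1  # long-TI sample, signal well above noise
        tube = layout.tube_mask(1)
        rng = np.random.default_rng(3)
        means = []
        proto500 = AcquisitionProtocol(0.064, "inversion_recovery",
                                       proto.times_ms, proto.tr_ms,
                                       noise_sigma=sigma)
        for _ in range(500):
            proto500.seed = int(rng.integers(2**31))
            s = simulate_phantom_series(layout, proto500, [agent])
            means.append(s.data[tube, j].mean())
        snr2 = (clean[j] / sigma) ** 2
        # exp(-x)·I_n(x) via the scaled Bessel function avoids overflow
        analytic = (
            sigma * np.sqrt(np.pi / 2.0)
            * ((1 + snr2 / 2) * special.ive(0, snr2 / 4)
               + (snr2 / 2) * special.ive(1, snr2 / 4))
        )
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - analytic) < 3 * se


class TestMagnetizationCurves:
    def test_zero_field_zero_remanence(self, agents):
        curve = simulate_magnetization_curve(agents["D"])
        assert curve.M_Am2_per_kg[0] == 0.0

    def test_saturation_with_large_moment(self, agents):
        big = type(agents["D"])(**{**agents["D"].__dict__, "mu_J_per_T": 1e-17})
        curve = simulate_magnetization_curve(big)
        assert curve.M_Am2_per_kg[-1] / 42.4 > 0.99

    def test_chelate_is_linear(self, agents):
        curve = simulate_magnetization_curve(agents["Gd-BOPTA"])
        assert np.allclose(np.diff(curve.M_Am2_per_kg, n=2), 0.0, atol=1e-12)

    def test_determinism(self, agents):
        c1 = simulate_magnetization_curve(agents["B"], rel_noise=0.01, seed=9)
        c2 = simulate_magnetization_curve(agents["B"], rel_noise=0.01, seed=9)
        assert np.array_equal(c1.M_Am2_per_kg, c2.M_Am2_per_kg)


class TestNMRDProfiles:
    def test_noiseless_equals_forward_model(self, agents):
        p = spm_params_for_agent(agents["C"], 21.5)
        prof = simulate_nmrd_profile("spm", p, rel_noise=0.0)
        assert np.array_equal(prof.r1, spm_r1(prof.freqs_MHz, p))

    def test_default_grid_spans_instrument_range(self, agents):
        prof = simulate_nmrd_profile("spm", spm_params_for_agent(agents["C"], 21.5),
                                     rel_noise=0.0)
        assert prof.freqs_MHz[0] == pytest.approx(0.01)
        assert prof.freqs_MHz[-1] == pytest.approx(40.0)

    def test_seeded_repeat_identical(self, agents):
        p = spm_params_for_agent(agents["C"], 21.5)
        p1 = simulate_nmrd_profile("spm", p, rel_noise=0.01, seed=4)
        p2 = simulate_nmrd_profile("spm", p, rel_noise=0.01, seed=4)
        assert np.array_equal(p1.r1, p2.r1)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            simulate_nmrd_profile("bogus", None)

    def test_amplitude_anchored_to_known_dispersion_value(self, agents):
        for name in ("A", "D", "Ferumoxytol"):
            p = spm_params_for_agent(agents[name], 37.0)
            got = float(spm_r1(larmor_frequency(0.064), p))
            assert got == pytest.approx(agents[name].nmrd_r1_true[37.0], rel=1e-9)
        ps = sbm_params_for_agent(agents["Gd-BOPTA"], 21.5)
        from lowfield_relax import sbm_r1
        assert float(sbm_r1(larmor_frequency(0.064), ps)) == pytest.approx(6.9, rel=1e-9)


class TestFileRoundTrips:
    def test_image_series_nifti_roundtrip(self, tmp_path, agents):
        layout = circular_tube_layout("A", [0.0, 0.06], shape=(28, 28, 1),
                                      tube_radius=3.0)
        proto = default_protocol(0.064, "inversion_recovery", noise_sigma=0.01, seed=1)
        series = simulate_phantom_series(layout, proto, [agents["A"]])
        write_image_series(series, tmp_path, "test")
        back = read_image_series(tmp_path, "test")
        assert np.allclose(back.data, series.data, rtol=1e-6)
        assert np.array_equal(back.index_ms, series.index_ms)
        assert back.mode == series.mode

    def test_curve_csv_roundtrip(self, tmp_path, agents):
        curve = simulate_magnetization_curve(agents["B"], rel_noise=0.01, seed=2)
        write_magnetization_curve(curve, tmp_path / "c.csv")
        back = read_magnetization_curve(tmp_path / "c.csv")
        assert np.allclose(back.M_Am2_per_kg, curve.M_Am2_per_kg)

    def test_profile_csv_roundtrip(self, tmp_path, agents):
        prof = simulate_nmrd_profile("spm", spm_params_for_agent(agents["B"], 21.5),
                                     rel_noise=0.01, seed=3)
        write_nmrd_profile(prof, tmp_path / "p.csv")
        back = read_nmrd_profile(tmp_path / "p.csv")
        assert np.allclose(back.r1, prof.r1)
        assert np.allclose(back.sd, prof.sd)
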