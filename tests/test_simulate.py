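"""Scene simulator: motion physics, determinism, multipath structure."""

import numpy as np
import pytest

import bioradar as br
from bioradar.ranging import decompose_ranges, highpass_filter
from bioradar.timefreq import band_spectrum

from conftest import make_breathing_scene


class TestChestMotion:
    def test_zero_amplitude_is_identically_zero(self, radar):
        t = np.linspace(0, 60, 1200)
        tr = br.simulate_chest_motion(br.ChestMotionParams(0.0, 0.3), t, radar)
        assert np.all(tr.x == 0) and np.all(tr.v == 0) and np.all(tr.f_D == 0)

    def test_peak_doppler_frequency_closed_form(self, radar):
        # max |f_D| = 4 pi f_resp x_max / lambda
        t = np.linspace(0, 60, 48000)
        tr = br.simulate_chest_motion(br.ChestMotionParams(0.005, 0.3), t, radar)
        expected = 4 * np.pi * 0.3 * 0.005 / radar.wavelength
        assert expected == pytest.approx(0.0817, abs=2e-4)
        assert np.max(np.abs(tr.f_D)) == pytest.approx(expected, rel=1e-6)

    def test_velocity_is_derivative_of_displacement(self, radar):
        t = np.linspace(0, 60, 6000)
        tr = br.simulate_chest_motion(br.ChestMotionParams(0.004, 0.25, 1.0), t, radar)
        v_num = np.gradient(tr.x, t)
        # interior points only: np.gradient is first-order at the ends
        assert np.allclose(v_num[1:-1], tr.v[1:-1], atol=5e-3 * np.max(np.abs(tr.v)))

    def test_doppler_sign_oscillates_at_respiratory_rate(self, radar):
        # f_resp stable over the minute; f_D changes sign twice per cycle
        t = np.linspace(0, 60, 12000)
        tr = br.simulate_chest_motion(br.ChestMotionParams(0.005, 0.3), t, radar)
        sign_changes = np.sum(np.diff(np.sign(tr.f_D)) != 0)
        assert sign_changes == pytest.approx(2 * 0.3 * 60, abs=1)

    def test_rejects_nonfinite_parameters(self):
        with pytest.raises(ValueError):
            br.ChestMotionParams(np.nan, 0.3)
        with pytest.raises(ValueError):
            br.ChestMotionParams(0.005, np.inf)

    def test_rejects_unsorted_time_grid(self, radar):
        with pytest.raises(ValueError):
            br.simulate_chest_motion(
                br.ChestMotionParams(0.005, 0.3), np.array([0.0, 2.0, 1.0]), radar
            )


class TestMeasurement:
    def test_static_scene_is_constant_in_time(self, radar):
        scene = br.SceneConfig(
            label=br.WITHOUT_PERSON,
            paths=(br.MultipathComponent(3, 1.0, 0.0),),
        )
        m = br.simulate_measurement(scene, radar, seed=0)
        assert np.allclose(m.tones, m.tones[:, :1])

    def test_same_seed_is_bit_identical(self, radar):
        scene = make_breathing_scene()
        a = br.simulate_measurement(scene, radar, seed=42)
        b = br.simulate_measurement(scene, radar, seed=42)
        np.testing.assert_array_equal(a.tones, b.tones)

    def test_unresolvable_range_bin_rejected(self, radar):
        scene = br.SceneConfig(
            label=br.WITHOUT_PERSON,
            paths=(br.MultipathComponent(radar.n_tones // 2, 1.0, 0.0),),
        )
        with pytest.raises(ValueError, match="unresolvable"):
            br.simulate_measurement(scene, radar, seed=0)

    def test_label_motion_consistency_enforced(self):
        with pytest.raises(ValueError):
            br.SceneConfig(label=br.WITH_PERSON, motion=None)
        with pytest.raises(ValueError):
            br.SceneConfig(
                label=br.WITHOUT_PERSON,
                motion=br.ChestMotionParams(0.005, 0.3),
            )

    def test_uncoupled_bin_is_immune_to_motion_and_disturbance(self, radar):
        # motion perpendicular to the wave in one bin: that sub-signal stays
        # flat while the coupled bin carries periodicity and the transient
        dist = br.Disturbance(start=25.0, duration=5.0, amplitude=1.0, range_bins=(1,))
        scene = br.SceneConfig(
            label=br.WITH_PERSON,
            motion=br.ChestMotionParams(0.005, 0.3),
            paths=(
                br.MultipathComponent(1, 1.0, 1.0),
                br.MultipathComponent(2, 1.0, 0.0),
            ),
            disturbance=dist,
        )
        m = br.simulate_measurement(scene, radar, seed=0)
        subs = decompose_ranges(m, 5)
        bin1, bin2 = subs[0].series, subs[1].series
        # bin 2 stays essentially static (only tone-dependent phase leakage)
        assert np.std(np.abs(bin2)) < 5e-3 * np.mean(np.abs(bin2))
        assert np.std(np.angle(bin1 / bin1[0])) > 1e-2
        assert np.std(np.angle(bin1 / bin1[0])) > 20 * np.std(np.angle(bin2 / bin2[0]))

    def test_spectral_placement_of_breathing_line(self, radar):
        # low-noise with-person scene: band argmax within one FFT step of f_resp
        scene = make_breathing_scene(f_resp=0.27, noise_sigma=1e-4, drift=0.0)
        m = br.simulate_measurement(scene, radar, seed=0)
        sub = highpass_filter(decompose_ranges(m, 5)[1])
        sp = band_spectrum(sub)
        df = 1.0 / m.T_meas
        assert abs(sp.f_fft - 0.27) <= df

    def test_empty_scene_band_edge_capture(self, radar):
        # drift-only scene: residual low-frequency energy captures f_fft at
        # the lower band edge, not at a breathing-like frequency
        scene = br.SceneConfig(
            label=br.WITHOUT_PERSON,
            clutter_amplitudes=(0.0, 0.5, 0.5, 0.5, 0.5, 0.5),
            drift=0.3,
            noise_sigma=0.0,
        )
        m = br.simulate_measurement(scene, radar, seed=2)
        sub = highpass_filter(decompose_ranges(m, 5)[0])
        assert band_spectrum(sub).f_fft < 0.15


class TestDataset:
    def test_minimal_dataset_counts(self):
        ms, manifest = br.generate_dataset(1, 1, ranges_per_measurement=1, seed=0)
        assert len(ms) == 2
        assert manifest.attrs["n_observations"] == 2

    def test_labels_and_manifest_align(self):
        ms, manifest = br.generate_dataset(3, 2, seed=0)
        assert [m.label for m in ms] == list(manifest["label"])
        assert sum(m.label == br.WITH_PERSON for m in ms) == 3

    def test_body_position_sampling_proportions(self):
        rng = np.random.default_rng(0)
        n = 1000
        scenes = [br.sample_scene(br.WITH_PERSON, rng=rng) for _ in range(n)]
        counts = {p: 0 for p in br.BODY_POSITIONS}
        for s in scenes:
            counts[s.body_position] += 1
        for pos, w in zip(br.BODY_POSITIONS, br.BODY_POSITION_WEIGHTS):
            # within ~4 binomial standard deviations
            tol = 4 * np.sqrt(w * (1 - w) / n)
            assert abs(counts[pos] / n - w) < tol

    def test_dataset_determinism(self):
        a, ma = br.generate_dataset(2, 2, seed=9)
        b, mb = br.generate_dataset(2, 2, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.tones, y.tones)
        assert ma.equals(mb)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            br.generate_dataset(0, 1)
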