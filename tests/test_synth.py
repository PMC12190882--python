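"""Synthetic EEG generator: topographies, noise calibration, sessions."""

import numpy as np
import pytest

import cvepsim as cv
from cvepsim.montage import FULL16, REDUCED6
from cvepsim.synth import make_noise, subject_focus, NoiseSpec


class TestMontage:
    def test_full16_and_reduced6_definitions(self):
        assert len(FULL16) == 16
        assert len(REDUCED6) == 6
        assert REDUCED6.issubset(FULL16)
        assert FULL16.reference == "Cz" and FULL16.ground == "AFz"
        assert REDUCED6.names == ("PO3", "POz", "PO4", "O1", "Oz", "O2")

    def test_unknown_electrode_rejected(self):
        with pytest.raises(ValueError, match="Fz"):
            FULL16.indices_of(cv.Montage(names=("Fz",)))


class TestSubjectSampling:
    def test_same_seed_gives_identical_subject(self):
        a = cv.sample_subject(3, focus_target=0.5)
        b = cv.sample_subject(3, focus_target=0.5)
        assert np.array_equal(a.topography, b.topography)
        assert a.latency == b.latency
        assert a.noise_sigma == b.noise_sigma

    @pytest.mark.parametrize("focus", [0.0, 0.25, 0.7, 1.0])
    def test_focus_is_recoverable(self, focus):
        sub = cv.sample_subject(4, focus_target=focus)
        assert subject_focus(sub) == pytest.approx(focus, abs=1e-9)

    def test_focus_one_puts_all_mass_on_reduced6(self):
        sub = cv.sample_subject(5, focus_target=1.0)
        keep = FULL16.indices_of(REDUCED6)
        outside = np.setdiff1d(np.arange(16), keep)
        assert np.all(sub.topography[outside] == 0)

    def test_focus_zero_zeroes_the_retained_channels(self):
        sub = cv.sample_subject(5, focus_target=0.0)
        keep = FULL16.indices_of(REDUCED6)
        assert np.all(sub.topography[keep] == 0)

    def test_focus_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cv.sample_subject(1, focus_target=1.5)

    def test_topography_unit_norm(self):
        sub = cv.sample_subject(6, focus_target=0.3)
        assert np.linalg.norm(sub.topography) == pytest.approx(1.0)


class TestEpochSimulation:
    def test_noiseless_oz_trace_is_kernel_filtered_timeline(self, subject, timelines):
        ep = cv.simulate_epoch(subject, timelines[0], rng=0, noise_scale=0.0)
        from cvepsim.synth import _evoked_waveform

        s = _evoked_waveform(
            timelines[0].as_pm1(), subject.kernel,
            int(round(subject.latency * subject.fs)),
        )
        oz = ep.data[FULL16.index("Oz")]
        r = np.corrcoef(oz, s)[0, 1]
        assert abs(r) > 0.999

    def test_snr_calibration_contract(self, timelines):
        # montage-average evoked/noise variance ratio matches snr_db
        sub = cv.sample_subject(8, focus_target=0.6, snr_db=0.0)
        ratios = []
        for i in range(100):
            _, evoked, noise = cv.simulate_epoch(
                sub, timelines[0], rng=i, return_parts=True
            )
            ratios.append(np.mean(evoked**2) / np.mean(noise**2))
        measured_db = 10 * np.log10(np.mean(ratios))
        assert abs(measured_db - 0.0) < 0.5

    def test_evoked_component_independent_of_noise_seed(self, subject, timelines):
        _, ev1, n1 = cv.simulate_epoch(subject, timelines[1], rng=1, return_parts=True)
        _, ev2, n2 = cv.simulate_epoch(subject, timelines[1], rng=2, return_parts=True)
        assert np.array_equal(ev1, ev2)
        assert not np.array_equal(n1, n2)

    def test_empty_timeline_rejected(self, subject):
        from cvepsim.codes import SampleTimeline

        empty = SampleTimeline(np.array([]), fs=600.0, n_cycles=1, cycle_duration=0.0)
        with pytest.raises(ValueError, match="empty"):
            cv.simulate_epoch(subject, empty)

    def test_evoked_energy_conserved_under_topography_rotation(self, timelines):
        # total squared evoked amplitude depends only on the topography norm
        a = cv.sample_subject(9, focus_target=0.3)
        b = cv.sample_subject(10, focus_target=0.8)
        _, ev_a, _ = cv.simulate_epoch(a, timelines[0], rng=0, return_parts=True)
        from dataclasses import replace

        bb = replace(a, topography=b.topography)
        _, ev_b, _ = cv.simulate_epoch(bb, timelines[0], rng=0, return_parts=True)
        assert np.sum(ev_a**2) == pytest.approx(np.sum(ev_b**2), rel=1e-9)


class TestNoise:
    def test_pink_spectral_slope(self):
        # slope of the log-periodogram over 1-40 Hz near -alpha for pure pink
        spec = NoiseSpec(white_fraction=0.0, alpha_fraction=0.0, spatial_corr=0.0)
        rng = np.random.default_rng(11)
        slopes = []
        for _ in range(50):
            x = make_noise(6000, 1, spec, rng)[0]
            f = np.fft.rfftfreq(len(x), 1 / 600.0)
            p = np.abs(np.fft.rfft(x)) ** 2
            band = (f >= 1) & (f <= 40)
            slopes.append(np.polyfit(np.log10(f[band]), np.log10(p[band]), 1)[0])
        assert abs(np.mean(slopes) - (-spec.alpha_exponent)) < 0.3

    def test_unit_variance_per_channel(self):
        rng = np.random.default_rng(12)
        sub = cv.sample_subject(12)
        x = make_noise(3000, 16, sub.noise_spec, rng, mixing=sub.noise_mixing)
        assert np.allclose(x.var(axis=1), 1.0, atol=1e-12)

    def test_spatially_coherent_components_correlate_neighbors(self):
        spec = NoiseSpec(white_fraction=0.0, alpha_fraction=0.0, spatial_corr=0.9)
        from cvepsim.synth import spatial_mixing

        rng = np.random.default_rng(13)
        x = make_noise(6000, 16, spec, rng, mixing=spatial_mixing(spec, FULL16))
        i, j = FULL16.index("O1"), FULL16.index("Oz")
        assert np.corrcoef(x[i], x[j])[0, 1] > 0.5


class TestTrainingSession:
    def test_default_session_is_24_trials_of_1260_samples(self, subject, timelines):
        ts = cv.simulate_training_session(subject, timelines, rng=1)
        assert len(ts) == 24
        assert ts.data.shape == (24, 16, 1260)
        for k in range(1, 5):
            assert (ts.labels == k).sum() == 6

    def test_nb_below_one_rejected(self, subject, timelines):
        with pytest.raises(ValueError):
            cv.simulate_training_session(subject, timelines, nb=0)


class TestRestriction:
    def test_epoch_restriction_keeps_rows_in_order(self, subject, timelines):
        ep = cv.simulate_epoch(subject, timelines[0], rng=0)
        ep6 = cv.restrict_channels(ep, REDUCED6)
        assert ep6.n_channels == 6
        assert np.array_equal(ep6.data, ep.data[FULL16.indices_of(REDUCED6)])

    def test_restriction_to_same_montage_is_identity(self, subject, timelines):
        ep = cv.simulate_epoch(subject, timelines[0], rng=0)
        same = cv.restrict_channels(ep, FULL16)
        assert np.array_equal(same.data, ep.data)

    def test_weight_vector_restriction(self):
        w = np.arange(16.0)
        w6 = cv.restrict_channels(w, REDUCED6, source=FULL16)
        assert np.array_equal(w6, w[FULL16.indices_of(REDUCED6)])

    def test_subject_restriction_preserves_gains_and_noise_level(self, subject):
        sub6 = cv.restrict_channels(subject, REDUCED6)
        assert sub6.n_channels == 6
        keep = FULL16.indices_of(REDUCED6)
        assert np.array_equal(sub6.topography, subject.topography[keep])
        assert sub6.noise_sigma == subject.noise_sigma

    def test_unknown_label_rejected(self, subject):
        with pytest.raises(ValueError):
            cv.restrict_channels(subject, cv.Montage(names=("Cz",)))


class TestDrift:
    def test_drift_preserves_norm_and_updates_focus(self, subject):
        drifted = cv.perturb_topography(subject, 0.5, rng=3)
        assert np.linalg.norm(drifted.topography) == pytest.approx(1.0)
        assert drifted.focus == pytest.approx(subject_focus(drifted))
        cos = drifted.topography @ subject.topography
        assert 0.7 < cos < 1.0

    def test_zero_drift_is_identity(self, subject):
        same = cv.perturb_topography(subject, 0.0, rng=3)
        assert np.allclose(same.topography, subject.topography)
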