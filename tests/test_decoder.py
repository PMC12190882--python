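"""Online selection loop: buffering, evaluation, margin thresholding."""

import numpy as np
import pytest

import cvepsim as cv
from cvepsim.decoder import (
    DecoderConfig,
    DecoderState,
    Evaluation,
    decode_stream,
    evaluate,
    maybe_select,
    push_block,
    run_selection,
    stream_from_subject,
)
from cvepsim.montage import REDUCED6
from cvepsim.cca import restrict_model
from cvepsim.synth import restrict_channels


@pytest.fixture()
def cfg():
    return DecoderConfig()


def fresh_state(cfg, m=16):
    return DecoderState.empty(m, cfg, cycle_len=630)


class TestBuffer:
    def test_one_block_buffers_30_samples(self, cfg):
        st = fresh_state(cfg)
        push_block(st, np.ones((16, 30)))
        assert st.n_y == 30
        assert st.elapsed == pytest.approx(0.05)

    def test_reset_clears_buffer(self, cfg):
        st = fresh_state(cfg)
        push_block(st, np.ones((16, 30)))
        st.reset()
        assert st.n_y == 0

    def test_slide_arithmetic_after_42_pushes(self, cfg):
        # hand count: 42 pushes x 30 = 1260 samples exactly fill the buffer
        st = fresh_state(cfg)
        for _ in range(42):
            push_block(st, np.zeros((16, 30)))
        assert st.n_y == 1260
        assert st.code_phase == (42 * 30 - 1260) % 630 == 0

    def test_slide_drops_oldest_and_advances_phase(self, cfg):
        st = fresh_state(cfg)
        for i in range(50):
            push_block(st, np.full((16, 30), float(i)))
        assert st.n_y == 1260
        assert st.code_phase == (50 * 30 - 1260) % 630
        assert st.buffer[0, 0] == 8.0  # blocks 0..7 were dropped

    def test_wrong_shape_rejected(self, cfg):
        st = fresh_state(cfg)
        with pytest.raises(ValueError):
            push_block(st, np.zeros((16, 29)))


class TestEvaluate:
    def test_below_minimum_samples_raises(self, cfg, trained):
        st = fresh_state(cfg)
        push_block(st, np.zeros((16, 30)))
        with pytest.raises(ValueError, match="required before evaluation"):
            evaluate(st, trained)

    def test_margin_zero_when_all_lambdas_tie(self):
        ev = Evaluation(lambdas=np.array([0.4, 0.4, 0.4, 0.4]), margin=0.0, best=1)
        assert maybe_select(ev, DecoderConfig()) is None

    def test_noiseless_buffer_from_class2_decodes_class2(
        self, noiseless_subject, cfg
    ):
        from cvepsim.study import calibrate_subject

        model = calibrate_subject(noiseless_subject, rng=1, noise_scale=0.0)
        blocks = stream_from_subject(
            noiseless_subject, 2, model, cfg, rng=2, noise_scale=0.0
        )
        ev = None
        st = fresh_state(cfg)
        for i, b in enumerate(blocks):
            push_block(st, b)
            if st.n_y >= cfg.min_eval_samples:
                ev = evaluate(st, model)
                break
        assert ev.best == 2

    def test_margin_bounds_on_random_buffers(self, trained, cfg):
        rng = np.random.default_rng(3)
        for _ in range(200):
            st = fresh_state(cfg)
            st.buffer[:, :630] = rng.standard_normal((16, 630))
            st.n_y = 630
            ev = evaluate(st, trained)
            assert 0.0 <= ev.margin <= 2.0
            assert np.all(np.abs(ev.lambdas) <= 1.0)

    def test_montage_mismatch_raises(self, trained, cfg):
        st = fresh_state(cfg, m=6)
        st.n_y = 630
        with pytest.raises(ValueError, match="mismatch"):
            evaluate(st, trained)


class TestMaybeSelect:
    @pytest.mark.parametrize(
        "margin,expect", [(0.20, 2), (0.15, None), (0.10, None)]
    )
    def test_strict_threshold(self, margin, expect):
        ev = Evaluation(lambdas=np.array([0.1, 0.5, 0.2, 0.1]), margin=margin, best=2)
        assert maybe_select(ev, DecoderConfig(beta=0.15)) == expect


class TestRunSelection:
    def test_high_snr_selections_hit_target(self, cfg):
        from cvepsim.study import calibrate_subject

        sub = cv.sample_subject(21, focus_target=0.7, snr_db=10.0)
        model = calibrate_subject(sub, rng=22)
        rng = np.random.default_rng(23)
        hits = 0
        for i in range(100):
            ev = run_selection(sub, (i % 4) + 1, model, cfg, rng)
            hits += int(not ev.timed_out and ev.predicted == ev.true_class)
        assert hits >= 95

    def test_impossible_beta_always_times_out(self, subject, trained):
        cfg = DecoderConfig(beta=2.5, max_trial_seconds=3.0)
        rng = np.random.default_rng(24)
        for k in (1, 2):
            ev = run_selection(subject, k, trained, cfg, rng)
            assert ev.timed_out and ev.predicted is None

    def test_latency_at_least_one_code_cycle(self, subject, trained, cfg):
        rng = np.random.default_rng(25)
        for k in range(1, 5):
            ev = run_selection(subject, k, trained, cfg, rng)
            if not ev.timed_out:
                assert ev.latency >= cfg.min_eval_samples / cfg.fs

    def test_deterministic_given_seeds(self, subject, trained, cfg):
        a = run_selection(subject, 3, trained, cfg, rng=26)
        b = run_selection(subject, 3, trained, cfg, rng=26)
        assert a.predicted == b.predicted
        assert a.latency == b.latency
        assert np.array_equal(a.lambdas, b.lambdas)

    def test_out_of_range_target_rejected(self, subject, trained, cfg):
        with pytest.raises(ValueError):
            run_selection(subject, 5, trained, cfg, rng=0)


class TestDecodeStreamProperties:
    def _recorded_blocks(self, subject, trained, cfg, seed):
        return list(stream_from_subject(subject, 1, trained, cfg, rng=seed))

    def test_beta_monotonicity_on_fixed_stream(self, subject, trained):
        # raising beta never shortens latency and never adds selections
        blocks = self._recorded_blocks(subject, trained, DecoderConfig(), 30)
        results = []
        for beta in (0.10, 0.15, 0.22, 0.30):
            cfg = DecoderConfig(beta=beta)
            results.append(decode_stream(iter(blocks), trained, cfg, true_class=1))
        latencies = [r.latency if not r.timed_out else np.inf for r in results]
        assert latencies == sorted(latencies)
        selections = [int(not r.timed_out) for r in results]
        assert selections == sorted(selections, reverse=True)

    def test_restricted_decode_equals_zero_padded_filters_on_full_stream(
        self, subject, trained
    ):
        # dropping channels from stream + filters commutes with decoding:
        # lambda sequences are bit-identical to filters zero-padded off-subset
        from dataclasses import replace

        from cvepsim.cca import SpatialFilterPair

        cfg = DecoderConfig(max_trial_seconds=3.0)
        blocks16 = self._recorded_blocks(subject, trained, cfg, 31)
        idx = trained.montage.indices_of(REDUCED6)
        model6 = restrict_model(trained, REDUCED6)

        padded_filters = []
        for f in model6.filters:
            wx = np.zeros(16)
            wy = np.zeros(16)
            wx[idx] = f.w_x
            wy[idx] = f.w_y
            padded_filters.append(
                SpatialFilterPair(wx, wy, f.rho, f.class_index)
            )
        padded_model = replace(trained, filters=padded_filters)

        trace_a, trace_b = [], []
        decode_stream((b[idx] for b in blocks16), model6, cfg, trace=trace_a)
        decode_stream(iter(blocks16), padded_model, cfg, trace=trace_b)
        assert len(trace_a) == len(trace_b) > 0
        for ra, rb in zip(trace_a, trace_b):
            for i in range(1, 5):
                assert ra[f"lambda_{i}"] == pytest.approx(
                    rb[f"lambda_{i}"], abs=1e-12
                )

    def test_accuracy_nondecreasing_in_snr(self):
        from cvepsim.study import calibrate_subject

        cfg = DecoderConfig(max_trial_seconds=4.0)
        mean_acc = []
        for snr in (-30.0, -24.0, -18.0):
            sub = cv.sample_subject(33, focus_target=0.7, snr_db=snr)
            model = calibrate_subject(sub, rng=34)
            rng = np.random.default_rng(35)
            ok = 0
            for i in range(40):
                ev = run_selection(sub, (i % 4) + 1, model, cfg, rng)
                ok += int(not ev.timed_out and ev.predicted == ev.true_class)
            mean_acc.append(ok / 40)
        assert mean_acc[0] <= mean_acc[1] + 0.1
        assert mean_acc[1] <= mean_acc[2] + 0.1


class TestTraceExport:
    def test_csv_export(self, subject, trained, tmp_path, cfg):
        from cvepsim.decoder import export_trace_csv

        trace = []
        run_selection(subject, 1, trained, cfg, rng=36, trace=trace)
        p = tmp_path / "trace.csv"
        export_trace_csv(trace, p)
        import pandas as pd

        df = pd.read_csv(p)
        assert {"elapsed", "lambda_1", "lambda_4", "margin"} <= set(df.columns)
        assert len(df) == len(trace)
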