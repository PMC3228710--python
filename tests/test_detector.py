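import numpy as np
import pandas as pd
import pytest

from emma_eog import (
    DetectorConfig,
    Recording,
    SimulationConfig,
    detect,
    detect_epoch,
    epoch_grid,
    simulate_recording,
    validate_against_reference,
)
from emma_eog.detector import (
    _Thresholds,
    _build_context,
    amplitude_criterion,
    delineate,
    lag2_criterion,
    resolve_adjacent,
)

CFG = DetectorConfig()


def _signal_with_exact_percentiles():
    """32 samples with P85 = 10 and P15 = -10 exactly (order statistics)."""
    values = (
        [-41.0, -12.0, -11.0, -10.0, -10.0, -10.0]
        + list(np.linspace(-9.0, 9.0, 20))
        + [10.0, 10.0, 11.0, 30.0, 45.0, 50.0]
    )
    x = np.array(values)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(x))
    x = x[perm]
    assert np.percentile(x, 85) == 10.0 and np.percentile(x, 15) == -10.0
    return x


class TestAmplitudeCriterion:
    def test_hand_enumerated_keep_reject(self):
        x = _signal_with_exact_percentiles()
        idx = {v: int(np.flatnonzero(x == v)[0]) for v in (45.0, 30.0, -41.0)}
        kept = amplitude_criterion(x, [idx[45.0], idx[30.0], idx[-41.0]], CFG)
        # 45 > 4*P85 = 40 kept; |30| inside (-40, 40) rejected; -41 < -40 kept
        assert kept == [idx[45.0], idx[-41.0]]


class TestLag2Criterion:
    def _toy(self):
        # 32-sample ramp of slope 0.5 (every lag-2 difference = 1.0) with a
        # +20 step at sample 16
        x = 0.5 * np.arange(32)
        x[16:] += 20.0
        return x

    def test_step_survives_ramp_rejected(self):
        x = self._toy()
        keep = lag2_criterion(x, [(14, 18), (24, 26)], CFG)
        # background lag-2 diffs are all 1.0 -> Q95 = 1, threshold = 2;
        # the step's max lag-2 diff is 21, the ramp stretch's is 1
        assert keep == [True, False]

    def test_matches_brute_force_enumeration(self):
        x = self._toy()
        spans = [(14, 18), (24, 26)]
        lag = 2
        diffs = np.abs(x[lag:] - x[:-lag])
        in_span = np.zeros(x.size, bool)
        for s, e in spans:
            in_span[s:e + 1] = True
        bg = diffs[~(in_span[lag:] | in_span[:-lag])]
        thr = 2.0 * np.quantile(bg, 0.95)
        expected = [bool(diffs[max(0, s - lag):e - lag + 1 + lag].max() > thr)
                    for s, e in spans]
        assert lag2_criterion(x, spans, CFG) == expected

    def test_no_background_rejects_none(self):
        x = np.arange(10.0)
        assert lag2_criterion(x, [(0, 9)], CFG) == [True]


class TestDelineate:
    TOY = np.array([0.0, -2.0, 0.0, 8.0, 0.0, -2.0, 0.0])

    def test_toy_sequence(self):
        assert delineate(self.TOY, 3, 1.0) == (1, 3, 5)

    def test_mirrored_sequence_downward(self):
        assert delineate(-self.TOY, 3, -1.0) == (1, 3, 5)

    def test_missing_extremum_returns_none(self):
        assert delineate(np.arange(10.0), 5, 1.0) is None

    def test_simulated_landmark_accuracy(self):
        # 200 constructed deflections with crisp extrema and jittered
        # singularity positions: median |error| <= 1 sample per landmark
        rng = np.random.default_rng(42)
        errs = {"start": [], "peak": [], "end": []}
        for _ in range(200):
            amp = rng.uniform(50, 200)
            rise = rng.integers(2, 6)
            fall = rng.integers(2, 6)
            x = rng.normal(scale=0.01 * amp, size=64)
            p = 32
            s, e = p - rise, p + fall
            x[s] -= 0.25 * amp
            x[e] -= 0.35 * amp
            x[p] += amp
            for i in range(1, rise):
                x[s + i] += amp * (i / rise) - 0.25 * amp * (1 - i / rise)
            for i in range(1, fall):
                x[p + i] += amp * (1 - i / fall) - 0.35 * amp * (i / fall)
            sing = p + int(rng.integers(-2, 3))
            got = delineate(x, sing, 1.0)
            assert got is not None
            errs["start"].append(abs(got[0] - s))
            errs["peak"].append(abs(got[1] - p))
            errs["end"].append(abs(got[2] - e))
        for k, v in errs.items():
            assert np.median(v) <= 1, k


class TestResolveAdjacent:
    THRESH = _Thresholds(amp_hi=40.0, amp_lo=-40.0)

    def _staircase(self, second_peak):
        # flanking dips at 9 and 19; deflection to 60 (peak 12), dip to 25
        # (shared change point 14), deflection to ``second_peak`` (peak 16)
        x = np.zeros(64)
        x[9] = -5.0
        x[10:19] = [10, 30, 60, 45, 25, 40, second_peak, second_peak / 2, 5]
        x[19] = -5.0
        return x

    def test_both_peaks_above_threshold_two_events(self):
        x = self._staircase(80.0)
        tris, _ = resolve_adjacent(x, [12, 16], CFG, [1.0, 1.0], self.THRESH)
        assert [t[1] for t in tris] == [12, 16]
        assert tris[0][2] == tris[1][0]      # shared change point

    def test_second_peak_below_threshold_merged(self):
        x = self._staircase(35.0)
        tris, _ = resolve_adjacent(x, [12, 16], CFG, [1.0, 1.0], self.THRESH)
        assert len(tris) == 1
        s, p, e = tris[0]
        assert p == 12
        assert e > 16                         # end extended to final return

    def test_chain_of_three_matches_hand_enumeration(self):
        # three stacked deflections, middle one sub-threshold -> 2 events
        x = np.zeros(64)
        x[9] = -5.0
        x[10:24] = [5, 30, 70, 40, 20, 30, 38, 25, 15, 35, 65, 30, 10, -4]
        tris, _ = resolve_adjacent(x, [12, 16, 20], CFG, [1.0, 1.0, 1.0], self.THRESH)
        peaks = [t[1] for t in tris]
        assert peaks == [12, 20]
        # hand enumeration: local maxima at 12 (70), 16 (38), 20 (65); the
        # 38 peak fails the 4*P85-style threshold of 40 and is absorbed
        assert len(tris) == 2


def _one_event_recording(pos=640, amp=150.0, dur=6, n=1280, noise=3.0, seed=5):
    from emma_eog.simulate import _pulse
    rng = np.random.default_rng(seed)
    x = rng.normal(scale=noise, size=n)
    x[pos:pos + dur + 1] += amp * _pulse(dur)
    from emma_eog import Hypnogram
    rec = Recording(x, fs=64.0)
    hyp = Hypnogram(["NREM"] * (n // 256))
    return rec, hyp, pos + dur // 2


class TestDetectEpoch:
    def test_boundary_event_detected_once_in_its_epoch(self):
        # peak at sample 2 of epoch 2 (straddles the boundary)
        rec, hyp, _ = _one_event_recording(pos=512 - 3, dur=6)
        det = detect(rec, hyp)
        assert len(det) == 1
        assert det["epoch_index"].iloc[0] == 2

    def test_determinism(self):
        rec, hyp, _ = _one_event_recording()
        eps = epoch_grid(rec, hyp)
        a = detect_epoch(rec, eps[2], CFG)
        b = detect_epoch(rec, eps[2], CFG)
        assert a == b

    def test_single_vs_three_window_agreement_away_from_edges(self):
        cfg3 = DetectorConfig()
        cfg1 = DetectorConfig(window_offsets_s=(0.0,))
        sim = SimulationConfig(hours=0.25, seed=13, amplitude_min=93.0)
        rec, hyp, _ = simulate_recording(sim)
        d3 = detect(rec, hyp, cfg3)
        d1 = detect(rec, hyp, cfg1)

        def interior(df):
            off = df["peak"] % 256
            return set(df.loc[(off >= 32) & (off < 224), "peak"])

        assert interior(d3) == interior(d1)


class TestDetectorProperties:
    def test_scale_equivariance(self, small_sim):
        _, rec, hyp, _ = small_sim
        det1 = detect(rec, hyp)
        rec2 = Recording(rec.eog * 37.5, rec.emg_rms, fs=rec.fs, t0=rec.t0)
        det2 = detect(rec2, hyp)
        assert len(det1) == len(det2)
        assert (det1[["start", "peak", "end"]].to_numpy()
                == det2[["start", "peak", "end"]].to_numpy()).all()

    def test_full_run_determinism(self, small_sim):
        _, rec, hyp, _ = small_sim
        assert detect(rec, hyp).equals(detect(rec, hyp))

    def test_events_ordered_and_non_overlapping(self, small_sim):
        _, rec, hyp, _ = small_sim
        det = detect(rec, hyp).sort_values("start")
        assert (det["start"].to_numpy()[1:] >= det["end"].to_numpy()[:-1]).all()
        assert (det["start"] < det["peak"]).all() and (det["peak"] < det["end"]).all()

    def test_events_pass_criteria_post_hoc(self, small_sim):
        _, rec, hyp, _ = small_sim
        cfg = DetectorConfig()
        det = detect(rec, hyp, cfg)
        ctx = _build_context(rec, hyp, cfg)
        thr = ctx.thresholds
        f = ctx.filtered
        amps = det["amplitude_mV"].to_numpy()
        assert ((amps > thr.amp_hi) | (amps < thr.amp_lo)).all()
        for _, r in det.iterrows():
            # every lag-2 difference touching the span [start, end]
            seg = f[max(0, int(r.start) - 2):min(len(f), int(r.end) + 3)]
            lagmax = np.abs(seg[2:] - seg[:-2]).max()
            assert lagmax > thr.lag2

    def test_noise_only_false_alarms_below_half_per_epoch(self):
        # pure background (no planted events) over > 1000 sleep epochs
        sim = SimulationConfig(hours=1.5, seed=29,
                               rem_rate_rem_stage=0.0, rem_rate_nrem_stage=0.0,
                               arousal_rate_per_min=0.0)
        rec, hyp, truth = simulate_recording(sim)
        assert truth.n_events == 0
        det = detect(rec, hyp)
        n_sleep = int((hyp.stages != "WAKE").sum())
        assert n_sleep >= 1000
        assert len(det) / n_sleep < 0.5


class TestValidation:
    def _frames(self, det_ms, ref_ms):
        return (pd.DataFrame({"peak_ms": det_ms}),
                pd.DataFrame({"peak_ms": ref_ms}))

    def test_perfect_agreement(self):
        det, ref = self._frames([100.0, 5000.0], [100.0, 5000.0])
        res = validate_against_reference(det, ref, n_epochs=4)
        assert res["event"]["sensitivity"] == 1.0 and res["event"]["ppv"] == 1.0
        assert res["epoch"]["specificity"] == 1.0 and res["epoch"]["npv"] == 1.0

    def test_no_detections(self):
        det, ref = self._frames([], [100.0])
        res = validate_against_reference(det, ref, n_epochs=4)
        assert res["event"]["sensitivity"] == 0.0
        assert res["epoch"]["npv"] < 1.0

    def test_empty_reference_and_detection_is_na(self):
        det, ref = self._frames([], [])
        res = validate_against_reference(det, ref, n_epochs=4)
        assert np.isnan(res["event"]["sensitivity"])
        assert np.isnan(res["epoch"]["sensitivity"])

    def test_hand_tabulated_mixed_case(self):
        # 8 true events in distinct epochs, 6 matched; 2 false detections in
        # otherwise event-free epochs; 28 epochs total -> 20 event-free,
        # 18 true negatives at epoch level
        ref = [4000.0 * i + 500.0 for i in range(8)]
        det = list(ref[:6]) + [4000.0 * 10 + 500.0, 4000.0 * 11 + 500.0]
        d, r = self._frames(det, ref)
        res = validate_against_reference(d, r, n_epochs=28)
        assert res["event"]["sensitivity"] == pytest.approx(6 / 8)
        assert res["event"]["ppv"] == pytest.approx(6 / 8)
        t = res["epoch"]["table"]
        assert (t["tp"], t["fp"], t["fn"], t["tn"]) == (6, 2, 2, 18)
        assert res["epoch"]["specificity"] == pytest.approx(18 / 20)
        assert res["epoch"]["npv"] == pytest.approx(18 / 20)
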