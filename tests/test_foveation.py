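import numpy as np
import pytest

from nystcal import (
    FoveationError,
    PipelineConfig,
    WaveformSpec,
    detect_foveations,
    filter_and_differentiate,
    point_of_regard,
    segment_recording,
    window_length,
)
from nystcal.preprocess import FilteredSignal
from nystcal.segmentation import SLOW, QUICK, INVALID, Cycle, CycleSet, PhaseLabels


def make_fs(speed, x=None, y=None, valid=None, rate=1000.0):
    """Hand-built filtered signal for direct foveation unit tests."""
    n = len(speed)
    speed = np.asarray(speed, dtype=float)
    x = np.zeros(n) if x is None else np.asarray(x, dtype=float)
    y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    return FilteredSignal(
        t_ms=np.arange(n) * 1000.0 / rate, x=x, y=y,
        vx=speed.copy(), vy=np.zeros(n), speed=speed.copy(),
        valid=valid, rate=rate, primary="x",
    )


def labels_of(codes):
    return PhaseLabels(np.asarray(codes, dtype=np.int8))


class TestWindowLength:
    def test_single_400ms_slow_phase_gives_40ms(self):
        lab = labels_of([SLOW] * 400 + [QUICK] * 100)
        cyc = Cycle(0, 250, 500, True)
        assert window_length(cyc, lab, 1000.0) == 40

    def test_multiple_slow_runs_summed(self):
        # 100 ms + 60 ms of slow phase in one cycle -> 16 ms window
        codes = [SLOW] * 100 + [QUICK] * 40 + [SLOW] * 60 + [QUICK] * 40
        lab = labels_of(codes)
        cyc = Cycle(0, 120, 240, True)
        assert window_length(cyc, lab, 1000.0) == 16

    def test_short_slow_phase_yields_no_foveation(self):
        # 50 ms slow -> 5 ms window < 7 ms floor: cycle contributes nothing
        codes = [SLOW] * 50 + [QUICK] * 50
        lab = labels_of(codes)
        fs = make_fs(np.ones(100))
        cycles = CycleSet([Cycle(0, 50, 99, True)])
        assert window_length(cycles[0], lab, 1000.0) == 5
        assert detect_foveations(fs, cycles, lab) == []

    def test_zero_slow_samples(self):
        lab = labels_of([QUICK] * 100)
        assert window_length(Cycle(0, 50, 100, True), lab, 1000.0) == 0


class TestDetectFoveations:
    def test_monotone_speed_window_abuts_slow_onset(self):
        # speed strictly increasing through the slow phase, as in an
        # accelerating jerk slow phase: earliest window is minimal
        speed = np.concatenate([np.linspace(1, 30, 300), np.full(50, 200.0)])
        lab = labels_of([SLOW] * 300 + [QUICK] * 50)
        fs = make_fs(speed)
        cycles = CycleSet([Cycle(0, 150, 349, True)])
        (fov,) = detect_foveations(fs, cycles, lab)
        assert fov.start == 0
        assert fov.end == 30  # 10% of 300 slow samples

    def test_sine_window_centred_on_extremum(self, recording_factory):
        t = np.arange(3000) / 1000.0
        rec = recording_factory(2.0 * np.sin(2 * np.pi * 3.0 * t))
        res = segment_recording(rec)
        assert len(res.foveations) > 0
        period = 1000.0 / 3.0
        for f in res.foveations:
            centre = 0.5 * (f.start + f.end)
            # nearest position extremum (quarter-period grid)
            k = np.round((centre - period / 4) / (period / 2))
            extremum = period / 4 + k * period / 2
            assert abs(centre - extremum) <= (f.end - f.start) / 2 + 1

    def test_window_cannot_overrun_extension_limit(self):
        # deep minimum 1.5 window-lengths past the closing peak is out of
        # range; the best in-range window is returned instead
        speed = np.full(200, 50.0)
        speed[40:50] = 10.0  # in-range moderate dip
        speed[112:122] = 0.1  # unreachable deep dip
        lab = labels_of([SLOW] * 200)
        fs = make_fs(speed)
        cycles = CycleSet([Cycle(0, 50, 100, True)])
        cfg = PipelineConfig()
        (fov,) = detect_foveations(fs, cycles, lab, cfg)
        assert fov.start == 40
        # window length is 10% of the 100 slow samples in [0, 100)
        assert fov.end - fov.start == 10

    def test_post_peak_extension_reserves_samples(self):
        # a window extending past the boundary peak claims those samples
        # away from the following cycle
        speed = np.full(300, 50.0)
        speed[95:105] = 0.5  # straddles the peak at 100
        speed[106:116] = 1.0  # next-best, overlapping the reserved region
        speed[150:160] = 5.0
        lab = labels_of([SLOW] * 300)
        fs = make_fs(speed)
        cycles = CycleSet([Cycle(0, 50, 100, True), Cycle(100, 150, 200, True)])
        fovs = detect_foveations(fs, cycles, lab)
        assert fovs[0].start == 95 and fovs[0].end == 105
        assert fovs[1].start >= 105  # reserved hand-off respected

    def test_matches_exhaustive_search_on_simulation(
        self, single_target, foveation_oracle
    ):
        rec, _ = single_target(WaveformSpec(amplitude_deg=4.0), seed=12, blinks=1)
        res = segment_recording(rec)
        got = [(f.cycle_id, f.start, f.end) for f in res.foveations]
        expected = foveation_oracle(res.fs, res.cycles, res.labels)
        assert got == expected

    def test_windows_never_overlap_quick_or_invalid(self, single_target):
        rec, _ = single_target(WaveformSpec(frequency_hz=5.0), seed=13, blinks=2)
        res = segment_recording(rec)
        assert len(res.foveations) > 10
        for f in res.foveations:
            assert res.labels.slow[f.start:f.end].all()
            assert res.fs.valid[f.start:f.end].all()

    @pytest.mark.parametrize("scale", [0.04, 7.0])
    def test_scale_invariance_of_selected_windows(self, single_target, scale):
        rec, _ = single_target(WaveformSpec(), seed=14, dwell_ms=4000)
        res = segment_recording(rec)
        rec2 = rec.copy()
        rec2.x = rec.x * scale
        rec2.y = rec.y * scale
        res2 = segment_recording(rec2)
        assert [(f.start, f.end) for f in res2.foveations] == [
            (f.start, f.end) for f in res.foveations
        ]


class TestPointOfRegard:
    def test_median_is_outlier_robust(self):
        fs = make_fs(np.zeros(3), x=[1.0, 2.0, 100.0], y=[5.0, 6.0, 7.0])
        from nystcal.foveation import FoveationInterval

        fov = FoveationInterval(0, 0, 3, 3.0, 34.3, 6.0, 0.0)
        por = point_of_regard([fov], fs, (0.0, 10.0), skip_initial_ms=0.0)
        assert por.x_raw == 2.0  # median, not the 34.3 mean
        assert por.y_raw == 6.0

    def test_single_symmetric_foveation_is_its_mean(self):
        fs = make_fs(np.zeros(5), x=[1.0, 2.0, 3.0, 4.0, 5.0])
        from nystcal.foveation import FoveationInterval

        fov = FoveationInterval(0, 0, 5, 5.0, 3.0, 0.0, 0.0)
        por = point_of_regard([fov], fs, (0.0, 10.0), skip_initial_ms=0.0)
        assert por.x_raw == 3.0
        assert por.n_foveations == 1

    def test_no_foveations_raises_with_target_name(self):
        fs = make_fs(np.zeros(10))
        with pytest.raises(FoveationError, match="target 3"):
            point_of_regard([], fs, (0.0, 10.0), target_id=3)

    def test_initial_skip_excludes_early_foveations(self):
        from nystcal.foveation import FoveationInterval

        fs = make_fs(np.zeros(1000), x=np.arange(1000, dtype=float))
        early = FoveationInterval(0, 100, 120, 20.0, 110.0, 0.0, 0.0)
        late = FoveationInterval(1, 500, 520, 20.0, 510.0, 0.0, 0.0)
        por = point_of_regard([early, late], fs, (0.0, 1000.0), skip_initial_ms=300.0)
        assert por.n_foveations == 1
        assert por.x_raw == pytest.approx(509.5)

    def test_recovers_fixation_position_on_jerk(self, single_target):
        # 10 s fixation: POR within 5% of the raw waveform amplitude
        rec, truth = single_target(WaveformSpec(amplitude_deg=4.0), seed=15, blinks=1)
        res = segment_recording(rec)
        por = point_of_regard(
            res.foveations, res.fs, (rec.t_ms[0], rec.t_ms[-1]), skip_initial_ms=300.0
        )
        x_true, y_true = truth.transform.apply(0.0, 0.0)
        raw_amp = 4.0 * abs(truth.transform.gain_x)
        assert abs(por.x_raw - x_true) < 0.05 * raw_amp
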