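"""Filtering, epoch extraction, overlap handling and segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tvdfc.ingest import (
    BANDS,
    EventRecord,
    Recording,
    SegmentWindow,
    band_decompose,
    bandpass_filter,
    drop_overlapping_events,
    extract_baseline_epochs,
    extract_event_epoch,
    segment,
    segment_windows,
)
from conftest import make_epoch


def _sine_recording(freq, duration=20.0, sfreq=250.0, n_ch=2):
    t = np.arange(int(duration * sfreq)) / sfreq
    data = np.tile(np.cos(2 * np.pi * freq * t), (n_ch, 1))
    return Recording("sub-01", sfreq, [f"ch{i}" for i in range(n_ch)], data)


def _event(click, subject="sub-01", emotion="happy", **kw):
    defaults = dict(valence=5, arousal=5, dominance=5, liking=3,
                    familiarity=3, relevance=3)
    defaults.update(kw)
    return EventRecord(subject=subject, stimulus="s", click_time=click,
                      emotion=emotion, **defaults)


class TestBandpassFilter:
    def test_stopband_tone_is_suppressed(self):
        rec = bandpass_filter(_sine_recording(50.0), 1.0, 40.0)
        mid = rec.data[0, 500:-500]
        assert np.sqrt(np.mean(mid**2)) < 0.05 * np.sqrt(0.5)

    def test_passband_tone_is_preserved(self):
        rec = bandpass_filter(_sine_recording(10.0), 1.0, 40.0)
        mid = rec.data[0, 500:-500]
        assert np.sqrt(np.mean(mid**2)) == pytest.approx(
            np.sqrt(0.5), rel=0.05
        )

    def test_zero_signal_stays_zero(self):
        rec = _sine_recording(10.0)
        rec.data[:] = 0.0
        out = bandpass_filter(rec, 1.0, 40.0)
        assert not out.data.any()
        assert out.data.shape == rec.data.shape

    def test_band_edges_must_respect_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(_sine_recording(10.0), 1.0, 130.0)


class TestEventEpochs:
    def test_click_at_10s_gives_samples_1000_to_2750(self):
        rec = _sine_recording(5.0)
        rec.data[0] = np.arange(rec.n_samples)  # ramp encodes sample index
        ep = extract_event_epoch(rec, _event(10.0))
        assert ep.data.shape[1] == 1750
        assert ep.data[0, 0] == 1000
        assert ep.data[0, -1] == 2749

    def test_pre_click_underflow_is_rejected(self):
        # a click before 6 s cannot even construct a valid event
        with pytest.raises(ValueError, match="pre-click"):
            _event(5.0)

    def test_window_beyond_recording_end_is_rejected(self):
        rec = _sine_recording(5.0, duration=10.0)
        with pytest.raises(ValueError, match="outside the recording"):
            extract_event_epoch(rec, _event(9.8))

    def test_epoch_is_seven_seconds_at_250hz(self):
        ep = extract_event_epoch(_sine_recording(5.0), _event(8.0))
        assert ep.data.shape[1] == int(7 * 250) == 1750


class TestBaselineEpochs:
    def test_eight_epochs_fit_and_start_in_bounds(self):
        rec = _sine_recording(5.0, duration=80.0)
        eps = extract_baseline_epochs(rec, 8, seed=1)
        assert len(eps) == 8
        for ep in eps:
            assert ep.data.shape[1] == 1750
            assert 10.0 <= ep.baseline_start <= 63.0

    def test_same_seed_reproduces_starts(self):
        rec = _sine_recording(5.0, duration=80.0)
        a = extract_baseline_epochs(rec, 5, seed=3)
        b = extract_baseline_epochs(rec, 5, seed=3)
        assert [e.baseline_start for e in a] == [e.baseline_start for e in b]

    def test_nine_non_overlapping_windows_cannot_fit(self):
        rec = _sine_recording(5.0, duration=80.0)
        with pytest.raises(ValueError, match="max 8"):
            extract_baseline_epochs(rec, 9, seed=0)

    def test_windows_do_not_overlap(self):
        rec = _sine_recording(5.0, duration=80.0)
        starts = sorted(
            e.baseline_start for e in extract_baseline_epochs(rec, 8, seed=2)
        )
        assert all(b - a >= 7.0 - 1e-9 for a, b in zip(starts, starts[1:]))


class TestOverlapRule:
    def test_well_separated_clicks_are_kept(self):
        evs = [_event(20.0), _event(40.0)]
        assert len(drop_overlapping_events(evs)) == 2

    def test_both_members_of_an_overlap_are_dropped(self):
        evs = [_event(20.0), _event(24.0)]  # [14,21) vs [18,25)
        assert drop_overlapping_events(evs) == []

    def test_touching_windows_are_kept_half_open(self):
        evs = [_event(20.0), _event(27.0)]  # [14,21) and [21,28)
        assert len(drop_overlapping_events(evs)) == 2

    def test_overlap_is_per_subject(self):
        evs = [_event(20.0, subject="sub-01"), _event(24.0, subject="sub-02")]
        assert len(drop_overlapping_events(evs)) == 2

    def test_chain_of_overlaps_drops_all_members(self):
        evs = [_event(20.0), _event(24.0), _event(28.0)]
        assert drop_overlapping_events(evs) == []


class TestBandDecompose:
    def test_returns_exactly_six_band_epochs(self):
        ep = make_epoch(np.random.default_rng(0).standard_normal((2, 1750)))
        ep.band = None
        out = band_decompose(ep)
        assert [e.band.name for e in out] == [b.name for b in BANDS]

    def test_25hz_tone_lands_in_upper_beta(self):
        t = np.arange(1750) / 250.0
        ep = make_epoch(np.cos(2 * np.pi * 25.0 * t)[None, :])
        ep.band = None
        out = band_decompose(ep)
        power = {e.band.name: np.mean(e.data**2) for e in out}
        total = sum(power.values())
        assert power["upper_beta"] / total > 0.95

    def test_band_sum_reconstructs_wideband_signal(self):
        # the Butterworth bank is not exactly complementary; crossover
        # leakage keeps the relative L2 error around 15% on broadband noise
        rng = np.random.default_rng(1)
        rec = Recording(
            "sub-01", 250.0, ["ch0"], rng.standard_normal((1, 5000))
        )
        wide = bandpass_filter(rec, 1.0, 40.0)
        ep = make_epoch(wide.data[:, 1000:2750])
        ep.band = None
        recon = sum(e.data for e in band_decompose(ep))
        mid = slice(250, 1500)
        err = np.linalg.norm(recon[:, mid] - ep.data[:, mid])
        assert err / np.linalg.norm(ep.data[:, mid]) < 0.25


class TestSegmentation:
    def test_1750_samples_give_nine_windows_last_at_1400(self):
        ws = segment_windows(1750)
        assert len(ws) == 9
        assert [w.start for w in ws] == [175 * k for k in range(9)]
        assert (ws[-1].start, ws[-1].end) == (1400, 1650)

    def test_single_window_input(self):
        ws = segment_windows(250)
        assert len(ws) == 1
        assert (ws[0].start, ws[0].end) == (0, 250)

    def test_too_short_input_is_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            segment_windows(249)

    def test_segment_slices_match_windows(self):
        data = np.arange(2 * 1750).reshape(2, 1750).astype(float)
        ep = make_epoch(data)
        for w, chunk in segment(ep):
            assert chunk.shape == (2, 250)
            np.testing.assert_array_equal(chunk, data[:, w.start : w.end])

    @given(st.integers(min_value=250, max_value=6000))
    @settings(max_examples=60, deadline=None)
    def test_window_count_matches_bruteforce_enumeration(self, length):
        brute = 0
        start = 0
        while start + 250 <= length:
            brute += 1
            start += 175
        assert len(segment_windows(length)) == brute == 1 + (length - 250) // 175

    def test_window_invariants_are_enforced(self):
        with pytest.raises(ValueError):
            SegmentWindow(index=1, start=100, end=350)
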