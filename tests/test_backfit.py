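"""Backfitting, temporal smoothing and microstate statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microstates import (LabelSequence, MapSet, Recording, backfit, cd_ratios,
                         compute_stats, make_layout, smooth_labels)
from microstates.cluster import CLASS_NAMES


def seq_from(labels, rate=256.0, segments=None):
    labels = np.asarray(labels, dtype=int)
    segments = segments or [(0, labels.size)]
    return LabelSequence(labels=labels, rate=rate, segments=segments,
                        class_names=CLASS_NAMES)


class TestBackfit:
    def test_noiseless_rendering_recovered(self, noiseless_subject, templates):
        rec, seq = noiseless_subject
        out = backfit(rec, templates)
        agree = np.mean(out.labels == seq.labels)
        assert agree > 0.97          # mismatches only at near-zero carrier crossings

    def test_polarity_invariance(self, noiseless_subject, templates):
        rec, _ = noiseless_subject
        flipped = rec.copy(data=-rec.data)
        assert np.array_equal(backfit(rec, templates).labels,
                              backfit(flipped, templates).labels)

    def test_scale_invariance(self, rendered_subject, templates):
        rec, _ = rendered_subject
        scaled = rec.copy(data=7.0 * rec.data)
        assert np.array_equal(backfit(rec, templates).labels,
                              backfit(scaled, templates).labels)

    def test_two_channel_toy_by_hand(self):
        # maps m1=[.707,-.707], m2=[.707,.707]; sample [1,.9] matches m2:
        # |cos| with m2 = 1.343/1.345 vs 0.0707/1.345 with m1
        maps = np.zeros((2, 19))
        maps[0, 0], maps[0, 1] = 0.707, -0.707
        maps[1, 0], maps[1, 1] = 0.707, 0.707
        sample = np.zeros((19, 1))
        sample[0, 0], sample[1, 0] = 1.0, 0.9
        corr = np.abs(maps @ sample[:, 0])
        assert np.argmax(corr) == 1

    def test_flat_sample_inherits_neighbour(self, templates):
        layout = make_layout()
        data = np.zeros((19, 4))
        data[:, 0] = templates.maps[2]
        data[:, 3] = templates.maps[1]
        rec = Recording(data=data, rate=256.0, layout=layout, reference="average")
        out = backfit(rec, templates)
        assert out.labels.tolist() == [2, 2, 2, 1]

    def test_channel_mismatch_rejected(self, templates, rendered_subject):
        rec, _ = rendered_subject
        trunc = templates.maps[:, :10] - templates.maps[:, :10].mean(axis=1,
                                                                     keepdims=True)
        trunc /= np.linalg.norm(trunc, axis=1, keepdims=True)
        with pytest.raises(ValueError):
            backfit(rec, MapSet(maps=trunc))


class TestSmoothing:
    def test_short_intrusion_removed(self):
        labels = [2] * 30 + [3] * 2 + [2] * 30
        out = smooth_labels(seq_from(labels), 82.0)
        assert np.all(out.labels == 2)

    def test_constant_is_fixed_point(self):
        out = smooth_labels(seq_from([1] * 100), 82.0)
        assert np.all(out.labels == 1)

    def test_alternating_labels_leave_no_short_runs(self):
        labels = np.tile([0, 1], 200)
        out = smooth_labels(seq_from(labels), 82.0)   # w=21 at 256 Hz
        runs = np.diff(np.r_[0, np.flatnonzero(np.diff(out.labels)) + 1,
                             out.labels.size])
        assert runs.min() >= 11

    def test_window_arithmetic_82ms_at_256hz(self):
        assert int(round(82.0 * 256.0 / 1000.0)) == 21

    def test_respects_segment_boundaries(self):
        # smoothing a spliced record equals smoothing each span separately
        labels = np.array([2] * 40 + [3] * 8 + [2] * 40)
        split = smooth_labels(seq_from(labels, segments=[(0, 48), (48, 88)]), 82.0)
        first = smooth_labels(seq_from(labels[:48]), 82.0)
        second = smooth_labels(seq_from(labels[48:]), 82.0)
        assert np.array_equal(split.labels,
                              np.concatenate([first.labels, second.labels]))

    def test_sample_count_conserved_and_no_new_classes(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 300)              # only classes 0 and 1
        out = smooth_labels(seq_from(labels), 82.0)
        assert out.labels.size == 300
        assert set(out.labels.tolist()) <= {0, 1}

    def test_window_longer_than_segment_rejected(self):
        with pytest.raises(ValueError):
            smooth_labels(seq_from([0] * 10), 82.0)


class TestComputeStats:
    def test_hand_enumerated_example(self):
        # 10 Hz: A x6, B x4, A x6, C x4  ->  2 s total
        seq = seq_from([0] * 6 + [1] * 4 + [0] * 6 + [2] * 4, rate=10.0)
        st = compute_stats(seq)
        assert st.occurrence.tolist() == [1.0, 0.5, 0.5, 0.0]
        assert st.coverage.tolist() == [60.0, 20.0, 20.0, 0.0]
        assert st.mean_duration[0] == pytest.approx(600.0)
        assert st.mean_duration[1] == pytest.approx(400.0)
        assert st.mean_duration[2] == pytest.approx(400.0)
        assert np.isnan(st.mean_duration[3])

    def test_single_class_degenerate(self):
        seq = seq_from([1] * 500, rate=250.0)
        st = compute_stats(seq)
        assert st.coverage[1] == pytest.approx(100.0)
        assert st.occurrence[1] == pytest.approx(1.0 / 2.0)

    def test_runs_not_counted_across_splices(self):
        labels = [0] * 10 + [0] * 10
        merged = compute_stats(seq_from(labels))
        split = compute_stats(seq_from(labels, segments=[(0, 10), (10, 20)]))
        assert merged.n_runs[0] == 1
        assert split.n_runs[0] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_stats(seq_from([]))

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=300),
           st.sampled_from([128.0, 250.0, 256.0, 500.0]))
    @settings(max_examples=60, deadline=None)
    def test_identities_hold_for_any_sequence(self, labels, rate):
        st_ = compute_stats(seq_from(labels, rate=rate))
        assert st_.coverage.sum() == pytest.approx(100.0, abs=1e-9)
        ok = st_.n_runs > 0
        assert np.allclose(st_.occurrence[ok] * st_.mean_duration[ok] / 1000.0,
                           st_.coverage[ok] / 100.0, atol=1e-9)

    @given(st.lists(st.integers(0, 3), min_size=42, max_size=200))
    @settings(max_examples=40, deadline=None)
    def test_identities_survive_smoothing(self, labels):
        sm = smooth_labels(seq_from(labels), 82.0)
        st_ = compute_stats(sm)
        assert st_.coverage.sum() == pytest.approx(100.0, abs=1e-9)
        ok = st_.n_runs > 0
        assert np.allclose(st_.occurrence[ok] * st_.mean_duration[ok] / 1000.0,
                           st_.coverage[ok] / 100.0, atol=1e-9)


class TestRatios:
    def test_equal_classes_give_unit_ratios(self):
        seq = seq_from(([2] * 10 + [3] * 10) * 5)
        r = cd_ratios(compute_stats(seq))
        assert r.occurrence == pytest.approx(1.0)
        assert r.coverage == pytest.approx(1.0)
        assert r.mean_duration == pytest.approx(1.0)

    def test_coverage_ratio_arithmetic(self):
        # C covers 30 samples, D covers 20 -> ratio 1.5
        seq = seq_from([2] * 30 + [3] * 20 + [0] * 50)
        r = cd_ratios(compute_stats(seq))
        assert r.coverage == pytest.approx(1.5)

    def test_absent_denominator_flagged(self):
        seq = seq_from([2] * 40 + [0] * 40)
        with pytest.warns(UserWarning, match="absent"):
            r = cd_ratios(compute_stats(seq))
        assert np.isnan(r.coverage)
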