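"""Back-fitting contracts: assignment rules, smoothing behavior, and the
closed-form microstate parameters."""

import numpy as np
import pytest

import mstates as ms
from mstates import Recording, TemplateMaps
from mstates.backfit import UNASSIGNED, segmentation_from_sequence
from mstates.exceptions import InvalidArgumentError
from mstates.synth import _run_lengths


class TestAssignLabels:
    def test_polarity_inverted_sample_assigned(self, ortho_templates):
        data = -ortho_templates.maps[1][:, None] * np.ones((1, 3)) * 5.0
        rec = Recording(data=data, sfreq=250.0)
        seg = ms.assign_labels(rec, ortho_templates)
        assert np.all(seg.labels == 1)
        assert np.allclose(seg.abs_corr, 1.0)

    def test_orthogonal_sample_unassigned(self, ortho_templates):
        sample = np.zeros(8)
        sample[4], sample[5] = 1.0, -1.0
        rec = Recording(data=np.tile(sample[:, None], (1, 3)), sfreq=250.0)
        seg = ms.assign_labels(rec, ortho_templates, threshold=0.5)
        assert np.all(seg.labels == UNASSIGNED)

    def test_tie_goes_to_lower_index(self, ortho_templates):
        sample = ortho_templates.maps[0] + ortho_templates.maps[1]
        rec = Recording(data=np.tile(sample[:, None], (1, 3)), sfreq=250.0)
        seg = ms.assign_labels(rec, ortho_templates, threshold=0.0)
        assert np.all(seg.labels == 0)

    def test_channel_mismatch_rejected(self, ortho_templates):
        rec = Recording(data=np.random.default_rng(0).standard_normal((6, 10)), sfreq=250.0)
        with pytest.raises(InvalidArgumentError):
            ms.assign_labels(rec, ortho_templates)

    def test_noiseless_roundtrip(self, truth4, montage64):
        seq = ms.simulate_state_sequence(truth4, 10.0, 250.0, seed=20)
        rec = ms.simulate_recording(truth4, seq, montage64, snr=np.inf, seed=21)
        seg = ms.assign_labels(rec, TemplateMaps(truth4.template_maps), threshold=0.0)
        assert np.array_equal(seg.labels, seq.labels)


class TestSmoothing:
    def test_zero_parameters_identity(self, ortho_templates):
        labels = np.arange(40) % 2
        rec = Recording(data=ortho_templates.maps[labels].T * 9.0, sfreq=250.0)
        seg = ms.assign_labels(rec, ortho_templates, threshold=0.0)
        out = ms.smooth_labels(seg, half_window=0, strength=0)
        assert np.array_equal(out.labels, seg.labels)

    def test_single_sample_flip_removed(self, ortho_templates):
        labels = np.zeros(50, dtype=int)
        labels[25] = 1
        rec = Recording(data=ortho_templates.maps[labels].T * 9.0, sfreq=250.0)
        seg = ms.assign_labels(rec, ortho_templates, threshold=0.0)
        out = ms.smooth_labels(seg)
        assert np.all(out.labels == 0)

    def test_alternating_labels_coalesce(self, ortho_templates):
        labels = np.arange(60) % 2
        rec = Recording(data=ortho_templates.maps[labels].T * 9.0, sfreq=250.0)
        seg = ms.assign_labels(rec, ortho_templates, threshold=0.0)
        out = ms.smooth_labels(seg)
        _, lens = _run_lengths(out.labels)
        assert lens.min() >= 2  # no single-sample runs survive

    def test_unassigned_untouched(self, ortho_templates):
        labels = np.zeros(30, dtype=int)
        data = ortho_templates.maps[labels].T * 9.0
        data[:, 10] = 0.0  # flat sample -> unassigned
        rec = Recording(data=data + 1e-9, sfreq=250.0)
        seg = ms.assign_labels(rec, ortho_templates, threshold=0.5)
        assert seg.labels[10] == UNASSIGNED
        out = ms.smooth_labels(seg)
        assert out.labels[10] == UNASSIGNED


class TestMetrics:
    def test_single_map_closed_form(self):
        seq = ms.StateSequence(labels=np.zeros(1000, dtype=int), sfreq=250.0)
        seg = segmentation_from_sequence(seq, 1)
        m = ms.compute_metrics(seg)
        assert m.loc[0, "coverage_pct"] == pytest.approx(100.0)
        assert m.loc[0, "occurrence_per_s"] == pytest.approx(0.25)
        assert m.loc[0, "mean_duration_ms"] == pytest.approx(4000.0)

    def test_alternating_two_maps_closed_form(self):
        labels = np.repeat(np.arange(40) % 2, 25)
        seg = segmentation_from_sequence(ms.StateSequence(labels, 250.0), 2)
        m = ms.compute_metrics(seg)
        for i in (0, 1):
            assert m.loc[i, "coverage_pct"] == pytest.approx(50.0)
            assert m.loc[i, "mean_duration_ms"] == pytest.approx(100.0)
            assert m.loc[i, "occurrence_per_s"] == pytest.approx(5.0)

    def test_generator_roundtrip_matches_sequence_metrics(self, truth4):
        seq = ms.simulate_state_sequence(truth4, 30.0, 250.0, seed=22)
        seg = segmentation_from_sequence(seq, 4)
        m = ms.compute_metrics(seg)
        truth_m = ms.sequence_metrics(seq, 4)
        assert np.allclose(m["coverage_pct"], truth_m["coverage_pct"], atol=1e-9)
        assert np.allclose(m["mean_duration_ms"], truth_m["mean_duration_ms"], atol=1e-9)
        assert np.allclose(m["occurrence_per_s"], truth_m["occurrence_per_s"], atol=1e-9)

    def test_gev_sums_to_100_for_perfect_fit(self, truth4):
        seq = ms.simulate_state_sequence(truth4, 10.0, 250.0, seed=23)
        seg = segmentation_from_sequence(seq, 4)
        m = ms.compute_metrics(seg)
        assert m["gev_pct"].sum() == pytest.approx(100.0)

    def test_metrics_invariant_to_amplitude(self, truth4, montage64):
        seq = ms.simulate_state_sequence(truth4, 10.0, 250.0, seed=24)
        rec = ms.simulate_recording(truth4, seq, montage64, snr=4.0, seed=25)
        templates = TemplateMaps(truth4.template_maps)
        _, m1 = ms.backfit(rec, templates)
        _, m2 = ms.backfit(rec.copy_with(data=rec.data * 3.0), templates)
        for col in ("gev_pct", "mean_duration_ms", "coverage_pct", "occurrence_per_s"):
            assert np.allclose(m1[col], m2[col], atol=1e-9, equal_nan=True)

    def test_unassigned_reduces_coverage_sum(self, ortho_templates):
        labels = np.zeros(20, dtype=int)
        data = ortho_templates.maps[labels].T * 9.0
        data[:, 5:8] = 1e-12
        rec = Recording(data=data, sfreq=250.0)
        seg = ms.assign_labels(rec, ortho_templates, threshold=0.5)
        m = ms.compute_metrics(seg)
        assert m["coverage_pct"].sum() < 100.0
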