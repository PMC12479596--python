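"""Generator contracts: montage geometry, template separation, semi-Markov
dwell statistics, SNR control, and bitwise reproducibility."""

import numpy as np
import pytest

import mstates as ms
from mstates.exceptions import InvalidArgumentError
from mstates.synth import _run_lengths


class TestMontage:
    def test_positions_distinct_and_upper_hemisphere(self):
        for n in (8, 32, 204):
            pos = ms.make_montage(n)
            assert pos.shape == (n, 3)
            assert np.all(pos[:, 2] >= 0)
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() > 1e-6
            assert np.allclose(np.linalg.norm(pos, axis=1), 1.0)

    def test_deterministic(self):
        assert np.array_equal(ms.make_montage(32), ms.make_montage(32))

    def test_too_few_channels_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ms.make_montage(7)


class TestTemplateMaps:
    def test_average_referenced_unit_norm_separated(self, montage64):
        maps = ms.make_template_maps(4, montage64, seed=3)
        assert maps.shape == (4, 64)
        assert np.allclose(maps.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(np.linalg.norm(maps, axis=1), 1.0)
        corr = np.abs(maps @ maps.T)
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.8

    def test_two_maps_zero_channel_mean(self, montage64):
        maps = ms.make_template_maps(2, montage64, seed=99)
        assert np.allclose(maps.mean(axis=1), 0.0, atol=1e-12)

    def test_seed_dependence(self, montage64):
        a = ms.make_template_maps(4, montage64, seed=1)
        b = ms.make_template_maps(4, montage64, seed=2)
        assert not np.array_equal(a, b)


class TestStateSequence:
    def test_empirical_dwell_matches_target(self, truth4):
        truth = ms.SimulationTruth(
            truth4.template_maps, 80.0, truth4.transition_matrix, seed=0
        )
        seq = ms.simulate_state_sequence(truth, 240.0, 250.0, seed=4)
        metrics = ms.sequence_metrics(seq)
        assert np.all(np.abs(metrics["mean_duration_ms"] - 80.0) <= 5.0)

    def test_single_map_yields_single_run(self, montage64):
        maps = ms.make_template_maps(2, montage64, seed=1)[:1]
        truth = ms.SimulationTruth(maps, [80.0], np.zeros((1, 1)), seed=0)
        seq = ms.simulate_state_sequence(truth, 2.0, 250.0, seed=0)
        labels, lens = _run_lengths(seq.labels)
        assert labels.tolist() == [0] and lens.tolist() == [500]

    def test_uniform_transitions_recovered(self, truth4):
        """Off-diagonal successor frequencies match the uniform row within
        3 standard errors of the multinomial count."""
        seq = ms.simulate_state_sequence(truth4, 600.0, 250.0, seed=5)
        run_labels, _ = _run_lengths(seq.labels)
        counts = np.zeros((4, 4))
        np.add.at(counts, (run_labels[:-1], run_labels[1:]), 1)
        for i in range(4):
            row_n = counts[i].sum()
            p_hat = counts[i] / row_n
            se = np.sqrt((1 / 3) * (2 / 3) / row_n)
            off = np.delete(p_hat, i)
            assert np.all(np.abs(off - 1 / 3) <= 3 * se)

    def test_closed_form_identity(self, truth4):
        seq = ms.simulate_state_sequence(truth4, 30.0, 250.0, seed=6)
        m = ms.sequence_metrics(seq)
        lhs = m["coverage_pct"].to_numpy()
        rhs = (m["occurrence_per_s"] * m["mean_duration_ms"] / 10.0).to_numpy()
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_longer_records_shrink_dwell_standard_error(self, truth4):
        """SE of the empirical mean dwell scales as 1/sqrt(duration):
        quadrupling the record roughly halves it."""

        def spread(duration):
            est = [
                ms.sequence_metrics(
                    ms.simulate_state_sequence(truth4, duration, 250.0, seed=s)
                )["mean_duration_ms"].mean()
                for s in range(30)
            ]
            return np.std(est)

        ratio = spread(15.0) / spread(60.0)
        assert 1.4 <= ratio <= 2.9


class TestRecording:
    def test_snr_ratio_exact(self, truth4, montage64):
        seq = ms.simulate_state_sequence(truth4, 20.0, 250.0, seed=7)
        clean = ms.simulate_recording(truth4, seq, montage64, snr=np.inf, seed=8)
        noisy = ms.simulate_recording(truth4, seq, montage64, snr=4.0, seed=8)
        noise = noisy.data - clean.data
        ratio = np.sqrt((clean.data**2).mean()) / np.sqrt((noise**2).mean())
        assert abs(ratio - 4.0) / 4.0 < 0.05

    def test_noiseless_backfit_recovers_sequence(self, truth4, montage64):
        seq = ms.simulate_state_sequence(truth4, 20.0, 250.0, seed=9)
        rec = ms.simulate_recording(truth4, seq, montage64, snr=np.inf, seed=10)
        seg = ms.assign_labels(rec, ms.TemplateMaps(truth4.template_maps), threshold=0.0)
        assert np.array_equal(seg.labels, seq.labels)

    def test_alpha_band_spectral_peak(self, truth4, montage64):
        seq = ms.simulate_state_sequence(truth4, 30.0, 250.0, seed=11)
        rec = ms.simulate_recording(truth4, seq, montage64, snr=4.0, seed=12)
        rec = ms.preprocess(rec)
        spec = ms.power_spectrum(rec)
        mean_p = spec.mean_over_channels()
        sel = (spec.freqs >= 2) & (spec.freqs <= 45)
        peak_f = spec.freqs[sel][np.argmax(mean_p[sel])]
        assert 8.0 <= peak_f <= 14.0

    def test_bitwise_reproducible(self, truth4, montage64):
        seq = ms.simulate_state_sequence(truth4, 5.0, 250.0, seed=13)
        a = ms.simulate_recording(truth4, seq, montage64, seed=14)
        b = ms.simulate_recording(truth4, seq, montage64, seed=14)
        assert np.array_equal(a.data, b.data)

    def test_channel_mismatch_rejected(self, truth4):
        seq = ms.simulate_state_sequence(truth4, 2.0, 250.0, seed=0)
        with pytest.raises(InvalidArgumentError):
            ms.simulate_recording(truth4, seq, ms.make_montage(32), seed=0)


class TestCohort:
    def test_sizes_and_groups(self, truth4):
        recs, metrics = ms.simulate_cohort(3, truth=truth4, seed=2, duration_s=5.0)
        assert len(recs) == 6
        assert sum(r.group == "A" for r in recs) == 3
        assert set(metrics["group"]) == {"A", "B"}

    def test_dwell_effect_planted_in_group_b(self, truth4):
        effects = ms.GroupEffects(dwell={2: 1.3})
        recs, metrics = ms.simulate_cohort(
            8, truth=truth4, group_effects=effects, seed=3, duration_s=60.0
        )
        map_c = metrics[metrics["map"] == 2]
        mean_a = map_c[map_c["group"] == "A"]["mean_duration_ms"].mean()
        mean_b = map_c[map_c["group"] == "B"]["mean_duration_ms"].mean()
        assert mean_b > mean_a

    def test_null_effect_groups_exchangeable(self, truth4):
        """With effect 1.0, the planted dwell test rejects at roughly the
        nominal rate (here: simply not overwhelmingly)."""
        effects = ms.GroupEffects(dwell={})
        ps = []
        for s in range(10):
            _, metrics = ms.simulate_cohort(
                8, truth=truth4, group_effects=effects, seed=50 + s, duration_s=30.0
            )
            map_c = metrics[metrics["map"] == 2]
            a = map_c[map_c["group"] == "A"]["mean_duration_ms"]
            b = map_c[map_c["group"] == "B"]["mean_duration_ms"]
            ps.append(ms.mann_whitney(a, b).p)
        assert sum(p < 0.05 for p in ps) <= 3
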