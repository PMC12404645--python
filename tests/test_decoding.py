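"""Pairwise decoding: pseudo-trials, schemes, TGA, TFR, ROI, searchlight."""

import numpy as np
import pytest

from maskmvpa.decoding import (
    AccuracyMatrix,
    aggregate_pairs,
    bin_pseudotrials,
    decode_timecourse,
    feature_array,
    pairwise_accuracy,
    roi_decode,
    searchlight_decode,
    sphere_offsets,
    temporal_generalization,
    timefreq_decode,
)
from maskmvpa.design import DesignSpec
from maskmvpa.synthetic import simulate_eeg_dataset
from maskmvpa.tfr import TFRSet

from conftest import make_truth


class TestPseudoTrials:
    def test_53_trials_give_4_bins_of_13(self):
        rng = np.random.default_rng(0)
        trials = np.arange(53.0)[:, None]
        out = bin_pseudotrials(trials, 4, rng)
        assert out.shape == (4, 1)
        # 52 of the 53 values averaged in groups of 13
        total = out.sum() * 13
        assert total != np.arange(53).sum()  # one trial dropped

    def test_four_trials_four_bins_returns_the_trials(self):
        rng = np.random.default_rng(1)
        trials = np.array([[1.0], [2.0], [3.0], [4.0]])
        out = bin_pseudotrials(trials, 4, rng)
        assert sorted(out.ravel().tolist()) == [1.0, 2.0, 3.0, 4.0]

    def test_fixed_rng_reproducible(self):
        trials = np.random.default_rng(2).standard_normal((10, 3))
        a = bin_pseudotrials(trials, 4, np.random.default_rng(7))
        b = bin_pseudotrials(trials, 4, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="cannot fill"):
            bin_pseudotrials(np.zeros((3, 2)), 4, np.random.default_rng(0))


class TestPairwiseAccuracy:
    def test_linearly_separated_classes_decode_perfectly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 6)) + 4.0
        b = rng.normal(size=(4, 6)) - 4.0
        assert pairwise_accuracy(a, b) == 100.0

    def test_shuffled_labels_on_separable_data_hit_chance(self):
        """Label permutation destroys the class structure -> 50% expected."""
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 6)) + 4.0
        b = rng.normal(size=(4, 6)) - 4.0
        pooled = np.vstack([a, b])
        accs = []
        for _ in range(200):
            perm = rng.permutation(8)
            accs.append(pairwise_accuracy(pooled[perm[:4]], pooled[perm[4:]]))
        assert abs(np.mean(accs) - 50.0) < 5.0

    def test_identical_distributions_average_to_chance(self):
        rng = np.random.default_rng(2)
        accs = [
            pairwise_accuracy(rng.normal(size=(4, 6)), rng.normal(size=(4, 6)))
            for _ in range(200)
        ]
        assert abs(np.mean(accs) - 50.0) < 5.0

    def test_single_pseudotrial_rejected(self):
        with pytest.raises(ValueError, match="leave-one-out"):
            pairwise_accuracy(np.ones((1, 3)), np.zeros((1, 3)))


class TestAggregatePairs:
    def setup_method(self):
        values = np.array(
            [
                [np.nan, 60.0, 70.0, 80.0],
                [60.0, np.nan, 90.0, 55.0],
                [70.0, 90.0, np.nan, 65.0],
                [80.0, 55.0, 65.0, np.nan],
            ]
        )
        self.matrix = AccuracyMatrix(values, np.arange(4))

    def test_all_offdiagonal_equals_grand_mean(self):
        mask = ~np.eye(4, dtype=bool)
        assert aggregate_pairs(self.matrix, mask) == pytest.approx(
            self.matrix.grand_mean
        )

    def test_single_pair(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 2] = mask[2, 0] = True
        assert aggregate_pairs(self.matrix, mask) == 70.0

    def test_between_category_mean_hand_computed(self):
        # categories {0,1} vs {2,3}: cells (0,2),(0,3),(1,2),(1,3)
        cat = np.array([0, 0, 1, 1])
        mask = cat[:, None] != cat[None, :]
        expected = np.mean([70.0, 80.0, 90.0, 55.0])
        assert aggregate_pairs(self.matrix, mask) == pytest.approx(expected)

    def test_invalid_masks_rejected(self):
        asym = np.zeros((4, 4), bool)
        asym[0, 1] = True
        with pytest.raises(ValueError, match="symmetric"):
            aggregate_pairs(self.matrix, asym)
        with pytest.raises(ValueError, match="no cells"):
            aggregate_pairs(self.matrix, np.zeros((4, 4), bool))


class TestSchemes:
    def _decode(self, truth, scheme, seed=0, reps=3):
        design = DesignSpec(
            n_objects=4, trials_per_cell=8, n_channels=12,
            tmin_ms=200.0, tmax_ms=400.0, tstep_ms=50.0, n_subjects=1,
        )
        epochs = simulate_eeg_dataset(design, truth, seed=seed)[0]
        res = decode_timecourse(epochs, scheme, n_reps=reps, rng=seed)
        return res.grand_average().mean()

    def test_shared_geometry_cross_matches_within(self):
        """Identical geometry across masks -> cross decodes like within."""
        truth = make_truth(ff_amp=0.0, rec_early=1.0, rec_late=1.0,
                           overlap=1.0, noise=0.8, jitter=0.0)
        within = np.mean([
            self._decode(truth, "within-early"), self._decode(truth, "within-late")
        ])
        cross = self._decode(truth, "cross")
        assert within > 65.0
        assert abs(within - cross) < 10.0

    def test_orthogonal_geometry_kills_cross_decoding(self):
        """Independent pattern geometries per mask: within decodes near
        ceiling while cross sits at chance.  Cross accuracy per pair is
        near-binary (the fixed random projection decides it), so chance
        emerges only in the average over independent geometry draws."""
        truth = make_truth(ff_amp=0.0, rec_early=1.0, rec_late=1.0,
                           overlap=0.0, noise=1.0, jitter=0.0)
        design = DesignSpec(
            n_objects=8, trials_per_cell=8, n_channels=12,
            tmin_ms=200.0, tmax_ms=400.0, tstep_ms=200.0, n_subjects=1,
        )
        cross, within = [], []
        for seed in range(8):
            epochs = simulate_eeg_dataset(design, truth, seed=seed)[0]
            cross.append(
                decode_timecourse(epochs, "cross", n_reps=1, rng=seed)
                .grand_average().mean()
            )
            within.append(
                decode_timecourse(epochs, "within-late", n_reps=1, rng=seed)
                .grand_average().mean()
            )
        assert np.mean(within) > 85.0
        assert abs(np.mean(cross) - 50.0) < 8.0

    def test_missing_mask_condition_rejected(self):
        design = DesignSpec(n_objects=3, trials_per_cell=4, n_channels=4,
                            tstep_ms=200.0, mask_conditions=("early",),
                            n_subjects=1)
        epochs = simulate_eeg_dataset(design, make_truth(), seed=0)[0]
        with pytest.raises(ValueError, match="two mask conditions"):
            decode_timecourse(epochs, "cross", n_reps=1, rng=0)
        with pytest.raises(ValueError, match="not present"):
            decode_timecourse(epochs, "within-late", n_reps=1, rng=0)


class TestTemporalGeneralization:
    def _epochs(self, truth, tstep=50.0):
        design = DesignSpec(
            n_objects=4, trials_per_cell=8, n_channels=12,
            tmin_ms=-100.0, tmax_ms=600.0, tstep_ms=tstep, n_subjects=1,
        )
        return simulate_eeg_dataset(design, truth, seed=3)[0]

    def test_symmetrized_and_diagonal_matches_timecourse(self):
        truth = make_truth(noise=0.8, jitter=0.0)
        epochs = self._epochs(truth)
        tgm = temporal_generalization(epochs, "within-late", n_reps=3, rng=5)
        assert tgm.symmetrized
        np.testing.assert_allclose(tgm.values, tgm.values.T)
        tc = decode_timecourse(epochs, "within-late", n_reps=3, rng=5)
        # same engine, same seed stream -> close but independently binned
        assert np.nanmax(np.abs(np.diag(tgm.values) - tc.grand_average())) < 10.0
        assert abs(np.nanmean(np.diag(tgm.values) - tc.grand_average())) < 2.0

    def test_persistent_code_generalizes_farther_than_transient(self):
        transient = make_truth(ff_amp=1.0, rec_early=0.0, rec_late=0.0,
                               noise=0.3, jitter=0.0)
        persistent = make_truth(ff_amp=0.0, rec_early=1.0, rec_late=1.0,
                                noise=0.3, jitter=0.0)

        def offdiag_spread(truth):
            tgm = temporal_generalization(
                self._epochs(truth), "within-late", n_reps=2, rng=1
            )
            t = tgm.time_ms
            post = (t >= 100) & (t <= 500)
            far = np.abs(np.subtract.outer(t[post], t[post])) >= 200
            return (tgm.values[np.ix_(post, post)][far] > 60).mean()

        assert offdiag_spread(persistent) > offdiag_spread(transient) + 0.3

    def test_phase_shifted_oscillation_gives_below_chance_cells(self):
        """Object-specific oscillatory phase flips the code half a cycle
        later, producing below-chance generalization off the diagonal."""
        truth = make_truth(ff_amp=0.0, rec_early=0.0, rec_late=0.0,
                           osc_amp=1.0, osc_freq=10.0, noise=0.2, jitter=0.0)
        epochs = self._epochs(truth, tstep=25.0)
        tgm = temporal_generalization(epochs, "within-late", n_reps=2, rng=2)
        t = tgm.time_ms
        post = np.flatnonzero((t >= 100) & (t <= 500))

        def offset_mean(offset_ms):
            vals = [
                tgm.values[i, np.argmin(np.abs(t - (t[i] + offset_ms)))]
                for i in post
            ]
            return np.mean(vals)

        assert offset_mean(50.0) < 45.0  # half cycle: clearly below chance
        assert offset_mean(100.0) > 80.0  # full cycle: code realigns


class TestTimeFrequencyDecoding:
    def _tfrset(self, signal_builder, n_trials=8, n_channels=6, seed=0):
        """Coefficients built directly: 2 objects x n_trials, 2 freqs, 3 times."""
        rng = np.random.default_rng(seed)
        n = 2 * n_trials
        coeffs = np.empty((n, n_channels, 2, 3), complex)
        labels = np.repeat([0, 1], n_trials)
        for tr in range(n):
            coeffs[tr] = signal_builder(labels[tr], rng)
        return TFRSet(
            coeffs=coeffs,
            freqs_hz=np.array([10.0, 20.0]),
            time_ms=np.array([0.0, 20.0, 40.0]),
            object_label=labels,
            mask_label=np.array(["late"] * n),
            channel_ids=np.array([f"ch{i}" for i in range(n_channels)]),
        )

    def test_amplitude_code_decodes_from_power_not_phase(self):
        def builder(obj, rng):
            amp = 1.0 + 2.0 * obj + 0.05 * rng.standard_normal((6, 2, 3))
            return amp * np.exp(1j * 0.3)  # common phase

        tfr = self._tfrset(builder)
        p_map = timefreq_decode(tfr, "power", "within-late", n_reps=2, rng=0)
        ph_map = timefreq_decode(tfr, "phase", "within-late", n_reps=2, rng=0)
        assert p_map.mean() > 90.0
        assert abs(ph_map.mean() - 50.0) < 15.0

    def test_phase_code_decodes_from_phase_not_power(self):
        def builder(obj, rng):
            phase = np.pi * obj + 0.05 * rng.standard_normal((6, 2, 3))
            amp = 1.0 + 0.05 * rng.standard_normal((6, 2, 3))
            return amp * np.exp(1j * phase)

        tfr = self._tfrset(builder)
        p_map = timefreq_decode(tfr, "power", "within-late", n_reps=2, rng=0)
        ph_map = timefreq_decode(tfr, "phase", "within-late", n_reps=2, rng=0)
        assert ph_map.mean() > 90.0
        assert abs(p_map.mean() - 50.0) < 15.0

    def test_phase_features_double_the_channel_count(self):
        tfr = self._tfrset(lambda obj, rng: np.ones((6, 2, 3)) * (1 + 1j))
        assert feature_array(tfr, "power").shape[1] == 6
        assert feature_array(tfr, "phase").shape[1] == 12
        with pytest.raises(ValueError, match="'power' or 'phase'"):
            feature_array(tfr, "magnitude")


class TestROIDecoding:
    def _betas(self, distinct=True, noise=0.0, n_runs=12, seed=0):
        rng = np.random.default_rng(seed)
        k, v = 4, 10
        patterns = rng.standard_normal((k, v)) if distinct else np.zeros((k, v))
        betas = patterns[None] + noise * rng.standard_normal((n_runs, k, v))
        if not distinct:
            betas = rng.standard_normal((n_runs, k, v))
        return betas, np.arange(k)

    def test_12_runs_group_into_4_pseudoruns_and_decode_perfectly(self):
        betas, labels = self._betas(distinct=True, noise=0.05)
        res = roi_decode(betas, labels, n_pseudoruns=4, rng=0)
        assert res.grand_mean == 100.0
        assert np.all(np.isnan(np.diag(res.values)))
        np.testing.assert_allclose(res.values, res.values.T)

    def test_pattern_free_betas_decode_at_chance(self):
        accs = []
        for seed in range(10):
            betas, labels = self._betas(distinct=False, seed=seed)
            accs.append(roi_decode(betas, labels, rng=seed).grand_mean)
        assert abs(np.mean(accs) - 50.0) < 8.0

    def test_indivisible_runs_rejected(self):
        betas, labels = self._betas(n_runs=10)
        with pytest.raises(ValueError, match="not divisible"):
            roi_decode(betas, labels, n_pseudoruns=4)


class TestSearchlight:
    def test_sphere_offsets_radius_0_and_1(self):
        assert sphere_offsets(0).shape == (1, 3)
        assert sphere_offsets(1).shape == (7, 3)  # center + 6 face neighbours

    def test_planted_signal_is_localized(self):
        rng = np.random.default_rng(0)
        n_runs, k = 4, 3
        shape = (8, 6, 4)
        vol = 0.3 * rng.standard_normal((n_runs, k) + shape)
        patterns = 2.0 * rng.standard_normal((k, 2, 2, 2))
        vol[:, :, :2, :2, :2] += patterns  # corner cube carries the signal
        mask = np.ones(shape, bool)
        res = searchlight_decode(vol, np.arange(k), mask, radius=1.5,
                                 n_pseudoruns=4, rng=1)
        peak = np.unravel_index(np.nanargmax(res.values), shape)
        assert all(p <= 2 for p in peak)
        corner = res.values[:2, :2, :2].mean()
        outside = res.values[4:, :, :].mean()
        assert corner > outside + 20.0
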