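"""Preprocessing and burst/suppression segmentation."""

import numpy as np
import pytest

from bspquant import segmentation as seg
from bspquant import synthetic as syn


def _record(arr, fs=256.0):
    return seg.EEGRecord(np.asarray(arr, dtype=float), fs)


class TestAverageMontage:
    def test_identical_channels_become_zero(self):
        out = seg.apply_average_montage(_record(np.full((3, 512), 7.0)))
        assert np.allclose(out.samples, 0.0)

    def test_zero_mean_pair_unchanged(self):
        x = np.vstack([np.ones(512), -np.ones(512)])
        out = seg.apply_average_montage(_record(x))
        assert np.allclose(out.samples, x)

    def test_mean_removal_arithmetic(self):
        x = np.zeros((3, 256))
        x[0, 0] = 3.0
        out = seg.apply_average_montage(_record(x))
        assert np.allclose(out.samples[:, 0], [2.0, -1.0, -1.0])

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            seg.apply_average_montage(_record(np.ones((1, 256))))

    def test_idempotent(self, rng):
        r = _record(rng.normal(size=(5, 1024)))
        once = seg.apply_average_montage(r)
        twice = seg.apply_average_montage(once)
        assert np.allclose(once.samples, twice.samples)


class TestBandpass:
    fs = 256.0

    def test_dc_offset_removed(self):
        r = _record(np.full((2, int(self.fs) * 20), 10.0), self.fs)
        out = seg.bandpass(r)
        core = out.samples[:, int(5 * self.fs) : -int(5 * self.fs)]
        assert np.sqrt(np.mean(core**2)) < 0.1

    @pytest.mark.parametrize(
        "freq,lo_gain,hi_gain", [(10.0, 0.95, 1.05), (80.0, 0.0, 0.10)]
    )
    def test_frequency_response(self, freq, lo_gain, hi_gain):
        t = np.arange(int(self.fs) * 30) / self.fs
        r = _record(np.sin(2 * np.pi * freq * t)[None, :].repeat(2, 0), self.fs)
        out = seg.bandpass(r)
        core = out.samples[0, int(5 * self.fs) : -int(5 * self.fs)]
        amp = np.sqrt(2) * np.sqrt(np.mean(core**2))
        assert lo_gain <= amp <= hi_gain

    def test_cutoff_above_nyquist_rejected(self):
        r = _record(np.zeros((2, 512)), 100.0)
        with pytest.raises(ValueError):
            seg.bandpass(r, 0.5, 55.0)


class TestArtifactRejection:
    def test_quiet_record_all_valid(self, rng):
        r = _record(rng.normal(0, 20, size=(3, 256 * 10)))
        assert seg.reject_artifacts(r).valid.all()

    def test_single_spike_invalidates_its_epoch_only(self):
        x = np.zeros((2, 256 * 10))
        x[1, int(7.2 * 256)] = 600.0
        mask = seg.reject_artifacts(_record(x))
        expected = np.ones(10, bool)
        expected[7] = False
        assert np.array_equal(mask.valid, expected)

    def test_half_open_epoch_boundary(self):
        x = np.zeros((1, 256 * 10))
        x[0, 8 * 256] = -700.0  # exactly t = 8.0 s belongs to epoch [8, 9)
        mask = seg.reject_artifacts(_record(x))
        assert mask.valid[7] and not mask.valid[8]

    def test_threshold_is_strict(self):
        x = np.full((1, 256 * 2), 500.0)  # |v| == thresh is not "> thresh"
        assert seg.reject_artifacts(_record(x)).valid.all()


class TestBinarize:
    fs = 256.0

    def test_constant_low_amplitude_is_suppression(self):
        sig = seg.binarize_channel(np.full(int(self.fs) * 10, 2.0), self.fs)
        assert sig.values.all()

    def test_constant_high_amplitude_is_burst(self):
        sig = seg.binarize_channel(np.full(int(self.fs) * 10, 25.0), self.fs)
        assert not sig.values.any()

    def test_block_pattern_recovered_within_half_second(self, rng):
        # alternating 10 s blocks at RMS 25 / 2.5 µV
        n_blocks, fs = 12, self.fs
        state = np.repeat(np.arange(n_blocks) % 2, int(10 * fs)).astype(np.uint8)
        eeg = syn.synthesize_eeg(state, 1, fs, seed=7)
        sig = seg.binarize_channel(eeg.samples[0], fs)
        edges_true = np.flatnonzero(np.diff(state)) + 1
        edges_est = np.flatnonzero(np.diff(sig.values)) + 1
        assert len(edges_est) == len(edges_true)
        assert np.max(np.abs(edges_est - edges_true)) <= 0.5 * fs

    def test_min_duration_enforced_interior(self, rng):
        state = np.repeat(rng.integers(0, 2, 40), int(3 * self.fs)).astype(np.uint8)
        eeg = syn.synthesize_eeg(state, 1, self.fs, seed=8)
        sig = seg.binarize_channel(eeg.samples[0], self.fs)
        runs = np.diff(np.concatenate(([0], np.flatnonzero(np.diff(sig.values)) + 1,
                                       [len(sig.values)])))
        assert (runs[1:-1] >= 0.5 * self.fs).all()

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            seg.binarize_channel(np.zeros(256), self.fs, theta=0.0)


def _const_signal(value, n=256 * 4, fs=256.0, mask=None):
    return seg.BinarySuppressionSignal(np.full(n, value, np.uint8), fs, mask)


class TestVote:
    def test_unanimous_suppression(self):
        out = seg.vote([_const_signal(1) for _ in range(19)])
        assert out.values.all()

    @pytest.mark.parametrize("k,expected", [(10, 1), (9, 0)])
    def test_strict_majority_of_19(self, k, expected):
        sigs = [_const_signal(1)] * k + [_const_signal(0)] * (19 - k)
        assert (seg.vote(sigs).values == expected).all()

    def test_majority_of_contributing_channels(self):
        # 4 of 19 channels masked out; 8 of the remaining 15 say suppression
        dead = seg.EpochMask(np.zeros(4, bool))
        sigs = (
            [_const_signal(1) for _ in range(8)]
            + [_const_signal(0) for _ in range(7)]
            + [_const_signal(0, mask=dead) for _ in range(4)]
        )
        assert seg.vote(sigs).values.all()

    def test_zero_channels_rejected(self):
        with pytest.raises(ValueError):
            seg.vote([])

    def test_complement_symmetry(self, rng):
        vals = rng.integers(0, 2, size=(5, 1024)).astype(np.uint8)
        sigs = [seg.BinarySuppressionSignal(v, 256.0) for v in vals]
        comp = [seg.BinarySuppressionSignal(1 - v, 256.0) for v in vals]
        direct = seg.vote(sigs, tie_value=0)
        swapped = seg.vote(comp, tie_value=1)
        assert np.array_equal(1 - direct.values, swapped.values)


def test_full_chain_recovers_generator_states():
    """Noise-free synthetic record: montage+filter+binarize+vote reproduce the
    ground-truth state sequence away from transitions."""
    fs = 256.0
    state = syn.simulate_state_sequence(np.full(120, 0.8), fs, seed=3)
    eeg = syn.synthesize_eeg(state, 19, fs, seed=4)
    mask = seg.reject_artifacts(eeg)
    pre = seg.apply_average_montage(seg.bandpass(eeg))
    sigs = [seg.binarize_channel(pre.samples[c], fs) for c in range(pre.n_channels)]
    out = seg.vote(sigs, mask)
    half = int(0.5 * fs)
    excl = np.zeros(len(state), bool)
    for k in np.flatnonzero(np.diff(state.astype(int))) + 1:
        excl[max(k - half, 0) : k + half] = True
    agreement = (out.values[~excl] == state[~excl]).mean()
    assert agreement >= 0.99
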