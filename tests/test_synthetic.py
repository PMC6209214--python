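"""Synthetic cohort generator: PK/PD dynamics, renewal process, EEG synthesis."""

import numpy as np
import pytest

from bspquant import synthetic as syn
from bspquant.records import MedicationRecord


def _const_regimen(rate=3.0, drug="propofol"):
    return MedicationRecord({drug: [(0.0, rate)]}, subject_id="S01")


class TestPKPD:
    def test_zero_regimen_zero_everything(self):
        ce, bsp = syn.simulate_pkpd(MedicationRecord(), syn.PKPDParams(), 3600, 1.0)
        assert not ce.any() and not bsp.any()

    def test_steady_state_and_half_maximal_point(self):
        p = syn.PKPDParams(k_in=1.0)
        rate = p.c50 * p.k_out / 1.0  # steady-state Ce equals C50
        ce, bsp = syn.simulate_pkpd(_const_regimen(rate), p, 12 * 3600, 1.0)
        assert ce[-1] == pytest.approx(p.c50, rel=1e-4)
        assert bsp[-1] == pytest.approx(0.5, abs=1e-3)

    def test_matches_closed_form_step_response(self):
        p = syn.PKPDParams(k_in=1.0)
        ce, _ = syn.simulate_pkpd(_const_regimen(3.0), p, 7200, 1.0)
        ss = 3.0 / p.k_out
        t_h = (np.arange(7200) + 1) / 3600.0
        closed = ss * (1 - np.exp(-p.k_out * t_h))
        assert np.max(np.abs(ce - closed) / closed) < 1e-3

    def test_bolus_adds_instantaneous_effect(self):
        reg = MedicationRecord({}, {"propofol": [(100.0, 2.0)]}, subject_id="S")
        ce, _ = syn.simulate_pkpd(reg, syn.PKPDParams(k_in=1.5), 300, 1.0)
        assert ce[99] == 0.0
        assert ce[100] == pytest.approx(2.0 * 1.5, rel=1e-3)

    def test_negative_rate_rejected_naming_step(self):
        with pytest.raises(ValueError, match="propofol.*t=60"):
            MedicationRecord({"propofol": [(0.0, 2.0), (60.0, -1.0)]})

    def test_monotone_in_rate(self):
        p = syn.PKPDParams()
        finals = [
            syn.simulate_pkpd(_const_regimen(r), p, 6 * 3600, 1.0)[1][-1]
            for r in [0.0, 2.0, 4.0, 8.0, 16.0]
        ]
        assert all(a <= b for a, b in zip(finals, finals[1:]))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            syn.PKPDParams(k_out=-1.0)
        with pytest.raises(ValueError):
            syn.PKPDParams(gamma=0.5)
        with pytest.raises(ValueError):
            syn.PKPDParams(drift_sd=-0.1)


class TestStateSequence:
    def test_constant_extremes(self):
        assert not syn.simulate_state_sequence(np.zeros(60), 256, seed=1).any()
        assert syn.simulate_state_sequence(np.ones(60), 256, seed=1).all()

    def test_occupancy_converges_to_p(self):
        p = 0.8
        st = syn.simulate_state_sequence(np.full(3600, p), 256, seed=2)
        assert abs(st.mean() - p) < 0.03

    def test_occupancy_within_renewal_bound(self):
        # long-run fraction within 3*sqrt(p(1-p)*mean_cycle/T)
        for p, seed in [(0.3, 5), (0.5, 6), (0.9, 7)]:
            T = 3600.0
            st = syn.simulate_state_sequence(np.full(int(T), p), 256, seed=seed)
            mu_cycle = 1.5 + 1.5 * p / (1 - p)
            bound = 3 * np.sqrt(p * (1 - p) * mu_cycle / T)
            assert abs(st.mean() - p) < bound

    def test_deterministic_given_seed(self):
        a = syn.simulate_state_sequence(np.full(120, 0.7), 256, seed=9)
        b = syn.simulate_state_sequence(np.full(120, 0.7), 256, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_fs_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_state_sequence(np.full(10, 0.5), 0.0)


class TestEEGSynthesis:
    def test_burst_rms(self):
        eeg = syn.synthesize_eeg(np.zeros(256 * 120, np.uint8), 3, 256, seed=3)
        rms = np.sqrt(np.mean(eeg.samples.astype(float) ** 2, axis=1))
        assert ((22.5 < rms) & (rms < 27.5)).all()

    def test_suppression_rms(self):
        eeg = syn.synthesize_eeg(np.ones(256 * 120, np.uint8), 3, 256, seed=4)
        rms = np.sqrt(np.mean(eeg.samples.astype(float) ** 2, axis=1))
        assert ((2.25 < rms) & (rms < 2.75)).all()

    def test_artifact_exceeds_rejection_threshold(self):
        eeg = syn.synthesize_eeg(
            np.ones(256 * 120, np.uint8), 2, 256, artifact_times=(100.0,), seed=5
        )
        epoch = eeg.samples[:, 100 * 256 : 101 * 256]
        assert np.abs(epoch).max() > 500.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            syn.synthesize_eeg(np.zeros(256, np.uint8), 0, 256)
        with pytest.raises(ValueError):
            syn.synthesize_eeg(np.zeros(256, np.uint8), 2, 256, burst_rms=2.0, supp_rms=5.0)

    def test_ten_twenty_labels(self):
        eeg = syn.synthesize_eeg(np.zeros(256 * 2, np.uint8), 19, 256, seed=6)
        assert eeg.channel_labels[:3] == ["Fp1", "Fp2", "F7"]


class TestCohort:
    def _tiny(self, **kw):
        base = dict(n_subjects=1, n_anoxic=0, duration_h=0.05, n_channels=2)
        base.update(kw)
        return syn.CohortConfig(**base)

    def test_zero_cv_gives_median_parameters(self):
        cfg = self._tiny(c50_cv=0.0, k_out_cv=0.0)
        (subj,) = syn.make_cohort(cfg, seed=0)
        assert subj.params.c50 == cfg.c50_median
        assert subj.params.k_out == cfg.k_out_median

    def test_deterministic_given_seed(self):
        cfg = self._tiny(n_subjects=3, n_anoxic=1)
        a = syn.make_cohort(cfg, seed=11)
        b = syn.make_cohort(cfg, seed=11)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.true_bsp, sb.true_bsp)
            assert np.array_equal(sa.state_seq, sb.state_seq)
            assert np.array_equal(sa.eeg.samples, sb.eeg.samples)

    def test_c50_spread_changes_steady_state_bsp(self):
        cfg = self._tiny(
            n_subjects=2, duration_h=2.0, c50_cv=0.3, k_out_cv=0.0, drift_sd=0.0,
            shared_regimen=True, rate_change_interval_h=100.0, bolus_rate_per_h=0.0,
            propofol_rates=(3.0,), p_midazolam=0.0,
        )
        a, b = syn.make_cohort(cfg, seed=5)
        assert a.params.c50 != b.params.c50
        tail = slice(-600, None)
        assert abs(a.true_bsp[tail].mean() - b.true_bsp[tail].mean()) > 0.05

    def test_group_assignment(self):
        cfg = self._tiny(n_subjects=4, n_anoxic=2)
        cohort = syn.make_cohort(cfg, seed=1)
        assert [s.group for s in cohort] == ["aRSE", "aRSE", "nRSE", "nRSE"]
        assert [s.subject_id for s in cohort] == ["A01", "A02", "N01", "N02"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            self._tiny(c50_cv=-0.2)
        with pytest.raises(ValueError):
            self._tiny(n_subjects=0)

    def test_state_sequence_matches_eeg_length(self):
        (subj,) = syn.make_cohort(self._tiny(), seed=3)
        assert len(subj.state_seq) == subj.eeg.n_samples
        assert (0 <= subj.true_bsp).all() and (subj.true_bsp <= 1).all()
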