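"""Synthetic cohort generator: age-morphology map, record rendering, folds."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from ecgage import synth


class TestAgeToMorphology:
    def test_noise_free_map_is_exactly_linear(self, default_model):
        m = default_model.zero_noise()
        wp, hr = synth.age_to_morphology(60.0, m, np.random.default_rng(0))
        assert hr == pytest.approx(78.0 - 0.08 * 60)
        assert wp.pr == pytest.approx(0.14 + 0.0004 * 60)
        assert wp.qrs == pytest.approx(0.085 + 0.0003 * 60)
        assert wp.qt == pytest.approx(0.36 + 0.0006 * 60)
        assert wp.waves["R"].amplitude == pytest.approx(1.2 - 0.004 * 60)
        assert wp.waves["T"].amplitude == pytest.approx(0.3 - 0.001 * 60)

    def test_pr_nondecreasing_over_full_age_scan(self, default_model):
        # brute-force scan of the noise-free linear map
        m = default_model.zero_noise()
        prs = [synth.age_to_morphology(a, m, np.random.default_rng(0))[0].pr
               for a in range(0, 96)]
        assert all(b >= a for a, b in zip(prs, prs[1:]))

    def test_same_seed_bit_identical(self, default_model):
        a = synth.age_to_morphology(40.0, default_model, np.random.default_rng(5))
        b = synth.age_to_morphology(40.0, default_model, np.random.default_rng(5))
        assert a[1] == b[1]
        assert a[0] == b[0]

    @pytest.mark.parametrize("age", [-1.0, 95.5, 200.0])
    def test_age_out_of_range_rejected(self, age, default_model):
        with pytest.raises(ValueError, match="age"):
            synth.age_to_morphology(age, default_model)


class TestSynthesizeRecord:
    def test_zero_amplitude_model_gives_zero_signal(self, default_model):
        m = default_model.zero_noise()
        m = synth.AgeMorphologyModel(
            heart_rate=m.heart_rate, pr=m.pr, qrs=m.qrs, qt=m.qt,
            r_amp=synth.LinearMap(1e-9, 0.0, 0.0),
            t_amp=synth.LinearMap(1e-9, 0.0, 0.0),
            lead_weights=(0.0,) * 12, wander_amp=0.0, noise_sd=0.0)
        rec = synth.synthesize_record(50.0, 500.0, 10.0, m, seed=0)
        assert np.all(rec.signal == 0.0)

    def test_rr_period_matches_drawn_heart_rate(self, record500):
        lead0 = record500.signal[0]
        peaks, _ = find_peaks(lead0, height=0.5 * lead0.max(),
                              distance=int(0.4 * record500.rate))
        rr = np.diff(peaks) / record500.rate
        # recover the drawn rate through the record's own annotations
        r_centers = [(a.qrs_onset + a.qrs_offset) / 2
                     for a in record500.annotations]
        drawn_period = np.mean(np.diff(r_centers)) / record500.rate
        assert np.median(rr) == pytest.approx(drawn_period, rel=0.05)

    def test_r_peak_count_tracks_heart_rate(self, record500):
        n_beats = len(record500.annotations)
        r_centers = np.diff([(a.qrs_onset + a.qrs_offset) / 2
                             for a in record500.annotations])
        hr = 60.0 * record500.rate / np.mean(r_centers)
        assert abs(n_beats - hr * record500.duration / 60.0) <= 1.0

    def test_per_lead_mean_bounded_by_wander(self, record500, default_model):
        means = record500.signal.mean(axis=1)
        # beat waves are transient; only wander + noise shift the baseline
        assert np.all(np.abs(means) < 3 * default_model.wander_amp
                      + 5 * default_model.noise_sd)

    def test_invalid_rate_duration_rejected(self):
        with pytest.raises(ValueError):
            synth.synthesize_record(50.0, rate=0.0)
        with pytest.raises(ValueError):
            synth.synthesize_record(50.0, duration=-1.0)

    @pytest.mark.parametrize("age,rate", [(5.0, 100.0), (50.0, 500.0),
                                          (90.0, 100.0)])
    def test_annotations_sound_and_match_intervals(self, age, rate,
                                                   default_model):
        rec = synth.synthesize_record(age, rate, 10.0, default_model,
                                      seed=int(age))
        m = default_model
        assert len(rec.annotations) >= 5
        prev_end = -1
        for a in rec.annotations:
            assert a.p_onset < a.qrs_onset < a.qrs_offset < a.t_offset
            assert 0 <= a.p_onset and a.t_offset < rec.n_samples
            assert a.p_onset > prev_end  # beats do not overlap
            prev_end = a.t_offset
        # masked-interval lengths reproduce the generating durations to 1 sample
        first = rec.annotations[0]
        for lo, hi, dur_map in [
            (first.p_onset, first.qrs_onset, m.pr),
            (first.qrs_onset, first.qrs_offset, m.qrs),
            (first.qrs_onset, first.t_offset, m.qt),
        ]:
            n = hi - lo
            expected = dur_map(age) * rate
            assert abs(n - expected) <= 1 + 3 * dur_map.sd * rate


class TestGenerateCohort:
    def test_age_distribution_matches_cohort_statistics(self):
        table, _ = synth.generate_cohort(2000, 1, seed=13, render=False)
        ages = table.frame.age.to_numpy()
        q25, q50, q75 = np.percentile(ages, [25, 50, 75])
        assert abs(q50 - 62.0) <= 2.0
        assert abs((q75 - q25) - 22.0) <= 3.0
        assert ages.min() >= 0.0 and ages.max() <= 95.0
        # left-skew: mean pulled below the median
        assert ages.mean() < q50

    def test_single_patient_degenerate_cohort(self):
        table, records = synth.generate_cohort(1, 3, rates=(100.0,), seed=0,
                                               duration=2.0)
        assert len(table) == 3
        assert table.frame.fold_id.nunique() == 1
        assert len(records) == 3

    def test_patient_fold_mapping_is_a_function(self):
        table, _ = synth.generate_cohort(500, 2, seed=99, render=False)
        per_patient = table.frame.groupby("patient_id")["fold_id"].nunique()
        assert (per_patient == 1).all()
        assert set(table.frame.fold_id.unique()) == set(range(10))

    def test_same_seed_reproduces_cohort_bitwise(self):
        t1, r1 = synth.generate_cohort(5, 1, rates=(100.0,), seed=3,
                                       duration=2.0)
        t2, r2 = synth.generate_cohort(5, 1, rates=(100.0,), seed=3,
                                       duration=2.0)
        assert t1.frame.equals(t2.frame)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.signal, b.signal)
            assert a.annotations == b.annotations

    def test_age_signal_visible_in_pr_duration(self):
        # correlation between age and annotated PR duration across a cohort:
        # the age signal the downstream regressors are supposed to recover
        table, records = synth.generate_cohort(1000, 1, rates=(100.0,),
                                               seed=5, duration=2.0)
        ages, prs = [], []
        for row, rec in zip(table.frame.itertuples(), records):
            pr = np.mean([a.qrs_onset - a.p_onset for a in rec.annotations])
            ages.append(row.age)
            prs.append(pr / rec.rate)
        assert np.corrcoef(ages, prs)[0, 1] > 0.5


def test_shifted_model_perturbs_slopes_and_leads(default_model):
    shifted = synth.shifted_model(default_model, seed=4)
    ratios = [getattr(shifted, q).slope / getattr(default_model, q).slope
              for q in ("heart_rate", "pr", "qrs", "qt", "r_amp", "t_amp")]
    assert all(abs(abs(r) - 1.0) == pytest.approx(0.2) for r in ratios)
    assert shifted.lead_weights != default_model.lead_weights
    assert min(shifted.lead_weights) < 0
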