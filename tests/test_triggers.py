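"""ECG cleaning, alignment, the ISD statistic and the paired statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selfgate import synth
from selfgate.triggers import (
    TriggerTrain,
    align_triggers,
    bland_altman,
    bonett_seier_paired,
    clean_ecg,
    compute_isd,
    rsa_split,
    rsa_paired_test,
)


def constant_train(n=200, interval=1000.0, source="ECG"):
    return TriggerTrain(times=np.arange(n) * interval, source=source)


def brute_force_isd(sg_iv, ecg_iv):
    """Eq.-style reference with explicit loops: SD of absolute differences."""
    d = []
    for a, b in zip(sg_iv, ecg_iv):
        d.append(abs(a - b))
    mu = sum(d) / len(d)
    acc = 0.0
    for dn in d:
        acc += (dn - mu) ** 2
    return (acc / (len(d) - 1)) ** 0.5


class TestCleanECG:
    def test_constant_train_unflagged(self):
        out = clean_ecg(constant_train())
        assert np.all(out.interval_valid())

    def test_single_gap_flagged_missing(self):
        t = np.arange(100) * 1000.0
        t = np.delete(t, 50)  # one 2000 ms interval
        out = clean_ecg(TriggerTrain(times=t))
        bad = np.flatnonzero(~out.interval_valid())
        assert bad.tolist() == [49]
        assert out.interval_flags[49] == "missing-adjacent"

    def test_inserted_trigger_flags_short_interval(self):
        t = np.arange(100) * 1000.0
        t = np.sort(np.append(t, 50300.0))  # splits one interval into 300/700
        out = clean_ecg(TriggerTrain(times=t))
        iv = out.intervals
        bad = np.flatnonzero(~out.interval_valid())
        assert len(bad) == 1
        assert np.isclose(iv[bad[0]], 300.0)
        assert out.interval_flags[bad[0]] == "extrasystolic"

    def test_short_train_warns(self):
        with pytest.warns(UserWarning):
            clean_ecg(constant_train(n=10))

    def test_detection_statistics_on_simulated_defects(self):
        hits = total = false = clean_total = 0
        for seed in range(50):
            gt = synth.simulate_physio(hr_sd_bpm=2, seed=seed)
            ecg, book = synth.simulate_ecg_train(gt, missing_rate=0.02, seed=seed + 100)
            cl = clean_ecg(ecg)
            ok = cl.interval_valid()
            contains = np.zeros(ok.size, bool)
            dels = book["deleted_times"]
            if dels.size:
                j = np.searchsorted(cl.times, dels) - 1
                contains[j[(j >= 0) & (j < ok.size)]] = True
            total += dels.size
            hits += int((~ok & contains).sum())
            clean_total += int((~contains).sum())
            false += int((~ok & ~contains).sum())
        assert hits / total >= 0.95
        assert false / clean_total < 0.01


class TestAlignTriggers:
    def test_identity_offset_zero(self):
        sg = constant_train(source="SG")
        _, off = align_triggers(sg, constant_train())
        assert off == 0.0

    def test_pure_shift_recovered_exactly(self):
        ecg = constant_train()
        sg = ecg.shifted(130.0)
        aligned, off = align_triggers(sg, ecg)
        assert off == -130.0
        _, dist = np.array([]), np.abs(aligned.times - ecg.times)
        assert dist.max() < 1e-9

    def test_fractional_shift_within_half_step(self):
        ecg = constant_train()
        aligned, off = align_triggers(ecg.shifted(134.0), ecg)
        assert abs(off - (-134.0)) <= 5.0

    def test_non_overlapping_trains_raise(self):
        a = TriggerTrain(times=np.arange(20) * 1000.0)
        b = TriggerTrain(times=np.arange(20) * 1000.0 + 1e6)
        with pytest.raises(ValueError):
            align_triggers(a, b)


class TestComputeISD:
    def test_perfect_agreement_is_zero(self):
        sg = constant_train(source="SG")
        comp = compute_isd(sg, constant_train())
        assert comp.mu == 0.0 and comp.isd == 0.0

    def test_worked_example(self):
        # S intervals (800, 820, 790), E intervals (810, 800, 800)
        e = np.array([0.0, 810.0, 1610.0, 2410.0])
        s = np.array([0.0, 800.0, 1620.0, 2410.0])
        comp = compute_isd(TriggerTrain(times=s), TriggerTrain(times=e))
        np.testing.assert_allclose(comp.abs_diff, [10.0, 20.0, 10.0])
        np.testing.assert_allclose(comp.mu, 13.3333, atol=1e-3)
        np.testing.assert_allclose(comp.isd, 5.7735, atol=1e-3)

    def test_global_shift_invariance(self):
        rng = np.random.default_rng(0)
        e = np.cumsum(rng.uniform(800, 1200, 50))
        s = e + rng.normal(0, 10, 50)
        s = np.sort(s)
        a = compute_isd(TriggerTrain(times=s), TriggerTrain(times=e))
        b = compute_isd(TriggerTrain(times=s + 500), TriggerTrain(times=e + 500))
        assert np.isclose(a.isd, b.isd)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_on_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 120)
        e = np.cumsum(rng.uniform(700, 1300, n))
        s = np.sort(e + rng.normal(0, 15, n))
        comp = compute_isd(TriggerTrain(times=s), TriggerTrain(times=e))
        ref = brute_force_isd(comp.sg_intervals, comp.ecg_intervals)
        assert abs(comp.isd - ref) < 1e-9


class TestRSASplit:
    def test_constant_rate_zero_difference(self, default_gt):
        train = TriggerTrain(times=np.arange(200) * 1000.0)
        resp = np.sin(2 * np.pi * 0.25 * np.arange(int(200 * 16)) / 16.0)
        hi, he, _ = rsa_split(train, resp, 16.0)
        assert hi == he == 60.0

    def test_null_case_small_difference(self):
        diffs = []
        for seed in range(25):
            gt = synth.simulate_physio(hr_sd_bpm=2, rsa_gain_bpm=0, duration_s=120, seed=seed)
            train = TriggerTrain(times=gt.trigger_times)
            hi, he, _ = rsa_split(train, gt.resp_waveform, gt.fs)
            diffs.append(hi - he)
        assert abs(np.mean(diffs)) < 1.0

    def test_rsa_raises_inspiration_rate(self):
        wins = 0
        for seed in range(25):
            gt = synth.simulate_physio(hr_sd_bpm=2, rsa_gain_bpm=5, duration_s=120, seed=seed)
            train = TriggerTrain(times=gt.trigger_times)
            hi, he, _ = rsa_split(train, gt.resp_waveform, gt.fs)
            wins += hi > he
        assert wins >= 22  # >= 45/50 scaled to 25 seeds

    def test_paired_test_across_subjects(self):
        hi = [66.0, 65.2, 67.1, 64.8, 66.5]
        he = [63.0, 63.1, 64.0, 62.9, 63.5]
        t, p = rsa_paired_test(hi, he)
        assert t > 0 and p < 0.01


class TestBonettSeier:
    def test_identical_samples_null(self):
        d = np.random.default_rng(0).normal(0, 5, 40)
        z, p = bonett_seier_paired(d, d.copy())
        assert z == 0.0 and p == 0.5

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        d1 = rng.normal(0, 1, 60)
        d2 = rng.normal(0, 2, 60)
        z12, _ = bonett_seier_paired(d1, d2)
        z21, _ = bonett_seier_paired(d2, d1)
        np.testing.assert_allclose(z12, -z21)

    def test_detects_three_fold_dispersion(self):
        rejections = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            d1 = rng.normal(0, 1, 50)
            d2 = 3 * d1 + rng.normal(0, 0.3, 50)
            _, p = bonett_seier_paired(d1, d2, alternative="less")
            rejections += p < 0.05
        assert rejections >= 48

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(2)
        d1 = rng.normal(0, 1.0, 50)
        d2 = rng.normal(0, 1.35, 50)
        z, p = bonett_seier_paired(d1, d2, alternative="less")

        def stat(a, b):
            return np.log(np.abs(a - a.mean()).mean()) - np.log(np.abs(b - b.mean()).mean())

        obs = stat(d1, d2)
        cnt = 0
        for _ in range(10_000):
            sw = rng.random(50) < 0.5
            a = np.where(sw, d2, d1)
            b = np.where(sw, d1, d2)
            cnt += stat(a, b) <= obs
        assert abs(p - cnt / 10_000) < 0.02

    def test_zero_mad_raises(self):
        with pytest.raises(ValueError):
            bonett_seier_paired(np.ones(10), np.random.default_rng(0).normal(size=10))


class TestBlandAltman:
    def test_identical_inputs(self):
        x = np.random.default_rng(0).uniform(800, 1200, 50)
        ba = bland_altman(x, x.copy())
        assert ba.mean_diff == 0 and ba.lower_limit == 0 and ba.upper_limit == 0
        assert np.isclose(ba.r_squared, 1.0)

    def test_constant_bias(self):
        x = np.random.default_rng(1).uniform(800, 1200, 50)
        ba = bland_altman(x + 10.0, x)
        np.testing.assert_allclose(ba.mean_diff, 10.0)
        np.testing.assert_allclose(ba.upper_limit - ba.lower_limit, 0.0, atol=1e-9)

    def test_limit_width_matches_noise_model(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(800, 1200, 500)
        y = x + rng.normal(0, 5, 500)
        ba = bland_altman(y, x)
        width = ba.upper_limit - ba.lower_limit
        assert abs(width - 2 * 1.96 * 5) < 0.15 * 2 * 1.96 * 5
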