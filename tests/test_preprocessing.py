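"""R-peak detection, beat scoring, and the generalized-ESD filter."""

import numpy as np
import pytest
from scipy import stats

from hrvrisk.errors import ConfigurationError, InsufficientDataError
from hrvrisk.io import ECGRecord, RRSeries
from hrvrisk.preprocessing import (
    RPeakSet,
    detect_r_peaks,
    rosner_filter,
    rr_from_peaks,
    score_detection,
)
from hrvrisk.synthetic import generate_ecg, generate_rr


class TestScoreDetection:
    @pytest.mark.parametrize(
        "n_truth, n_missed, n_spurious, se, ac",
        [
            (100, 0, 0, 100.0, 100.0),
            (100, 4, 0, 96.0, 96.0),
            (100, 0, 25, 100.0, 80.0),
        ],
    )
    def test_counting(self, n_truth, n_missed, n_spurious, se, ac):
        fs = 250.0
        truth = np.arange(n_truth) * 200 + 100
        detected = list(truth[: n_truth - n_missed])
        # spurious peaks midway between beats, far outside the 50 ms window
        detected += [int(t) + 100 for t in truth[:n_spurious]]
        peaks = RPeakSet(indices=np.sort(detected), fs=fs)
        score = score_detection(peaks, truth)
        assert score.Se == pytest.approx(se)
        assert score.Ac == pytest.approx(ac)
        assert score.FN == n_missed and score.FP == n_spurious


class TestDetectRPeaks:
    def test_clean_synthetic_recovers_every_beat(self):
        rr = generate_rr(duration_s=60, seed=7)
        ecg, truth = generate_ecg(rr, fs=250, noise_sd=0.0, seed=7)
        score = score_detection(detect_r_peaks(ecg, level=4), truth)
        assert score.Se == 100.0 and score.Ac == 100.0

    def test_flat_signal_yields_no_peaks(self):
        ecg = ECGRecord(samples=np.zeros(2500), fs=250)
        assert len(detect_r_peaks(ecg, level=4)) == 0

    def test_higher_level_detects_more_accurately_under_noise(self):
        """The detail reconstruction at level 1 keeps only the top octave,
        which discards most QRS energy: under added broadband noise the
        level sweep must show fewer total beat errors at level 4."""
        rr = generate_rr(duration_s=60, seed=3)
        ecg, truth = generate_ecg(rr, fs=250, noise_sd=0.0, seed=3)
        rng = np.random.default_rng(3)
        noisy = ECGRecord(
            samples=ecg.samples + 0.25 * rng.normal(size=ecg.samples.size),
            fs=ecg.fs,
        )
        s1 = score_detection(detect_r_peaks(noisy, level=1), truth)
        s4 = score_detection(detect_r_peaks(noisy, level=4), truth)
        assert s1.FP + s1.FN >= s4.FP + s4.FN
        assert s4.Ac >= s1.Ac

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_r_peaks(ECGRecord(samples=np.zeros(100), fs=30), level=4)


class TestRRFromPeaks:
    def test_uniform_and_mixed_intervals(self):
        rr = rr_from_peaks(RPeakSet(indices=[0, 250, 500], fs=250))
        np.testing.assert_allclose(rr.intervals, [1000, 1000])
        rr = rr_from_peaks(RPeakSet(indices=[0, 200, 450], fs=250))
        np.testing.assert_allclose(rr.intervals, [800, 1000])

    def test_single_peak_is_error(self):
        with pytest.raises(InsufficientDataError):
            rr_from_peaks(RPeakSet(indices=[10], fs=250))

    def test_intervals_sum_to_peak_span(self):
        rng = np.random.default_rng(5)
        idx = np.cumsum(rng.integers(150, 300, 40))
        peaks = RPeakSet(indices=idx, fs=250)
        rr = rr_from_peaks(peaks)
        assert rr.intervals.sum() == pytest.approx(
            1000 * (idx[-1] - idx[0]) / 250, rel=1e-12
        )


def esd_oracle(x: np.ndarray, k_max: int, alpha: float) -> set[int]:
    """Direct generalized-ESD enumeration used as an independent check."""
    x = np.asarray(x, dtype=float)
    n = x.size
    remaining = list(range(n))
    order, decisions = [], []
    for i in range(1, k_max + 1):
        sub = x[remaining]
        s = sub.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(sub - sub.mean()) / s
        j = int(np.argmax(dev))
        ni = n - i + 1
        t = stats.t.ppf(1 - alpha / (2 * ni), ni - 2)
        lam = (ni - 1) * t / np.sqrt((ni - 2 + t**2) * ni)
        order.append(remaining[j])
        decisions.append(dev[j] > lam)
        del remaining[j]
    n_out = max([i + 1 for i, d in enumerate(decisions) if d], default=0)
    return set(order[:n_out])


class TestRosnerFilter:
    def test_constant_series_nothing_removed(self):
        rr = RRSeries(intervals=np.full(60, 800.0))
        cleaned, report = rosner_filter(rr, k_max=3)
        assert report.removed_indices == []
        assert len(cleaned) == 60

    def test_single_gross_ectopic_removed(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(800, 20, 59), [2000.0]])
        with pytest.warns(UserWarning, match="ectopic"):
            cleaned, report = rosner_filter(RRSeries(intervals=x), k_max=5, alpha=0.05)
        assert report.removed_indices == [59]
        assert len(cleaned) == 59

    def test_matches_direct_esd_enumeration(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(800, 25, 80)
            # contaminate a few positions
            x[rng.integers(0, 80, 3)] += rng.choice([-1, 1], 3) * rng.uniform(200, 600, 3)
            _, report = rosner_filter(RRSeries(intervals=np.abs(x) + 1), k_max=8)
            assert set(report.removed_indices) == esd_oracle(np.abs(x) + 1, 8, 0.05)

    def test_k_max_zero_returns_input(self):
        rr = RRSeries(intervals=np.random.default_rng(1).normal(800, 30, 40))
        cleaned, report = rosner_filter(rr, k_max=0)
        np.testing.assert_array_equal(cleaned.intervals, rr.intervals)
        assert report.removed_indices == []

    def test_excessive_budget_rejected(self):
        rr = RRSeries(intervals=np.full(20, 800.0))
        with pytest.raises(ConfigurationError):
            rosner_filter(rr, k_max=10)

    def test_outlier_set_is_permutation_invariant(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(800, 20, 58), [1500.0, 400.0]])
        _, rep = rosner_filter(RRSeries(intervals=x), k_max=5)
        removed_values = set(np.round(x[rep.removed_indices], 9))
        perm = rng.permutation(x)
        _, rep_p = rosner_filter(RRSeries(intervals=perm), k_max=5)
        assert set(np.round(perm[rep_p.removed_indices], 9)) == removed_values

    def test_stricter_alpha_removes_subset(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(800, 20, 55), [1400, 1300, 350, 1250, 390.0]])
        _, rep_strict = rosner_filter(RRSeries(intervals=x), k_max=8, alpha=0.01)
        _, rep_loose = rosner_filter(RRSeries(intervals=x), k_max=8, alpha=0.05)
        assert set(rep_strict.removed_indices) <= set(rep_loose.removed_indices)
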