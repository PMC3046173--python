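"""Poincare geometry and entropy measures against brute-force oracles."""

import numpy as np
import pytest

from hrvrisk.errors import InsufficientDataError
from hrvrisk.io import RRSeries
from hrvrisk.nonlinear import (
    ComplexityParams,
    apen,
    complexity_features,
    poincare_features,
    smen,
)


def apen_oracle(x: np.ndarray, m: int, r: float) -> float:
    """Direct template counting per the definition (self-matches included)."""

    def phi(mm: int) -> float:
        templates = [x[i : i + mm] for i in range(len(x) - mm + 1)]
        n = len(templates)
        logs = []
        for ti in templates:
            count = sum(np.max(np.abs(ti - tj)) <= r for tj in templates)
            logs.append(np.log(count / n))
        return float(np.mean(logs))

    return phi(m) - phi(m + 1)


def smen_oracle(x: np.ndarray, m: int, r: float) -> float:
    """Direct pair counting (self-matches excluded, N-m templates)."""
    n_templ = len(x) - m
    B = A = 0
    for i in range(n_templ):
        for j in range(n_templ):
            if i == j:
                continue
            if np.max(np.abs(x[i : i + m] - x[j : j + m])) <= r:
                B += 1
            if np.max(np.abs(x[i : i + m + 1] - x[j : j + m + 1])) <= r:
                A += 1
    if A == 0 or B == 0:
        return float("nan")
    return float(-np.log(A / B))


class TestPoincare:
    def test_constant_series_collapses(self):
        f = poincare_features(RRSeries(intervals=np.full(50, 800.0)))
        for name in ("SD1", "SD2", "widthNN", "widthW", "widthL"):
            assert getattr(f, name) == pytest.approx(0.0, abs=1e-9)

    def test_alternating_series_closed_form(self):
        x = np.tile([800.0, 820.0], 30)
        f = poincare_features(RRSeries(intervals=x), bin_ms=0.0)
        # the 59-point cloud has 30 (+) and 29 (-) differences, so the
        # population sd is (20/sqrt 2) * sqrt(1 - 1/59^2), ~ 20/sqrt 2
        assert f.SD1 == pytest.approx(20 / np.sqrt(2) * np.sqrt(1 - 1 / 59**2), rel=1e-9)
        assert f.SD1 == pytest.approx(20 / np.sqrt(2), rel=1e-3)
        assert f.SD2 == pytest.approx(0.0, abs=1e-9)
        assert f.widthL == pytest.approx(0.0, abs=1e-9)
        assert f.widthW == pytest.approx(2 * 20 / np.sqrt(2), rel=1e-9)

    def test_white_noise_sd1_equals_sd2(self):
        rng = np.random.default_rng(0)
        x = rng.normal(800, 25, 400)
        f = poincare_features(RRSeries(intervals=x))
        assert f.SD1 == pytest.approx(25, rel=0.10)
        assert f.SD2 == pytest.approx(25, rel=0.10)

    def test_widths_round_up_to_whole_bins(self):
        x = np.tile([800.0, 820.0], 30)
        f = poincare_features(RRSeries(intervals=x), bin_ms=7.8125)
        assert f.widthNN == pytest.approx(np.ceil(20 / 7.8125) * 7.8125)
        assert f.widthW == pytest.approx(np.ceil(28.2842 / 7.8125) * 7.8125, rel=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_sd1_sd2_identities_vs_sdnn_sdsd(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(600, 1000, 200)
        f = poincare_features(RRSeries(intervals=x))
        # population-sd convention over the (N-1)-point Poincare cloud
        a, b = x[:-1], x[1:]
        sdsd2 = np.diff(x).std(ddof=0) ** 2
        assert f.SD1**2 == pytest.approx(sdsd2 / 2, rel=1e-9)
        u_var = ((b + a) / np.sqrt(2)).std(ddof=0) ** 2
        assert f.SD2**2 == pytest.approx(u_var, rel=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            poincare_features(RRSeries(intervals=np.array([800.0, 810.0])))


class TestEntropies:
    def test_constant_series_is_perfectly_regular(self):
        rr = RRSeries(intervals=np.full(60, 800.0))
        assert apen(rr, ComplexityParams(m=2, r=1.0)) == 0.0
        assert smen(rr, ComplexityParams(m=2, r=1.0)) == 0.0

    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_apen_matches_oracle(self, m):
        rng = np.random.default_rng(m)
        x = rng.uniform(0, 1, 100) * 1000
        r = 0.2 * x.std(ddof=1)
        got = apen(RRSeries(intervals=x), ComplexityParams(m=m, r=r))
        assert got == pytest.approx(apen_oracle(x, m, r), abs=1e-12)

    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_smen_matches_oracle(self, m):
        rng = np.random.default_rng(m + 10)
        x = rng.uniform(0, 1, 100) * 1000
        r = 0.2 * x.std(ddof=1)
        got = smen(RRSeries(intervals=x), ComplexityParams(m=m, r=r))
        expected = smen_oracle(x, m, r)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_no_long_matches_gives_missing_value_not_exception(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 30) * 1000
        with pytest.warns(UserWarning, match="undefined"):
            value = smen(RRSeries(intervals=x), ComplexityParams(m=4, r=1e-6))
        assert np.isnan(value)

    def test_periodic_series_less_complex_than_noise(self):
        rng = np.random.default_rng(1)
        periodic = np.tile([780.0, 820.0], 100)
        noise = rng.normal(800, periodic.std(), 200)
        p = ComplexityParams(m=2, r=0.2 * periodic.std(ddof=1))
        pn = ComplexityParams(m=2, r=0.2 * noise.std(ddof=1))
        assert apen(RRSeries(intervals=periodic), p) < apen(RRSeries(intervals=noise), pn)

    @pytest.mark.parametrize("seed", range(3))
    def test_shift_and_matched_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(800, 25, 150)
        r = 0.2 * x.std(ddof=1)
        base_a = apen(RRSeries(intervals=x), ComplexityParams(2, r))
        base_s = smen(RRSeries(intervals=x), ComplexityParams(2, r))
        shifted = RRSeries(intervals=x + 200)
        assert apen(shifted, ComplexityParams(2, r)) == pytest.approx(base_a, abs=1e-12)
        assert smen(shifted, ComplexityParams(2, r)) == pytest.approx(base_s, abs=1e-12)
        scaled = RRSeries(intervals=1.5 * x)
        assert apen(scaled, ComplexityParams(2, 1.5 * r)) == pytest.approx(base_a, abs=1e-12)
        assert smen(scaled, ComplexityParams(2, 1.5 * r)) == pytest.approx(base_s, abs=1e-12)

    def test_smen_non_increasing_in_tolerance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(800, 25, 200)
        sd = x.std(ddof=1)
        values = [smen(RRSeries(intervals=x), ComplexityParams(2, k * sd))
                  for k in (0.1, 0.15, 0.2, 0.3)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_feature_sweep_emits_eight_names(self):
        rng = np.random.default_rng(3)
        feats = complexity_features(RRSeries(intervals=rng.normal(800, 25, 200)))
        assert sorted(feats) == sorted(
            [f"ApEn_m{m}" for m in range(1, 5)] + [f"SmEn_m{m}" for m in range(1, 5)]
        )
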