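"""LTR pair alignment, K2P distance and insertion-time estimation."""

import math

import numpy as np
import pytest

from palm_ltr.dating import (DivergenceEstimate, SaturationError,
                             align_ltr_pair, date_element, divergence_profile,
                             insertion_time, k2p_distance)
from palm_ltr.mutation import mutate, random_sequence


def _gotoh_score(a, b, match=2.0, mismatch=-3.0, gap_open=-8.0,
                 gap_extend=-2.0):
    """Independent affine-gap global alignment score (plain Gotoh DP)."""
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)   # gap in b
    Y = np.full((n + 1, m + 1), neg)   # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


class TestAlignment:
    def test_identical_sequences_align_without_gaps(self, rng):
        s = random_sequence(200, 0.45, rng)
        a, b, _ = align_ltr_pair(s, s)
        assert a == b == s

    def test_single_deletion_gives_one_three_column_gap(self, rng):
        s = random_sequence(300, 0.45, rng)
        deleted = s[:100] + s[103:]
        a, b, _ = align_ltr_pair(s, deleted)
        assert b.count("-") == 3 and a.count("-") == 0
        gap_start = b.index("-")
        assert b[gap_start:gap_start + 3] == "---"
        assert "-" not in b[gap_start + 3:]

    def test_score_matches_independent_dp_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(20, 80))
            a = random_sequence(n, 0.45, rng)
            b = mutate(a, 0.15, 2.0, rng)
            if rng.random() < 0.5:      # occasional indel
                cut = int(rng.integers(5, n - 5))
                b = b[:cut] + b[cut + int(rng.integers(1, 4)):]
            _, _, score = align_ltr_pair(a, b)
            assert score == pytest.approx(_gotoh_score(a, b), abs=1e-6)

    def test_empty_or_short_input_rejected(self):
        with pytest.raises(ValueError):
            align_ltr_pair("", "ACGT" * 10)
        with pytest.raises(ValueError):
            align_ltr_pair("ACGT", "ACGT" * 10)


class TestK2P:
    def test_zero_divergence(self):
        p, q, k, n = k2p_distance("ACGT" * 25, "ACGT" * 25)
        assert (p, q, k, n) == (0.0, 0.0, 0.0, 100)

    def test_closed_form_spot_check(self):
        # 100 columns: 10 transitions (A<->G), 5 transversions (A<->C)
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        p, q, k, _ = k2p_distance(a, b)
        assert (p, q) == (0.10, 0.05)
        assert k == pytest.approx(0.17018, abs=1e-4)

    def test_correction_at_least_raw_mismatch(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = random_sequence(500, 0.45, rng)
            b = mutate(a, rng.uniform(0.0, 0.4), 2.0, rng)
            try:
                p, q, k, _ = k2p_distance(a, b)
            except SaturationError:
                continue
            assert k >= p + q - 1e-12

    def test_gapped_columns_excluded(self):
        p, q, k, n = k2p_distance("AC-GT", "ACCGT"[:2] + "-" + "GT")
        assert n == 4
        a, b = "ACG-T", "ACGG-"
        p, q, k, n = k2p_distance(a, b)
        assert n == 3 and k == 0.0

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("A" * 100, "G" * 100)

    def test_monotone_in_p_and_q(self):
        grid = np.linspace(0.0, 0.2, 11)
        for q in (0.0, 0.05, 0.1):
            ks = []
            for p in grid:
                if 1 - 2 * p - q > 0:
                    ks.append(k2p_distance_from(p, q))
            assert all(x < y for x, y in zip(ks, ks[1:]))
        for p in (0.0, 0.05, 0.1):
            ks = [k2p_distance_from(p, q) for q in grid
                  if 1 - 2 * p - q > 0 and 1 - 2 * q > 0]
            assert all(x < y for x, y in zip(ks, ks[1:]))


def k2p_distance_from(p, q):
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


class TestInsertionTime:
    def test_zero_distance_is_age_zero(self):
        assert insertion_time(0.0) == 0.0

    def test_spot_check_at_default_rate(self):
        assert insertion_time(0.17018, 1.3e-8) == \
            pytest.approx(6.545e6, rel=1e-3)

    def test_doubling_rate_halves_age(self):
        assert insertion_time(0.1, 2.6e-8) == \
            pytest.approx(insertion_time(0.1, 1.3e-8) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            insertion_time(-0.1)
        with pytest.raises(ValueError):
            insertion_time(0.1, 0.0)


class TestProfile:
    def _est(self, eid, k):
        return DivergenceEstimate(eid, 100, 0.0, 0.0, k, k / 2.6e-8)

    def test_zero_divergence_single_bin(self):
        ests = [self._est(f"e{i}", 0.0) for i in range(5)]
        hists, edges, recent = divergence_profile(ests, {f"e{i}": "RLC"
                                                         for i in range(5)})
        assert hists["RLC"][0] == 5 and hists["RLC"][1:].sum() == 0
        assert len(recent) == 5

    def test_bimodal_cohort_recovers_two_modes(self):
        rng = np.random.default_rng(4)
        ests, sfs = [], {}
        for i in range(200):
            k_true = 0.05 if i % 2 else 0.20
            ests.append(self._est(f"e{i}", k_true + rng.normal(0, 0.005)))
            sfs[f"e{i}"] = "RLC"
        hists, edges, _ = divergence_profile(ests, sfs, bin_width=0.01)
        h = hists["RLC"]
        top2 = np.argsort(h)[-2:]
        centers = sorted(edges[i] + 0.005 for i in top2)
        assert abs(centers[0] - 0.05) <= 0.01
        assert abs(centers[1] - 0.20) <= 0.01

    def test_empty_input(self):
        hists, edges, recent = divergence_profile([], {})
        assert hists == {} and recent == []


class TestRecovery:
    def test_planted_strata_recovered_within_tolerance(self):
        """Mean K̂ within 10 % of planted K for each divergence stratum."""
        rng = np.random.default_rng(5)
        for k_true in (0.02, 0.10):
            ks = []
            for _ in range(40):
                ltr5 = random_sequence(1000, 0.45, rng)
                ltr3 = mutate(ltr5, k_true, 2.0, rng)
                est = date_element("e", ltr5, ltr3)
                ks.append(est.k)
            assert abs(np.mean(ks) - k_true) / k_true < 0.10
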