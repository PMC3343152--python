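import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qensemble.correlation import (ContingencyTable, CorrelationProfile,
                                   ZeroCellError, delta_delta_g,
                                   dominant_period, long_range_flag,
                                   odds_ratio, or_profile,
                                   pearson_psi_profile, profile_similarity,
                                   region_mask)
from qensemble.rama_regions import (ALPHA_R, BETA, MISSING_LABEL,
                                    RegionLabelMatrix)

KBT300 = 0.0019872 * 300.0


class TestOddsRatio:
    def test_independence_is_one(self):
        value, _ = odds_ratio(ContingencyTable(10, 10, 10, 10))
        assert value == 1.0

    def test_hand_arithmetic(self):
        value, _ = odds_ratio(ContingencyTable(30, 10, 20, 40))
        assert value == pytest.approx(6.0)

    def test_zero_cell_with_and_without_correction(self):
        t = ContingencyTable(5, 0, 3, 7)
        raw, corrected = odds_ratio(t, correction=False)
        assert raw == np.inf and not corrected
        fixed, corrected = odds_ratio(t, correction=True)
        assert corrected
        assert fixed == pytest.approx(5.5 * 7.5 / (0.5 * 3.5), rel=1e-12)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n00, n01, n10, n11 = rng.integers(1, 50, 4)
            a, _ = odds_ratio(ContingencyTable(n00, n01, n10, n11))
            b, _ = odds_ratio(ContingencyTable(n00, n10, n01, n11))
            assert a == pytest.approx(b, rel=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(ContingencyTable(0, 0, 0, 0))


class TestDeltaDeltaG:
    def test_or_one_gives_zero_any_temperature(self):
        for T in (100.0, 300.0, 500.0):
            score, se, _ = delta_delta_g(ContingencyTable(7, 7, 7, 7), T)
            assert score == 0.0

    def test_hand_evaluation_at_300K(self):
        score, se, _ = delta_delta_g(ContingencyTable(30, 10, 20, 40), 300.0)
        assert score == pytest.approx(KBT300 * np.log(6.0), rel=1e-12)
        assert se == pytest.approx(
            KBT300 * np.sqrt(1 / 30 + 1 / 10 + 1 / 20 + 1 / 40), rel=1e-12)

    def test_recoding_negates_score_keeps_se(self):
        t = ContingencyTable(30, 10, 20, 40)
        flipped = ContingencyTable(10, 30, 40, 20)  # swap one variable's 0/1
        s1, e1, _ = delta_delta_g(t)
        s2, e2, _ = delta_delta_g(flipped)
        assert s2 == pytest.approx(-s1, rel=1e-12)
        assert e2 == pytest.approx(e1, rel=1e-12)

    def test_zero_cell_error_names_cell(self):
        with pytest.raises(ZeroCellError, match="n01"):
            delta_delta_g(ContingencyTable(5, 0, 3, 7), correction=False)

    def test_coverage_of_asymptotic_se(self):
        """Independent masks: |score| < 2 se in >= 93% of replicates."""
        rng = np.random.default_rng(7)
        n = 2000
        hits = 0
        reps = 500
        for _ in range(reps):
            x = rng.random(n) < 0.3
            y = rng.random(n) < 0.3
            t = ContingencyTable(
                int(np.sum(~x & ~y)), int(np.sum(~x & y)),
                int(np.sum(x & ~y)), int(np.sum(x & y)))
            score, se, _ = delta_delta_g(t)
            hits += abs(score) < 2 * se
        assert hits / reps >= 0.93


class TestOrProfile:
    def test_independent_null_mostly_within_2se(self):
        rng = np.random.default_rng(1)
        mask = (rng.random((10000, 20)) < 0.3).astype(np.int8)
        prof = or_profile(mask, trim=2)
        frac = np.mean(np.abs(prof.value) < 2 * prof.se)
        assert frac >= 0.90

    def test_duplicated_column_perfect_dependence(self):
        # every pair at distance 5 is an exact duplicate -> the pooled
        # table has n01 = n10 = 0 (infinite OR without correction)
        rng = np.random.default_rng(2)
        mask = (rng.random((500, 10)) < 0.4).astype(np.int8)
        mask[:, 5:] = mask[:, :5]
        prof = or_profile(mask, trim=0, correction=True)
        i5 = np.flatnonzero(prof.r == 5)[0]
        assert prof.value[i5] > 5 * prof.se[i5]
        assert prof.corrected[i5]  # zero cells flagged and corrected
        with pytest.raises(ZeroCellError):
            or_profile(mask, trim=0, correction=False)
        # other distances stay near the independence null
        others = prof.value[prof.r != 5]
        assert np.mean(np.abs(others) < 3 * prof.se[prof.r != 5]) > 0.8

    def test_pooled_equals_manual_summation(self):
        """3-pair toy case: pooled profile equals the hand-summed table."""
        mask = np.array([
            [1, 1, 0, 0],
            [0, 1, 1, 0],
            [1, 0, 1, 1],
        ], dtype=np.int8)
        prof = or_profile(mask, r_max=1, trim=0, correction=True)
        t = {"00": 0, "01": 0, "10": 0, "11": 0}
        for row in mask:
            for i in range(3):
                t[f"{row[i]}{row[i + 1]}"] += 1
        expected, se, _ = delta_delta_g(
            ContingencyTable(t["00"], t["01"], t["10"], t["11"]))
        assert prof.value[0] == pytest.approx(expected, rel=1e-12)
        assert prof.se[0] == pytest.approx(se, rel=1e-12)

    def test_excluded_cells_skipped(self):
        mask = np.array([[1, -1, 1, 0, 1, 0]] * 10, dtype=np.int8)
        prof = or_profile(mask, r_max=2, trim=0, correction=True)
        assert prof.r.size >= 1  # pairs containing -1 are dropped, not fatal

    def test_per_pair_agrees_with_pooled_on_homogeneous_mask(self):
        rng = np.random.default_rng(13)
        mask = (rng.random((4000, 16)) < 0.4).astype(np.int8)
        mask[:, 8:] = mask[:, :8] ^ (rng.random((4000, 8)) < 0.1)
        pooled = or_profile(mask, trim=2, pooling="pooled")
        per_pair = or_profile(mask, trim=2, pooling="per_pair")
        i8 = np.flatnonzero(pooled.r == 8)[0]
        assert per_pair.value[i8] == pytest.approx(pooled.value[i8], abs=0.1)
        assert per_pair.value[i8] > 3 * per_pair.se[i8]

    def test_trim_too_large_rejected(self):
        mask = np.zeros((5, 10), dtype=np.int8)
        with pytest.raises(ValueError):
            or_profile(mask, trim=5)


class TestRegionMask:
    def test_all_alpha_r(self):
        labels = RegionLabelMatrix(
            np.full((4, 6), ALPHA_R, dtype=np.int8), "hard", ["GLN"] * 6)
        assert region_mask(labels, "alphaR").all()
        assert not region_mask(labels, "beta").any()

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(-1, 4, (20, 10)).astype(np.int8)
        labels = RegionLabelMatrix(mat, "hard", ["GLN"] * 10)
        mask = region_mask(labels, "beta")
        for c in range(20):
            for r in range(10):
                if mat[c, r] == MISSING_LABEL:
                    assert mask[c, r] == -1
                else:
                    assert mask[c, r] == int(mat[c, r] == BETA)

    def test_unknown_region_rejected(self):
        labels = RegionLabelMatrix(
            np.zeros((2, 2), dtype=np.int8), "hard", ["GLN"] * 2)
        with pytest.raises(ValueError):
            region_mask(labels, "xi")


class TestPearsonPsi:
    def _ens(self, psi, names=None):
        from qensemble.ensemble_io import ConformationEnsemble

        psi = np.asarray(psi, dtype=float)
        n, m = psi.shape
        phi = np.full((n, m), -60.0)
        phi[:, 0] = np.nan
        omega = np.full((n, m), 180.0)
        return ConformationEnsemble("t", names or ["GLN"] * m, phi, psi, omega)

    def test_duplicated_column_gives_unit_correlation(self):
        # every eligible pair at distance 4 is an exact copy
        rng = np.random.default_rng(4)
        psi = rng.uniform(-170, 170, (200, 12))
        for i in range(8):
            psi[:, i + 4] = psi[:, i]
        ens = self._ens(psi)
        prof = pearson_psi_profile(ens, shift_deg=0.0, trim=2)
        assert prof.value[np.flatnonzero(prof.r == 4)[0]] == pytest.approx(1.0)

    def test_negated_column_gives_minus_one(self):
        rng = np.random.default_rng(5)
        psi = rng.uniform(-170, 170, (200, 12))
        for i in range(8):
            psi[:, i + 4] = -psi[:, i]
        ens = self._ens(psi)
        prof = pearson_psi_profile(ens, shift_deg=0.0, trim=2)
        assert prof.value[np.flatnonzero(prof.r == 4)[0]] == pytest.approx(-1.0)

    def test_independent_null_is_small(self):
        rng = np.random.default_rng(6)
        psi = rng.normal(150.0, 15.0, (10000, 15))
        ens = self._ens(psi)
        prof = pearson_psi_profile(ens, trim=2)
        assert np.nanmax(np.abs(prof.value)) < 0.05


class TestProfileComparison:
    def _profile(self, values, se=0.05):
        values = np.asarray(values, dtype=float)
        r = np.arange(1, values.size + 1)
        return CorrelationProfile(
            r=r, value=values, se=np.full(values.size, se),
            n_pairs=np.full(values.size, 100), statistic_kind="or_region")

    def test_affine_invariance(self):
        p1 = self._profile(np.sin(np.arange(10)))
        p2 = self._profile(2.0 * p1.value + 0.1)
        assert profile_similarity(p1, p2) == pytest.approx(1.0)

    def test_negation(self):
        p1 = self._profile(np.sin(np.arange(10)))
        p2 = self._profile(-p1.value)
        assert profile_similarity(p1, p2) == pytest.approx(-1.0)

    def test_too_few_points_rejected(self):
        p1 = self._profile(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            profile_similarity(p1, p1)

    def test_pure_tone_period(self):
        r = np.arange(1, 21)
        p = self._profile(np.cos(2 * np.pi * r / 8.0))
        period, frac = dominant_period(p)
        assert period == pytest.approx(8.0, abs=0.5)
        assert frac > 0.5

    def test_pure_trend_has_low_residual_power(self):
        p = self._profile(0.2 * np.arange(1, 21))
        period, frac = dominant_period(p)
        assert frac < 0.2

    def test_long_range_flag_examples(self):
        rng = np.random.default_rng(8)
        noisy_zero = self._profile(rng.normal(0, 0.02, 20), se=0.05)
        flag, _, _ = long_range_flag(noisy_zero)
        assert not flag
        r = np.arange(1, 21)
        oscillating = self._profile(0.3 + 0.2 * np.cos(2 * np.pi * r / 7), se=0.05)
        flag, tail_mean, threshold = long_range_flag(oscillating)
        assert flag and tail_mean > 0.1 and threshold == pytest.approx(0.1)
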