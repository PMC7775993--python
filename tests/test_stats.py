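"""Reliability statistics against hand computations and independent oracles."""

import numpy as np
import pytest

from mrfmorph.stats import (
    bland_altman,
    cicchetti_category,
    icc_agreement,
    percent_relative_difference,
    reliability_report,
    wcv,
)


def icc21_anova_oracle(x):
    """Brute-force ICC(2,1) from explicit ANOVA sums of squares (independent
    of the implementation under test)."""
    x = np.asarray(x, float)
    n, k = x.shape
    mean = x.mean()
    ms_rows = k * ((x.mean(1) - mean) ** 2).sum() / (n - 1)
    ms_cols = n * ((x.mean(0) - mean) ** 2).sum() / (k - 1)
    resid = x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True) + mean
    ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )


TOY_MATRICES = [
    np.array([[9, 2], [1, 10], [8, 4], [2, 8], [7, 6], [3, 9]], float),
    np.array([[10.2, 10.4], [9.1, 9.0], [11.5, 11.9], [8.8, 8.6], [10.0, 10.3]]),
    np.array([[1, 2, 3], [4, 5, 6], [7, 9, 8], [2, 2, 4]], float),
    np.array([[5.0, 5.1], [5.2, 5.1], [4.9, 5.0]]),
]


class TestWcv:
    def test_identical_pairs_zero(self):
        assert wcv(np.array([[5.0, 5.0], [7.0, 7.0]])) == 0.0

    def test_hand_computed_example(self):
        """{(10,12),(9,9),(11,10)}: sqrt(mean(d^2/2)) / grand mean * 100
        = sqrt(5/6) / (61/6) * 100 = 8.97906..."""
        value = wcv(np.array([[10.0, 12.0], [9.0, 9.0], [11.0, 10.0]]))
        assert value == pytest.approx(8.979061, abs=1e-5)

    @pytest.mark.parametrize("c", [0.1, 3.0, 1000.0])
    def test_scale_invariance(self, c, rng):
        pairs = rng.uniform(5, 15, size=(8, 2))
        assert wcv(c * pairs) == pytest.approx(wcv(pairs), rel=1e-12)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            wcv(np.array([[1.0, 0.0], [2.0, 3.0]]))


class TestIcc:
    def test_duplicated_column_is_perfect(self):
        col = np.array([3.0, 6.0, 9.0, 4.0])
        icc, degenerate = icc_agreement(np.stack([col, col], 1))
        assert icc == pytest.approx(1.0)
        assert not degenerate

    @pytest.mark.parametrize("x", TOY_MATRICES)
    def test_matches_anova_oracle(self, x):
        icc, _ = icc_agreement(x)
        assert icc == pytest.approx(icc21_anova_oracle(x), abs=1e-10)

    @pytest.mark.parametrize("x", TOY_MATRICES[:2])
    def test_matches_pingouin_icc2(self, x):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = x.shape
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "value": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "subject", "rater", "value")
        ref_val = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_agreement(x)[0] == pytest.approx(ref_val, abs=1e-8)

    def test_constant_offset_decreases_icc(self):
        col = np.array([3.0, 6.0, 9.0, 4.0, 7.0])
        perfect = icc_agreement(np.stack([col, col], 1))[0]
        offset = icc_agreement(np.stack([col, col + 2.0], 1))[0]
        assert offset < perfect

    def test_degenerate_zero_variance(self):
        icc, degenerate = icc_agreement(np.full((4, 2), 7.0))
        assert icc == 1.0 and degenerate

    def test_rejects_undersized(self):
        with pytest.raises(ValueError):
            icc_agreement(np.ones((1, 2)))


class TestCicchetti:
    @pytest.mark.parametrize(
        "icc,band",
        [
            (0.40, "fair"),
            (0.74, "good"),
            (0.75, "excellent"),
            (1.0, "excellent"),
            (0.60, "good"),
            (0.59, "fair"),
            (0.39, "poor"),
            (0.0, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_band_edges(self, icc, band):
        assert cicchetti_category(icc) == band

    def test_rejects_impossible_icc(self):
        with pytest.raises(ValueError):
            cicchetti_category(1.5)


class TestBlandAltman:
    def test_zero_differences(self):
        assert bland_altman(np.array([[4.0, 4.0], [6.0, 6.0]])) == (0.0, 0.0, 0.0)

    def test_hand_computed(self):
        """d = {1, -1}: bias 0, LOA = ±1.96*sqrt(2)."""
        bias, lo, hi = bland_altman(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert bias == 0.0
        assert hi == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-12)
        assert lo == pytest.approx(-1.96 * np.sqrt(2.0), abs=1e-12)

    def test_constant_bias_zero_width(self):
        pairs = np.array([[5.3, 5.0], [7.3, 7.0], [9.3, 9.0]])
        bias, lo, hi = bland_altman(pairs)
        assert bias == pytest.approx(0.3)
        assert lo == pytest.approx(bias) and hi == pytest.approx(bias)


class TestPercentRelativeDifference:
    def test_equal_inputs(self):
        assert percent_relative_difference(4.2, 4.2) == 0.0

    def test_direct_evaluation(self):
        assert percent_relative_difference(2.3, 2.5) == pytest.approx(100 * 0.2 / 2.4)

    def test_symmetric(self):
        assert percent_relative_difference(3.0, 5.0) == percent_relative_difference(5.0, 3.0)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            percent_relative_difference(0.0, 1.0)


def test_report_internal_consistency(rng):
    """bias within LOA; category consistent with ICC; n recorded."""
    for _ in range(20):
        pairs = rng.uniform(2, 4, size=(12, 2))
        rep = reliability_report(pairs, metric="x")
        assert rep.loa_lower <= rep.bias <= rep.loa_upper
        assert rep.icc_category == cicchetti_category(rep.icc)
        assert rep.n == 12
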