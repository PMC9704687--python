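"""Agreement statistics: correlations, ICC, alpha, parameter comparison."""

import numpy as np
import pytest

from scorelink import (
    GRMItem,
    ResponseMatrix,
    coefficient_alpha,
    compare_item_parameters,
    disattenuated_correlation,
    icc_agreement,
    score_agreement,
    summary_stats,
)


class TestScoreAgreement:
    def test_identity_vectors(self):
        x = np.array([48.0, 50.0, 55.0, 61.0])
        rep = score_agreement(x, x)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.icc == pytest.approx(1.0)
        assert rep.mean_diff == rep.sd_diff == rep.rmsd == 0.0

    def test_alternating_unit_differences(self):
        obs = np.array([50.0, 52.0, 50.0, 53.0])
        der = obs + np.array([1.0, -1.0, 1.0, -1.0])
        rep = score_agreement(obs, der)
        assert rep.mean_diff == pytest.approx(0.0)
        assert rep.rmsd == pytest.approx(1.0)
        assert rep.sd_diff == pytest.approx(np.sqrt(4.0 / 3.0))

    def test_zero_variance_vector_rejected(self):
        # a constant derived vector leaves the correlation undefined
        with pytest.raises(ValueError, match="variance"):
            score_agreement([50.0, 52.0, 50.0], [51.0, 51.0, 51.0])

    def test_known_bias_recovered(self, rng):
        obs = rng.normal(50, 9, size=500)
        der = obs + 1.5 + rng.normal(0, 5, size=500)
        rep = score_agreement(obs, der)
        assert rep.mean_diff == pytest.approx(1.5, abs=3 * 5 / np.sqrt(500))
        d = der - obs
        # independently coded formulas
        assert rep.rmsd == pytest.approx(np.sqrt(np.sum(d * d) / d.size), abs=1e-12)
        assert rep.bland_altman["loa_low"] == pytest.approx(rep.mean_diff - 1.96 * rep.sd_diff)
        assert rep.bland_altman["loa_high"] == pytest.approx(rep.mean_diff + 1.96 * rep.sd_diff)

    def test_rmsd_decomposition_identity(self, rng):
        for _ in range(20):
            obs = rng.normal(50, 8, size=int(rng.integers(5, 200)))
            der = obs + rng.normal(1, 4, size=obs.size)
            rep = score_agreement(obs, der)
            n = rep.n
            assert rep.rmsd**2 == pytest.approx(
                rep.mean_diff**2 + rep.sd_diff**2 * (n - 1) / n, abs=1e-10
            )

    def test_error_cases(self):
        with pytest.raises(ValueError, match="variance"):
            score_agreement([50.0, 50.0, 50.0], [49.0, 50.0, 51.0])
        with pytest.raises(ValueError, match="pair"):
            score_agreement([1.0, 2.0, 3.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="3"):
            score_agreement([1.0, 2.0], [1.0, 2.0])


class TestICC:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert icc_agreement(x, x) == pytest.approx(1.0)

    def test_large_shift_small_variance_near_zero(self):
        x = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        assert icc_agreement(x, x + 100.0) < 0.01

    def test_offset_monotone_decrease(self):
        x = np.linspace(40, 60, 30)
        vals = [icc_agreement(x, x + c) for c in (0.0, 2.0, 5.0, 10.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_anova_oracle_and_pingouin(self, rng):
        x = rng.normal(50, 10, size=50)
        y = x + rng.normal(1, 4, size=50)
        got = icc_agreement(x, y)
        # hand-computed mean-squares formula, written independently
        data = np.column_stack([x, y])
        n, k = data.shape
        msr = np.var(data.mean(axis=1), ddof=1) * k
        msc = np.var(data.mean(axis=0), ddof=1) * n
        sse = ((data - data.mean(1, keepdims=True) - data.mean(0) + data.mean()) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        want = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert got == pytest.approx(want, abs=1e-10)
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), 2),
                "raters": np.tile(["obs", "der"], n),
                "scores": data.ravel(),
            }
        )
        tab = pingouin.intraclass_corr(long, targets="targets", raters="raters", ratings="scores")
        ref = float(tab.set_index("Type").loc["ICC(A,1)", "ICC"])
        assert got == pytest.approx(ref, abs=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_agreement(np.full(5, 3.0), np.full(5, 3.0))


class TestDisattenuation:
    def test_perfect_reliability_returns_raw_r(self, rng):
        x = rng.normal(size=100)
        y = x + rng.normal(size=100)
        from scipy.stats import pearsonr

        assert disattenuated_correlation(x, y, 1.0, 1.0) == pytest.approx(
            pearsonr(x, y).statistic
        )

    def test_arithmetic(self):
        # r=0.72 with reliabilities 0.9, 0.9 disattenuates to 0.8
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 3.0])
        # construct a pair with known r via mixing
        rng = np.random.default_rng(5)
        a = rng.normal(size=4000)
        b = 0.72 * a + np.sqrt(1 - 0.72**2) * rng.normal(size=4000)
        got = disattenuated_correlation(a, b, 0.9, 0.9)
        from scipy.stats import pearsonr

        assert got == pytest.approx(pearsonr(a, b).statistic / 0.9)

    def test_true_score_model_recovery(self, rng):
        n = 20000
        t1 = rng.normal(size=n)
        t2 = 0.8 * t1 + np.sqrt(1 - 0.64) * rng.normal(size=n)
        rel_x, rel_y = 0.7, 0.8
        x = t1 + np.sqrt(1 / rel_x - 1) * rng.normal(size=n)
        y = t2 + np.sqrt(1 / rel_y - 1) * rng.normal(size=n)
        got = disattenuated_correlation(x, y, rel_x, rel_y)
        assert got == pytest.approx(0.8, abs=0.03)

    def test_warning_and_errors(self, rng):
        x = rng.normal(size=50)
        y = x + 0.05 * rng.normal(size=50)
        with pytest.warns(UserWarning, match="exceeds 1"):
            disattenuated_correlation(x, y, 0.5, 0.5)
        with pytest.raises(ValueError):
            disattenuated_correlation(x, y, 0.0, 0.9)


class TestAlpha:
    def _resp(self, vals):
        vals = np.asarray(vals, dtype=int)
        return ResponseMatrix(vals, tuple(f"i{j}" for j in range(vals.shape[1])))

    def test_parallel_duplicates_approach_one(self, rng):
        base = rng.integers(0, 5, size=(300, 1))
        for k in (2, 6, 12):
            resp = self._resp(np.tile(base, (1, k)))
            assert coefficient_alpha(resp) == pytest.approx(1.0)
        # noisy parallel items: alpha grows with test length
        noisy = lambda k: self._resp(
            np.clip(base + rng.integers(-1, 2, size=(300, k)), 0, 4)
        )
        assert coefficient_alpha(noisy(12)) > coefficient_alpha(noisy(2))

    def test_uncorrelated_items_nonpositive(self, rng):
        vals = rng.integers(0, 5, size=(2000, 2))
        assert coefficient_alpha(self._resp(vals)) < 0.1

    def test_variance_formula_oracle(self, bsi_8a, rng):
        from scorelink import simulate_responses

        resp = simulate_responses(rng.normal(size=200), bsi_8a, seed=9)
        got = coefficient_alpha(resp)
        v = resp.values.astype(float)
        k = v.shape[1]
        want = k / (k - 1) * (1 - sum(np.var(v[:, j], ddof=1) for j in range(k))
                              / np.var(v.sum(axis=1), ddof=1))
        assert got == pytest.approx(want, abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            coefficient_alpha(self._resp(np.zeros((50, 2))))
        with pytest.raises(ValueError):
            coefficient_alpha(self._resp(np.array([[1], [2]])))


class TestParamComparison:
    def test_identical_sets_all_overlap(self, bsi_8a):
        se = {it.item_id: np.full(5, 0.1) for it in bsi_8a}
        cmp = compare_item_parameters(bsi_8a, bsi_8a, se, se)
        assert cmp.max_abs_diff == 0.0
        assert cmp.n_overlap_slopes == cmp.n_slopes == 6
        assert cmp.n_overlap_thresholds == cmp.n_thresholds == 24

    def test_interval_logic(self):
        a = [GRMItem("i", 1.5, (0.0,))]
        b = [GRMItem("i", 2.0, (0.0,))]
        # slope intervals [1, 2] vs [1.5, 2.5] overlap
        cmp = compare_item_parameters(a, b, {"i": [0.2551, 0.1]}, {"i": [0.2551, 0.1]})
        assert bool(cmp.table.loc[cmp.table.param == "a", "ci_overlap"].iloc[0])
        # [1, 2] vs [2.1, 3] do not
        b2 = [GRMItem("i", 2.55, (0.0,))]
        cmp2 = compare_item_parameters(a, b2, {"i": [0.2551, 0.1]}, {"i": [0.2296, 0.1]})
        assert not bool(cmp2.table.loc[cmp2.table.param == "a", "ci_overlap"].iloc[0])

    def test_printed_sets_estimate_mode(self, bsi_8a, bsi_18):
        cmp = compare_item_parameters(bsi_8a, bsi_18)
        assert cmp.mode == "estimate"
        assert cmp.max_abs_diff <= 0.1 + 1e-12
        assert len(cmp.table) == 30

    def test_structural_mismatch(self, bsi_8a, symmetric_item):
        with pytest.raises(ValueError):
            compare_item_parameters(bsi_8a, [symmetric_item] * 6)


class TestSummaryStats:
    def test_small_example(self):
        s = summary_stats([1, 2, 3, 4, 5])
        assert s["mean"] == 3 and s["median"] == 3 and s["min"] == 1 and s["max"] == 5
        assert s["iqr"] == [2.0, 4.0]

    def test_constant_vector(self):
        assert summary_stats([7.0, 7.0, 7.0])["sd"] == 0.0

    def test_large_fixture_oracle(self, rng):
        x = rng.normal(50, 10, size=1000)
        s = summary_stats(x)
        assert s["mean"] == pytest.approx(np.sum(x) / 1000, abs=1e-10)
        assert s["sd"] == pytest.approx(np.sqrt(np.sum((x - x.mean()) ** 2) / 999), abs=1e-10)
        assert s["iqr"][0] == pytest.approx(np.quantile(x, 0.25))
        assert s["iqr"][1] == pytest.approx(np.quantile(x, 0.75))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summary_stats([])
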