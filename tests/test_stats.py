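"""Category statistics: spectra, deleterious fraction, rank tests, meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import alleleclock as ac
from alleleclock import stats as cst


class TestSfs:
    def test_counts_and_zero_fill(self):
        variants = pd.DataFrame(
            {
                "mac": [2, 2, 2, 2, 3, 3, 4, 2, 5, 6],
                "category": ["synonymous"] * 4 + ["benign"] * 4 + ["synonymous"] * 2,
            }
        )
        table = cst.sfs_by_category(variants, (2, 6))
        assert table.loc[2, "synonymous"] == 4
        assert table.loc[4, "synonymous"] == 0
        assert table.loc["total", "benign"] == 4

    def test_empty_input(self):
        table = cst.sfs_by_category(pd.DataFrame({"mac": [], "category": []}), (2, 4))
        assert (table.to_numpy() == 0).all() if table.size else True

    def test_totals_are_column_sums(self):
        rng = np.random.default_rng(1)
        variants = pd.DataFrame(
            {
                "mac": rng.integers(2, 7, 200),
                "category": rng.choice(["synonymous", "benign"], 200),
            }
        )
        table = cst.sfs_by_category(variants, (2, 6))
        for cat in table.columns:
            assert table.loc["total", cat] == table.loc[2:6, cat].sum()


class TestDeleteriousFraction:
    def test_neutral_expectation_met_gives_zero(self):
        assert cst.deleterious_fraction(100, 1000, 200, 2000) == pytest.approx(0.0)

    def test_zero_denominator_errors(self):
        with pytest.raises(ZeroDivisionError):
            cst.deleterious_fraction(10, 100, 5, 0)
        with pytest.raises(ZeroDivisionError):
            cst.deleterious_fraction(0, 100, 5, 50)

    def test_deficit_reported_negative(self):
        assert cst.deleterious_fraction(50, 1000, 200, 2000) < 0

    @given(
        n=st.integers(1, 500),
        tot=st.integers(500, 5000),
        ns=st.integers(1, 500),
        ts=st.integers(500, 5000),
    )
    def test_bounded_above_by_one(self, n, tot, ns, ts):
        f = cst.deleterious_fraction(n, tot, ns, ts)
        assert f <= 1.0


class TestCompare:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=200)
        t = pd.DataFrame(
            {
                "mac": 2,
                "category": ["synonymous"] * 200 + ["missense"] * 200,
                "nc": np.concatenate([vals, vals]),
            }
        )
        out = cst.compare_nc(t, mac_values=(2,), n_boot=200, seed=1)
        row = out[(out["category"] == "missense") & (out["mac"] == 2)].iloc[0]
        assert row["effect_size"] == pytest.approx(0.0, abs=1e-12)
        assert 0.4 < row["p"] < 0.6

    def test_large_shift_detected(self):
        # oracle: normal approximation of the rank-sum statistic at n=200
        rng = np.random.default_rng(4)
        base = rng.normal(size=200)
        shifted = rng.normal(size=200) + 2.0
        t = pd.DataFrame(
            {
                "mac": 2,
                "category": ["synonymous"] * 200 + ["missense"] * 200,
                "nc": np.concatenate([base, shifted]),
            }
        )
        out = cst.compare_nc(t, mac_values=(2,), n_boot=200, seed=1)
        row = out[(out["category"] == "missense") & (out["mac"] == 2)].iloc[0]
        assert row["effect_size"] > 0
        assert row["p"] < 0.01
        u = sps.mannwhitneyu(shifted, base, alternative="greater")
        n1 = n2 = 200
        z = (u.statistic - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert row["p"] == pytest.approx(sps.norm.sf(z), rel=0.05)

    def test_rank_sum_identity(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=40)
        u_xy = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
        u_yx = sps.mannwhitneyu(y, x, alternative="two-sided").statistic
        assert u_xy + u_yx == len(x) * len(y)

    def test_ci_brackets_effect_on_large_samples(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame(
            {
                "mac": 3,
                "category": ["synonymous"] * 500 + ["missense"] * 500,
                "nc": np.concatenate(
                    [rng.normal(size=500), rng.normal(size=500) + 0.4]
                ),
            }
        )
        out = cst.compare_nc(t, mac_values=(3,), n_boot=500, seed=2)
        row = out[out["category"] == "missense"].iloc[0]
        assert row["ci_low"] <= row["effect_size"] <= row["ci_high"]


class TestBootstrap:
    def test_identical_constant_groups(self):
        x = np.full(10, 3.0)
        assert cst.bootstrap_ci(x, x, n_boot=100, seed=0) == (0.0, 0.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert cst.bootstrap_ci(x, y, seed=11) == cst.bootstrap_ci(x, y, seed=11)

    def test_coverage_of_known_shift(self):
        # groups of 500 with a true 0.3-SD shift: the 95% CI should cover the
        # generative value in at least 90% of replicates
        rng = np.random.default_rng(8)
        true = 0.3
        hits = 0
        reps = 100
        for _ in range(reps):
            base = rng.normal(size=500)
            cat = rng.normal(size=500) + true
            lo, hi = cst.bootstrap_ci(cat, base, n_boot=400, seed=rng)
            hits += lo <= true <= hi
        assert hits >= 0.90 * reps


class TestMetaCombine:
    def test_single_study_unchanged(self):
        assert cst.meta_combine([0.07], [100]) == pytest.approx(0.07, rel=1e-9)

    def test_two_equal_studies(self):
        # z = 1.6449 each -> Z = 2.3262 -> p = 0.0100
        assert cst.meta_combine([0.05, 0.05], [50, 50]) == pytest.approx(
            0.00997, abs=2e-4
        )

    def test_symmetric_cancellation(self):
        assert cst.meta_combine([0.05, 0.95], [50, 50]) == pytest.approx(0.5, abs=1e-9)

    def test_monotone_in_each_p(self):
        base = cst.meta_combine([0.05, 0.2, 0.5], [10, 20, 30])
        better = cst.meta_combine([0.01, 0.2, 0.5], [10, 20, 30])
        assert better < base

    def test_degenerate_p_clipped(self, caplog):
        p = cst.meta_combine([0.0, 0.5], [10, 10])
        assert 0.0 < p < 0.5

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cst.meta_combine([0.1], [10, 20])
        with pytest.raises(ValueError):
            cst.meta_combine([0.1], [0])


class TestSpearman:
    def test_perfect_concordance(self):
        rho, p = cst.spearman_vs_score([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_reversed_ranks(self):
        rho, p = cst.spearman_vs_score([4, 3, 2, 1], [0.1, 0.2, 0.3, 0.4])
        assert rho == pytest.approx(-1.0)
        assert p > 0.9

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            cst.spearman_vs_score([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    def test_recovers_generative_rank_dependence(self):
        rng = np.random.default_rng(9)
        n = 2000
        r = 0.5
        x = rng.normal(size=n)
        y = r * x + np.sqrt(1 - r * r) * rng.normal(size=n)
        expected = 6.0 / np.pi * np.arcsin(r / 2.0)  # rank corr of bivariate normal
        rho, p = cst.spearman_vs_score(x, y)
        assert abs(rho - expected) < 3.0 / np.sqrt(n)
        assert p < 1e-10


class TestPrivateFraction:
    def test_single_population_all_private(self):
        v = pd.DataFrame(
            {
                "category": ["synonymous", "benign"],
                "mac": [2, 3],
                "populations": [{"NL"}, {"NL"}],
            }
        )
        out = cst.private_fraction(v)
        assert (out["private_fraction"] == 1.0).all()

    def test_shared_variant_not_private(self):
        v = pd.DataFrame(
            {
                "category": ["synonymous"],
                "mac": [2],
                "populations": [{"A", "B"}],
            }
        )
        out = cst.private_fraction(v)
        assert out["private_fraction"].iloc[0] == 0.0

    def test_empty_presence_set_rejected(self):
        v = pd.DataFrame(
            {"category": ["synonymous"], "mac": [2], "populations": [set()]}
        )
        with pytest.raises(ValueError):
            cst.private_fraction(v)

    def test_island_model_private_fraction_decreases_with_frequency(self):
        # two-deme Wright-Fisher with symmetric migration: rarer alleles are
        # more often confined to the deme where they arose
        rng = np.random.default_rng(10)
        N, m, gens, M = 200, 0.02, 400, 4000
        c1 = np.zeros(M, dtype=np.int64)
        c2 = np.zeros(M, dtype=np.int64)
        c1[: M // 2] = 1  # half the mutations arise in deme 1
        c2[M // 2 :] = 1
        for _ in range(gens):
            x1, x2 = c1 / (2 * N), c2 / (2 * N)
            e1 = (1 - m) * x1 + m * x2
            e2 = (1 - m) * x2 + m * x1
            c1 = rng.binomial(2 * N, e1)
            c2 = rng.binomial(2 * N, e2)
        tot = c1 + c2
        seg = (tot > 0) & (tot < 4 * N)
        pops = [
            {"d1"} if (a > 0 and b == 0) else {"d2"} if (a == 0 and b > 0) else {"d1", "d2"}
            for a, b in zip(c1[seg], c2[seg])
        ]
        freq_class = np.where(tot[seg] <= 0.05 * 4 * N, "low", "high")
        v = pd.DataFrame(
            {"category": "synonymous", "mac": freq_class, "populations": pops}
        )
        out = cst.private_fraction(v).set_index("mac")
        assert (
            out.loc["low", "private_fraction"] > out.loc["high", "private_fraction"]
        )
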