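"""Statistical layer vs closed forms, brute force, and reference packages."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from arousalpipe import stats


class TestPairedT:
    def test_identical_samples(self):
        r = stats.paired_location_test([1.0, 2, 3], [1.0, 2, 3])
        assert r.statistic == 0 and r.p == 1 and r.effect_size == 0

    def test_closed_form_toy_diffs(self):
        # d = [1..5]: t = 3 / (1.5811/sqrt(5)) = 4.2426...
        x = np.array([1.0, 2, 3, 4, 5])
        r = stats.paired_location_test(x)
        assert r.statistic == pytest.approx(4.242640687, abs=1e-8)
        t_ref, p_ref = sstats.ttest_1samp(x, 0.0)
        assert r.statistic == pytest.approx(t_ref, abs=1e-12)
        assert r.p == pytest.approx(p_ref, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            stats.paired_location_test([1, 2], [1, 2, 3])


class TestWilcoxon:
    def test_perfect_tie_gives_p_one(self):
        # diffs [1, -1]: exhaustive sign assignment gives p = 1
        r = stats.paired_location_test([1.0, -1.0], method="wilcoxon")
        assert r.p == pytest.approx(1.0)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            d = rng.normal(0.3, 1, 10)
            d += np.arange(10) * 1e-6          # break ties
            r = stats.paired_location_test(d, method="wilcoxon")
            w_ref, p_ref = sstats.wilcoxon(d, method="exact")
            assert r.p == pytest.approx(p_ref, abs=1e-10)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 1, 40)
        r = stats.paired_location_test(d, method="wilcoxon")
        _, p_ref = sstats.wilcoxon(d, correction=True, method="approx")
        assert r.p == pytest.approx(p_ref, abs=1e-10)


class TestHolm:
    def test_single_p_unchanged(self):
        assert stats.holm_sequential_bonferroni([0.03]) == \
            pytest.approx([0.03])

    def test_step_down_example(self):
        adj = stats.holm_sequential_bonferroni([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_equal_ps(self):
        adj = stats.holm_sequential_bonferroni([0.05, 0.05, 0.05])
        assert adj == pytest.approx([0.15, 0.15, 0.15])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.holm_sequential_bonferroni([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = stats.holm_sequential_bonferroni(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _long(values, factors):
    """values: ndarray indexed (subject, *levels); factors: names."""
    rows = []
    for idx in np.ndindex(values.shape):
        row = {"participant": idx[0]}
        for name, lev in zip(factors, idx[1:]):
            row[name] = f"l{lev}"
        row["y"] = values[idx]
        rows.append(row)
    return pd.DataFrame(rows)


def _bruteforce_ss(values, term_axes):
    """Balanced-factorial SS of a term by direct mean decomposition.

    SS(term) = sum over all cells of (sum over subsets of the term's axes
    with inclusion-exclusion of marginal means).
    """
    axes = tuple(range(values.ndim))
    total = 0.0
    it = np.ndindex(values.shape)
    # effect value at each cell via inclusion-exclusion of marginal means
    for idx in it:
        est = 0.0
        for r in range(len(term_axes) + 1):
            for sub in itertools.combinations(term_axes, r):
                keep = sub
                marg = values.mean(axis=tuple(a for a in axes
                                              if a not in keep))
                sign = (-1) ** (len(term_axes) - len(sub))
                est += sign * marg[tuple(idx[a] for a in keep)]
        total += est ** 2
    return total


class TestRmAnova:
    def test_two_level_factor_equals_paired_t(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, (8, 2))
        df = _long(vals, ["cond"])
        out = stats.rm_anova(df, "y", "cond")
        t = stats.paired_location_test(vals[:, 0], vals[:, 1])
        assert out["F"].iloc[0] == pytest.approx(t.statistic ** 2, abs=1e-9)
        assert out["epsilon"].iloc[0] == 1.0

    def test_ss_match_bruteforce(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (6, 3))
        df = _long(vals, ["cond"])
        out = stats.rm_anova(df, "y", "cond")
        assert out["ss"].iloc[0] == pytest.approx(
            _bruteforce_ss(vals, (1,)), abs=1e-9)
        assert out["ss_error"].iloc[0] == pytest.approx(
            _bruteforce_ss(vals, (0, 1)), abs=1e-9)

    def test_ss_conservation_three_way(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (5, 2, 3, 2))
        df = _long(vals, ["a", "b", "c"])
        out = stats.rm_anova(df, "y", ["a", "b", "c"], gg_policy="never")
        ss_total = float(((vals - vals.mean()) ** 2).sum())
        ss_subject = _bruteforce_ss(vals, (0,))
        assert out["ss"].sum() + out["ss_error"].sum() + ss_subject == \
            pytest.approx(ss_total, abs=1e-9)

    def test_three_way_effects_match_bruteforce(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (4, 2, 2, 3))
        df = _long(vals, ["a", "b", "c"])
        out = stats.rm_anova(df, "y", ["a", "b", "c"]).set_index("effect")
        axis = {"a": 1, "b": 2, "c": 3}
        for eff in ("a", "b", "c", "a*b", "a*c", "b*c", "a*b*c"):
            axes = tuple(axis[f] for f in eff.split("*"))
            assert out.loc[eff, "ss"] == pytest.approx(
                _bruteforce_ss(vals, axes), abs=1e-9), eff

    def test_agrees_with_pingouin_one_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (10, 4))
        df = _long(vals, ["cond"])
        ours = stats.rm_anova(df, "y", "cond", gg_policy="always")
        ref = pg.rm_anova(data=df, dv="y", within="cond",
                          subject="participant", correction=True,
                          detailed=True)
        assert ours["F"].iloc[0] == pytest.approx(ref["F"].iloc[0])
        assert ours["epsilon"].iloc[0] == pytest.approx(ref["eps"].iloc[0],
                                                        abs=1e-6)
        assert ours["p_gg"].iloc[0] == pytest.approx(
            ref["p_GG_corr"].iloc[0], abs=1e-6)
        assert ours["eta_p2"].iloc[0] == pytest.approx(ref["ng2"].iloc[0],
                                                       abs=0.2)

    def test_agrees_with_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, (9, 3, 2))
        df = _long(vals, ["a", "b"])
        ours = stats.rm_anova(df, "y", ["a", "b"],
                              gg_policy="never").set_index("effect")
        ref = pg.rm_anova(data=df, dv="y", within=["a", "b"],
                          subject="participant").set_index("Source")
        for eff, key in (("a", "a"), ("b", "b"), ("a*b", "a * b")):
            assert ours.loc[eff, "F"] == pytest.approx(ref.loc[key, "F"],
                                                       rel=1e-9)
            assert ours.loc[eff, "p"] == pytest.approx(
                ref.loc[key, "p_unc"], abs=1e-12)

    def test_incomplete_design_rejected(self):
        df = _long(np.zeros((4, 2)), ["cond"]).iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            stats.rm_anova(df, "y", "cond")


class TestRmCorrelation:
    def test_perfect_within_subject_relation(self):
        x = np.tile(np.arange(4.0), 5)
        subj = np.repeat(np.arange(5), 4)
        y = x + subj * 10
        r = stats.rm_correlation(x, y, subj)
        assert r.r_rm == pytest.approx(1.0)

    def test_between_subject_structure_is_removed(self):
        rng = np.random.default_rng(6)
        subj = np.repeat(np.arange(20), 10)
        offsets = rng.normal(0, 5, 20)[subj]
        x = offsets + rng.normal(0, 1, 200)
        y = offsets + rng.normal(0, 1, 200)   # only offsets are shared
        r = stats.rm_correlation(x, y, subj)
        assert abs(r.r_rm) < 0.1

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_sub = int(rng.integers(4, 9))
            k = int(rng.integers(3, 6))
            subj = np.repeat(np.arange(n_sub), k)
            x = rng.normal(0, 1, n_sub * k)
            y = 0.4 * x + rng.normal(0, 1, n_sub * k)
            ours = stats.rm_correlation(x, y, subj)
            df = pd.DataFrame({"x": x, "y": y, "s": subj})
            ref = pg.rm_corr(data=df, x="x", y="y", subject="s")
            assert ours.r_rm == pytest.approx(float(ref["r"].iloc[0]),
                                              abs=1e-6)
            assert ours.df == int(ref["dof"].iloc[0])
            assert ours.p == pytest.approx(float(ref["pval"].iloc[0]),
                                           abs=1e-9)

    def test_df_formula(self):
        x = np.tile(np.arange(3.0), 6)
        y = x + np.random.default_rng(8).normal(0, 1, 18)
        r = stats.rm_correlation(x, y, np.repeat(np.arange(6), 3))
        assert r.df == 18 - 6 - 1


class TestMengZ:
    @staticmethod
    def _oracle(r_jk, r_jh, r_kh, n):
        # independent transcription of the dependent-correlation z test
        zjk, zjh = np.arctanh(r_jk), np.arctanh(r_jh)
        rbar2 = (r_jk ** 2 + r_jh ** 2) / 2
        f = (1 - r_kh) / (2 * (1 - rbar2))
        f = 1.0 if f > 1 else f
        h = (1 - f * rbar2) / (1 - rbar2)
        z = (zjk - zjh) * np.sqrt((n - 3) / (2 * (1 - r_kh) * h))
        return z, 2 * sstats.norm.sf(abs(z))

    def test_equal_correlations_give_zero(self):
        z, p = stats.meng_dependent_correlation_z(0.4, 0.4, 0.2, 30)
        assert z == 0 and p == 1

    def test_formula_oracle(self):
        z, p = stats.meng_dependent_correlation_z(0.5, 0.2, 0.3, 30)
        z_ref, p_ref = self._oracle(0.5, 0.2, 0.3, 30)
        assert z == pytest.approx(z_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_antisymmetry(self):
        z1, _ = stats.meng_dependent_correlation_z(0.5, 0.2, 0.3, 30)
        z2, _ = stats.meng_dependent_correlation_z(0.2, 0.5, 0.3, 30)
        assert z1 == pytest.approx(-z2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stats.meng_dependent_correlation_z(1.0, 0.2, 0.3, 30)
        with pytest.raises(ValueError):
            stats.meng_dependent_correlation_z(0.5, 0.2, 0.3, 3)


class TestCorrelation:
    def test_linear_relation(self):
        x = np.arange(10.0)
        r = stats.correlation(x, 2 * x)
        assert r.statistic == pytest.approx(1.0)

    def test_rank_invariance_of_spearman(self):
        x = np.linspace(0.1, 3, 20)
        y = np.exp(x)
        assert stats.correlation(x, y, "spearman").statistic == \
            pytest.approx(1.0)
        assert stats.correlation(x, y, "pearson").statistic < 1.0

    def test_matches_manual_formulas(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, (2, 20))
        r = stats.correlation(x, y).statistic
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(manual, abs=1e-9)
        rho = stats.correlation(x, y, "spearman").statistic
        rx, ry = sstats.rankdata(x), sstats.rankdata(y)
        manual_rho = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(manual_rho, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stats.correlation(np.ones(5), np.arange(5.0))


class TestTypeICalibration:
    """Rejection rates under the null stay near nominal (500 replicates)."""

    BAND = (0.021, 0.079)   # 0.05 +- 3 binomial SDs at n=500

    def test_paired_t(self):
        rng = np.random.default_rng(100)
        hits = sum(stats.paired_location_test(rng.normal(0, 1, 12)).p < 0.05
                   for _ in range(500))
        assert self.BAND[0] <= hits / 500 <= self.BAND[1]

    def test_wilcoxon(self):
        rng = np.random.default_rng(101)
        hits = sum(stats.paired_location_test(rng.normal(0, 1, 14),
                                              method="wilcoxon").p < 0.05
                   for _ in range(500))
        assert self.BAND[0] <= hits / 500 <= self.BAND[1]

    def test_rm_anova(self):
        rng = np.random.default_rng(102)
        hits = 0
        for _ in range(500):
            df = _long(rng.normal(0, 1, (8, 3)), ["cond"])
            hits += stats.rm_anova(df, "y", "cond")["p_gg"].iloc[0] < 0.05
        assert self.BAND[0] <= hits / 500 <= self.BAND[1]

    def test_rm_correlation(self):
        rng = np.random.default_rng(103)
        subj = np.repeat(np.arange(8), 3)
        hits = 0
        for _ in range(500):
            x = rng.normal(0, 1, 24)
            y = rng.normal(0, 1, 24)
            hits += stats.rm_correlation(x, y, subj).p < 0.05
        assert self.BAND[0] <= hits / 500 <= self.BAND[1]
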