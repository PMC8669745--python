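"""Factorial statistics: ANOVA decompositions, Tukey letters, diagnostics,
percent declines and enzyme ratios."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from exokin import profile_stats as ps


def two_by_two():
    """Balanced 2x2 with 2 replicates; hand-decomposed cell means give
    SS_A = 18, SS_B = 72, SS_AB = 8, SS_err = 8 (F = 9, 36, 4)."""
    rows = []
    data = {("a1", "b1"): [1.0, 3.0], ("a1", "b2"): [5.0, 7.0],
            ("a2", "b1"): [2.0, 4.0], ("a2", "b2"): [10.0, 12.0]}
    for (a, b), vals in data.items():
        for v in vals:
            rows.append({"depth_cm": a, "temperature_C": b, "y": v})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_hand_computed_decomposition(self):
        res = ps.anova_two_way(two_by_two(), "y")
        tab = res.table
        terms = [t for t in tab.index if t != "Residual"]
        ss = {t: tab.loc[t, "sum_sq"] for t in terms}
        a_term = [t for t in terms if "depth" in t and ":" not in t][0]
        b_term = [t for t in terms if "temperature" in t
                  and ":" not in t][0]
        ab_term = [t for t in terms if ":" in t][0]
        assert ss[a_term] == pytest.approx(18.0)
        assert ss[b_term] == pytest.approx(72.0)
        assert ss[ab_term] == pytest.approx(8.0)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(8.0)
        assert tab.loc[a_term, "F"] == pytest.approx(9.0)
        assert tab.loc[b_term, "F"] == pytest.approx(36.0)
        assert tab.loc[ab_term, "F"] == pytest.approx(4.0)

    def test_constant_response_reports_p_one(self):
        df = two_by_two()
        df["y"] = 5.0
        res = ps.anova_two_way(df, "y")
        terms = [t for t in res.table.index if t != "Residual"]
        assert (res.table.loc[terms, "p"] == 1.0).all()

    def test_ss_decomposition_sums_to_total(self, rng):
        rows = []
        for a in "pqr":
            for b in "uv":
                for _ in range(3):
                    rows.append({"depth_cm": a, "temperature_C": b,
                                 "y": rng.normal()})
        df = pd.DataFrame(rows)
        res = ps.anova_two_way(df, "y")
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert res.table["sum_sq"].sum() == pytest.approx(total, rel=1e-10)

    def test_interaction_null_calibration(self):
        """Additive truth: the interaction test rejects at ~alpha."""
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rows = []
            for i, a in enumerate(["a1", "a2", "a3"]):
                for j, b in enumerate(["b1", "b2"]):
                    for _ in range(3):
                        rows.append({"depth_cm": a, "temperature_C": b,
                                     "y": i + 0.5 * j + rng.normal()})
            res = ps.anova_two_way(pd.DataFrame(rows), "y")
            ab = [t for t in res.table.index if ":" in t][0]
            rejections += res.table.loc[ab, "p"] < 0.05
        # binomial(100, 0.05): 3-sigma band ~ [0, 12]
        assert rejections <= 12

    def test_empty_cell_with_interaction_rejected(self):
        df = two_by_two().iloc[2:]
        with pytest.raises(ValueError, match="empty cells"):
            ps.anova_two_way(df, "y")


class TestBlockedAnova:
    def test_pure_factor_effect_matches_two_way_without_interaction(self,
                                                                    rng):
        rows = []
        for i, a in enumerate(["a1", "a2", "a3"]):
            for b in ["b1", "b2"]:
                for _ in range(2):
                    rows.append({"depth_cm": a, "temperature_C": b,
                                 "y": 2.0 * i + rng.normal()})
        df = pd.DataFrame(rows)
        blocked = ps.anova_blocked(df, "y")
        twoway = ps.anova_two_way(df, "y", interaction=False)
        a_term = [t for t in blocked.table.index if "depth" in t][0]
        assert blocked.table.loc[a_term, "F"] == pytest.approx(
            twoway.table.loc[a_term, "F"])

    def test_block_shift_absorbed(self):
        """Pure block shifts with no factor effect: the block soaks up all
        systematic variation and the factor F stays near zero."""
        rows = []
        rng = np.random.default_rng(7)
        for a in ["a1", "a2"]:
            for j, b in enumerate(["b1", "b2", "b3"]):
                for _ in range(3):
                    rows.append({"depth_cm": a, "temperature_C": b,
                                 "y": 10.0 * j + rng.normal()})
        res = ps.anova_blocked(pd.DataFrame(rows), "y")
        block_term = [t for t in res.table.index if "temperature" in t][0]
        a_term = [t for t in res.table.index if "depth" in t][0]
        assert res.table.loc[block_term, "sum_sq"] > \
            100 * res.table.loc[a_term, "sum_sq"]
        assert res.table.loc[a_term, "p"] > 0.05

    def test_factor_null_p_uniform_over_seeds(self):
        """With no factor effect the factor p-value is ~Uniform(0,1)."""
        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            rows = [{"depth_cm": a, "temperature_C": b,
                     "y": j + rng.normal()}
                    for a in ["a1", "a2", "a3"]
                    for j, b in enumerate(["b1", "b2"])
                    for _ in range(2)]
            res = ps.anova_blocked(pd.DataFrame(rows), "y")
            a_term = [t for t in res.table.index if "depth" in t][0]
            pvals.append(res.table.loc[a_term, "p"])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_block_reduces_to_one_way(self, rng):
        rows = [{"depth_cm": a, "temperature_C": "b1", "y": rng.normal()}
                for a in ["a1", "a2", "a3"] for _ in range(4)]
        df = pd.DataFrame(rows)
        blocked = ps.anova_blocked(df, "y")
        oneway = ps.anova_one_way(df, "y", "depth_cm")
        a_b = [t for t in blocked.table.index if "depth" in t][0]
        a_o = [t for t in oneway.table.index if "depth" in t][0]
        assert blocked.table.loc[a_b, "F"] == pytest.approx(
            oneway.table.loc[a_o, "F"])

    def test_missing_cell_named_in_error(self):
        df = pd.DataFrame({"depth_cm": ["a1", "a1", "a2"],
                           "temperature_C": ["b1", "b2", "b1"],
                           "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing cells"):
            ps.anova_blocked(df, "y")


def make_groups(means, sd, n, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, m in enumerate(means):
        for _ in range(n):
            rows.append({"depth_cm": f"g{i}", "y": m + rng.normal(0, sd)})
    return pd.DataFrame(rows)


class TestTukeyCLD:
    def test_identical_groups_share_a_letter(self):
        df = pd.DataFrame({"depth_cm": ["g0"] * 4 + ["g1"] * 4,
                           "y": [5.0, 5.1, 4.9, 5.0] * 2})
        res = ps.anova_one_way(df, "y", "depth_cm")
        cld = ps.tukey_cld(res, df, "y", "depth_cm")
        assert cld.letters["g0"] == cld.letters["g1"] == "a"
        assert cld.p_matrix.loc["g0", "g1"] > 0.9

    def test_separated_group_gets_own_letter(self):
        df = make_groups([0.0, 0.0, 10.0], sd=0.1, n=5)
        res = ps.anova_one_way(df, "y", "depth_cm")
        cld = ps.tukey_cld(res, df, "y", "depth_cm")
        assert cld.letters["g0"] == cld.letters["g1"]
        assert cld.letters["g2"] != cld.letters["g0"]
        assert len(set(cld.letters.values())) == 2

    def test_tukey_p_not_below_pairwise_t(self):
        """Against the unadjusted pairwise t-test on the same error stratum
        (ANOVA MSE, residual df), the studentized-range p is never smaller."""
        df = make_groups([0.0, 0.5, 1.0, 2.0], sd=1.0, n=5, seed=3)
        res = ps.anova_one_way(df, "y", "depth_cm")
        cld = ps.tukey_cld(res, df, "y", "depth_cm")
        tab = res.table
        mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
        dfr = tab.loc["Residual", "df"]
        for a, b in itertools.combinations(df["depth_cm"].unique(), 2):
            ya = df[df["depth_cm"] == a]["y"]
            yb = df[df["depth_cm"] == b]["y"]
            t = abs(ya.mean() - yb.mean()) / np.sqrt(
                mse * (1 / len(ya) + 1 / len(yb)))
            p_t = 2 * sps.t.sf(t, dfr)
            assert cld.p_matrix.loc[a, b] >= p_t - 1e-10

    def test_letters_consistent_with_p_matrix_over_random_draws(self):
        """Brute-force validity: levels share a letter iff p > alpha, and
        every non-significant pair shares at least one letter."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = make_groups(rng.uniform(0, 3, 5), sd=0.5, n=4, seed=seed)
            res = ps.anova_one_way(df, "y", "depth_cm")
            cld = ps.tukey_cld(res, df, "y", "depth_cm")
            for a, b in itertools.combinations(df["depth_cm"].unique(), 2):
                shared = set(cld.letters[a]) & set(cld.letters[b])
                if cld.p_matrix.loc[a, b] > 0.05:
                    assert shared, (a, b, cld.letters)
                else:
                    assert not shared, (a, b, cld.letters)


class TestAssumptionChecks:
    def test_symmetric_residuals_near_zero_skew(self):
        r = np.concatenate([np.linspace(-3, 3, 101)])
        out = ps.assumption_checks(r)
        assert abs(out["skewness"]) < 1e-10

    def test_normal_residuals_pass_shapiro_most_seeds(self):
        passes = 0
        for seed in range(40):
            r = np.random.default_rng(seed).normal(size=100)
            out = ps.assumption_checks(r)
            passes += out["shapiro_p"] > 0.05
        assert passes >= 33  # ~95% nominal

    def test_equal_variance_groups_levene_null(self):
        pvals = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            r = rng.normal(size=60)
            g = np.repeat(["a", "b", "c"], 20)
            pvals.append(ps.assumption_checks(r, g)["levene_p"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_tiny_sample_skipped(self):
        assert ps.assumption_checks([1.0, 2.0]).get("skipped")


class TestPercentDecline:
    def _table(self, upper_vals, lower_vals):
        rows = []
        for t in (4.0, 25.0):
            for depth, vals in (("0-10", upper_vals), ("80-90", lower_vals)):
                for v in vals:
                    rows.append({"depth_cm": depth, "temperature_C": t,
                                 "vmax_ds": v})
        return pd.DataFrame(rows)

    def test_direct_arithmetic(self):
        out = ps.percent_decline(self._table([100.0], [3.6]), "vmax_ds",
                                 upper=("0-10",), lower=("80-90",))
        assert out["mean"] == pytest.approx(96.4)

    def test_max_upper_min_lower(self):
        # upper means {100, 90}, lower means {5, 3.6} -> (100-3.6)/100
        rows = []
        for t in (4.0,):
            for depth, v in [("0-10", 100.0), ("10-20", 90.0),
                             ("60-70", 5.0), ("80-90", 3.6)]:
                rows.append({"depth_cm": depth, "temperature_C": t,
                             "vmax_ds": v})
        out = ps.percent_decline(pd.DataFrame(rows), "vmax_ds")
        assert out["per_temperature"][4.0] == pytest.approx(96.4)

    def test_equal_profiles_zero_decline(self):
        out = ps.percent_decline(self._table([7.0], [7.0]), "vmax_ds",
                                 upper=("0-10",), lower=("80-90",))
        assert out["mean"] == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        tab = self._table(rng.uniform(50, 100, 3), rng.uniform(1, 10, 3))
        out1 = ps.percent_decline(tab, "vmax_ds",
                                  upper=("0-10",), lower=("80-90",))
        tab2 = tab.copy()
        tab2["vmax_ds"] *= 13.7
        out2 = ps.percent_decline(tab2, "vmax_ds",
                                  upper=("0-10",), lower=("80-90",))
        assert out1["mean"] == pytest.approx(out2["mean"], rel=1e-12)

    def test_cell_exclusion_mechanism(self):
        tab = self._table([100.0], [5.0])
        # poison one temperature's lower cell, then exclude it
        tab.loc[(tab["temperature_C"] == 25.0)
                & (tab["depth_cm"] == "80-90"), "vmax_ds"] = 90.0
        out = ps.percent_decline(tab, "vmax_ds", upper=("0-10",),
                                 lower=("80-90",),
                                 exclude_cells=[("80-90", 25.0)])
        assert out["per_temperature"][4.0] == pytest.approx(95.0)
        assert 25.0 not in out["per_temperature"]


class TestEnzymeRatios:
    def _traits(self, vals_by_enzyme):
        rows = []
        for enz, (vm, km, ce) in vals_by_enzyme.items():
            rows.append({"enzyme": enz, "depth_cm": "0-10", "core": 1,
                         "temperature_C": 16.0, "vmax_ds": vm, "km": km,
                         "ce_ds": ce})
        return pd.DataFrame(rows)

    def test_identical_traits_unit_ratios(self):
        tr = self._traits({"BG": (10, 5, 2), "LAP": (10, 5, 2),
                           "AP": (10, 5, 2)})
        out = ps.enzyme_ratios(tr)
        assert len(out) == 3
        assert np.allclose(out[["vmax_ds_ratio", "km_ratio",
                                "ce_ds_ratio"]], 1.0)

    def test_direct_ratio(self):
        tr = self._traits({"BG": (10, 5, 2), "AP": (4, 5, 0.8)})
        out = ps.enzyme_ratios(tr)
        bg_ap = out[out["pair"] == "BG:AP"].iloc[0]
        assert bg_ap["vmax_ds_ratio"] == pytest.approx(2.5)

    def test_reciprocal_product_is_one(self, rng):
        tr = self._traits({e: tuple(rng.uniform(1, 100, 3))
                           for e in ("BG", "LAP", "AP")})
        out = ps.enzyme_ratios(tr).set_index("pair")
        for col in ("vmax_ds_ratio", "km_ratio", "ce_ds_ratio"):
            fwd = out.loc["BG:AP", col]
            # reconstruct the reverse from the raw table
            bg = tr[tr["enzyme"] == "BG"].iloc[0]
            ap = tr[tr["enzyme"] == "AP"].iloc[0]
            rev = ap[col.replace("_ratio", "")] / bg[col.replace("_ratio",
                                                                 "")]
            assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_missing_partner_gives_no_row(self):
        tr = self._traits({"BG": (10, 5, 2)})
        out = ps.enzyme_ratios(tr)
        assert out.empty
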