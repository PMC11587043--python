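"""Repeated-measures ANOVA, Dunnett many-to-one, Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import critpow as cw
from critpow.stats import StatsError, _dunnett_max_abs_cdf


def _random_table(rng, n=10, conds=("3MT", "CPT<1", "CPT1-3", "CPT3-6"),
                  effect=0.0, variable="total_w_prime"):
    rows = []
    for i in range(n):
        base = rng.normal(0, 1)
        for j, c in enumerate(conds):
            rows.append((f"a{i:02d}", c, variable,
                         base + rng.normal(0, 1) + effect * j))
    return pd.DataFrame(rows, columns=["athlete_id", "condition", "variable", "value"])


class TestDunnettDistribution:
    def test_single_comparison_reduces_to_two_sided_t(self):
        for t in (0.5, 1.5, 2.5):
            p = cw.dunnett_pvalue(t, 1, 30)[0]
            assert p == pytest.approx(2 * sps.t.sf(t, 30), abs=2e-4)

    def test_matches_multivariate_t_oracle(self):
        k, df = 5, 135
        R = np.full((k, k), 0.5)
        np.fill_diagonal(R, 1.0)
        mvt = sps.multivariate_t(shape=R, df=df)
        for q in (1.5, 2.0, 2.6, 3.2):
            mine = _dunnett_max_abs_cdf(q, k, df)[0]
            oracle = mvt.cdf(np.full(k, q), lower_limit=np.full(k, -q),
                             random_state=np.random.default_rng(0))
            assert mine == pytest.approx(float(oracle), abs=2e-3)

    def test_critical_value_inverts_cdf(self):
        c = cw.dunnett_critical(0.05, 5, 135)
        assert 2.0 < c < 3.0
        assert _dunnett_max_abs_cdf(c, 5, 135)[0] == pytest.approx(0.95, abs=1e-6)

    def test_pvalue_monotone_in_statistic(self):
        p = cw.dunnett_pvalue(np.array([0.5, 1.0, 2.0, 3.0]), 5, 100)
        assert np.all(np.diff(p) < 0)


class TestRmAnova:
    def test_identical_values_give_null_result(self):
        rows = [(f"a{i}", c, "ep", 10.0 + i)
                for i in range(5) for c in ("3MT", "CPT<1", "CPT1-3")]
        table = pd.DataFrame(rows, columns=["athlete_id", "condition", "variable", "value"])
        res = cw.rm_anova_cs(table, "ep", "3MT")
        assert res.F == 0.0
        assert res.p_omnibus == 1.0
        assert np.all(res.comparisons["p_adj"] == 1.0)

    def test_balanced_f_matches_anovarm(self, rng):
        table = _random_table(rng, n=12, effect=0.3)
        res = cw.rm_anova_cs(table, "total_w_prime", "3MT")
        from statsmodels.stats.anova import AnovaRM
        ref = AnovaRM(table.rename(columns={"athlete_id": "s", "condition": "c",
                                            "value": "v"}),
                      "v", "s", within=["c"]).fit().anova_table
        assert res.F == pytest.approx(float(ref["F Value"].iloc[0]))
        assert res.df_den == float(ref["Den DF"].iloc[0])
        assert res.p_omnibus == pytest.approx(float(ref["Pr > F"].iloc[0]))

    def test_balanced_f_matches_pingouin(self, rng):
        import pingouin as pg
        table = _random_table(rng, n=9, effect=0.5)
        res = cw.rm_anova_cs(table, "total_w_prime", "3MT")
        ref = pg.rm_anova(data=table, dv="value", within="condition",
                          subject="athlete_id")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]))

    def test_unbalanced_mixed_model_close_to_balanced(self, rng):
        table = _random_table(rng, n=14, effect=0.4)
        balanced = cw.rm_anova_cs(table, "total_w_prime", "3MT")
        dropped = table.drop(index=[3]).reset_index(drop=True)
        mixed = cw.rm_anova_cs(dropped, "total_w_prime", "3MT")
        assert mixed.F == pytest.approx(balanced.F, rel=0.25)
        assert set(mixed.comparisons["condition"]) == set(balanced.comparisons["condition"])
        assert np.all((mixed.comparisons["p_adj"] >= 0) & (mixed.comparisons["p_adj"] <= 1))

    def test_missing_variable_or_control_rejected(self, rng):
        table = _random_table(rng)
        with pytest.raises(StatsError, match="absent"):
            cw.rm_anova_cs(table, "ep", "3MT")
        with pytest.raises(StatsError, match="control"):
            cw.rm_anova_cs(table, "total_w_prime", "Traditional")

    def test_omnibus_invariant_under_condition_relabeling(self, rng):
        table = _random_table(rng, n=10, effect=0.3)
        res1 = cw.rm_anova_cs(table, "total_w_prime", "3MT")
        relabeled = table.replace({"condition": {"CPT<1": "CPT3-6", "CPT3-6": "CPT<1"}})
        res2 = cw.rm_anova_cs(relabeled, "total_w_prime", "3MT")
        assert res2.F == pytest.approx(res1.F)

    def test_dunnett_never_exceeds_bonferroni(self, rng):
        for _ in range(15):
            table = _random_table(rng, n=8, effect=rng.uniform(0, 0.6))
            dun = cw.rm_anova_cs(table, "total_w_prime", "3MT", procedure="dunnett")
            bon = cw.rm_anova_cs(table, "total_w_prime", "3MT", procedure="bonferroni")
            assert np.all(dun.comparisons["p_adj"] <= bon.comparisons["p_adj"] + 1e-12)

    def test_summary_renders(self, rng):
        res = cw.rm_anova_cs(_random_table(rng), "total_w_prime", "3MT")
        assert "omnibus" in res.summary()


class TestBonferroniCompare:
    def test_single_pair_unadjusted(self, rng):
        table = _random_table(rng)
        res = cw.bonferroni_compare(table, "total_w_prime", [("3MT", "CPT<1")])
        row = res.comparisons.iloc[0]
        assert row["p_adj"] == pytest.approx(row["p_raw"])

    def test_adjustment_capped_at_one(self, rng):
        table = _random_table(rng, n=12, effect=0.0)
        pairs = [("3MT", c) for c in ("CPT<1", "CPT1-3", "CPT3-6")] * 2
        res = cw.bonferroni_compare(table, "total_w_prime", pairs)
        assert np.all(res.comparisons["p_adj"] <= 1.0)
        assert np.all(res.comparisons["p_adj"] == np.minimum(
            1.0, len(pairs) * res.comparisons["p_raw"]))

    def test_missing_condition_rejected(self, rng):
        table = _random_table(rng)
        with pytest.raises(StatsError, match="missing condition"):
            cw.bonferroni_compare(table, "total_w_prime", [("3MT", "Traditional")])


class TestBuildLongTable:
    @staticmethod
    def _athlete(aid, cohort_entry=None):
        fit = cw.fit_power_inverse_time([(450.0, 60.0), (350.0, 120.0),
                                         (290.0, 300.0), (270.0, 600.0)])
        three = cw.ThreeMtResult(ep=260.0, w_prime=14000.0, ep_window_s=30,
                                 test_duration_s=180)
        cpt = cw.CptResult(ep_individual=255.0, ep_reference=260.0,
                           constant_w_prime=9000.0, unaccounted_w_prime=2000.0,
                           used_fallback=False, duration_bin="3-6 min",
                           constant_duration_s=200.0)
        return cw.AthleteResult(athlete_id=aid, traditional_fit=fit,
                                three_mt=three, cpt_results={"3-6 min": cpt})

    def test_row_counts_and_values(self):
        table = cw.build_long_table([self._athlete("a1"), self._athlete("a2")])
        # per athlete: 2 (Traditional) + 2 (3MT) + 4 (one CPT) = 8 rows
        assert len(table) == 16
        cell = table.query("athlete_id == 'a1' and condition == 'CPT3-6' and "
                           "variable == 'total_w_prime'")["value"]
        assert float(cell.iloc[0]) == pytest.approx(11000.0)

    def test_missing_bin_produces_no_row(self):
        athlete = self._athlete("a1")
        athlete.cpt_results = {}
        table = cw.build_long_table([athlete])
        assert not (table["condition"].str.startswith("CPT")).any()

    def test_duplicates_rejected(self):
        with pytest.raises(StatsError, match="duplicate"):
            cw.build_long_table([self._athlete("a1"), self._athlete("a1")])

    def test_cohort_aggregation_consistency(self, small_noisy_cohort):
        """Condition means of the long table equal means of the underlying
        per-athlete results."""
        report = cw.analyze_cohort(small_noisy_cohort)
        table = report.long_table
        ep_mean = table.query("condition == '3MT' and variable == 'ep'")["value"].mean()
        direct = np.mean([a.three_mt.ep for a in report.athletes])
        assert ep_mean == pytest.approx(direct)


class TestCalibration:
    def test_null_fwer_near_alpha(self):
        """At a reduced replicate count the family-wise error sits near the
        nominal 5% and Dunnett dominates Bonferroni on every replicate."""
        out = cw.simulate_null_fwer(n_athletes=28, k_conditions=6, reps=400,
                                    alpha=0.05, seed=2)
        assert 0.02 <= out["fwer_dunnett"] <= 0.09
        assert out["dunnett_le_bonferroni_fraction"] == 1.0
        assert out["fwer_bonferroni"] <= out["fwer_dunnett"] + 0.01

    def test_power_pattern_mimicking_cohort_totals(self):
        """With condition means/SDs like the observed total-W' pattern and a
        0.7 compound-symmetric correlation, the long-duration tests are
        flagged against the all-out control in most replicates."""
        means = np.array([15311.0, 14674.0, 15941.0, 20417.0, 26968.0])
        sds = np.array([5397.0, 3390.0, 6476.0, 8297.0, 14624.0])
        rho, n, reps = 0.7, 28, 100
        cov = rho * np.outer(sds, sds)
        np.fill_diagonal(cov, sds ** 2)
        rng = np.random.default_rng(5)
        conds = ["3MT", "CPT<1", "CPT1-3", "CPT3-6", "CPT>6"]
        flagged = np.zeros(2)
        for _ in range(reps):
            y = rng.multivariate_normal(means, cov, size=n)
            rows = [(f"a{i}", c, "total_w_prime", y[i, j])
                    for i in range(n) for j, c in enumerate(conds)]
            table = pd.DataFrame(rows, columns=["athlete_id", "condition",
                                                "variable", "value"])
            res = cw.rm_anova_cs(table, "total_w_prime", "3MT")
            cmp = res.comparisons.set_index("condition")["p_adj"]
            flagged += [cmp["CPT3-6"] < 0.05, cmp["CPT>6"] < 0.05]
        assert flagged[1] / reps >= 0.8  # >6 min separates almost always
        assert flagged[0] / reps >= 0.8
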