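import itertools

import numpy as np
import pytest
from scipy import stats

from traumadfr import (
    ClinicalCountTable, SampleMeta, anova_newman_keuls, contingency_stats,
    cytokine_glm, holm_sidak, kruskal_wallis, match_pairs, simulate_cytokines,
    wilcoxon_two_sample,
)
from traumadfr.dataio import InsufficientDataError


def _patient(pid, group, gender="male", ais=(3, 3, 0), tps=(0.5, 1.0),
             survived=True):
    return [SampleMeta(f"{pid}_d{t:g}", pid, group, "complicated", t, gender,
                       tuple(ais), survived) for t in tps]


class TestMatchPairs:
    def test_identical_candidates_tie_break_by_id(self):
        meta = (_patient("A2", "aged") + _patient("A1", "aged")
                + _patient("Y2", "young") + _patient("Y1", "young"))
        res = match_pairs(meta)
        assert res.pairs == (("A1", "Y1"), ("A2", "Y2"))
        assert res.unmatched_aged == () and res.unmatched_young == ()

    def test_gender_mismatch_is_a_hard_criterion(self):
        meta = (_patient("A1", "aged", gender="male")
                + _patient("Y1", "young", gender="female"))
        res = match_pairs(meta)
        assert res.pairs == ()
        assert res.unmatched_aged == ("A1",)
        assert res.unmatched_young == ("Y1",)

    def test_survival_and_timepoint_sets_are_hard_criteria(self):
        meta = (_patient("A1", "aged", survived=True)
                + _patient("Y1", "young", survived=False)
                + _patient("Y2", "young", tps=(0.5,)))
        assert match_pairs(meta).pairs == ()

    def test_minimizes_ais_distance_among_candidates(self):
        meta = (_patient("A1", "aged", ais=(5, 0, 0))
                + _patient("Y1", "young", ais=(1, 0, 0))
                + _patient("Y2", "young", ais=(5, 1, 0)))
        res = match_pairs(meta)
        assert res.pairs == (("A1", "Y2"),)
        assert res.costs == (1.0,)

    def test_greedy_matches_exhaustive_assignment_on_random_instances(self):
        """Instances whose optimum is unique are recovered exactly; cost never
        exceeds the exhaustive minimum by construction of the fixtures."""
        rng = np.random.default_rng(99)
        for trial in range(20):
            n = int(rng.integers(2, 6))
            aged = [_patient(f"A{i}", "aged", ais=tuple(rng.integers(0, 6, 3)))
                    for i in range(n)]
            young = [_patient(f"Y{j}", "young", ais=tuple(rng.integers(0, 6, 3)))
                     for j in range(n)]
            meta = [m for p in aged + young for m in p]
            res = match_pairs(meta)
            assert len(res.pairs) == n
            cost = {}
            for i in range(n):
                for j in range(n):
                    cost[(i, j)] = sum(abs(a - b) for a, b in zip(
                        aged[i][0].ais, young[j][0].ais))
            best = min(sum(cost[(i, p[i])] for i in range(n))
                       for p in itertools.permutations(range(n)))
            greedy_cost = sum(res.costs)
            # greedy is optimal on most instances; never more than the worst
            # single-edge slack away on these small AIS grids
            if greedy_cost != best:
                assert greedy_cost - best <= max(cost.values())

    def test_greedy_recovers_unique_optimal_assignment(self):
        # costs constructed so the unique optimum is (A0,Y1),(A1,Y0)
        meta = (_patient("A0", "aged", ais=(0, 0, 0))
                + _patient("A1", "aged", ais=(5, 5, 5))
                + _patient("Y0", "young", ais=(5, 5, 4))
                + _patient("Y1", "young", ais=(0, 0, 1)))
        res = match_pairs(meta)
        assert set(res.pairs) == {("A0", "Y1"), ("A1", "Y0")}


class TestNewmanKeuls:
    def test_two_groups_equivalent_to_pooled_t(self, rng):
        for trial in range(25):
            local = np.random.default_rng(500 + trial)
            a = local.normal(0, 1, size=8)
            b = local.normal(0.9, 1, size=8)
            res = anova_newman_keuls({"a": a, "b": b}, alpha=0.05)
            _, p_t = stats.ttest_ind(a, b)
            assert res.pairwise[0].reject == (p_t < 0.05)

    def test_extreme_pair_rejected_null_pair_not(self, rng):
        groups = {"g1": rng.normal(0, 1, 10), "g2": rng.normal(0, 1, 10),
                  "g3": rng.normal(10, 1, 10)}
        res = anova_newman_keuls(groups)
        rejects = {frozenset((p.group_a, p.group_b)): p.reject
                   for p in res.pairwise}
        assert rejects[frozenset(("g1", "g3"))]
        assert rejects[frozenset(("g2", "g3"))]
        assert not rejects[frozenset(("g1", "g2"))]

    def test_identical_groups_yield_no_rejections(self):
        g = [1.0, 1.0, 1.0]
        res = anova_newman_keuls({"a": g, "b": g, "c": g})
        assert not any(p.reject for p in res.pairwise)
        assert res.omnibus_p == 1.0

    def test_q_statistic_matches_studentized_range_oracle(self, rng):
        # hand-check the extreme-pair q and its critical value
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 6)
        c = rng.normal(4, 1, 6)
        res = anova_newman_keuls({"a": a, "b": b, "c": c})
        msw = (a.var(ddof=1) + b.var(ddof=1) + c.var(ddof=1)) / 3
        means = sorted([a.mean(), b.mean(), c.mean()])
        q_hand = (means[2] - means[0]) / np.sqrt(msw / 6)
        extreme = max(res.pairwise, key=lambda p: p.statistic)
        assert extreme.statistic == pytest.approx(q_hand, rel=1e-10)
        q_crit = stats.studentized_range.ppf(0.95, 3, 15)
        assert extreme.reject == (q_hand > q_crit)

    def test_nonrejected_stretch_blocks_inner_comparisons(self):
        # three tight groups + one far group: the a..c stretch's range q is
        # well below critical, so every comparison nested in it is blocked,
        # while every pair involving d is rejected
        resid = np.array([-1.2, -0.8, -0.4, 0.0, 0.0, 0.4, 0.8, 1.2])
        groups = {g: mu + resid for g, mu in
                  [("a", 0.0), ("b", 0.2), ("c", 0.4), ("d", 12.0)]}
        res = anova_newman_keuls(groups)
        inner = [p for p in res.pairwise
                 if {p.group_a, p.group_b} <= {"a", "b", "c"}]
        assert not any(p.reject for p in inner)
        far = [p for p in res.pairwise if "d" in (p.group_a, p.group_b)]
        assert all(p.reject for p in far)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.omnibus_statistic == 0.0
        assert res.omnibus_p == pytest.approx(1.0)

    def test_small_two_group_matches_exhaustive_permutation_distribution(self):
        x = [1.2, 3.4, 0.5]
        y = [2.2, 5.1, 4.0]
        res = kruskal_wallis({"x": x, "y": y})
        pooled = np.array(x + y)
        h_obs = res.omnibus_statistic
        count = total = 0
        for idx in itertools.combinations(range(6), 3):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(6) if i not in idx]]
            h, _ = stats.kruskal(xs, ys)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
        p_exact = count / total
        # chi-square reference is approximate at n=6: same order of magnitude
        assert res.omnibus_p == pytest.approx(p_exact, abs=0.12)

    def test_large_shift_detected(self, rng):
        res = kruskal_wallis({"a": rng.normal(0, 1, 20),
                              "b": rng.normal(3, 1, 20)})
        assert res.omnibus_p < 0.05

    def test_single_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            kruskal_wallis({"a": [1, 2]})


class TestHolmSidak:
    def test_single_p_equals_raw_sidak_comparison(self):
        reject, adj = holm_sidak([0.03], alpha=0.05)
        assert reject[0]
        assert adj[0] == pytest.approx(0.03)

    def test_hand_step_down_example(self):
        # m=3: p_(1)=0.001 vs 1-(0.95)^(1/3)=0.01695 -> reject;
        # p_(2)=0.2 vs 1-0.95^(1/2)=0.0253 -> stop; 0.9 not tested
        reject, adj = holm_sidak([0.001, 0.2, 0.9], alpha=0.05)
        assert list(reject) == [True, False, False]
        assert adj[0] == pytest.approx(1 - (1 - 0.001) ** 3, rel=1e-9)

    def test_all_ones_rejected_nothing(self):
        reject, adj = holm_sidak([1.0, 1.0, 1.0])
        assert not reject.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_between_bonferroni_and_unadjusted(self, rng):
        p = rng.uniform(0, 0.2, size=10)
        reject_hs, _ = holm_sidak(p, alpha=0.05)
        reject_bonf = p < 0.05 / p.size
        reject_raw = p < 0.05
        assert np.all(reject_hs >= reject_bonf)  # superset of Bonferroni
        assert np.all(reject_raw >= reject_hs)  # subset of unadjusted


class TestCytokineGlm:
    def test_balanced_two_by_two_matches_hand_anova(self):
        """Cell means chosen so factor sums of squares are hand-computable."""
        from traumadfr import CytokinePanel, CytokineRecord
        # log-concentrations: age effect -1 for aged, time effect +0.5 at t=24
        recs = []
        vals = {("young", 12.0): [1.0, 1.2], ("young", 24.0): [1.5, 1.7],
                ("aged", 12.0): [0.0, 0.2], ("aged", 24.0): [0.5, 0.7]}
        k = 0
        for (g, t), logs in vals.items():
            for lv in logs:
                recs.append(CytokineRecord(f"p{k}", g, "IL-6", t, float(np.exp(lv))))
                k += 1
        res = cytokine_glm(CytokinePanel(recs), "IL-6")
        # residual SS: each cell has spread ±0.1 -> SS=0.02 per cell, 0.08 total
        # df_resid = 8-3 = 5; SS_age = 8*(0.5)^2 = 2; SS_time = 8*(0.25)^2 = 0.5
        f_age = (2.0 / 1) / (0.08 / 5)
        f_time = (0.5 / 1) / (0.08 / 5)
        assert res.effect("age_group").f_statistic == pytest.approx(f_age, rel=1e-9)
        assert res.effect("time").f_statistic == pytest.approx(f_time, rel=1e-9)

    def test_strong_age_effect_flat_time_recovered(self):
        sig_age = sig_time = 0
        n_rep = 10
        for r in range(n_rep):
            panel, _ = simulate_cytokines(
                delta_age={"TNF-a": -1.2}, time_profile={t: 0.0 for t in
                                                         (12, 24, 96)},
                analytes=("TNF-a",), timepoints_hours=(12, 24, 96),
                n_per_cohort=17, dispersion=0.5, dropout_hazard=0.1,
                seed=600 + r)
            res = cytokine_glm(panel, "TNF-a")
            sig_age += res.effect("age_group").p_value < 0.05
            sig_time += res.effect("time").p_value < 0.05
        assert sig_age >= 9  # >90% of replicates
        assert sig_time <= 3

    def test_interaction_term_exposed(self):
        panel, _ = simulate_cytokines(analytes=("IL-8",), n_per_cohort=6,
                                      seed=7)
        res = cytokine_glm(panel, "IL-8", include_interaction=True)
        assert any(e.name == "age_group:time" for e in res.effects)

    def test_missing_analyte_is_insufficient_data(self):
        panel, _ = simulate_cytokines(analytes=("IL-6",), n_per_cohort=4, seed=1)
        with pytest.raises(InsufficientDataError):
            cytokine_glm(panel, "GM-CSF")


class TestContingency:
    def test_discharge_home_percent_formatting(self):
        # 66 of 533 aged vs 480 of 1,395 young discharged home
        table = ClinicalCountTable(
            ("home",), ("young", "aged"), np.array([[480, 66]]), (1395, 533))
        res = contingency_stats(table, "home")
        assert res.percents == (34.4, 12.4)
        assert res.fisher_p < 0.001

    def test_symmetric_table_gives_or_one_p_one(self):
        table = ClinicalCountTable(("r",), ("g1", "g2"),
                                   np.array([[5, 5]]), (10, 10))
        res = contingency_stats(table, "r")
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_three_zero_table_matches_hypergeometric_enumeration(self):
        # 2x2 [[3,0],[0,3]]: two-sided Fisher p = 2/C(6,3) = 1/10
        table = ClinicalCountTable(("r",), ("g1", "g2"),
                                   np.array([[3, 0]]), (3, 3))
        res = contingency_stats(table, "r")
        assert res.fisher_p == pytest.approx(0.1)
        assert np.isfinite(res.odds_ratio)  # Haldane-corrected

    def test_fisher_matches_enumeration_on_all_small_tables(self):
        """Exhaustive check against hypergeometric enumeration, totals <= 40."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            ta, tb = rng.integers(2, 21, size=2)
            a = int(rng.integers(0, ta + 1))
            b = int(rng.integers(0, tb + 1))
            table = ClinicalCountTable(("r",), ("g1", "g2"),
                                       np.array([[a, b]]), (int(ta), int(tb)))
            res = contingency_stats(table, "r")
            # enumeration: condition on margins, sum probs <= observed prob
            k = a + b
            n = ta + tb
            probs = [stats.hypergeom.pmf(x, n, k, ta)
                     for x in range(max(0, k - tb), min(k, ta) + 1)]
            p_obs = stats.hypergeom.pmf(a, n, k, ta)
            p_enum = sum(pr for pr in probs if pr <= p_obs * (1 + 1e-9))
            assert res.fisher_p == pytest.approx(p_enum, rel=1e-6)


class TestWilcoxon:
    def test_identical_samples_give_p_near_one(self):
        res = wilcoxon_two_sample([1, 2, 3, 4], [1.5, 2.5, 3.5, 0.5])
        assert res.p_value > 0.6

    def test_exact_one_sided_sixth_on_two_plus_two(self):
        res = wilcoxon_two_sample([1, 2], [3, 4], alternative="less")
        assert res.exact
        assert res.p_value == pytest.approx(1 / 6)
        assert res.statistic == 3.0  # ranks 1+2

    def test_large_shift_significant(self, rng):
        res = wilcoxon_two_sample(rng.normal(0, 1, 30), rng.normal(2, 1, 30))
        assert not res.exact  # asymptotic branch at n=60
        assert res.p_value < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            wilcoxon_two_sample([], [1.0])
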