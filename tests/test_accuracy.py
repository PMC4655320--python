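"""Paired diagnostic accuracy: metric identities, paired tests, oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from popscreen._errors import UndefinedMetricError
from popscreen.accuracy import (
    DiagnosticSummary,
    PairedScreenData,
    bootstrap_paired_p,
    likelihood_ratio_test,
    mcnemar_p,
    predictive_value_test,
    relative_sensitivity,
    roc_auc,
    round_half_up,
    summarize,
)


def random_paired(rng, n=800, prev=0.2, sens=(0.6, 0.75), spec=(0.9, 0.85)):
    d = rng.random(n) < prev
    a = np.where(d, rng.random(n) < sens[0], rng.random(n) < 1 - spec[0])
    b = np.where(d, rng.random(n) < sens[1], rng.random(n) < 1 - spec[1])
    return PairedScreenData.from_labels(a.astype(int), b.astype(int), d.astype(int))


class TestSummarize:
    def test_metrics_match_per_subject_counting_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            d = rng.random(300) < 0.3
            t = rng.random(300) < np.where(d, 0.7, 0.15)
            tp = int((t & d).sum())
            fp = int((t & ~d).sum())
            fn = int((~t & d).sum())
            tn = int((~t & ~d).sum())
            s = summarize((tp, fp, fn, tn))
            assert s.sensitivity[0] == pytest.approx(np.mean(t[d]))
            assert s.specificity[0] == pytest.approx(np.mean(~t[~d]))
            assert s.ppv[0] == pytest.approx(np.mean(d[t]))
            assert s.npv[0] == pytest.approx(np.mean(~d[~t]))

    def test_metric_identities_hold_to_machine_precision(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            tp, fp, fn, tn = rng.integers(1, 500, 4)
            s = summarize((tp, fp, fn, tn))
            assert abs(s.sensitivity[0] + s.fnr[0] - 1.0) < 1e-12
            assert abs(s.specificity[0] + s.fpr[0] - 1.0) < 1e-12
            assert s.lr_pos[0] == pytest.approx(
                s.sensitivity[0] / (1 - s.specificity[0]), rel=1e-12
            )
            assert s.lr_neg[0] == pytest.approx(
                (1 - s.sensitivity[0]) / s.specificity[0], rel=1e-12
            )

    def test_perfect_test(self):
        s = summarize((40, 0, 0, 400))
        assert s.sensitivity[0] == s.specificity[0] == s.ppv[0] == s.npv[0] == 1.0

    def test_zero_margin_names_metric(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            summarize((0, 10, 0, 100))
        with pytest.raises(UndefinedMetricError, match="specificity"):
            summarize((10, 0, 5, 0))

    def test_rounding_is_half_up(self):
        assert round_half_up(56.5) == 57.0
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(2.249, 1) == 2.2


class TestPairedScreenData:
    def test_collapsing_reproduces_marginal_tables(self):
        rng = np.random.default_rng(8)
        p = random_paired(rng)
        tp, fp, fn, tn = p.table("a")
        a_pos = p.counts[1, :, :].sum()
        assert tp + fp == a_pos
        assert tp + fp + fn + tn == p.n
        s_direct = summarize(p.table("b"))
        # rebuild test B's table from raw labels
        c = p.counts
        tb = (
            int(c[:, 1, 1].sum()),
            int(c[:, 1, 0].sum()),
            int(c[:, 0, 1].sum()),
            int(c[:, 0, 0].sum()),
        )
        assert summarize(tb) == s_direct


class TestRelativeSensitivity:
    def test_identical_tests(self):
        c = np.zeros((2, 2, 2))
        c[1, 1, 1], c[0, 0, 1], c[1, 1, 0], c[0, 0, 0] = 30, 70, 50, 850
        r = relative_sensitivity(PairedScreenData(c))
        assert r["ratio"] == 1.0 and r["p_mcnemar"] == 1.0

    def test_mcnemar_equals_exact_binomial_enumeration(self):
        # oracle: two-sided exact binomial tail over discordant pairs
        for b, c in [(2, 9), (0, 5), (7, 7), (1, 14)]:
            m = b + c
            k = min(b, c)
            oracle = min(
                1.0,
                2.0 * sum(math.comb(m, i) * 0.5**m for i in range(0, k + 1)),
            )
            assert mcnemar_p(b, c) == pytest.approx(oracle, rel=1e-12)

    def test_mcnemar_invariant_to_concordant_counts(self):
        c1 = np.zeros((2, 2, 2))
        c1[1, 0, 1], c1[0, 1, 1], c1[1, 1, 1], c1[0, 0, 1] = 12, 30, 5, 10
        c2 = c1.copy()
        c2[1, 1, 1], c2[0, 0, 1] = 500, 700
        p1 = relative_sensitivity(PairedScreenData(c1))["p_mcnemar"]
        p2 = relative_sensitivity(PairedScreenData(c2))["p_mcnemar"]
        assert p1 == p2

    def test_detection_counts_reproduce_published_ratio(self):
        # 69 vs 199 detections among 352 diseased: ratio rounds to 2.9
        c = np.zeros((2, 2, 2))
        c[1, 1, 1], c[0, 1, 1], c[0, 0, 1] = 69, 130, 153
        c[0, 0, 0] = 3625
        r = relative_sensitivity(PairedScreenData(c))
        assert round_half_up(r["ratio"], 1) == 2.9

    def test_no_diseased_raises(self):
        c = np.zeros((2, 2, 2))
        c[1, 1, 0] = 50
        with pytest.raises(UndefinedMetricError):
            relative_sensitivity(PairedScreenData(c))


class TestPredictiveValueTest:
    def test_identical_tests_give_null_result(self):
        c = np.zeros((2, 2, 2))
        c[1, 1, 1], c[0, 0, 1], c[1, 1, 0], c[0, 0, 0] = 30, 70, 50, 850
        chi2, p = predictive_value_test(PairedScreenData(c), "ppv")
        assert chi2 == 0.0 and p == 1.0

    @pytest.mark.parametrize("which", ["ppv", "npv"])
    def test_score_and_bootstrap_agree_on_large_gap(self, which):
        # constructed paired data with a large predictive-value gap
        rng = np.random.default_rng(21)
        p = random_paired(rng, n=1500, prev=0.25, sens=(0.5, 0.85), spec=(0.7, 0.95))
        _, p_score = predictive_value_test(p, which)
        p_boot = bootstrap_paired_p(p, which, n_boot=10_000, seed=5)
        assert p_score < 0.05 and p_boot < 0.05

    def test_degenerate_recommends_bootstrap(self):
        c = np.zeros((2, 2, 2))
        c[0, 1, 1], c[0, 0, 0] = 10, 100  # test A never calls positive
        with pytest.raises(UndefinedMetricError, match="bootstrap"):
            predictive_value_test(PairedScreenData(c), "ppv")


class TestLikelihoodRatioTest:
    def test_identical_tests(self):
        c = np.zeros((2, 2, 2))
        c[1, 1, 1], c[0, 0, 1], c[1, 1, 0], c[0, 0, 0] = 30, 70, 50, 850
        z, p = likelihood_ratio_test(PairedScreenData(c), "pos")
        assert z == 0.0 and p == 1.0

    def test_published_tables_direction_favours_selective_lr_pos(self):
        # margins of the published 2x2s; selective LR+ 10.3 vs universal 5.6
        c = np.zeros((2, 2, 2))
        c[1, 1, 1], c[0, 1, 1], c[0, 0, 1] = 69, 130, 153
        c[1, 1, 0], c[0, 1, 0], c[0, 0, 0] = 69, 294, 3262
        paired = PairedScreenData(c)
        sel = summarize(paired.table("a"))
        uni = summarize(paired.table("b"))
        assert round_half_up(sel.lr_pos[0], 1) == 10.3
        assert round_half_up(uni.lr_pos[0], 1) == 5.6
        z, p = likelihood_ratio_test(paired, "pos")
        assert z < 0 and p < 0.05  # universal LR+ significantly lower

    def test_lr_agrees_with_bootstrap_on_gap(self):
        rng = np.random.default_rng(17)
        p = random_paired(rng, n=1500, prev=0.25, sens=(0.5, 0.85), spec=(0.7, 0.95))
        _, p_wald = likelihood_ratio_test(p, "pos")
        p_boot = bootstrap_paired_p(p, "lr_pos", n_boot=10_000, seed=5)
        assert p_wald < 0.05 and p_boot < 0.05


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_null_score_near_half(self):
        rng = np.random.default_rng(14)
        auc, _ = roc_auc(rng.normal(size=2000), rng.random(2000) < 0.3)
        assert 0.47 <= auc <= 0.53

    def test_matches_exhaustive_pair_counting_oracle(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=150)
        d = rng.random(150) < 0.4
        auc, _ = roc_auc(s, d)
        x, z = s[d], s[~d]
        wins = sum((xi > zi) + 0.5 * (xi == zi) for xi in x for zi in z)
        assert auc == pytest.approx(wins / (len(x) * len(z)), rel=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1.0, 2.0], [1, 1])


class TestSensitivityCoverage:
    def test_wilson_interval_covers_in_most_replicates(self):
        """The universal-sensitivity Wilson CI on reduced synthetic cohorts
        covers the long-run sensitivity in >= 93% of 200 seeded replicates."""
        import popscreen.growth as growth
        from popscreen.synthesis import CohortParams, generate_cohort

        eq = growth.EFWEquation.from_registry("hadlock_efw_hc_ac_fl")
        std = growth.GrowthStandard.from_registry("hadlock_weight_for_ga")
        bw = growth.GrowthStandard.from_birthweight_table(
            "uk_birthweight_reference_synthetic.csv"
        )
        est, los, his = [], [], []
        for seed in range(200):
            c = generate_cohort(CohortParams(n_subjects=1000, seed=1000 + seed))
            scans = c.scans
            late = scans[scans["scan_policy"].isin(["research28", "research36"])]
            last = late.groupby("subject_id").tail(1)
            efw = eq.weight_g(
                {
                    "hc_cm": last["hc_mm"].to_numpy() / 10,
                    "ac_cm": last["ac_mm"].to_numpy() / 10,
                    "fl_cm": last["fl_mm"].to_numpy() / 10,
                }
            )
            pct = std.percentile(efw, last["scan_ga_weeks"].to_numpy())
            pos = dict(zip(last["subject_id"], pct < 10.0))
            out = c.outcomes
            bw_pct = bw.percentile(
                out["birthweight_g"].to_numpy(),
                np.clip(out["ga_delivery_weeks"].to_numpy(), *bw.ga_domain),
                out["sex"].to_numpy(),
            )
            sga = bw_pct < 10.0
            flags = out["subject_id"].map(pos).fillna(False).to_numpy(bool)
            tp = int((flags & sga).sum())
            nd = int(sga.sum())
            s = summarize((tp, int(flags.sum()) - tp, nd - tp, int((~sga & ~flags).sum())))
            est.append(s.sensitivity[0])
            los.append(s.sensitivity[1])
            his.append(s.sensitivity[2])
        truth = float(np.mean(est))
        covered = np.mean([(lo <= truth <= hi) for lo, hi in zip(los, his)])
        assert covered >= 0.93
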