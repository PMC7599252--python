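import numpy as np
import pandas as pd
import pytest

import netbiomark as nb
from netbiomark.activity import PathwayActivityMatrix
from netbiomark.patients import PatientScoreTable


class TestKaplanMeier:
    def test_censoring_reduces_risk_set_only(self):
        km = nb.km_estimate([5, 10], [1, 0])
        assert km.survival_at(5) == pytest.approx(0.5)
        assert km.survival_at(10) == pytest.approx(0.5)

    def test_all_censored_survival_stays_one(self):
        km = nb.km_estimate([3, 6, 9], [0, 0, 0])
        assert np.allclose(km.survival, 1.0)

    def test_two_events_product_limit(self):
        km = nb.km_estimate([1, 2], [1, 1])
        assert km.survival_at(1) == pytest.approx(0.5)
        assert km.survival_at(2) == pytest.approx(0.0)

    def test_hand_product_limit_five_records(self):
        # times 1,2(censor),3,4,5 -> S: 4/5, 4/5, 4/5*2/3, *1/2, 0
        km = nb.km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 1, 1])
        assert km.survival_at(1) == pytest.approx(4 / 5, abs=1e-9)
        assert km.survival_at(2) == pytest.approx(4 / 5, abs=1e-9)
        assert km.survival_at(3) == pytest.approx(4 / 5 * 2 / 3, abs=1e-9)
        assert km.survival_at(4) == pytest.approx(4 / 5 * 2 / 3 * 1 / 2, abs=1e-9)
        assert km.survival_at(5) == pytest.approx(0.0, abs=1e-9)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            nb.km_estimate([], [])


class TestLogRank:
    def test_identical_groups_null(self):
        r = nb.logrank_test(([1, 2, 3], [1, 1, 0]), ([1, 2, 3], [1, 1, 0]))
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_hand_life_table(self):
        # A events at 1,2; B events at 3,4. Hand O-E table:
        # t=1: E_A=.5 V=.25 | t=2: E_A=1/3 V=2/9 | t=3,4: E_A=0 V=0
        # chi2 = (2 - 5/6)^2 / (0.25 + 2/9) = 2.88235294...
        r = nb.logrank_test(([1, 2], [1, 1]), ([3, 4], [1, 1]))
        assert r.statistic == pytest.approx(49 / 17, abs=1e-9)

    def test_doubling_sample_increases_power(self):
        a, b = ([1, 2], [1, 1]), ([3, 4], [1, 1])
        small = nb.logrank_test(a, b)
        big = nb.logrank_test(([1, 1, 2, 2], [1, 1, 1, 1]),
                              ([3, 3, 4, 4], [1, 1, 1, 1]))
        assert big.statistic > small.statistic and big.p < small.p

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(0)
        a = (rng.exponential(5, 20), rng.integers(0, 2, 20))
        b = (rng.exponential(9, 15), rng.integers(0, 2, 15))
        assert nb.logrank_test(a, b).statistic == \
            pytest.approx(nb.logrank_test(b, a).statistic, abs=1e-12)

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test as ll

        rng = np.random.default_rng(3)
        for _ in range(50):
            na, nb_ = rng.integers(4, 30, 2)
            ta, tb = rng.exponential(8, na), rng.exponential(4, nb_)
            ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb_)
            if ea.sum() + eb.sum() == 0:
                continue
            mine = nb.logrank_test((ta, ea), (tb, eb))
            ref = ll(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert mine.statistic == pytest.approx(ref.test_statistic, abs=1e-8)
            assert mine.p == pytest.approx(ref.p_value, abs=1e-10)

    def test_no_events_error(self):
        with pytest.raises(ValueError, match="no events"):
            nb.logrank_test(([1, 2], [0, 0]), ([3], [0]))

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            nb.logrank_test(([], []), ([1], [1]))


class TestIsogenicContrast:
    def contrast(self, sens, resi):
        vals = list(sens) + list(resi)
        cols = [f"c{i}" for i in range(len(vals))]
        act = PathwayActivityMatrix(
            pd.DataFrame([vals], index=["P"], columns=cols, dtype=float),
            value_scale="nes")
        labels = pd.Series(["sensitive"] * len(sens) + ["resistant"] * len(resi),
                           index=cols)
        return nb.isogenic_contrast(act, labels, "P")

    def test_identical_groups(self):
        t, p, _ = self.contrast([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_pooled_variance(self):
        t, p, direction = self.contrast([2, 3, 4], [0, 1, 2])
        assert t == pytest.approx(2.449489743, abs=1e-6)
        assert direction == "sensitive"

    def test_group_too_small_error(self):
        with pytest.raises(ValueError):
            self.contrast([1], [1, 2, 3])

    def test_planted_downshift_power(self):
        """Resistant lines down-shift the biomarker pathway's member
        genes by 2 sd; the pathway-level contrast detects it with the
        correct direction in nearly every seed."""
        from netbiomark.simulate import (PLANTED, make_isogenic_lines,
                                         make_network_and_pathways)

        base = dict(n_genes=150, n_pathways=8, pathway_size_range=(8, 15),
                    n_organoids=8, n_patients_treated=10,
                    n_patients_untreated=10)
        net, coll, _ = make_network_and_pathways(nb.ScenarioConfig(seed=0, **base))
        hits = 0
        for seed in range(60):
            iso = make_isogenic_lines(nb.ScenarioConfig(seed=seed, **base),
                                      net, coll)
            act = nb.ssgsea_scores(iso.expression, coll)
            _, p, direction = nb.isogenic_contrast(act, iso.labels, PLANTED)
            hits += (p < 0.01) and direction == "sensitive"
        assert hits >= 57  # >= 95%


class TestValidateBiomarker:
    def test_planted_scenario_pattern(self, scenario, scenario_activities,
                                      scenario_ranking):
        clin = scenario.patients.clinical
        scored = nb.score_patients(scenario_activities["patient"],
                                   scenario_ranking, n_top=1)
        treated_ids = clin.subset(True).patients
        untreated_ids = clin.subset(False).patients
        tr = nb.median_split(PatientScoreTable(
            scored.df.loc[treated_ids].copy(), 1))
        un = nb.median_split(PatientScoreTable(
            scored.df.loc[untreated_ids].copy(), 1))
        rep = nb.validate_biomarker(clin, tr, un)
        assert rep.treated.p < 0.05
        assert rep.untreated.p > 0.05
        assert rep.treated_counts[0] + rep.treated_counts[1] == len(treated_ids)
        for curve in rep.treated_curves.values():
            assert (np.diff(curve.survival) <= 1e-12).all()  # non-increasing

    def test_empty_class_error(self, scenario):
        clin = scenario.patients.clinical
        ids = clin.subset(True).patients[:4]
        df = pd.DataFrame({"score": [1.0, 2.0, 3.0, 4.0],
                           "cls": ["responder"] * 4}, index=ids)
        with pytest.raises(ValueError):
            nb.validate_biomarker(clin, PatientScoreTable(df, 1),
                                  PatientScoreTable(df, 1))


class TestLeaveOutRobustness:
    def build(self, n=12, n_pat=60, seed=0):
        """Small strong-signal fixture: one driver pathway, two noise."""
        rng = np.random.default_rng(seed)
        orgs = [f"org{i}" for i in range(n)]
        pats = [f"pt{i}" for i in range(n_pat)]
        u_org = rng.normal(size=n)
        act_org = PathwayActivityMatrix(pd.DataFrame(
            [u_org, rng.normal(size=n), rng.normal(size=n)],
            index=["driver", "n1", "n2"], columns=orgs), value_scale="zscore")
        y = nb.DoseResponseTable(pd.Series(np.exp(0.9 * u_org), index=orgs))
        u_pat = rng.normal(size=n_pat)
        act_pat = PathwayActivityMatrix(pd.DataFrame(
            [u_pat, rng.normal(size=n_pat), rng.normal(size=n_pat)],
            index=["driver", "n1", "n2"], columns=pats), value_scale="zscore")
        status = pd.Series(u_pat > 0.3, index=pats)  # mutants resist (high u)
        return act_org, y, act_pat, status

    def test_strong_signal_robust_to_leave_three_out(self):
        act_org, y, act_pat, status = self.build()
        frac = nb.leave_out_robustness(act_org, y, act_pat, status, k_max=3)
        assert set(frac) == {0, 1, 2, 3}
        assert frac[0] in (0.0, 1.0)
        assert frac[3] >= 0.7

    def test_subset_cap_error(self):
        act_org, y, act_pat, status = self.build()
        with pytest.raises(ValueError, match="cap"):
            nb.leave_out_robustness(act_org, y, act_pat, status,
                                    k_max=3, max_subsets=10)
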