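import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncpair import evaluate

from conftest import make_clinical, make_profile


def mw_auc(scores, status):
    """Pairwise-concordance AUC oracle (ties count 1/2)."""
    pos = scores[status]
    neg = scores[~status]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestTdRoc:
    def test_perfect_ranking_auc1(self):
        time = np.array([10.0, 20, 30, 400, 500, 600])
        event = np.ones(6, dtype=int)
        profile = make_profile([6, 5, 4, 1, 2, 3])
        roc = evaluate.td_roc(profile, make_clinical(time, event), horizon=100.0)
        assert roc.auc == pytest.approx(1.0)

    def test_null_auc_half(self, rng):
        n = 2000
        time = rng.exponential(100, size=n)
        profile = make_profile(rng.normal(size=n))
        roc = evaluate.td_roc(profile, make_clinical(time, np.ones(n)),
                              horizon=float(np.median(time)))
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_six_sample_mw_equality(self):
        scores = np.array([3.0, 1.0, 2.0, 5.0, 4.0, 0.0])
        time = np.array([50.0, 60, 200, 30, 300, 400])
        event = np.ones(6, dtype=int)
        roc = evaluate.td_roc(make_profile(scores), make_clinical(time, event), 100.0)
        assert roc.auc == pytest.approx(mw_auc(scores, time <= 100.0), abs=1e-12)

    def test_uncensored_equals_binary_roc_random(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 30))
            time = rng.integers(1, 12, size=n).astype(float)
            scores = np.round(rng.normal(size=n), 1)
            status = time <= 6.0
            if status.all() or not status.any():
                continue
            roc = evaluate.td_roc(
                make_profile(scores), make_clinical(time, np.ones(n)), 6.0
            )
            assert roc.auc == pytest.approx(mw_auc(scores, status), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        n = 80
        time = rng.exponential(50, size=n)
        event = rng.integers(0, 2, size=n)
        if event.sum() == 0:
            event[0] = 1
        scores = rng.normal(size=n)
        clin = make_clinical(time, event)
        a = evaluate.td_roc(make_profile(scores), clin, 40.0).auc
        b = evaluate.td_roc(make_profile(np.exp(scores)), clin, 40.0).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_roc_invariants(self, rng):
        n = 60
        time = rng.exponential(50, size=n)
        event = rng.integers(0, 2, size=n)
        event[:5] = 1
        roc = evaluate.td_roc(make_profile(rng.normal(size=n)),
                              make_clinical(time, event), float(np.median(time)))
        assert (np.diff(roc.tpr) >= -1e-12).all()
        assert (np.diff(roc.fpr) >= -1e-12).all()
        assert roc.tpr[0] == roc.fpr[0] == 0.0
        assert roc.tpr[-1] == pytest.approx(1.0)
        assert roc.fpr[-1] == pytest.approx(1.0)
        assert 0.0 <= roc.auc <= 1.0

    def test_no_cases_errors(self):
        profile = make_profile([1.0, 2.0])
        with pytest.raises(ValueError, match="cases"):
            evaluate.td_roc(profile, make_clinical([100.0, 200.0], [1, 1]), 50.0)


class TestOptimalCutoff:
    def test_perfect_separation(self):
        time = np.array([10.0, 20, 300, 400])
        profile = make_profile([5.0, 4.0, 1.0, 0.0])
        roc = evaluate.td_roc(profile, make_clinical(time, np.ones(4)), 100.0)
        cut = evaluate.optimal_cutoff(roc)
        assert cut.criterion == pytest.approx(1.0)
        assert 1.0 <= cut.cutoff <= 5.0

    def test_matches_bruteforce_grid(self, rng):
        n = 8
        scores = rng.normal(size=n)
        time = rng.integers(1, 10, size=n).astype(float)
        roc = evaluate.td_roc(make_profile(scores), make_clinical(time, np.ones(n)),
                              float(np.median(time)))
        cut = evaluate.optimal_cutoff(roc)
        j = roc.tpr - roc.fpr
        finite = np.isfinite(roc.thresholds)
        assert cut.criterion == pytest.approx(j[finite].max(), abs=1e-12)

    def test_null_tiebreak_largest_threshold(self):
        # two samples per score level, one case one control each: tpr == fpr
        scores = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        time = np.array([10.0, 500, 10, 500, 10, 500])
        roc = evaluate.td_roc(make_profile(scores), make_clinical(time, np.ones(6)),
                              100.0)
        cut = evaluate.optimal_cutoff(roc)
        assert cut.criterion == pytest.approx(0.0)
        assert cut.cutoff == 3.0

    def test_identical_scores_error(self):
        time = np.array([10.0, 500.0, 20.0, 600.0])
        roc = evaluate.td_roc(make_profile(np.ones(4)), make_clinical(time, np.ones(4)),
                              100.0)
        with pytest.raises(ValueError, match="identical"):
            evaluate.optimal_cutoff(roc)


class TestAssignGroups:
    def test_boundary_contract(self):
        profile = make_profile([1.0, 1.0 + 1e-9, 0.5])
        grouped = evaluate.assign_groups(profile, 1.0)
        assert grouped.group.tolist() == ["low", "high", "low"]

    def test_partition(self, rng):
        profile = make_profile(rng.normal(size=50))
        grouped = evaluate.assign_groups(profile, 0.0)
        assert grouped.group.isin(["high", "low"]).all()
        assert len(grouped.group) == 50


class TestKmLogrank:
    def _grouped(self, scores, cutoff=0.0):
        return evaluate.assign_groups(make_profile(scores), cutoff)

    def test_identical_groups_null(self):
        time = np.tile([10.0, 20, 30, 40], 2)
        event = np.tile([1, 0, 1, 1], 2)
        profile = self._grouped(np.r_[np.ones(4), -np.ones(4)])
        comp = evaluate.km_logrank(profile, make_clinical(time, event))
        assert comp.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert comp.p == pytest.approx(1.0)

    def test_textbook_oracle(self, rng):
        def oracle(t1, e1, t2, e2):
            times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
            O1 = E1 = V = 0.0
            for t in times:
                n1 = (t1 >= t).sum()
                n2 = (t2 >= t).sum()
                n = n1 + n2
                d1 = ((t1 == t) & (e1 == 1)).sum()
                d = d1 + ((t2 == t) & (e2 == 1)).sum()
                O1 += d1
                E1 += d * n1 / n
                if n > 1:
                    V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
            return (O1 - E1) ** 2 / V

        for _ in range(20):
            n1, n2 = rng.integers(4, 10, size=2)
            t1 = rng.integers(1, 15, size=n1).astype(float)
            t2 = rng.integers(1, 15, size=n2).astype(float)
            e1 = rng.integers(0, 2, size=n1)
            e2 = rng.integers(0, 2, size=n2)
            if e1.sum() + e2.sum() == 0:
                continue
            profile = self._grouped(np.r_[np.ones(n1), -np.ones(n2)])
            comp = evaluate.km_logrank(
                profile, make_clinical(np.r_[t1, t2], np.r_[e1, e2])
            )
            assert comp.logrank_stat == pytest.approx(oracle(t1, e1, t2, e2), abs=1e-8)

    def test_km_no_censoring_is_empirical_survival(self, rng):
        n = 20
        time = rng.integers(1, 30, size=n).astype(float)
        profile = self._grouped(np.ones(n), cutoff=0.0)
        profile.group.iloc[:] = "high"
        lowish = evaluate.assign_groups(make_profile(np.r_[np.ones(n), -1.0]), 0.0)
        comp = evaluate.km_logrank(
            lowish, make_clinical(np.r_[time, 5.0], np.ones(n + 1))
        )
        curve = comp.km_curves["high"]
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx((time > t).mean(), abs=1e-12)
        assert curve["survival"].iloc[0] == 1.0
        assert (np.diff(curve["survival"]) <= 1e-12).all()


class TestIndependence:
    def _cohort(self, rng, n=400):
        rs = rng.normal(size=n)
        time = rng.exponential(1.0 / (0.01 * np.exp(rs)))
        clin = make_clinical(
            time,
            np.ones(n),
            age=rng.integers(40, 85, size=n),
            gender=rng.choice(["male", "female"], size=n),
            stage=rng.choice(["I", "II", "III", "IV"], size=n),
        )
        return make_profile(rs), clin

    def test_rs_significant_noise_not(self, rng):
        profile, clin = self._cohort(rng)
        uni, multi = evaluate.independence_analysis(profile, clin)
        assert uni.loc["risk_score", "p"] < 1e-6
        assert multi.loc["risk_score", "p"] < 1e-6
        assert uni.loc["gender", "p"] > 0.001

    def test_k1_uni_equals_multi(self, rng):
        n = 200
        rs = rng.normal(size=n)
        time = rng.exponential(1.0 / (0.01 * np.exp(rs)))
        clin = make_clinical(time, np.ones(n))
        uni, multi = evaluate.independence_analysis(make_profile(rs), clin)
        assert uni.loc["risk_score", "coef"] == pytest.approx(
            multi.loc["risk_score", "coef"], rel=1e-9
        )

    def test_duplicate_covariate_warns(self, rng):
        profile, clin = self._cohort(rng, n=150)
        clin.data["age2"] = clin.data["age"]
        with pytest.warns(UserWarning, match="collinear"):
            evaluate.independence_analysis(profile, clin)

    def test_encoding_unknown_codes_nan(self):
        clin = make_clinical(
            [10.0, 20.0], [1, 0],
            T=["T2", "Tx"], N=["N0", "Nx"], M=["M1", "Mx"], stage=["II", "IV"],
        )
        enc = evaluate.encode_clinical(clin)
        assert enc["T"].tolist()[0] == 2 and np.isnan(enc["T"].iloc[1])
        assert enc["N"].tolist()[0] == 0 and np.isnan(enc["N"].iloc[1])
        assert enc["M"].tolist()[0] == 1 and np.isnan(enc["M"].iloc[1])
        assert enc["stage"].tolist() == [2, 4]


class TestCompareAuc:
    def test_rs_dominates_random(self, rng):
        n = 600
        rs = rng.normal(size=n)
        time = rng.exponential(1.0 / (0.005 * np.exp(1.5 * rs)))
        clin = make_clinical(time, np.ones(n), age=rng.integers(40, 85, size=n))
        table = evaluate.compare_auc(make_profile(rs), clin,
                                     horizon=float(np.median(time)))
        assert table.loc["risk_score", "auc"] > table.loc["age", "auc"]

    def test_constant_covariate_skipped(self, rng):
        n = 50
        time = rng.exponential(100, size=n)
        clin = make_clinical(time, np.ones(n), grade=["high"] * n)
        with pytest.warns(UserWarning, match="grade"):
            table = evaluate.compare_auc(make_profile(rng.normal(size=n)), clin,
                                         horizon=float(np.median(time)))
        assert "grade" not in table.index

    def test_monotone_covariate_invariance(self, rng):
        n = 100
        time = rng.exponential(100, size=n)
        age = rng.integers(40, 85, size=n).astype(float)
        clin1 = make_clinical(time, np.ones(n), age=age)
        clin2 = make_clinical(time, np.ones(n), age=np.exp(age / 20.0))
        h = float(np.median(time))
        profile = make_profile(rng.normal(size=n))
        a1 = evaluate.compare_auc(profile, clin1, h).loc["age", "auc"]
        a2 = evaluate.compare_auc(profile, clin2, h).loc["age", "auc"]
        assert a1 == pytest.approx(a2, abs=1e-12)
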