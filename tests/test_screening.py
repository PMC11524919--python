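"""Linear-SVM fitting, LOOCV, Platt scaling and model search."""
import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from olst import _svm, screening as scr
from olst.errors import ConfigError, InsufficientDataError, OlstError

from conftest import svm_primal_objective

TIGHT = dict(tol=1e-10, max_epochs=200000)


def _toy_table(n_high=8, n_low=24, gap=4.0, seed=0, p_noise=2):
    """Feature table where column 'sig' separates the groups by `gap`."""
    rng = np.random.default_rng(seed)
    n = n_high + n_low
    groups = ["High"] * n_high + ["Low"] * n_low
    sig = np.r_[rng.normal(gap, 1.0, n_high), rng.normal(0.0, 1.0, n_low)]
    data = {"participant_id": [f"p{i}" for i in range(n)],
            "sex": ["male"] * n, "srs_total": np.where(
                np.array(groups) == "High", 80.0, 20.0),
            "group": groups, "sig": sig}
    for j in range(p_noise):
        data[f"noise{j}"] = rng.normal(size=n)
    return pd.DataFrame(data)


class TestFitLinearSVM:
    def test_separable_direction(self):
        X = np.array([[-1.0], [-0.8], [1.0], [0.9]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        m = scr.fit_linear_svm(X, y, C=100.0)
        assert m.weights[0] > 0
        assert np.all(np.sign(m.decision(X)) == y)

    def test_single_class_rejected(self):
        with pytest.raises(OlstError, match="one class"):
            scr.fit_linear_svm(np.ones((4, 1)), np.ones(4), C=1.0)

    def test_duplication_keeps_separable_boundary(self):
        # with separable data at large C the hard-margin boundary is
        # unaffected by duplicating every sample
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        m1 = scr.fit_linear_svm(X, y, C=1e4, standardize=False)
        m2 = scr.fit_linear_svm(np.vstack([X, X]), np.r_[y, y], C=1e4,
                                standardize=False)
        b1 = -m1.intercept / m1.weights[0]
        b2 = -m2.intercept / m2.weights[0]
        assert b1 == pytest.approx(b2, abs=1e-3)

    def test_objective_matches_bruteforce_oracle(self):
        """4-point 1-D problem: primal objective at the solver's optimum
        matches direct numerical minimization of the same objective."""
        X = np.array([[-1.5], [-0.5], [0.3], [1.2]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        C = 1.0
        Xa = np.hstack([X, np.ones((4, 1))])
        w = _svm.dual_cd(Xa, y, C, TIGHT["tol"], TIGHT["max_epochs"], 5)
        mine = svm_primal_objective(X, y, C, w[:1], w[1])

        def obj(wb):
            return svm_primal_objective(X, y, C, wb[:1], wb[1])

        best = np.inf
        for w0 in np.linspace(-3, 3, 31):
            for b0 in np.linspace(-3, 3, 31):
                r = optimize.minimize(obj, [w0, b0], method="Nelder-Mead",
                                      options=dict(xatol=1e-12, fatol=1e-14))
                best = min(best, r.fun)
        assert mine == pytest.approx(best, abs=1e-6)

    def test_matches_reference_implementation(self):
        """Same objective as LinearSVC(loss='hinge'): objectives agree on
        random problems across the cost grid."""
        from sklearn.svm import LinearSVC
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 4))
        y = np.where(rng.random(60) < 0.3, 1.0, -1.0)
        Xs = (X - X.mean(0)) / X.std(0)
        Xa = np.hstack([Xs, np.ones((60, 1))])
        for C in (0.001, 0.01, 0.1, 1.0):
            w = _svm.dual_cd(Xa, y, C, TIGHT["tol"], TIGHT["max_epochs"], 1)
            ref = LinearSVC(loss="hinge", C=C, tol=1e-12,
                            max_iter=500000).fit(Xs, y)
            o_mine = svm_primal_objective(Xs, y, C, w[:4], w[4])
            o_ref = svm_primal_objective(Xs, y, C, ref.coef_[0],
                                         ref.intercept_[0])
            assert o_mine <= o_ref + 1e-5 * max(1.0, abs(o_ref))


class TestLoocv:
    def test_fold_count(self):
        t = _toy_table()
        dec, labels = scr.loocv_predict(t[["sig"]].to_numpy(), t["group"], 1.0)
        assert len(dec) == len(labels) == len(t)

    def test_wide_gap_all_correct(self):
        t = _toy_table(gap=8.0)
        _, labels = scr.loocv_predict(t[["sig"]].to_numpy(), t["group"], 1.0)
        assert labels == list(t["group"])

    def test_row_permutation_invariance(self):
        t = _toy_table(gap=3.0, seed=4)
        perm = np.random.default_rng(0).permutation(len(t))
        tp = t.iloc[perm].reset_index(drop=True)
        _, l1 = scr.loocv_predict(t[["sig", "noise0"]].to_numpy(),
                                  t["group"], 0.1)
        _, l2 = scr.loocv_predict(tp[["sig", "noise0"]].to_numpy(),
                                  tp["group"], 0.1)
        pairs1 = sorted(zip(t["participant_id"], l1))
        pairs2 = sorted(zip(tp["participant_id"], l2))
        assert pairs1 == pairs2

    def test_degenerate_class_counts_rejected(self):
        t = _toy_table(n_high=1, n_low=10)
        with pytest.raises(InsufficientDataError):
            scr.loocv_predict(t[["sig"]].to_numpy(), t["group"], 1.0)


class TestConfusionMetrics:
    def test_imbalanced_worked_example(self):
        """16 of 19 High and 107 of 107 Low correct: accuracy 0.976,
        sensitivity 0.842, specificity 1.000 at 3-decimal rounding."""
        true = ["High"] * 19 + ["Low"] * 107
        pred = ["High"] * 16 + ["Low"] * 3 + ["Low"] * 107
        conf, m = scr.confusion_metrics(pred, true)
        assert conf == {"TP": 16, "FN": 3, "TN": 107, "FP": 0}
        assert round(m["accuracy"], 3) == 0.976
        assert round(m["sensitivity"], 3) == 0.842
        assert round(m["specificity"], 3) == 1.000

    def test_all_correct_and_all_flipped(self):
        true = ["High", "Low", "High", "Low"]
        _, perfect = scr.confusion_metrics(true, true)
        assert (perfect["accuracy"], perfect["sensitivity"],
                perfect["specificity"]) == (1.0, 1.0, 1.0)
        flipped = ["Low", "High", "Low", "High"]
        _, worst = scr.confusion_metrics(flipped, true)
        assert (worst["accuracy"], worst["sensitivity"],
                worst["specificity"]) == (0.0, 0.0, 0.0)

    def test_identities_hold(self):
        rng = np.random.default_rng(0)
        true = list(rng.choice(["High", "Low"], 50))
        pred = list(rng.choice(["High", "Low"], 50))
        conf, m = scr.confusion_metrics(pred, true)
        assert conf["TP"] + conf["FN"] == true.count("High")
        assert conf["TN"] + conf["FP"] == true.count("Low")
        assert m["accuracy"] == (conf["TP"] + conf["TN"]) / 50

    def test_missing_metric_for_absent_class(self):
        _, m = scr.confusion_metrics(["Low", "Low"], ["Low", "Low"])
        assert np.isnan(m["sensitivity"])
        assert m["specificity"] == 1.0


class TestPlatt:
    def test_monotone_in_decision_value(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=30)
        labels = np.where(d + rng.normal(0, 0.5, 30) > 0, "High", "Low")
        probs, (A, B) = scr.platt_probabilities(d, labels)
        order = np.argsort(d)
        assert np.all(np.diff(probs[order]) >= 0) or \
            np.all(np.diff(probs[order]) <= 0)
        assert A < 0      # larger decision -> higher P(High)

    def test_symmetric_case_centered(self):
        d = np.array([-1.0, 1.0] * 10)
        labels = ["Low", "High"] * 10
        _, (A, B) = scr.platt_probabilities(d, labels)
        p0 = 1.0 / (1.0 + np.exp(B))
        assert p0 == pytest.approx(0.5, abs=0.05)

    def test_matches_independent_optimizer(self):
        rng = np.random.default_rng(8)
        d = rng.normal(size=10)
        labels = np.where(rng.random(10) < 0.5, "High", "Low")
        if len(set(labels)) == 1:
            labels[0] = "High" if labels[0] == "Low" else "Low"
        probs, (A, B) = scr.platt_probabilities(d, labels)
        y = np.where(np.array(labels) == "High", 1.0, -1.0)
        n1, n0 = (y > 0).sum(), (y < 0).sum()
        t = np.where(y > 0, (n1 + 1) / (n1 + 2), 1.0 / (n0 + 2))

        def nll(ab):
            f = ab[0] * d + ab[1]
            return np.sum(t * f + np.logaddexp(0.0, -f))

        res = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options=dict(xatol=1e-10, fatol=1e-12))
        assert A == pytest.approx(res.x[0], abs=1e-4)
        assert B == pytest.approx(res.x[1], abs=1e-4)

    def test_nonfinite_rejected(self):
        with pytest.raises(OlstError):
            scr.platt_probabilities(np.array([np.nan, 1.0]), ["High", "Low"])


class TestSearch:
    def test_informative_column_found(self):
        t = _toy_table(gap=8.0, p_noise=3)
        t = t.rename(columns={"sig": "len_total_path",
                              "noise0": "m_cop_speed",
                              "noise1": "cop_entropy",
                              "noise2": "cop_convex_hull"})
        t["len_max_trial"] = np.random.default_rng(1).normal(size=len(t))
        t["com_cop_dist"] = np.random.default_rng(2).normal(size=len(t))
        res = scr.search_best_model(t, "conventional", strategy="exhaustive")
        assert "len_total_path" in res.spec.subset
        assert res.metrics["accuracy"] == 1.0

    def test_tiebreak_prefers_smaller_subset(self):
        # duplicate the separating column: (sig,) and (sig, dup) tie on
        # accuracy and sensitivity; the singleton must win
        t = _toy_table(gap=8.0, p_noise=0)
        t["len_total_path"] = t["sig"]
        t["m_cop_speed"] = t["sig"]
        for c in ("cop_entropy", "cop_convex_hull", "len_max_trial",
                  "com_cop_dist"):
            t[c] = t["sig"]
        res = scr.search_best_model(t, "conventional", strategy="exhaustive")
        assert len(res.spec.subset) == 1

    def test_default_grid_contains_study_costs(self):
        assert 0.001 in scr.DEFAULT_COST_GRID
        assert 0.01 in scr.DEFAULT_COST_GRID

    def test_empty_grid_rejected(self, small_table):
        with pytest.raises(ConfigError):
            scr.search_best_model(small_table, "conventional", cost_grid=())

    def test_nested_mode_runs_and_reports_outer_metrics(self):
        t = _toy_table(n_high=6, n_low=18, gap=6.0, p_noise=1)
        t = t.rename(columns={"sig": "corr_shoulder"})
        for c in scr.category_columns("proposed"):
            if c not in t:
                t[c] = np.random.default_rng(hash(c) % 2 ** 31).normal(
                    size=len(t))
        res = scr.search_best_model(t, "proposed", mode="nested",
                                    strategy="forward_floating", seed=0)
        assert res.spec.selection_mode == "nested"
        assert len(res.decisions) == len(t)
        assert res.metrics["accuracy"] > 0.8

    def test_report_round_trip(self, tmp_path):
        from olst import io as oio
        t = _toy_table(gap=6.0)
        t = t.rename(columns={"sig": "corr_neck", "noise0": "corr_shoulder",
                              "noise1": "corr_right_elbow"})
        for c in scr.category_columns("proposed"):
            if c not in t:
                t[c] = np.random.default_rng(abs(hash(c)) % 2 ** 31).normal(
                    size=len(t))
        res = scr.search_best_model(t, "proposed",
                                    strategy="forward_floating")
        path = tmp_path / "report.json"
        oio.write_model_report(res.to_report(), path)
        back = oio.load_model_report(path)
        assert back["selected_variables"] == list(res.spec.subset)
        assert back["confusion"] == res.confusion
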