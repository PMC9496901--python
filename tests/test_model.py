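"""Outcome model: comparisons, screen, selection, LOO evaluation, F1."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prostamics.model import (
    build_comparisons,
    confusion_and_f1,
    fit_and_evaluate_loo,
    run_outcome_model,
    select_features,
    univariate_screen,
    welch_pvalues,
)


def _table(per_scan: dict[str, pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for sp, df in per_scan.items():
        d = df.copy()
        d["scan_point"] = sp
        d["patient_id"] = df.index
        frames.append(d.set_index(["patient_id", "scan_point"]))
    return pd.concat(frames).sort_index()


class TestBuildComparisons:
    def _toy(self):
        ids = [f"P{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        per_scan = {
            sp: pd.DataFrame({"A": rng.normal(size=6), "B": rng.normal(size=6)}, index=ids)
            for sp in ("S1", "S2", "S3", "S4")
        }
        labels = pd.Series([0, 1, 0, 1, 0, 1], index=ids)
        return per_scan, labels

    def test_full_cohort_has_ten_comparisons(self):
        per_scan, labels = self._toy()
        cs = build_comparisons(_table(per_scan), labels)
        assert len(cs.names()) == 10
        assert sum("-" in n for n in cs.names()) == 6  # C(4,2) deltas

    def test_missing_scan_presence_rule(self):
        per_scan, labels = self._toy()
        per_scan["S4"] = per_scan["S4"].drop(index="P0")
        cs = build_comparisons(_table(per_scan), labels)
        X4, _ = cs["S4"]
        assert "P0" not in X4.index
        X41, _ = cs["S4-S1"]
        assert "P0" not in X41.index
        X21, _ = cs["S2-S1"]
        assert "P0" in X21.index

    def test_delta_values_and_suffix(self):
        per_scan, labels = self._toy()
        cs = build_comparisons(_table(per_scan), labels)
        X, _ = cs["S2-S1"]
        assert "A_dS2S1" in X.columns
        expected = per_scan["S2"]["A"] - per_scan["S1"]["A"]
        assert np.allclose(X["A_dS2S1"], expected.loc[X.index])

    def test_nonbinary_labels_rejected(self):
        per_scan, labels = self._toy()
        with pytest.raises(ValueError, match="binary"):
            build_comparisons(_table(per_scan), labels.replace(1, 2))


class TestUnivariateScreen:
    def test_null_feature_fails_perfect_feature_passes(self, rng):
        n = 40
        y = pd.Series(np.repeat([0, 1], n // 2))
        X = pd.DataFrame(
            {
                "null": np.ones(n),
                "perfect": y + rng.normal(0, 1e-3, n),
                "noise": rng.normal(size=n),
            }
        )
        scr = univariate_screen(X, y)
        assert scr.loc["null", "p"] > 0.9
        assert scr.loc["perfect", "p"] < 1e-6
        assert scr.loc["perfect", "flagged"]  # complete separation is flagged

    def test_lrt_matches_closed_form_deviance_for_binary_feature(self):
        # grouped binary data: x=0 -> 2/10 positive, x=1 -> 8/10 positive
        x = np.repeat([0, 1], 10)
        y = np.concatenate([np.repeat([0, 1], [8, 2]), np.repeat([0, 1], [2, 8])])
        X = pd.DataFrame({"x": x.astype(float)})
        scr = univariate_screen(X, pd.Series(y))

        def ll(k, n):
            p = k / n
            return k * np.log(p) + (n - k) * np.log(1 - p) if 0 < p < 1 else 0.0

        lrt = 2 * (ll(2, 10) + ll(8, 10) - ll(10, 20))
        expected_p = sps.chi2.sf(lrt, 1)
        assert scr.loc["x", "p"] == pytest.approx(expected_p, rel=1e-4)


class TestSelectFeatures:
    def test_correlated_copies_yield_one_selection(self, rng):
        n = 60
        y = pd.Series(np.repeat([0, 1], n // 2))
        a = y * 2 + rng.normal(0, 0.5, n)
        X = pd.DataFrame({"A": a, "A2": a.copy()})
        assert len(select_features(X, y, max_k=0)) == 1

    def test_hand_traced_greedy_rule(self):
        from prostamics.evaluation import selection_trace

        trace = selection_trace()
        assert trace["selected"] == ["A", "C"]

    def test_selected_features_pairwise_decorrelated(self, rng):
        n = 80
        y = pd.Series(np.repeat([0, 1], n // 2))
        X = pd.DataFrame(
            {f"f{i}": y * rng.uniform(0.5, 2) + rng.normal(0, 1, n) for i in range(12)}
        )
        selected = select_features(X, y, max_k=0)
        for i, a in enumerate(selected):
            for b in selected[i + 1 :]:
                assert abs(X[a].corr(X[b])) <= 0.85

    def test_max_k_caps_selection(self, rng):
        n = 80
        y = pd.Series(np.repeat([0, 1], n // 2))
        X = pd.DataFrame(
            {f"f{i}": y * 2 + rng.normal(0, 0.7, n) * (i + 1) for i in range(10)}
        )
        assert len(select_features(X, y, max_k=4)) <= 4

    def test_nothing_passes_gives_empty_list(self, rng):
        y = pd.Series(np.repeat([0, 1], 10))
        X = pd.DataFrame({"noise": np.ones(20)})
        assert select_features(X, y) == []


class TestLooEvaluation:
    def test_separable_feature_gives_perfect_scores(self):
        n = 30
        y = pd.Series(np.repeat([0, 1], n // 2))
        X = pd.DataFrame({"f": np.repeat([-3.0, 3.0], n // 2)})
        res = fit_and_evaluate_loo(X, y)
        assert res.auc == 1.0
        assert res.f1 == 1.0

    def test_independent_features_give_chance_auc_at_large_n(self, rng):
        n = 200
        y = pd.Series(rng.integers(0, 2, n))
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        res = fit_and_evaluate_loo(X, y)
        assert abs(res.auc - 0.5) < 0.1

    def test_label_permutation_destroys_informative_auc(self, rng):
        n = 200
        y = pd.Series(np.repeat([0, 1], n // 2))
        X = pd.DataFrame({"f": y * 2 + rng.normal(0, 0.5, n)})
        informative = fit_and_evaluate_loo(X, y).auc
        y_perm = pd.Series(rng.permutation(y.to_numpy()))
        permuted = fit_and_evaluate_loo(X, y_perm).auc
        assert informative > 0.95
        assert abs(permuted - 0.5) < 0.1

    def test_auc_invariant_under_monotone_probability_transform(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, 50)
        p = rng.uniform(size=50)
        assert roc_auc_score(y, p) == roc_auc_score(y, p**3)

    def test_single_class_labels_rejected(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        with pytest.raises(ValueError, match="both classes"):
            fit_and_evaluate_loo(X, pd.Series(np.zeros(10, dtype=int)))


class TestConfusionAndF1:
    def test_perfect_probabilities(self):
        y = np.array([0, 1, 0, 1])
        mat, f1 = confusion_and_f1(y.astype(float), y)
        assert f1 == 1.0
        assert mat.sum() == 4

    def test_four_tp_two_fp_gives_point_eight(self):
        y = np.array([1] * 4 + [0] * 20)
        probs = np.array([0.9] * 4 + [0.9] * 2 + [0.1] * 18)
        mat, f1 = confusion_and_f1(probs, y, 0.5)
        assert mat[1, 1] == 4 and mat[0, 1] == 2 and mat[1, 0] == 0
        assert f1 == pytest.approx(0.80)

    def test_four_tp_three_fp_gives_0727(self):
        y = np.array([1] * 4 + [0] * 20)
        probs = np.array([0.9] * 4 + [0.9] * 3 + [0.1] * 17)
        _, f1 = confusion_and_f1(probs, y, 0.5)
        assert f1 == pytest.approx(8 / 11, abs=1e-9)
        assert round(f1, 3) == 0.727

    def test_no_positives_f1_undefined(self):
        _, f1 = confusion_and_f1(np.array([0.1, 0.2]), np.array([0, 0]))
        assert np.isnan(f1)

    def test_out_of_range_probs_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_f1(np.array([1.2]), np.array([1]))


class TestRunOutcomeModel:
    def test_nested_mode_runs_and_flags(self, rng):
        n = 40
        y = pd.Series(np.repeat([0, 1], n // 2))
        X = pd.DataFrame(
            {"sig": y * 3 + rng.normal(0, 0.5, n), "noise": rng.normal(size=n)}
        )
        flat = run_outcome_model(X, y, nested=False)
        nested = run_outcome_model(X, y, nested=True)
        assert flat.auc > 0.9 and nested.auc > 0.9
        assert "nested LOO" in nested.flags

    def test_returns_none_when_screen_empty(self, rng):
        y = pd.Series(np.repeat([0, 1], 10))
        X = pd.DataFrame({"flat": np.ones(20)})
        assert run_outcome_model(X, y) is None
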