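import json

import numpy as np
import pandas as pd
import pytest

from maldipanel.classify import (
    MarkerPanel,
    combine_logistic,
    confusion_at_cutoff,
    delong_variance,
    loocv_roc,
    loocv_scores,
    repeatability_report,
    roc_summary,
    select_panel,
    subgroup_score_analysis,
    train_svm,
)
from maldipanel.stats import group_summaries, wilcoxon_feature
from maldipanel.synthetic import GeneratorConfig, generate_amplitude_matrix

from conftest import make_matrix


def brute_force_confusion(scores, labels, cutoff):
    tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s > cutoff)
    fn = sum(1 for s, y in zip(scores, labels) if y == 1 and s <= cutoff)
    tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s <= cutoff)
    fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s > cutoff)
    return tp, fn, tn, fp


class TestConfusion:
    def test_study_counts_give_86_sensitivity_76_specificity(self):
        """21 positives (17 cases + 4 case-pool replicates) of which 18 score
        above the cutoff; 25 negatives of which 19 score below."""
        scores = np.array([0.5] * 18 + [-0.5] * 3 + [-0.5] * 19 + [0.5] * 6)
        labels = np.array([1] * 21 + [0] * 25)
        sens, spec, counts = confusion_at_cutoff(scores, labels, cutoff=-0.05)
        assert sens == 86.0
        assert spec == 76.0
        assert counts == {"tp": 18, "fn": 3, "tn": 19, "fp": 6}

    def test_degenerate_all_positive(self):
        sens, spec, _ = confusion_at_cutoff([1.0, 1.0], [1, 0], cutoff=-0.05)
        assert sens == 100.0 and spec == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_counting(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 40)
        labels = rng.integers(0, 2, 40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        cutoff = float(rng.normal())
        sens, spec, counts = confusion_at_cutoff(scores, labels, cutoff)
        tp, fn, tn, fp = brute_force_confusion(scores, labels, cutoff)
        assert (counts["tp"], counts["fn"], counts["tn"], counts["fp"]) == (tp, fn, tn, fp)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            confusion_at_cutoff([1.0], [1], -0.05)


class TestRepeatability:
    def test_two_of_eleven_misclassified_controls_is_18_percent(self):
        scores = pd.DataFrame(
            {
                "control-pool": [-0.5] * 9 + [0.2, 0.3],
                "case-pool": [0.4] * 11,
            }
        )
        rep = repeatability_report(scores, case_pools=["case-pool"], cutoff=-0.05)
        assert rep["false_positive_rate"] == 18.0
        assert rep["false_negative_rate"] == 0.0
        assert rep["n_control_replicates"] == 11

    def test_single_time_point_warns(self):
        scores = pd.DataFrame({"control-pool": [0.1], "case-pool": [0.2]})
        with pytest.warns(UserWarning, match="single time point"):
            repeatability_report(scores, case_pools=["case-pool"])


class TestDeLong:
    @pytest.mark.parametrize("seed", range(4))
    def test_auc_equals_rank_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 60)
        labels = (rng.random(60) < 0.5).astype(int)
        labels[:2] = [0, 1]
        auc, var = delong_variance(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        brute = np.mean([(p > neg).mean() + 0.5 * (p == neg).mean() for p in pos])
        assert auc == pytest.approx(brute, abs=1e-12)
        assert var >= 0

    def test_ci_contains_point_auc_and_shrinks_with_n(self):
        rng = np.random.default_rng(5)

        def width(n):
            scores = np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
            labels = np.array([1] * n + [0] * n)
            s = roc_summary(scores, labels)
            assert s.ci_low <= s.auc <= s.ci_high
            return s.ci_high - s.ci_low

        assert width(400) < width(40)

    def test_informative_scores_reject_randomness(self):
        scores = np.concatenate([np.linspace(1, 2, 30), np.linspace(-2, -1, 30)])
        labels = np.array([1] * 30 + [0] * 30)
        s = roc_summary(scores, labels)
        assert s.auc == 1.0
        assert s.p_vs_random < 1e-6

    def test_constant_scores_give_auc_half(self):
        s = roc_summary(np.zeros(20), np.array([1] * 10 + [0] * 10))
        assert s.auc == 0.5


def _informative_dataset(seed=0, n=20, n_feat=4, shift=2.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (2 * n, n_feat))
    X[:n] += shift
    # positive amplitude scale, as projected values are
    values = pd.DataFrame(np.exp(X) * 1e-4, index=[f"s{i}" for i in range(2 * n)],
                          columns=[f"f{j}" for j in range(n_feat)])
    groups = pd.Series(["AKI"] * n + ["non-AKI"] * n, index=values.index)
    return values, groups


class TestSvmTraining:
    def test_separable_training_data_classified_perfectly(self):
        values, groups = _informative_dataset(shift=4.0)
        panel = MarkerPanel(list(values.columns))
        clf = train_svm(values, groups, panel)
        acc = (clf.predict(values) == (groups == "AKI").astype(int).to_numpy()).mean()
        assert acc == 1.0

    def test_label_swap_flips_decision_scores(self):
        values, groups = _informative_dataset()
        panel = MarkerPanel(list(values.columns))
        clf = train_svm(values, groups, panel)
        swapped = groups.map({"AKI": "non-AKI", "non-AKI": "AKI"})
        clf2 = train_svm(values, swapped, panel)
        # antisymmetric up to the SMO solver's convergence tolerance
        np.testing.assert_allclose(
            clf.decision_scores(values), -clf2.decision_scores(values), atol=5e-3
        )

    def test_missing_panel_feature_rejected(self):
        values, groups = _informative_dataset()
        with pytest.raises(ValueError, match="absent"):
            train_svm(values, groups, MarkerPanel(["nope"]))

    def test_model_serialization_round_trips_key_fields(self):
        values, groups = _informative_dataset()
        panel = MarkerPanel(list(values.columns))
        clf = train_svm(values, groups, panel)
        payload = json.loads(clf.to_json())
        assert payload["format_version"] == 1
        assert payload["panel_feature_ids"] == [str(f) for f in panel.feature_ids]
        assert len(payload["svm"]["support_vectors"]) >= 2


class TestLoocv:
    def test_scores_are_sample_order_invariant(self):
        values, groups = _informative_dataset(seed=3, n=8)
        panel = MarkerPanel(list(values.columns))
        a = loocv_scores(values, groups, panel)
        perm = values.sample(frac=1, random_state=1).index
        b = loocv_scores(values.loc[perm], groups.loc[perm], panel)
        # identical up to the SMO solver's convergence tolerance
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index(),
                                       rtol=0, atol=5e-3)

    def test_null_features_random_labels_calibrate_near_half(self):
        rng = np.random.default_rng(11)
        n = 200
        values = pd.DataFrame(np.exp(rng.normal(0, 1, (n, 6))) * 1e-4,
                              index=[f"s{i}" for i in range(n)],
                              columns=[f"f{j}" for j in range(6)])
        groups = pd.Series(np.where(rng.random(n) < 0.5, "AKI", "non-AKI"),
                           index=values.index)
        panel = MarkerPanel(list(values.columns))
        s = loocv_roc(values, groups, panel)
        assert 0.4 <= s.auc <= 0.6

    def test_informative_features_score_high_out_of_fold(self):
        values, groups = _informative_dataset(seed=4, n=15, shift=2.5)
        panel = MarkerPanel(list(values.columns))
        s = loocv_roc(values, groups, panel)
        assert s.auc > 0.9


class TestSelectPanel:
    def test_perfectly_separating_feature_selected_first(self):
        rng = np.random.default_rng(2)
        n = 10
        values = pd.DataFrame(
            {
                "strong": np.concatenate([np.full(n, 9e-4), np.full(n, 1e-5)])
                * np.exp(0.01 * rng.standard_normal(2 * n)),
                "null1": np.exp(rng.normal(0, 1, 2 * n)) * 1e-4,
                "null2": np.exp(rng.normal(0, 1, 2 * n)) * 1e-4,
            },
            index=[f"s{i}" for i in range(2 * n)],
        )
        groups = pd.Series(["AKI"] * n + ["non-AKI"] * n, index=values.index)
        stats = group_summaries(make_matrix(values, groups))
        panel = select_panel(stats, values, groups)
        assert panel.feature_ids[0] == "strong"

    def test_no_significant_candidates_is_an_error(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(np.exp(rng.normal(0, 1, (20, 5))) * 1e-4,
                              index=[f"s{i}" for i in range(20)], columns=range(5))
        groups = pd.Series(["AKI"] * 10 + ["non-AKI"] * 10, index=values.index)
        stats = group_summaries(make_matrix(values, groups))
        with pytest.raises(ValueError, match="empty candidate pool"):
            select_panel(stats, values, groups, alpha=1e-9)

    def test_selection_on_full_data_inflates_loocv_auc_on_null_data(self):
        """Optimism check: selecting features on the full null cohort and then
        cross-validating the selected panel yields an AUC well above chance,
        because the selection step saw every sample."""
        cfg = GeneratorConfig(n_case=17, n_control=17, n_pool_replicates=0,
                              peptide_params=[], n_background=200, seed=6)
        values, groups, _ = generate_amplitude_matrix(cfg)
        stats = group_summaries(make_matrix(values, groups))
        dense = values.fillna(0.0)
        panel = select_panel(stats, dense, groups, alpha=0.05)
        s = loocv_roc(dense, groups, panel)
        assert s.auc > 0.65  # pure nulls, yet far above 0.5


class TestCombiner:
    def test_duplicated_score_adds_nothing(self):
        rng = np.random.default_rng(7)
        a = np.concatenate([rng.normal(1, 1, 30), rng.normal(-1, 1, 30)])
        y = np.array([1] * 30 + [0] * 30)
        single = roc_summary(a, y)
        _, combined, _ = combine_logistic(a, a.copy(), y)
        assert combined.auc == pytest.approx(single.auc, abs=1e-9)

    def test_two_informative_scores_combine_at_least_as_well(self):
        aucs_single, aucs_comb = [], []
        for seed in range(8):
            rng = np.random.default_rng(20 + seed)
            n = 40
            y = np.array([1] * n + [0] * n)
            a = np.concatenate([rng.normal(0.8, 1, n), rng.normal(0, 1, n)])
            b = np.concatenate([rng.normal(0.8, 1, n), rng.normal(0, 1, n)])
            best = max(roc_summary(a, y).auc, roc_summary(b, y).auc)
            _, comb, _ = combine_logistic(a, b, y)
            aucs_single.append(best)
            aucs_comb.append(comb.auc)
        assert np.median(aucs_comb) >= np.median(aucs_single)

    def test_youden_threshold_maximizes_j(self):
        rng = np.random.default_rng(9)
        y = np.array([1] * 25 + [0] * 25)
        a = np.concatenate([rng.normal(1, 1, 25), rng.normal(0, 1, 25)])
        b = rng.normal(0, 1, 50)
        _, roc, thr = combine_logistic(a, b, y)

        def j_at(t):
            return np.mean(roc.scores[y == 1] >= t) + np.mean(roc.scores[y == 0] < t) - 1

        best_j = max(j_at(t) for t in np.unique(roc.scores))
        assert j_at(thr) == pytest.approx(best_j, abs=1e-12)

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            combine_logistic([1.0, 2.0], [1.0, 2.0], [1, 1])

    def test_perfect_separation_falls_back_to_penalized_fit(self):
        y = np.array([1] * 10 + [0] * 10)
        a = np.concatenate([np.ones(10), -np.ones(10)])
        with pytest.warns(UserWarning, match="separation"):
            _, roc, _ = combine_logistic(a, a, y)
        assert roc.auc == 1.0


class TestSubgroups:
    def test_two_group_case_reduces_to_rank_sum(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(0, 1, 30)
        labels = np.array(["a"] * 14 + ["b"] * 16)
        p_kw = subgroup_score_analysis(scores, labels)
        p_w, _ = wilcoxon_feature(scores[labels == "a"], scores[labels == "b"])
        assert p_kw == pytest.approx(p_w, rel=1e-9)

    def test_shifted_subgroup_detected(self):
        rng = np.random.default_rng(13)
        scores = np.concatenate([rng.normal(0, 1, 15), rng.normal(10, 1, 15),
                                 rng.normal(0, 1, 15)])
        labels = np.repeat(["r", "i", "f"], 15)
        assert subgroup_score_analysis(scores, labels) < 1e-3

    def test_null_subgroups_not_flagged(self):
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(40):
            scores = rng.normal(0, 1, 45)
            labels = np.repeat(["r", "i", "f"], 15)
            ps.append(subgroup_score_analysis(scores, labels))
        # p-values roughly uniform under the null: no mass collapse at 0
        assert np.mean(np.array(ps) < 0.05) < 0.2
        assert np.median(ps) > 0.2
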