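"""Univariate statistics, DeLong machinery, Holm, LOOCV models, cohort stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ieeg_focality.focality_model import (
    cohens_d,
    cohort_stats,
    delong_auc_ci,
    delong_auc_variance,
    delong_paired_test,
    holm_bonferroni,
    loocv_predict,
    mann_whitney_auc,
    model_comparison_suite,
    model_specs,
    optimal_operating_point,
    subgroup_analysis,
    yates_chi2,
)


class TestCohensD:
    def test_identical_groups_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert cohens_d(x, x) == pytest.approx(0.0)

    def test_unit_shift_unit_sd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, size=20000)
        b = rng.normal(0.0, 1.0, size=20000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_hand_example(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestMannWhitney:
    def test_complete_separation(self):
        _, _, auc = mann_whitney_auc([5, 6, 7], [1, 2, 3])
        assert auc == 1.0

    def test_identical_samples_half(self):
        _, p, auc = mann_whitney_auc([1, 2, 3], [1, 2, 3])
        assert auc == pytest.approx(0.5)
        assert p == pytest.approx(1.0)

    def test_brute_force_pair_count(self):
        pos, neg = [0.15, 0.3], [0.1, 0.2]
        _, _, auc = mann_whitney_auc(pos, neg)
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / 4) == pytest.approx(0.75)


class TestDeLong:
    def test_auc_identity_with_mann_whitney(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n1, n0 = rng.integers(3, 40, size=2)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # ties included
            labels = np.r_[np.ones(n1), np.zeros(n0)].astype(bool)
            auc_d, _ = delong_auc_variance(scores, labels)
            _, _, auc_u = mann_whitney_auc(scores[labels], scores[~labels])
            assert auc_d == pytest.approx(auc_u, abs=1e-12)

    def test_perfect_separation_ci(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = scores > 0.5
        res = delong_auc_ci(scores, labels)
        assert res.auc == 1.0
        assert res.ci[1] == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_auc_ci(np.arange(5.0), np.ones(5, bool))

    def test_paired_identical_models_p_one(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=30)
        y = rng.random(30) > 0.4
        delta, z, p = delong_paired_test(s, s, y)
        assert delta == 0.0 and p == 1.0

    def test_paired_antisymmetry(self):
        rng = np.random.default_rng(3)
        s1 = rng.normal(size=40)
        s2 = rng.normal(size=40)
        y = rng.random(40) > 0.5
        d12, z12, p12 = delong_paired_test(s1, s2, y)
        d21, z21, p21 = delong_paired_test(s2, s1, y)
        assert d12 == pytest.approx(-d21)
        assert z12 == pytest.approx(-z21)
        assert p12 == pytest.approx(p21)

    def test_flipped_model_delta(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=30)
        y = rng.random(30) > 0.5
        auc, _ = delong_auc_variance(s, y)
        delta, _, _ = delong_paired_test(s, 1.0 - s, y)
        assert delta == pytest.approx(2 * auc - 1)

    def test_paired_p_close_to_permutation_oracle(self):
        # n=8 per class fixture; oracle swaps the two models' scores per
        # patient (exchangeable under H0) and recomputes ΔAUC
        rng = np.random.default_rng(5)
        n = 16
        y = np.r_[np.ones(8), np.zeros(8)].astype(bool)
        base = rng.normal(size=n) + 0.8 * y
        s1 = base + 0.4 * rng.normal(size=n)
        s2 = base + 0.4 * rng.normal(size=n)
        _, _, p_delong = delong_paired_test(s1, s2, y)

        def auc_of(s):
            return delong_auc_variance(s, y)[0]

        obs = abs(auc_of(s1) - auc_of(s2))
        n_perm = 10_000
        flips = np.random.default_rng(6).random((n_perm, n)) < 0.5
        count = 0
        for f in flips:
            a = np.where(f, s1, s2)
            b = np.where(f, s2, s1)
            if abs(auc_of(a) - auc_of(b)) >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert p_delong == pytest.approx(p_perm, abs=0.05)


class TestHolm:
    def test_smallest_in_family_of_three(self):
        adj, _ = holm_bonferroni([0.003, 0.2, 0.5])
        assert adj[0] == pytest.approx(0.009)

    def test_single_p_unchanged(self):
        adj, _ = holm_bonferroni([0.04])
        assert adj[0] == pytest.approx(0.04)

    def test_hand_stepdown(self):
        adj, reject = holm_bonferroni([0.01, 0.04, 0.30], alpha=0.05)
        assert np.allclose(adj, [0.03, 0.08, 0.30])
        assert list(reject) == [True, False, False]

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8),
        st.integers(0, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_adjusted_dominates_raw_and_bounded_by_bonferroni(self, ps, _seed):
        ps = np.asarray(ps)
        adj, _ = holm_bonferroni(ps)
        assert np.all(adj >= ps - 1e-15)
        assert np.all(adj <= np.minimum(ps * len(ps), 1.0) + 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])


class TestLOOCV:
    def _noise_features(self, rng, n=40, p=4):
        X = pd.DataFrame(
            rng.normal(size=(n, p)),
            columns=["five_sense", "implant_distance_mm", "wsd_a_power_mm", "wsd_b_power_mm"],
        )
        return X

    def test_label_feature_gives_perfect_cv_auc(self):
        rng = np.random.default_rng(7)
        y = rng.random(30) > 0.5
        X = self._noise_features(rng, n=30)
        X["five_sense"] = y.astype(float)
        spec = model_specs(X.columns)[0]
        cv = loocv_predict(X, y, spec)
        auc, _ = delong_auc_variance(cv.probabilities, y)
        assert auc == 1.0

    def test_shuffled_labels_near_null(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.ones(65), np.zeros(36)].astype(bool)
        rng.shuffle(y)
        X = self._noise_features(rng, n=101)
        cv = loocv_predict(X, y, model_specs(X.columns)[2])
        auc, _ = delong_auc_variance(cv.probabilities, y)
        assert 0.35 <= auc <= 0.65

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.random(24) > 0.4
        X = self._noise_features(rng, n=24)
        X["five_sense"] += y
        spec = model_specs(X.columns)[2]
        base = loocv_predict(X, y, spec).probabilities
        perm = rng.permutation(24)
        permuted = loocv_predict(X.iloc[perm].reset_index(drop=True), y[perm], spec).probabilities
        assert np.allclose(permuted, base[perm], atol=1e-9)

    def test_held_out_label_flip_never_changes_prediction(self):
        rng = np.random.default_rng(10)
        y = rng.random(20) > 0.5
        X = self._noise_features(rng, n=20)
        spec = model_specs(X.columns)[1]
        base = loocv_predict(X, y, spec).probabilities
        for i in range(0, 20, 5):
            y2 = y.copy()
            y2[i] = ~y2[i]
            flipped = loocv_predict(X, y2, spec).probabilities
            assert flipped[i] == pytest.approx(base[i], abs=1e-12)

    def test_single_class_fold_rejected(self):
        X = self._noise_features(np.random.default_rng(11), n=12)
        y = np.zeros(12, bool)
        y[0] = True  # removing the only positive leaves a single-class fold
        with pytest.raises(ValueError, match="single class"):
            loocv_predict(X, y, model_specs(X.columns)[0])

    def test_lasso_zeroes_noise_coefficients(self):
        rng = np.random.default_rng(12)
        y = np.r_[np.ones(50), np.zeros(51)].astype(bool)
        X = self._noise_features(rng, n=101)
        X["five_sense"] = y + 0.5 * rng.normal(size=101)
        cv = loocv_predict(X, y, model_specs(X.columns)[2])
        zeroed_per_fold = (cv.coefficients == 0).sum(axis=1)
        assert np.median(zeroed_per_fold) > 0


class TestOperatingPoint:
    def test_toy_threshold_enumeration(self):
        scores = np.array([0.1, 0.4, 0.3, 0.8])
        labels = np.array([0, 0, 1, 1], bool)
        res = delong_auc_ci(scores, labels)
        assert res.sensitivity == 1.0
        assert res.specificity == 0.5
        assert 0.1 < res.threshold <= 0.3

    def test_scores_equal_labels_diagonal_confusion(self):
        labels = np.array([0, 1, 0, 1, 1], bool)
        res = delong_auc_ci(labels.astype(float), labels)
        tn, fp = res.confusion[0]
        fn, tp = res.confusion[1]
        assert fp == fn == 0
        assert tn == 2 and tp == 3

    def test_tie_break_prefers_sensitivity(self):
        fpr = np.array([0.0, 0.2, 0.6, 1.0])
        tpr = np.array([0.0, 0.2, 0.6, 1.0])  # J = 0 everywhere
        thr = np.array([np.inf, 0.8, 0.5, 0.1])
        threshold, sens, spec = optimal_operating_point(fpr, tpr, thr)
        assert sens == 1.0 and threshold == 0.1


class TestModelComparison:
    def test_informative_features_beat_baseline(self):
        rng = np.random.default_rng(13)
        n = 80
        y = np.r_[np.ones(45), np.zeros(35)].astype(bool)
        X = pd.DataFrame(
            {
                "five_sense": 0.3 * y + rng.normal(size=n),
                "implant_distance_mm": rng.normal(size=n),
                "wsd_gamma_power_mm": -1.2 * y + rng.normal(size=n),
                "wsd_delta_power_mm": -1.0 * y + rng.normal(size=n),
            }
        )
        report = model_comparison_suite(X, y)
        models = report["models"].set_index("model")["auc"]
        assert models["five_sense+implant+abnormality"] > models["five_sense_only"]
        comp = report["comparisons"]
        assert set(comp.columns) >= {"model_a", "model_b", "delta_auc", "p", "p_holm", "reject"}
        assert (comp["p_holm"] >= comp["p"] - 1e-12).all()

    def test_nested_null_delta_centred_at_zero(self):
        deltas = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 80
            y = rng.random(n) > 0.45
            X = pd.DataFrame(
                {
                    "five_sense": 1.0 * y + rng.normal(size=n),
                    "implant_distance_mm": rng.normal(size=n),
                    "wsd_a_power_mm": rng.normal(size=n),
                }
            )
            report = model_comparison_suite(X, y)
            comp = report["comparisons"].set_index(["model_a", "model_b"])
            deltas.append(
                comp.loc[("five_sense+implant+abnormality", "five_sense_only"), "delta_auc"]
            )
        assert abs(np.mean(deltas)) < 0.06


class TestSubgroups:
    def _cohort(self, rng, n=60):
        focal = rng.random(n) > 0.4
        therapy = np.where(rng.random(n) < np.where(focal, 0.8, 0.3), "resection", "neurostimulation")
        outcome = np.where(
            therapy == "resection", np.where(rng.random(n) < 0.6, "ILAE 1-2", "ILAE 3-6"), "none"
        )
        return pd.DataFrame(
            {
                "focality_label": np.where(focal, "focal", "nonfocal"),
                "subtype": np.where(focal, "focal", rng.choice(["bifocal", "multifocal"], size=n)),
                "therapy": therapy,
                "outcome": outcome,
                "implant_type": rng.choice(["SEEG", "ECOG"], size=n),
            }
        )

    def test_generative_consistency_surgery_vs_device(self):
        rng = np.random.default_rng(14)
        cohort = self._cohort(rng)
        probs = (cohort["focality_label"] == "focal") + 0.3 * rng.normal(size=len(cohort))
        out = subgroup_analysis(probs, cohort)
        row = out[out["contrast"] == "surgery_vs_device"].iloc[0]
        assert row["status"] == "ok" and row["auc"] > 0.5

    def test_identical_predictions_null(self):
        rng = np.random.default_rng(15)
        cohort = self._cohort(rng)
        probs = np.full(len(cohort), 0.5)
        out = subgroup_analysis(probs, cohort)
        ok = out[out["status"] == "ok"]
        assert np.allclose(ok["auc"], 0.5)
        assert np.allclose(ok["p"], 1.0)

    def test_relabelling_flips_auc(self):
        rng = np.random.default_rng(16)
        cohort = self._cohort(rng)
        probs = rng.random(len(cohort))
        out = subgroup_analysis(probs, cohort)
        flipped = subgroup_analysis(1.0 - probs, cohort)
        a = out[out["contrast"] == "surgery_vs_device"]["auc"].iloc[0]
        b = flipped[flipped["contrast"] == "surgery_vs_device"]["auc"].iloc[0]
        assert a == pytest.approx(1.0 - b)

    def test_small_subgroup_reported_insufficient(self):
        rng = np.random.default_rng(17)
        cohort = self._cohort(rng, n=20)
        cohort.loc[:, "implant_type"] = "SEEG"
        cohort.loc[0, "implant_type"] = "ECOG"
        out = subgroup_analysis(rng.random(20), cohort)
        row = out[out["contrast"] == "focal_vs_nonfocal_ECOG"].iloc[0]
        assert row["status"] == "insufficient"


class TestCohortStats:
    def test_balanced_table_null(self):
        chi2, p = yates_chi2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_report_structure(self):
        rng = np.random.default_rng(18)
        n = 80
        focal = rng.random(n) > 0.4
        df = pd.DataFrame(
            {
                "focality_label": np.where(focal, "focal", "nonfocal"),
                "five_sense": rng.random(n),
                "therapy": rng.choice(["resection", "ablation", "neurostimulation"], size=n),
                "implant_type": rng.choice(["SEEG", "ECOG"], size=n),
            }
        )
        out = cohort_stats(df)
        assert {"continuous", "categorical"} == set(out["kind"])
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()
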