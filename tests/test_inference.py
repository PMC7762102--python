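"""Tests for the statistical battery: CI filter, t-tests/FDR, LOOCV GLM,
ROC/AUC and the DeLong comparison."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from nvcomplexity.features import FAMILIES, FEATURE_NAMES
from nvcomplexity.inference import (
    bh_adjust,
    bootstrap_ci_filter,
    compare_auc,
    glm_loocv_classify,
    roc_analysis,
    sweep_auc,
    ttests_fdr,
    youden_threshold,
)

from conftest import bh_bruteforce


def make_table(rng, n_ad=17, n_hc=18, shift=None, phase="P"):
    """Fabricate a cohort feature table with Gaussian features."""
    n = n_ad + n_hc
    groups = np.array([1] * n_ad + [0] * n_hc)
    rows = {}
    for feat in FEATURE_NAMES:
        x = rng.standard_normal(n)
        if shift:
            x += shift.get(feat, 0.0) * groups
        rows[feat] = x
    table = pd.DataFrame(rows)
    table.insert(0, "subject_id", [f"S{i:02d}" for i in range(n)])
    table.insert(1, "phase", phase)
    table.insert(2, "group", groups)
    for feat in FEATURE_NAMES:
        table[f"valid_{feat}"] = True
    return table


class TestBHAdjust:
    def test_hand_applied_step_up_rule(self):
        p = [0.001, 0.01, 0.02, 0.04, 0.05]
        q = bh_adjust(p)
        assert np.allclose(q, [0.005, 0.025, 1.0 / 30.0, 0.05, 0.05], atol=1e-12)

    def test_matches_bruteforce_and_statsmodels(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            p = rng.uniform(size=rng.integers(1, 25))
            q = bh_adjust(p)
            assert np.allclose(q, bh_bruteforce(p), atol=1e-12)
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)


class TestBootstrapCIFilter:
    def test_identical_values_all_retained(self):
        mask, (lo, hi) = bootstrap_ci_filter(np.full(10, 3.3), rng=np.random.default_rng(0))
        assert mask.all() and lo == hi == pytest.approx(3.3)

    def test_gross_outlier_excluded(self):
        excluded = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            values = np.append(rng.standard_normal(17), 10.0)
            mask, _ = bootstrap_ci_filter(values, rng=rng)
            excluded += not mask[-1]
        assert excluded == 50

    def test_contract_retained_subset_and_ordered_bounds(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal(20)
        mask, (lo, hi) = bootstrap_ci_filter(values, rng=rng)
        assert lo <= hi
        assert values[mask].min() >= lo and values[mask].max() <= hi

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            bootstrap_ci_filter([1.0, 2.0])


class TestTTestsFDR:
    def test_identical_groups_give_null_statistics(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(18)
        table = make_table(rng, n_ad=18, n_hc=18)
        for feat in FEATURE_NAMES:
            table[feat] = np.concatenate([base, base])
        results = ttests_fdr(table, "P")
        assert np.allclose(results["t"], 0.0)
        assert np.allclose(results["p"], 1.0)
        assert np.allclose(results["cohen_d"], 0.0)

    def test_separated_groups_flagged_significant(self):
        rng = np.random.default_rng(3)
        table = make_table(rng, shift={f: 0.0 for f in FEATURE_NAMES})
        feat = FEATURE_NAMES[0]
        table[feat] = table["group"] * 1.0 + 0.001 * rng.standard_normal(len(table))
        results = ttests_fdr(table, "P").set_index("metric")
        assert abs(results.loc[feat, "cohen_d"]) > 10
        assert results.loc[feat, "q"] < 0.05

    def test_degrees_of_freedom_reflect_exclusions(self):
        rng = np.random.default_rng(4)
        table = make_table(rng)
        feat = FEATURE_NAMES[3]
        table.loc[table.index[:4], f"valid_{feat}"] = False
        results = ttests_fdr(table, "P").set_index("metric")
        assert results.loc[feat, "df"] == 35 - 4 - 2
        assert results.loc[FEATURE_NAMES[0], "df"] == 33


class TestGLMLOOCV:
    def test_perfectly_separating_feature_gives_auc_one(self):
        rng = np.random.default_rng(5)
        table = make_table(rng)
        for feat in FAMILIES["fNIRS"]:
            table[feat] = table["group"] * 2.0 + 0.01 * rng.standard_normal(len(table))
        result = glm_loocv_classify(table, "fNIRS", "P")
        assert result.auc == pytest.approx(1.0)

    def test_pure_noise_features_near_chance(self):
        aucs = []
        for seed in range(50):
            table = make_table(np.random.default_rng(seed))
            aucs.append(glm_loocv_classify(table, "fNIRS", "P").auc)
        assert 0.3 <= np.mean(aucs) <= 0.7

    def test_collinear_duplicate_column_same_scores(self):
        from nvcomplexity.inference import _loocv_scores

        rng = np.random.default_rng(6)
        x = rng.standard_normal((35, 3))
        y = np.array([1.0] * 17 + [0.0] * 18)
        design = np.column_stack([np.ones(35), x])
        design_dup = np.column_stack([design, x[:, 0]])  # duplicated column
        ref = _loocv_scores(design, y)
        with pytest.warns(UserWarning, match="rank-deficient"):
            dup = _loocv_scores(design_dup, y)
        assert np.allclose(ref, dup, atol=1e-8)

    def test_invalid_subjects_dropped_per_family(self):
        rng = np.random.default_rng(7)
        table = make_table(rng)
        table.loc[table.index[0], f"valid_{FAMILIES['EEG'][0]}"] = False
        result = glm_loocv_classify(table, "EEG", "P")
        assert len(result.subject_ids) == 34

    def test_single_class_rejected(self):
        rng = np.random.default_rng(8)
        table = make_table(rng)
        table["group"] = 1
        with pytest.raises(ValueError, match="both groups"):
            glm_loocv_classify(table, "EEG", "P")

    def test_affine_feature_rescaling_leaves_scores_unchanged(self):
        rng = np.random.default_rng(9)
        table = make_table(rng, shift={f: 0.8 for f in FAMILIES["EEG"]})
        ref = glm_loocv_classify(table, "EEG", "P")
        table[FAMILIES["EEG"][2]] = 100.0 * table[FAMILIES["EEG"][2]] - 17.0
        rescaled = glm_loocv_classify(table, "EEG", "P")
        assert np.allclose(ref.scores, rescaled.scores, atol=1e-8)


class TestROC:
    def test_perfect_and_chance_scores(self):
        labels = np.array([0, 0, 1, 1, 1])
        assert roc_analysis(labels.astype(float), labels).auc == 1.0
        rng = np.random.default_rng(10)
        labels = rng.integers(0, 2, 2000)
        auc = roc_analysis(rng.standard_normal(2000), labels).auc
        assert abs(auc - 0.5) < 0.05

    def test_hand_computed_auc(self):
        result = roc_analysis([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert result.auc == pytest.approx(0.75)

    def test_sweep_area_equals_rank_formulation(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(6, 60))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            result = roc_analysis(scores, labels)
            assert sweep_auc(result) == pytest.approx(result.auc, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(12)
        result = roc_analysis(rng.standard_normal(40), rng.integers(0, 2, 40) | (np.arange(40) == 0))
        assert result.fpr[0] == 0.0 and result.tpr[0] == 0.0
        assert result.fpr[-1] == 1.0 and result.tpr[-1] == 1.0
        assert (np.diff(result.fpr) >= 0).all() and (np.diff(result.tpr) >= 0).all()

    def test_operating_point_and_youden(self):
        scores = np.array([0.1, 0.2, 0.6, 0.7])
        labels = np.array([0, 0, 1, 1])
        result = roc_analysis(scores, labels, threshold=0.5)
        assert result.sensitivity == 1.0 and result.specificity == 1.0
        assert 0.2 < youden_threshold(result) <= 0.6

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.2], [1, 1])


class TestCompareAUC:
    @staticmethod
    def _roc(scores, labels):
        result = roc_analysis(np.asarray(scores, float), np.asarray(labels))
        result.subject_ids = [f"S{i}" for i in range(len(labels))]
        return result

    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(13)
        r = self._roc(rng.standard_normal(35), [1] * 17 + [0] * 18)
        z, p = compare_auc(r, r)
        assert z == 0.0 and p == 1.0

    def test_matches_r_proc_reference(self):
        # frozen from R pROC::roc.test(method="delong", paired=TRUE)
        rng = np.random.default_rng(7)
        labels = np.array([1] * 17 + [0] * 18)
        a = labels * 1.0 + rng.normal(0, 0.8, 35)
        b = labels * 1.0 + rng.normal(0, 2.0, 35)
        ra, rb = self._roc(a, labels), self._roc(b, labels)
        assert ra.auc == pytest.approx(0.9575163, abs=1e-6)
        assert rb.auc == pytest.approx(0.6241830, abs=1e-6)
        z, p = compare_auc(ra, rb)
        assert z == pytest.approx(3.22371, abs=1e-4)
        assert p == pytest.approx(0.001265413, abs=1e-7)

    def test_antisymmetry(self):
        rng = np.random.default_rng(14)
        labels = np.array([1] * 10 + [0] * 10)
        ra = self._roc(labels + rng.standard_normal(20), labels)
        rb = self._roc(rng.standard_normal(20), labels)
        z1, p1 = compare_auc(ra, rb)
        z2, p2 = compare_auc(rb, ra)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_discriminating_vs_noise_significant(self):
        labels = np.array([1] * 17 + [0] * 18)
        significant = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            good = self._roc(labels + 0.05 * rng.standard_normal(35), labels)
            noise = self._roc(rng.standard_normal(35), labels)
            _, p = compare_auc(good, noise)
            significant += p < 0.01
        assert significant >= 45

    def test_unpaired_inputs_rejected(self):
        rng = np.random.default_rng(15)
        labels = np.array([1] * 5 + [0] * 5)
        ra = self._roc(rng.standard_normal(10), labels)
        rb = self._roc(rng.standard_normal(10), labels)
        rb.subject_ids = [f"T{i}" for i in range(10)]
        with pytest.raises(ValueError, match="unpaired"):
            compare_auc(ra, rb)
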