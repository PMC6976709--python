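"""Classifier post-processing tests: group mapping, confusion metrics,
threshold filtering to a precision target, and correction factors."""

import numpy as np
import pandas as pd
import pytest

from planktransect.classify import (
    UNKNOWN,
    ClassMap,
    apply_thresholds,
    confusion_and_metrics,
    correction_factors,
    fit_thresholds,
    harmonic_f1,
    map_to_groups,
    weighted_summary,
)
from planktransect.synth import ConfusionSpec, gen_classified_vignettes
from tests.conftest import diagonal_confusion


class TestClassMap:
    def test_identity_map_preserves_labels(self):
        cm = ClassMap({i: i for i in range(3)})
        labels = pd.Series([0, 1, 2, 1])
        pd.testing.assert_series_equal(map_to_groups(labels, cm), labels)

    def test_many_to_one_conserves_counts(self):
        cm = ClassMap({"chaet_a": "chaetognath", "chaet_b": "chaetognath",
                       "chaet_c": "chaetognath", "fish": "larval_fish"})
        labels = pd.Series(["chaet_a"] * 3 + ["chaet_b"] * 2 + ["chaet_c"] + ["fish"] * 4)
        grouped = map_to_groups(labels, cm)
        assert (grouped == "chaetognath").sum() == 6
        assert (grouped == "larval_fish").sum() == 4

    def test_unmapped_label_error_names_it(self):
        cm = ClassMap({0: "a"})
        with pytest.raises(KeyError, match="7"):
            map_to_groups(pd.Series([0, 7]), cm)

    def test_unknown_is_reserved(self):
        with pytest.raises(ValueError, match="reserved"):
            ClassMap({0: UNKNOWN})


class TestConfusionAndMetrics:
    def test_hand_arithmetic_counts(self):
        # TP=8, FP=2, FN=4 for group a -> P=0.8, R=2/3, F1=8/11
        cm = ClassMap({"a": "a", "b": "b"})
        df = pd.DataFrame({
            "true_fine": ["a"] * 8 + ["b"] * 2 + ["a"] * 4 + ["b"] * 6,
            "pred_fine": ["a"] * 8 + ["a"] * 2 + ["b"] * 4 + ["b"] * 6,
        })
        _, metrics = confusion_and_metrics(df, cm)
        assert metrics.loc["a", "precision"] == pytest.approx(0.8)
        assert metrics.loc["a", "recall"] == pytest.approx(2 / 3)
        assert metrics.loc["a", "f1"] == pytest.approx(8 / 11)

    def test_f1_worked_example(self):
        # precision 88.2%, recall 41.2% -> F1 = 56.2% at one decimal
        assert round(100 * harmonic_f1(0.882, 0.412), 1) == 56.2

    def test_perfect_predictions(self):
        cm = ClassMap({0: "x", 1: "y"})
        df = pd.DataFrame({"true_fine": [0, 0, 1, 1], "pred_fine": [0, 0, 1, 1]})
        _, metrics = confusion_and_metrics(df, cm)
        assert (metrics[["precision", "recall", "f1"]] == 1.0).all().all()

    def test_f1_between_min_and_max_of_p_and_r(self, confusion_setup):
        _, class_map, _, train, _ = confusion_setup
        _, metrics = confusion_and_metrics(train, class_map)
        ok = metrics[["precision", "recall", "f1"]].dropna()
        low = ok[["precision", "recall"]].min(axis=1)
        high = ok[["precision", "recall"]].max(axis=1)
        assert ((ok.f1 >= low - 1e-12) & (ok.f1 <= high + 1e-12)).all()

    def test_never_predicted_group_has_nan_precision(self):
        cm = ClassMap({0: "x", 1: "y"})
        df = pd.DataFrame({"true_fine": [0, 1, 1], "pred_fine": [0, 0, 0]})
        _, metrics = confusion_and_metrics(df, cm)
        assert np.isnan(metrics.loc["y", "precision"])
        summary = weighted_summary(metrics)
        assert np.isfinite(summary["precision"])


class TestFitAndApplyThresholds:
    def test_already_above_target_gives_zero_threshold(self):
        spec = ConfusionSpec(2, 2, (0, 1), diagonal_confusion(2, 0.98),
                             np.full(2, 2000.0), seed=1)
        cm = ClassMap({0: "a", 1: "b"})
        table = fit_thresholds(gen_classified_vignettes(spec), cm)
        assert (table.threshold == 0.0).all()
        assert table.attainable.all()

    def test_heldout_precision_reaches_target(self, confusion_setup):
        _, class_map, fine_to_group, train, test = confusion_setup
        thresholds = fit_thresholds(train, class_map, target_precision=0.90)
        assert thresholds.attainable.all()
        groups = apply_thresholds(test, thresholds, class_map)
        true_g = test.true_fine.map(fine_to_group)
        for g in class_map.groups:
            sel = groups == g
            realized = (true_g[sel] == g).mean()
            assert realized >= 0.88, f"group {g}: realized precision {realized:.3f}"

    def test_uninformative_confidence_unattainable(self):
        # confidence independent of correctness, raw precision ~0.5:
        # no threshold can reach 0.9 in expectation
        spec = ConfusionSpec(2, 2, (0, 1), np.full((2, 2), 0.5),
                             np.full(2, 5000.0),
                             beta_correct=(6.0, 4.0), beta_incorrect=(6.0, 4.0), seed=2)
        cm = ClassMap({0: "a", 1: "b"})
        df = gen_classified_vignettes(spec)
        table = fit_thresholds(df, cm)
        assert not table.attainable.any()
        # unattainable classes filter everything out
        groups = apply_thresholds(df, table, cm)
        assert (groups == UNKNOWN).all()

    def test_low_support_class_inherits_pooled_threshold(self, confusion_setup):
        spec, class_map, _, train, _ = confusion_setup
        rare = train.copy()
        keep = rare.pred_fine != 0
        rare = pd.concat([rare[keep], rare[~keep].head(5)])
        table = fit_thresholds(rare, class_map, min_support=20)
        assert table.loc[0, "pooled"]

    def test_strict_inequality_at_threshold(self):
        cm = ClassMap({0: "a"})
        df = pd.DataFrame({"pred_fine": [0, 0], "max_prob": [0.5, 0.5001]})
        thr = pd.DataFrame({"threshold": [0.5]}, index=pd.Index([0], name="fine"))
        groups = apply_thresholds(df, thr, cm)
        assert groups.tolist() == [UNKNOWN, "a"]

    def test_all_zero_thresholds_keep_everything(self, confusion_setup):
        _, class_map, _, train, _ = confusion_setup
        thr = pd.DataFrame({"threshold": 0.0}, index=pd.Index(range(8), name="fine"))
        groups = apply_thresholds(train, thr, class_map)
        assert (groups != UNKNOWN).all()

    def test_all_one_thresholds_reject_everything(self, confusion_setup):
        _, class_map, _, train, _ = confusion_setup
        thr = pd.DataFrame({"threshold": 1.0}, index=pd.Index(range(8), name="fine"))
        groups = apply_thresholds(train, thr, class_map)
        assert (groups == UNKNOWN).all()

    def test_kept_plus_unknown_conserved(self, confusion_setup):
        _, class_map, _, train, test = confusion_setup
        thresholds = fit_thresholds(train, class_map)
        groups = apply_thresholds(test, thresholds, class_map)
        assert ((groups == UNKNOWN) | groups.isin(class_map.groups)).all()
        assert len(groups) == len(test)

    def test_raising_threshold_does_not_decrease_precision(self, confusion_setup):
        # filtering monotonicity, checked empirically on the generative fixture
        _, class_map, fine_to_group, _, test = confusion_setup
        true_g = test.true_fine.map(fine_to_group)
        for lo, hi in [(0.0, 0.3), (0.3, 0.6), (0.6, 0.8)]:
            for g in class_map.groups:
                precisions = []
                for t in (lo, hi):
                    thr = pd.DataFrame({"threshold": t}, index=pd.Index(range(8), name="fine"))
                    groups = apply_thresholds(test, thr, class_map)
                    sel = groups == g
                    precisions.append((true_g[sel] == g).mean())
                # binomial noise allowance at these sample sizes
                assert precisions[1] >= precisions[0] - 0.02


class TestCorrectionFactors:
    def _metrics(self, p, r):
        return pd.DataFrame({"precision": [p], "recall": [r], "support": [100]},
                            index=pd.Index(["g"], name="group"))

    @pytest.mark.parametrize(
        "p, r, expected",
        [(0.882, 0.412, 2.14), (0.7, 0.7, 1.0), (0.9, 0.45, 2.0)],
    )
    def test_factor_values(self, p, r, expected):
        cf = correction_factors(self._metrics(p, r))
        assert round(float(cf.loc["g", "correction_factor"]), 2) == expected

    def test_zero_recall_flagged_uncorrectable(self):
        cf = correction_factors(self._metrics(0.8, 0.0))
        assert not cf.loc["g", "correctable"]
        assert np.isnan(cf.loc["g", "correction_factor"])

    def test_corrected_counts_recover_truth(self):
        # corrected = predicted count x P/R recovers true per-group counts
        # within 5% at n = 100,000 under homogeneous confusion
        k, g = 6, 3
        mapping = tuple(i % g for i in range(k))
        spec = ConfusionSpec(
            k, g, mapping, diagonal_confusion(k, 0.8),
            class_abundances=np.array([30000, 25000, 20000, 15000, 7000, 3000.0]),
            seed=31,
        )
        cm = ClassMap({i: f"g{mapping[i]}" for i in range(k)})
        fine_to_group = {i: f"g{mapping[i]}" for i in range(k)}
        train = gen_classified_vignettes(spec, seed=32)
        test = gen_classified_vignettes(spec, seed=33)
        _, metrics = confusion_and_metrics(train, cm)
        cf = correction_factors(metrics)["correction_factor"]
        true_counts = test.true_fine.map(fine_to_group).value_counts()
        pred_counts = test.pred_fine.map(fine_to_group).value_counts()
        for grp in cm.groups:
            corrected = pred_counts[grp] * cf[grp]
            assert corrected == pytest.approx(true_counts[grp], rel=0.05)
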