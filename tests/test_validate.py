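"""Segregation classification, labeling, Fisher tests and the logistic model."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from hetsnp import (
    TPModel,
    classify_segregation,
    fisher_exact_2x2,
    fit_tp_logit,
    label_true_false,
    tp_logit_predict,
    validation_summary,
)
from hetsnp.validate import DEFAULT_TP_COEFFS, percent, progeny_counts


def chi2_oracle(obs, exp):
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))


class TestSegregation:
    def test_f2_like_1_2_1(self):
        seg = classify_segregation("AB", "AB", (96, 181, 76))
        assert seg.expected_class == "ratio_1_2_1"
        n = 96 + 181 + 76
        assert seg.chi2 == pytest.approx(
            chi2_oracle((96, 181, 76), (n / 4, n / 2, n / 4))
        )
        assert seg.chi2 == pytest.approx(2.50, abs=0.01)
        assert seg.pvalue == pytest.approx(0.287, abs=0.005)

    def test_test_cross_1_1(self):
        seg = classify_segregation("AB", "AA", (195, 158, 0))
        assert seg.expected_class == "ratio_1_1"
        assert seg.chi2 == pytest.approx(chi2_oracle((195, 158), (176.5, 176.5)))
        assert seg.chi2 == pytest.approx(3.88, abs=0.01)

    def test_monomorphic(self):
        seg = classify_segregation("AA", "AA", (353, 0, 0))
        assert seg.expected_class == "monomorphic"

    def test_aa_x_bb_all_het_is_monomorphic(self):
        seg = classify_segregation("AA", "BB", (0, 100, 0))
        assert seg.expected_class == "monomorphic"

    def test_zero_progeny_unscorable(self):
        assert classify_segregation("AB", "AB", (0, 0, 0)).expected_class == "unscorable"

    def test_missing_parent_unscorable(self):
        assert classify_segregation("NA", "AB", (10, 20, 10)).expected_class == "unscorable"

    def test_impossible_class_beyond_tolerance_unscorable(self):
        # AB x AA cannot yield BB; 20% BB progeny exceeds the error tolerance
        assert classify_segregation("AB", "AA", (40, 40, 20)).expected_class == "unscorable"

    def test_impossible_class_within_tolerance_kept(self):
        seg = classify_segregation("AB", "AA", (98, 100, 2))
        assert seg.expected_class == "ratio_1_1"

    @pytest.mark.parametrize("counts", [(30, 50, 20), (10, 10, 10), (1, 2, 1)])
    def test_chi2_matches_brute_force(self, counts):
        seg = classify_segregation("AB", "AB", counts)
        n = sum(counts)
        assert seg.chi2 == pytest.approx(chi2_oracle(counts, (n / 4, n / 2, n / 4)))

    def test_progeny_counts_excludes_parents_and_na(self):
        col = pd.Series(
            ["AB", "AA", "AA", "AB", "BB", "NA"],
            index=["P1", "P2", "f1", "f2", "f3", "f4"],
        )
        assert progeny_counts(col, exclude=("P1", "P2")) == (1, 1, 1)


class TestLabeling:
    def test_monomorphic_is_false_positive(self):
        seg = classify_segregation("AA", "AA", (353, 0, 0))
        assert label_true_false(seg) == "false_positive"

    def test_test_cross_with_homozygous_discovery_parent(self):
        seg = classify_segregation("AA", "AB", (180, 170, 0))
        assert label_true_false(seg, discovery_parent="parent1") == "false_positive"

    def test_heterozygous_discovery_parent_segregating(self):
        seg = classify_segregation("AB", "AB", (96, 181, 76))
        assert label_true_false(seg) == "true_positive"

    def test_unscorable_propagates(self):
        seg = classify_segregation("NA", "AB", (10, 10, 0))
        assert label_true_false(seg) == "unscorable"


class TestFisher:
    def test_scorable_by_annotation_table(self):
        # genic/non-genic split of unscorable vs genotyped assays
        p = fisher_exact_2x2(378, 202, 3488, 1932)
        assert p == pytest.approx(0.7152, abs=5e-4)
        assert abs(p - 0.71) < 0.01

    def test_true_false_by_annotation_table(self):
        assert fisher_exact_2x2(1850, 805, 1638, 1127) < 1e-4

    def test_no_association(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_swap_invariance(self):
        p = fisher_exact_2x2(12, 5, 7, 21)
        assert fisher_exact_2x2(5, 12, 21, 7) == pytest.approx(p)  # column swap
        assert fisher_exact_2x2(7, 21, 12, 5) == pytest.approx(p)  # row swap

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)


class TestLogisticModel:
    def test_true_positive_group_means_predicted_true(self):
        p_false, label = tp_logit_predict(34.3, 18.4, 0.39)
        assert p_false == pytest.approx(expit(-0.758), abs=0.005)
        assert label == "true_positive"

    def test_false_positive_group_means_predicted_false(self):
        p_false, label = tp_logit_predict(33.7, 31.7, 0.34)
        assert p_false == pytest.approx(expit(0.740), abs=0.005)
        assert label == "false_positive"

    def test_zero_coefficients_give_half(self):
        model = TPModel(0.0, 0.0, 0.0, 0.0)
        assert tp_logit_predict(30, 20, 0.4, model)[0] == 0.5

    def test_monotonicity_signs(self):
        base = TPModel().predict(34, 20, 0.4)
        assert TPModel().predict(35, 20, 0.4) < base  # higher MQS -> less likely false
        assert TPModel().predict(34, 25, 0.4) > base  # higher RMD -> more likely false
        assert TPModel().predict(34, 20, 0.45) < base  # higher FVF -> less likely false

    def _sim_records(self, n, seed):
        rng = np.random.default_rng(seed)
        mqs = rng.normal(34, 1.8, n)
        rmd = np.clip(rng.gumbel(15, 9, n), 2, None)
        fvf = rng.uniform(0.05, 0.5, n)
        b0, b1, b2, b3 = DEFAULT_TP_COEFFS
        p = expit(b0 + b1 * mqs + b2 * rmd + b3 * fvf)
        return pd.DataFrame(
            dict(mqs=mqs, rmd=rmd, fvf=fvf, is_false=rng.random(n) < p)
        )

    def test_refit_recovers_generating_coefficients(self):
        model, report = fit_tp_logit(self._sim_records(5000, 11))
        for est, true, se in zip(
            (model.b0, model.b1, model.b2, model.b3), DEFAULT_TP_COEFFS, model.stderr
        ):
            assert abs(est - true) < 3 * se
        assert 0.5 < report["accuracy"] <= 1.0

    def test_training_accuracy_equals_confusion_arithmetic(self):
        df = self._sim_records(500, 3)
        model, report = fit_tp_logit(df)
        pred_false = np.array(
            [tp_logit_predict(r.mqs, r.rmd, r.fvf, model)[0] > 0.5 for r in df.itertuples()]
        )
        actual = df["is_false"].to_numpy()
        assert report["accuracy"] == pytest.approx(np.mean(pred_false == actual))

    def test_single_class_is_error(self):
        df = self._sim_records(100, 1)
        df["is_false"] = True
        with pytest.raises(ValueError):
            fit_tp_logit(df)

    def test_too_few_records_is_error(self):
        with pytest.raises(ValueError):
            fit_tp_logit(self._sim_records(20, 1))

    def test_perfect_separation_is_error(self):
        n = 200
        rng = np.random.default_rng(0)
        mqs = rng.normal(34, 2, n)
        df = pd.DataFrame(dict(mqs=mqs, rmd=20.0, fvf=0.4, is_false=mqs > 34))
        with pytest.raises(ValueError):
            fit_tp_logit(df)


class TestSummary:
    def test_printed_rate_arithmetic(self):
        assert percent(2655, 5420) == 49.0
        assert percent(5163, 6000) == 86.1
        assert percent(260, 2765) == 9.4

    def test_group_rates_and_fisher(self):
        labels = (
            ["false_positive"] * 1850 + ["true_positive"] * 1638  # genic
            + ["false_positive"] * 805 + ["true_positive"] * 1127  # nongenic
        )
        groups = ["genic"] * 3488 + ["nongenic"] * 1932
        out = validation_summary(labels, groups)
        assert out["false_positive_rate"] == 49.0
        assert out["by_group"]["genic"]["true_positive_rate"] == 47.0
        assert out["by_group"]["nongenic"]["true_positive_rate"] == 58.3
        assert out["fisher_p"] < 1e-4

    def test_unscorable_excluded_from_rates(self):
        out = validation_summary(["true_positive", "false_positive", "unscorable"])
        assert out["n_scored"] == 2 and out["true_positive_rate"] == 50.0

    def test_empty_input(self):
        assert validation_summary([]) == {"n": 0}
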