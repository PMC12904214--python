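import numpy as np
import pytest

import omgnet as og
from omgnet import ValidationInputError
from omgnet.validation import rank_auc


def pairwise_auc(scores, labels):
    """Oracle: explicit Mann-Whitney pairwise comparison, ties count 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        return None
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluate:
    def test_serology_training_row(self, model, records):
        rep = og.evaluate(model, records, ["achr"], n_samples=2001, seed=3)
        assert rep.n_cases == 89
        assert rep.n_misclassified == 8

    def test_pharmacologic_training_row(self, model, records):
        rep = og.evaluate(model, records, ["edrophonium"], n_samples=2001, seed=3)
        assert rep.n_cases == 71
        assert rep.n_misclassified == 6

    def test_constant_score_gives_half_auc(self, model, records):
        # sex-only evidence scores every male identically; restrict to one
        # sex so every record gets the same score: pure-tie AUC = 0.5
        males = [r for r in records if r.get("sex") == "male"]
        rep = og.evaluate(model, males, ["sex"], n_samples=501, seed=0)
        assert rep.auc == pytest.approx(0.5)

    def test_single_binary_predictor_auc_closed_form(self, model, records):
        # with two distinct scores, AUC = (sensitivity + specificity) / 2
        rep = og.evaluate(model, records, ["edrophonium"], n_samples=2001, seed=3)
        ss = og.sens_spec(records, "edrophonium")
        assert rep.auc == pytest.approx((ss.sensitivity + ss.specificity) / 2)

    def test_empty_evidence_acts_as_majority_classifier(self, model, records):
        # the no-evidence prediction assigns every record the outcome prior,
        # so thresholding it misclassifies exactly the minority class
        prior = og.predict(model, {}, n_samples=2001, seed=3)
        frac_pos = sum(r["omg"] == "positive" for r in records) / len(records)
        constant = prior.median > 0.5
        error = sum((r["omg"] == "positive") != constant for r in records) / len(records)
        assert error == pytest.approx(min(frac_pos, 1 - frac_pos))

    def test_rejects_empty_or_outcome_predictors(self, model, records):
        with pytest.raises(ValidationInputError):
            og.evaluate(model, records, [], n_samples=10, seed=0)
        with pytest.raises(ValidationInputError):
            og.evaluate(model, records, ["omg"], n_samples=10, seed=0)

    def test_zero_eligible_records_is_explicit_error(self, model):
        missing_all = [og.PatientRecord({"omg": "positive"})]
        with pytest.raises(ValidationInputError, match="no records"):
            og.evaluate(model, missing_all, ["ice"], n_samples=10, seed=0)


class TestRankAuc:
    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            scores = rng.choice([0.1, 0.3, 0.3, 0.6, 0.9], size=n).tolist()
            labels = rng.integers(0, 2, size=n).tolist()
            assert rank_auc(scores, labels) == pairwise_auc(scores, labels)

    def test_single_class_is_undefined(self):
        assert rank_auc([0.2, 0.8], [1, 1]) is None


class TestCrossValidate:
    def test_same_seed_identical_report(self, structure, records):
        a = og.cross_validate(records, structure, k=5,
                              predictor_set=["achr"], seed=17, n_samples=501)
        b = og.cross_validate(records, structure, k=5,
                              predictor_set=["achr"], seed=17, n_samples=501)
        assert a == b

    def test_leave_one_out_structure(self, structure, records):
        ten = records[:10]
        rep = og.cross_validate(ten, structure, k=10,
                                predictor_set=["achr"], seed=1, n_samples=201)
        assert rep.per_fold is not None and len(rep.per_fold) == 10
        assert all(f.n_cases == 1 for f in rep.per_fold)
        # singleton folds hold one class: AUC undefined but errors defined
        assert all(f.auc is None for f in rep.per_fold)
        assert rep.auc is None
        assert 0 <= rep.error_rate <= 1

    def test_eligibility_filter_matches_available_cases(self, structure, records):
        rep = og.cross_validate(records, structure, k=10,
                                predictor_set=["ice"], seed=2, n_samples=501)
        assert rep.n_cases == 51

    def test_too_few_records_raises(self, structure, records):
        with pytest.raises(ValidationInputError):
            og.cross_validate(records[:3], structure, k=5,
                              predictor_set=["achr"], seed=0)


class TestSensSpec:
    @pytest.mark.parametrize("variable, sens, spec", [
        ("edrophonium", (29, 31), (36, 40)),
        ("achr", (33, 39), (48, 50)),
        ("upgaze", (25, 38), (32, 46)),
        ("sfemg", (27, 36), (28, 50)),
    ])
    def test_training_cohort_test_accuracy(self, records, variable, sens, spec):
        result = og.sens_spec(records, variable)
        assert result.true_positive == sens[0]
        assert result.true_positive + result.false_negative == sens[1]
        assert result.true_negative == spec[0]
        assert result.true_negative + result.false_positive == spec[1]
        assert result.sensitivity == pytest.approx(sens[0] / sens[1])
        assert result.specificity == pytest.approx(spec[0] / spec[1])

    def test_empty_stratum_is_undefined(self):
        recs = [og.PatientRecord({"omg": "negative", "ice": "negative"})]
        result = og.sens_spec(recs, "ice")
        assert result.sensitivity is None
        assert result.specificity == 1.0
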