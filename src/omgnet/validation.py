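"""Model evaluation: error rate, ROC AUC, cross-validation, test accuracy.

Evaluation restricts to records that are complete with respect to the chosen
predictor set and the outcome ("available cases" for that predictor set).
Each eligible record is scored by the median predicted outcome probability
given only the predictor-set evidence; a score > 0.5 classifies the record
positive.  The error rate is the fraction misclassified.  The AUC is the
rank-based (Mann-Whitney) probability that a random positive case scores
above a random negative one, ties counting one half.

``cross_validate`` partitions the eligible records into k seeded folds of
near-equal size (unstratified), refits the network on k−1 folds with the
same prior, scores the held-out fold, and averages the per-fold error rates
and AUCs.  A fold containing a single outcome class has no defined AUC and
is skipped for the AUC average while still contributing its error rate.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .dataio import PatientRecord
from .errors import ValidationInputError
from .inference import DEFAULT_N_SAMPLES, DEFAULT_SEED, predict
from .model import FittedModel, count_records, fit
from .network import NetworkStructure

__all__ = ["FoldResult", "ValidationReport", "evaluate", "cross_validate",
           "sens_spec", "SensSpecResult", "complete_cases", "rank_auc"]


@dataclass(frozen=True)
class FoldResult:
    n_cases: int
    error_rate: float
    auc: float | None  # None when the fold holds a single outcome class


@dataclass
class ValidationReport:
    predictor_set: tuple[str, ...]
    n_cases: int
    error_rate: float
    auc: float | None
    per_fold: list[FoldResult] | None = None
    n_misclassified: int = 0


@dataclass(frozen=True)
class SensSpecResult:
    sensitivity: float | None
    specificity: float | None
    true_positive: int
    false_negative: int
    true_negative: int
    false_positive: int


def complete_cases(records: Sequence[PatientRecord],
                   variables: Sequence[str]) -> list[PatientRecord]:
    """Records in which every listed variable is observed."""
    return [r for r in records if r.observed(*variables)]


def rank_auc(scores: Sequence[float], labels: Sequence[int]) -> float | None:
    """Mann-Whitney AUC with the ½-tie convention; None if one class only."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)  # mid-ranks implement the ½-tie convention
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _score_records(model: FittedModel, records: Sequence[PatientRecord],
                   predictor_set: Sequence[str], n_samples: int, seed: int,
                   outcome: str) -> tuple[np.ndarray, np.ndarray]:
    """Median predicted outcome probability per record, with 0/1 truth labels.

    Evidence tuples repeat heavily across patients, so predictions are
    cached per distinct evidence configuration.
    """
    cache: dict[tuple, float] = {}
    scores, labels = [], []
    pos_idx = model.structure.state_index(outcome, "positive")
    positive_label = model.structure[outcome].states[pos_idx]
    for r in records:
        ev = {v: r[v] for v in predictor_set}
        key = tuple(sorted(ev.items()))
        if key not in cache:
            cache[key] = predict(model, ev, n_samples=n_samples, seed=seed,
                                 query=outcome).median
        scores.append(cache[key])
        labels.append(1 if r[outcome] == positive_label else 0)
    return np.asarray(scores), np.asarray(labels)


def evaluate(model: FittedModel, records: Sequence[PatientRecord],
             predictor_set: Sequence[str],
             n_samples: int = DEFAULT_N_SAMPLES, seed: int = DEFAULT_SEED) -> ValidationReport:
    """Error rate and AUC of the model on records, using only the predictor set.

    Restricts to records complete for ``predictor_set`` and the outcome;
    raises :class:`ValidationInputError` when none remain.
    """
    outcome = model.structure.outcome
    predictor_set = tuple(predictor_set)
    if not predictor_set:
        raise ValidationInputError("predictor set must be non-empty")
    if outcome in predictor_set:
        raise ValidationInputError(f"outcome {outcome!r} cannot be a predictor")
    eligible = complete_cases(records, [*predictor_set, outcome])
    if not eligible:
        raise ValidationInputError(
            f"no records are complete for predictors {list(predictor_set)} and {outcome!r}"
        )
    scores, labels = _score_records(model, eligible, predictor_set,
                                    n_samples, seed, outcome)
    predicted = (scores > 0.5).astype(int)
    n_wrong = int((predicted != labels).sum())
    return ValidationReport(
        predictor_set=predictor_set,
        n_cases=len(eligible),
        error_rate=n_wrong / len(eligible),
        auc=rank_auc(scores, labels),
        n_misclassified=n_wrong,
    )


def cross_validate(records: Sequence[PatientRecord], structure: NetworkStructure,
                   k: int, predictor_set: Sequence[str], seed: int,
                   prior_strength: float = 1.0,
                   n_samples: int = DEFAULT_N_SAMPLES) -> ValidationReport:
    """k-fold cross-validated error rate and AUC for one predictor set.

    Eligible records (complete for predictors + outcome) are shuffled with
    the given seed and split into k near-equal folds; the model is refitted
    on the remaining folds each time.  Identical seeds give identical folds
    and reports.
    """
    outcome = structure.outcome
    predictor_set = tuple(predictor_set)
    if k < 2:
        raise ValidationInputError("k must be >= 2")
    eligible = complete_cases(records, [*predictor_set, outcome])
    if len(eligible) < k:
        raise ValidationInputError(
            f"only {len(eligible)} eligible records for {k} folds"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(eligible))
    folds = np.array_split(perm, k)
    per_fold: list[FoldResult] = []
    for fold in folds:
        held = set(int(i) for i in fold)
        train = [r for i, r in enumerate(eligible) if i not in held]
        test = [eligible[i] for i in sorted(held)]
        fold_model = fit(count_records(train, structure), structure,
                         prior_strength=prior_strength)
        report = evaluate(fold_model, test, predictor_set,
                          n_samples=n_samples, seed=seed)
        per_fold.append(FoldResult(n_cases=report.n_cases,
                                   error_rate=report.error_rate, auc=report.auc))
    aucs = [f.auc for f in per_fold if f.auc is not None]
    return ValidationReport(
        predictor_set=predictor_set,
        n_cases=len(eligible),
        error_rate=float(np.mean([f.error_rate for f in per_fold])),
        auc=float(np.mean(aucs)) if aucs else None,
        per_fold=per_fold,
    )


def sens_spec(records: Sequence[PatientRecord], test_variable: str,
              outcome: str = "omg") -> SensSpecResult:
    """Sensitivity and specificity of one binary test against the outcome.

    Uses all records with both the test and the outcome observed.  An empty
    stratum leaves the corresponding measure undefined (``None``).
    """
    tp = fn = tn = fp = 0
    for r in records:
        if not r.observed(test_variable, outcome):
            continue
        if r[outcome] == "positive":
            if r[test_variable] == "positive":
                tp += 1
            else:
                fn += 1
        else:
            if r[test_variable] == "negative":
                tn += 1
            else:
                fp += 1
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    return SensSpecResult(sensitivity=sens, specificity=spec,
                          true_positive=tp, false_negative=fn,
                          true_negative=tn, false_positive=fp)


def report_table(reports: Sequence[ValidationReport]) -> str:
    """Human-readable text table: predictor set, cases, error, AUC."""
    lines = [f"{'predictors':40s} {'cases':>5s} {'error':>7s} {'AUC':>6s}"]
    for rep in reports:
        auc = f"{rep.auc:.3f}" if rep.auc is not None else "  --"
        lines.append(
            f"{', '.join(rep.predictor_set):40s} {rep.n_cases:5d} "
            f"{100 * rep.error_rate:6.2f}% {auc:>6s}"
        )
    return "\n".join(lines)
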