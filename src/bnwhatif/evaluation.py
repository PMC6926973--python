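"""Cross-validated comparison of network classifiers.

Compares the unrestricted learned network (GBN), its Markov-blanket
restricted variant (GBN-MB) and an in-house naive Bayes on accuracy,
class-frequency-weighted F-measure and weighted one-vs-rest ranking AUC.
Folds are stratified; per-fold test predictions are pooled and the metrics
computed once on the pooled records, so every row is scored exactly once.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .bn import (
    CategoricalVariable,
    DAGStructure,
    DiscreteBayesianNetwork,
    infer_posterior,
)
from .errors import (
    AUCUndefinedError,
    InconsistentEvidenceError,
    StratificationError,
)
from .learn import (
    LearnerConfig,
    estimate_cpts,
    gbn_mb_classifier,
    learn_structure,
    variables_from_data,
)

KNOWN_MODELS = ("gbn", "gbn-mb", "nb")


@dataclass(frozen=True)
class PredictionRecord:
    """Ground truth plus the predicted distribution over target states."""

    true_state: str
    states: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "probabilities", np.asarray(self.probabilities, dtype=float)
        )
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("prediction vector does not sum to 1")


@dataclass(frozen=True)
class EvaluationResult:
    model: str
    accuracy: float  # percent
    f_measure: float
    auc: float
    folds: int
    seed: int


def stratified_kfold(
    data: pd.DataFrame, class_var: str, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified folds as (train_idx, test_idx) pairs.

    Every class must have at least ``k`` rows so that each fold's class
    proportions stay within one row of the global proportions.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = data[class_var].astype(str).to_numpy()
    counts = pd.Series(labels).value_counts()
    if int(counts.min()) < k:
        rare = counts.idxmin()
        raise StratificationError(
            f"class {rare!r} has only {int(counts.min())} rows; cannot "
            f"stratify into {k} folds"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (np.asarray(tr), np.asarray(te))
        for tr, te in splitter.split(np.zeros(len(labels)), labels)
    ]


def classify_instance(
    net: DiscreteBayesianNetwork,
    class_var: str,
    row,
    fallback_net: DiscreteBayesianNetwork | None = None,
) -> PredictionRecord:
    """Posterior of the class given the row's evidence on the net's nodes.

    Evidence is restricted to variables the model actually contains (for the
    MB-restricted model that is exactly the blanket).  If the evidence has
    probability zero, the smoothed ``fallback_net`` is consulted instead.
    """
    if isinstance(row, dict):
        row = pd.Series(row)
    evidence = {
        n: str(row[n])
        for n in net.node_names
        if n != class_var and n in row.index
    }
    var = net.variable(class_var)
    try:
        post = infer_posterior(net, class_var, evidence)
    except InconsistentEvidenceError:
        if fallback_net is None:
            raise
        post = infer_posterior(fallback_net, class_var, evidence)
    return PredictionRecord(str(row[class_var]), var.states, post)


def _predicted_label(record: PredictionRecord) -> str:
    best = record.probabilities.max()
    candidates = [
        s for s, p in zip(record.states, record.probabilities) if p == best
    ]
    return min(candidates)


def compute_metrics(
    records: Sequence[PredictionRecord], average: str = "weighted"
) -> tuple[float, float, float]:
    """(accuracy %, averaged F-measure, averaged one-vs-rest AUC).

    Accuracy breaks posterior ties toward the lexicographically first state.
    F-measure and AUC average per-class values, weighted by class frequency
    by default (``average='macro'`` for unweighted means).  AUC uses midrank
    tie handling via the underlying rank statistic.
    """
    if not records:
        raise ValueError("no prediction records")
    states = records[0].states
    if any(r.states != states for r in records):
        raise ValueError("records disagree on the target state roster")
    y_true = np.array([r.true_state for r in records])
    y_pred = np.array([_predicted_label(r) for r in records])
    scores = np.vstack([r.probabilities for r in records])
    accuracy = 100.0 * float((y_true == y_pred).mean())

    observed = sorted(set(y_true))
    if len(observed) < 2:
        raise AUCUndefinedError("need at least two observed classes for AUC")
    f_measure = float(
        f1_score(y_true, y_pred, labels=observed, average=average, zero_division=0)
    )
    aucs = []
    weights = []
    for cls in observed:
        mask = y_true == cls
        aucs.append(float(roc_auc_score(mask, scores[:, states.index(cls)])))
        weights.append(float(mask.mean()))
    w = np.asarray(weights)
    if average == "weighted":
        auc = float((np.asarray(aucs) * w / w.sum()).sum())
    else:
        auc = float(np.mean(aucs))
    return accuracy, f_measure, auc


def _naive_bayes(
    train: pd.DataFrame,
    class_var: str,
    config: LearnerConfig,
    variables: Sequence[CategoricalVariable],
) -> DiscreteBayesianNetwork:
    features = [c for c in train.columns if c != class_var]
    structure = DAGStructure(
        tuple(sorted(train.columns)), tuple((class_var, f) for f in sorted(features))
    )
    return estimate_cpts(structure, train, config.smoothing_alpha, variables)


def _fit(model: str, train, class_var, config, variables):
    if model == "gbn":
        return learn_structure(train, config, variables)
    if model == "gbn-mb":
        net, _sel = gbn_mb_classifier(train, class_var, config, variables)
        return net
    if model == "nb":
        return _naive_bayes(train, class_var, config, variables)
    raise ValueError(f"unknown model {model!r}; known: {KNOWN_MODELS}")


def evaluate_models(
    data: pd.DataFrame,
    class_var: str,
    models: Sequence[str] = KNOWN_MODELS,
    k: int = 10,
    seed: int = 0,
    config: LearnerConfig | None = None,
    average: str = "weighted",
) -> list[EvaluationResult]:
    """k-fold cross-validated metrics per model, pooled over test folds.

    State rosters are derived from the full dataset so every fold shares
    them; CPTs are Laplace-smoothed per the learner config, which keeps
    held-out evidence consistent.
    """
    config = config or LearnerConfig(seed=seed)
    variables = variables_from_data(data)
    folds = stratified_kfold(data, class_var, k, seed)
    results = []
    for model in models:
        records: list[PredictionRecord] = []
        for train_idx, test_idx in folds:
            train = data.iloc[train_idx].reset_index(drop=True)
            test = data.iloc[test_idx]
            net = _fit(model, train, class_var, config, variables)
            fallback = None
            if config.smoothing_alpha == 0:
                fallback = estimate_cpts(net.structure, train, 1.0, variables)
            for _, row in test.iterrows():
                records.append(classify_instance(net, class_var, row, fallback))
        accuracy, f_measure, auc = compute_metrics(records, average=average)
        results.append(
            EvaluationResult(model, accuracy, f_measure, auc, k, seed)
        )
    return results


def write_evaluation_tsv(results: Sequence[EvaluationResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Model\tAccuracy\tF_Measure\tAUC\tFolds\tSeed\n")
        for r in results:
            fh.write(
                f"{r.model}\t{r.accuracy:.3f}\t{r.f_measure:.3f}\t{r.auc:.3f}"
                f"\t{r.folds}\t{r.seed}\n"
            )
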