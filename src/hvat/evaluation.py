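"""Evaluation: AUC, accuracy-maximizing threshold, sensitivity/specificity
reporting, the orderless tabular conversion, and the five-way model
comparison harness.

AUC is computed as the Mann-Whitney statistic — the probability that a random
case outscores a random control, ties counted half — via average ranks.  The
operating threshold is chosen on *training* scores only, as the accuracy-
maximizing cut with decision rule ``score >= threshold -> predicted case``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.stats import rankdata

from .events import ConceptVocabulary, StaticRecord
from .tokenization import TokenSequence, encode_static


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with tie correction (average ranks)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    m = int((labels == 1).sum())
    n = int((labels == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def choose_threshold(train_scores, train_labels) -> float:
    """Accuracy-maximizing threshold on training scores.

    Candidates are the midpoints between adjacent distinct sorted scores plus
    a below-minimum and an above-maximum sentinel; prediction is
    ``score >= threshold``.  Ties among maximizing candidates break toward the
    smallest threshold.
    """
    scores = np.asarray(train_scores, dtype=float)
    labels = np.asarray(train_labels)
    distinct = np.unique(scores)
    candidates = np.concatenate(
        ([distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0])
    )
    best_thr, best_acc = candidates[0], -1.0
    for thr in candidates:
        acc = float(((scores >= thr) == (labels == 1)).mean())
        if acc > best_acc:
            best_acc, best_thr = acc, float(thr)
    return best_thr


@dataclass
class SubsetMetrics:
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class EvalReport:
    threshold: float
    subsets: dict[str, SubsetMetrics] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "subsets": {
                k: {
                    "auc": v.auc,
                    "sensitivity": v.sensitivity,
                    "specificity": v.specificity,
                    "accuracy": v.accuracy,
                }
                for k, v in self.subsets.items()
            },
        }


def subset_metrics(scores, labels, threshold: float) -> SubsetMetrics:
    """Sensitivity, specificity and accuracy at a fixed threshold, plus AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    cases = labels == 1
    controls = labels == 0
    tp = int((pred & cases).sum())
    tn = int((~pred & controls).sum())
    return SubsetMetrics(
        auc=auc(scores, labels),
        sensitivity=tp / max(int(cases.sum()), 1),
        specificity=tn / max(int(controls.sum()), 1),
        accuracy=(tp + tn) / len(labels),
    )


def report(scores_by_subset: dict[str, tuple[np.ndarray, np.ndarray]]) -> EvalReport:
    """Build an EvalReport from per-subset (scores, labels).

    The threshold is fitted on the ``train`` subset and applied everywhere.
    """
    if "train" not in scores_by_subset:
        raise ValueError("report needs a 'train' subset to fit the threshold")
    thr = choose_threshold(*scores_by_subset["train"])
    rep = EvalReport(threshold=thr)
    for name, (scores, labels) in scores_by_subset.items():
        rep.subsets[name] = subset_metrics(scores, labels, thr)
    return rep


def aggregate_to_tabular(
    sequences: Iterable[TokenSequence],
    statics: list[StaticRecord],
    vocabulary: ConceptVocabulary,
) -> tuple[np.ndarray, list[str]]:
    """Collapse token sequences to one flat vector per patient.

    Temporal order is destroyed: unvalued concepts become whole-window
    presence indicators (0/1); valued concepts become whole-window aggregates
    of their per-interval token values (mean of means, or max of maxes, per
    the vocabulary rule; 0 when absent).  The 7 static variables are appended.
    Row order follows ``statics``.  This is the input representation for the
    orderless deep baseline (FFNN-NL) and the linear SVM comparator.
    """
    by_patient = {seq.patient_id: seq for seq in sequences}
    concepts = vocabulary.concepts
    columns = concepts + [
        "age", "sex", "race_black", "race_other", "race_unknown",
        "ethnicity_hispanic", "ethnicity_unknown",
    ]
    X = np.zeros((len(statics), len(columns)))
    for row, static in enumerate(statics):
        seq = by_patient.get(static.patient_id)
        if seq is not None:
            per_concept: dict[int, list[float]] = {}
            for tok in seq.tokens:
                if tok.t > 0:
                    per_concept.setdefault(tok.concept, []).append(tok.value)
            for cidx, values in per_concept.items():
                name = vocabulary.name(cidx)
                if vocabulary.has_values(name):
                    agg = vocabulary.aggregation(name)
                    X[row, cidx - 1] = np.mean(values) if agg == "mean" else np.max(values)
                else:
                    X[row, cidx - 1] = 1.0
        X[row, len(concepts):] = encode_static(static)
    return X, columns


# ---------------------------------------------------------------------------
# Five-way comparison harness (sequence model + ablations + orderless models)
# ---------------------------------------------------------------------------

@dataclass
class CohortArrays:
    """Per-subset model inputs assembled once for the harness."""

    sequences: dict[str, list[TokenSequence]]
    statics: dict[str, np.ndarray]  # encoded 7-vectors, age z-scored on train
    labels: dict[str, np.ndarray]
    tabular: dict[str, np.ndarray]  # orderless flat features, z-scored on train
    vocabulary: ConceptVocabulary


def assemble_cohort(
    sequences_by_subset: dict[str, list[TokenSequence]],
    statics_by_subset: dict[str, list[StaticRecord]],
    vocabulary: ConceptVocabulary,
) -> CohortArrays:
    """Encode statics and tabular features with training-set normalization.

    Age (and every orderless tabular column) is z-scored using training-set
    mean/SD for optimization stability; dummy variables pass through the
    static 7-vector untouched apart from that single age column.
    """
    statics_enc = {
        k: np.stack([encode_static(s) for s in v]) for k, v in statics_by_subset.items()
    }
    age_mean = statics_enc["train"][:, 0].mean()
    age_sd = statics_enc["train"][:, 0].std() or 1.0
    for arr in statics_enc.values():
        arr[:, 0] = (arr[:, 0] - age_mean) / age_sd

    tabular = {
        k: aggregate_to_tabular(sequences_by_subset[k], statics_by_subset[k], vocabulary)[0]
        for k in sequences_by_subset
    }
    mu = tabular["train"].mean(axis=0)
    sd = tabular["train"].std(axis=0)
    sd[sd == 0] = 1.0
    tabular = {k: (v - mu) / sd for k, v in tabular.items()}

    labels = {
        k: np.array([s.outcome for s in v], dtype=np.int64) for k, v in statics_by_subset.items()
    }
    return CohortArrays(
        sequences=sequences_by_subset,
        statics=statics_enc,
        labels=labels,
        tabular=tabular,
        vocabulary=vocabulary,
    )


def run_comparison(
    cohort: CohortArrays,
    model_config=None,
    train_config=None,
    models: tuple[str, ...] = ("full", "without_ffnn", "without_vat", "ffnn_nl", "svm"),
    seed: int = 0,
) -> dict[str, dict]:
    """Train and test the full model, its two ablations, and the two
    orderless comparators on one cohort.  Returns, per model, the test AUC,
    the training log (where applicable) and threshold metrics."""
    from dataclasses import replace

    from .network import HvatConfig, HvatModel, predict_sequences
    from .training import TrainConfig, train

    model_config = model_config or HvatConfig()
    train_config = train_config or TrainConfig()
    results: dict[str, dict] = {}

    def eval_scores(score_fn) -> dict:
        scores = {k: (score_fn(k), cohort.labels[k]) for k in ("train", "validation", "test")}
        rep = report(scores)
        return {
            "test_auc": rep.subsets["test"].auc,
            "validation_auc": rep.subsets["validation"].auc,
            "report": rep.to_dict(),
        }

    for variant in ("full", "without_ffnn", "without_vat"):
        if variant not in models:
            continue
        cfg = replace(model_config, variant=variant)
        model = HvatModel(cfg, cohort.vocabulary.n_rows, seed=seed)
        tcfg = replace(train_config, seed=seed)
        model, log = train(
            model,
            cohort.sequences["train"], cohort.statics["train"], cohort.labels["train"],
            cohort.sequences["validation"], cohort.statics["validation"], cohort.labels["validation"],
            tcfg,
        )
        entry = eval_scores(
            lambda k: predict_sequences(model, cohort.sequences[k], cohort.statics[k], cohort.labels[k])
        )
        entry["epochs_trained"] = len(log.epochs)
        entry["best_epoch"] = log.best_epoch
        results[variant] = entry

    if "ffnn_nl" in models:
        results["ffnn_nl"] = _train_orderless_ffnn(cohort, model_config, train_config, seed, eval_scores)

    if "svm" in models:
        from sklearn.svm import LinearSVC

        svm = LinearSVC(C=1.0, dual="auto", max_iter=5000, random_state=seed)
        svm.fit(cohort.tabular["train"], cohort.labels["train"])
        results["svm"] = eval_scores(lambda k: svm.decision_function(cohort.tabular[k]))

    return results


def _train_orderless_ffnn(cohort, model_config, train_config, seed, eval_scores):
    """FFNN-NL: the static branch widened to take every (aggregated)
    predictor; the transformer branch is absent."""
    from dataclasses import replace

    from .network import HvatModel, predict_sequences
    from .training import train

    n_features = cohort.tabular["train"].shape[1]
    cfg = replace(model_config, variant="without_vat", static_dim=n_features)
    model = HvatModel(cfg, cohort.vocabulary.n_rows, seed=seed)
    tcfg = replace(train_config, seed=seed, batch_patients=64)
    model, log = train(
        model,
        cohort.sequences["train"], cohort.tabular["train"], cohort.labels["train"],
        cohort.sequences["validation"], cohort.tabular["validation"], cohort.labels["validation"],
        tcfg,
    )
    entry = eval_scores(
        lambda k: predict_sequences(model, cohort.sequences[k], cohort.tabular[k], cohort.labels[k])
    )
    entry["epochs_trained"] = len(log.epochs)
    entry["best_epoch"] = log.best_epoch
    return entry
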