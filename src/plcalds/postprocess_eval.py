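"""ROC-derived decision thresholds and frame-wise F-measure evaluation.

Continuous symptom tracks are binarised with per-(symptom, target) cut-offs
selected on training frames only: candidate thresholds are the midpoints
between consecutive distinct scores (plus sentinels just outside the score
range), each candidate is scored by TPR + (1 - FPR), and the final cut-off is
the mean of the top-5 candidates. Decisions (score > theta) are scored with
frame-wise precision/recall/F1 per symptom and per temporal-state target,
either per participant (personalised: mean of per-participant F1) or pooled
over the cohort (population).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocessing import STATE_NAMES
from .synthetic_cohort import ValidationError

logger = logging.getLogger(__name__)

#: evaluation targets: whole-symptom detection plus the three temporal states
TARGETS = ("overall",) + STATE_NAMES


def threshold_candidates(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, with sentinels outside the range."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])


def youden_like(scores: np.ndarray, labels: np.ndarray, theta: float) -> float:
    """TPR + (1 - FPR) of the decision rule ``score > theta``."""
    pred = scores > theta
    pos = labels == 1
    P, N = int(pos.sum()), int((~pos).sum())
    tpr = float((pred & pos).sum()) / P if P else 0.0
    fpr = float((pred & ~pos).sum()) / N if N else 0.0
    return tpr + (1.0 - fpr)


def select_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cut-off maximising TPR + (1 - FPR), averaged over the top-5 optima.

    Every candidate attaining the maximal criterion value is an "optimum
    threshold"; up to five of them — preferring the higher thresholds when
    more than five tie — are averaged into the final cut-off. If the labels
    contain a single class the threshold is +inf (never fire) with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        logger.warning("single-class labels: threshold set to +inf (never fires)")
        return np.inf
    cands = threshold_candidates(scores)
    crit = np.array([youden_like(scores, labels, th) for th in cands])
    optima = np.sort(cands[crit >= crit.max() - 1e-12])[::-1]
    return float(optima[:5].mean())


@dataclass
class ThresholdSet:
    """Per-(symptom, target) decision cut-offs fitted on training scores."""

    theta: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, symptom: str, target: str) -> float:
        return self.theta.get((symptom, target), np.inf)


def select_thresholds(train_scores: Mapping[tuple[str, str], np.ndarray],
                      train_labels: Mapping[tuple[str, str], np.ndarray]) -> ThresholdSet:
    """Fit one cut-off per (symptom, target) key present in the score map."""
    ts = ThresholdSet()
    for key, scores in train_scores.items():
        ts.theta[key] = select_threshold(scores, train_labels[key])
    return ts


def binarise_activations(tracked: np.ndarray, thresholds: ThresholdSet,
                         symptom_names: list[str],
                         state_scores: np.ndarray | None = None,
                         ) -> dict[tuple[str, str], np.ndarray]:
    """Binary decisions per (symptom, target): ``score > theta``.

    ``tracked`` is the S x T overall symptom track; ``state_scores`` is the
    optional A x S x T per-temporal-state track (P(t) P(s|t) P(a|s,t)).
    """
    decisions: dict[tuple[str, str], np.ndarray] = {}
    for i, name in enumerate(symptom_names):
        decisions[(name, "overall")] = (tracked[i] > thresholds.get(name, "overall")).astype(int)
        if state_scores is not None:
            for a, state in enumerate(STATE_NAMES):
                decisions[(name, state)] = (
                    state_scores[a, i] > thresholds.get(name, state)).astype(int)
    return decisions


def event_f_measure(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """Frame-wise (precision, recall, F1); each is 0 when its ratio is undefined."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValidationError("prediction and truth must share the frame axis")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


@dataclass
class EvalReport:
    """Long-format precision/recall/F1 per (participant, symptom, target)."""

    table: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Macro mean and standard deviation of F1 per target."""
        return self.table.groupby("target")["f1"].agg(["mean", "std", "count"])

    def f1(self, symptom: str, target: str = "overall") -> float:
        sel = self.table[(self.table.symptom == symptom) & (self.table.target == target)]
        return float(sel["f1"].mean())


def evaluate_cohort(decisions: Mapping[str, Mapping[tuple[str, str], np.ndarray]],
                    truths: Mapping[str, Mapping[tuple[str, str], np.ndarray]],
                    grouping: str = "personalised") -> EvalReport:
    """Score decisions against ground truth per symptom and target.

    ``decisions[participant][(symptom, target)]`` and the matching ``truths``
    must share frame axes. Personalised grouping reports per-participant rows
    (macro averages are means over participants); population grouping pools
    all participants' frames per (symptom, target) before computing one row.
    """
    if grouping not in ("personalised", "population"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    rows = []
    if grouping == "personalised":
        for pid, dec in decisions.items():
            for (symptom, target), pred in dec.items():
                truth = truths[pid][(symptom, target)]
                if truth.sum() == 0:
                    logger.info("symptom %s/%s absent from truth for %s; excluded",
                                symptom, target, pid)
                    continue
                p, r, f1 = event_f_measure(pred, truth)
                rows.append((pid, symptom, target, p, r, f1, int(truth.sum())))
    else:
        pooled: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]] = {}
        for pid, dec in decisions.items():
            for key, pred in dec.items():
                pooled.setdefault(key, []).append((pred, truths[pid][key]))
        for (symptom, target), pairs in pooled.items():
            pred = np.concatenate([p for p, _ in pairs])
            truth = np.concatenate([t for _, t in pairs])
            if truth.sum() == 0:
                logger.info("symptom %s/%s absent from pooled truth; excluded", symptom, target)
                continue
            p, r, f1 = event_f_measure(pred, truth)
            rows.append(("pooled", symptom, target, p, r, f1, int(truth.sum())))
    table = pd.DataFrame(rows, columns=["participant", "symptom", "target",
                                        "precision", "recall", "f1", "support"])
    return EvalReport(table=table)
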