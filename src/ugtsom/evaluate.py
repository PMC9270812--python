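"""Classification and ranking metrics plus report assembly.

Binary-classification metrics follow the standard confusion-table
definitions: ACC = (TP+TN)/n, SE = TP/(TP+FN), SP = TN/(TN+FP) and the
Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with the convention MCC = 0 whenever a factor of the denominator vanishes.
AUC is computed as the rank-based (Mann-Whitney) statistic, which is
equivalent to trapezoidal ROC integration and robust to ties (ties count
one half).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label/prediction length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))))


def confusion_metrics(c: ConfusionCounts) -> Dict[str, float]:
    """ACC, SE, SP and MCC from confusion counts.

    SE/SP are NaN when their class is absent; MCC uses the zero-denominator
    convention MCC = 0.
    """
    if c.n == 0:
        raise ValueError("all confusion counts are zero")
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    acc = (tp + tn) / c.n
    se = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    sp = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return {"ACC": acc, "SE": se, "SP": sp, "MCC": mcc}


def auc(scores, labels) -> float:
    """Mann-Whitney AUC; requires both classes present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks: ties contribute 1/2
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def classification_row(y_true, scores, threshold: float = 0.5) -> Dict[str, float]:
    """One report row in the ACC/SP/SE/AUC/MCC layout. The substrate label
    is assigned when the probability is >= threshold (boundary inclusive)."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    m = confusion_metrics(confusion_from_predictions(y_true, y_pred))
    try:
        a = auc(scores, y_true)
    except ValueError:
        a = float("nan")
    return {"ACC": m["ACC"], "SP": m["SP"], "SE": m["SE"],
            "AUC": a, "MCC": m["MCC"]}


def som_site_metrics(predictions, truths) -> Dict[str, float]:
    """Site-level AUC/MCC for ranked-site predictions.

    Every enumerated candidate site becomes one binary case (1 if it is an
    observed SOM) scored by its reactivity logit; predicted-positive means
    logit >= 0 (probability >= 0.5).
    """
    labels: List[int] = []
    scores: List[float] = []
    for pred in predictions:
        true_atoms = {a for a, _ in truths[pred.substrate_id]}
        for atom_idx, _cls, score in pred.ranked_sites:
            labels.append(1 if atom_idx in true_atoms else 0)
            scores.append(score)
    out: Dict[str, float] = {}
    try:
        out["AUC"] = auc(scores, labels)
    except ValueError:
        out["AUC"] = float("nan")
    y_pred = (np.asarray(scores) >= 0.0).astype(int)
    out["MCC"] = confusion_metrics(
        confusion_from_predictions(labels, y_pred))["MCC"]
    return out


CLASSIFICATION_COLUMNS = ("ACC", "SP", "SE", "AUC", "MCC")


def evaluation_report(classification: Optional[Sequence[dict]] = None,
                      som: Optional[Sequence[dict]] = None) -> Dict:
    """Assemble a structured report.

    ``classification`` entries: {"model", "y_true", "scores"}.
    ``som`` entries: {"model", "predictions", "truths"} where predictions
    are ranked-site objects and truths map substrate id to a set of
    (atom_index, som_class) pairs.

    A metric failure is recorded in the row's ``error`` field and never
    aborts the whole report.
    """
    from .som_wln import topk_accuracy  # local import to avoid a cycle

    report: Dict = {"classification": [], "som": []}
    for entry in classification or []:
        row = {"model": entry["model"]}
        try:
            row.update(classification_row(entry["y_true"], entry["scores"]))
        except Exception as exc:
            row["error"] = str(exc)
        report["classification"].append(row)
    for entry in som or []:
        row = {"model": entry["model"]}
        try:
            preds, truths = entry["predictions"], entry["truths"]
            for k in (1, 2, 3):
                row[f"Top-{k}"] = topk_accuracy(preds, truths, k)
            row.update(som_site_metrics(preds, truths))
        except Exception as exc:
            row["error"] = str(exc)
        report["som"].append(row)
    return report


def report_to_json(report: Dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def report_to_text(report: Dict) -> str:
    """Fixed-width human-readable rendering; deterministic."""
    lines: List[str] = []
    if report.get("classification"):
        lines.append("Model" + "".join(f"{c:>8}" for c in CLASSIFICATION_COLUMNS))
        for row in report["classification"]:
            cells = "".join(
                f"{row.get(c, float('nan')):>8.3f}" for c in CLASSIFICATION_COLUMNS)
            lines.append(f"{row['model']}{cells}"
                         + (f"  [{row['error']}]" if "error" in row else ""))
    if report.get("som"):
        cols = ("Top-1", "Top-2", "Top-3", "AUC", "MCC")
        lines.append("Model" + "".join(f"{c:>8}" for c in cols))
        for row in report["som"]:
            cells = "".join(
                f"{row.get(c, float('nan')):>8.3f}" for c in cols)
            lines.append(f"{row['model']}{cells}"
                         + (f"  [{row['error']}]" if "error" in row else ""))
    return "\n".join(lines)
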