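"""Multi-label and one-vs-all evaluation, correlation and attention summaries.

Two headline multi-label scores:

* ``acc_example`` — the example-based accuracy: the mean over samples of the
  Jaccard index |L ∩ L̂| / |L ∪ L̂| between true and predicted label sets
  (two empty sets count as a perfect 1, flagged in reports).
* ``f1_label`` — macro-F1: the unweighted mean over functions of the
  per-function binary F1.

Per-function one-vs-all metrics (AUC, MCC, F1, precision, recall) are
computed from the model's per-function probabilities at the 0.5 threshold,
plus Gorodkin's K-category correlation coefficient RkCC from a confusion
matrix (equal to MCC when K = 2). Shot-group stratified macro-F1, Pearson
correlation matrices over labels or learned representations, and received-
attention summaries round out the reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .encoding import FunctionVocabulary
from .network import AttentionRecord

DEFAULT_SHOT_THRESHOLDS = (1000, 200)   # many > 1000, few < 200


# -- core multi-label metrics -------------------------------------------

def _check_label_pair(Y, Yhat):
    Y = np.asarray(Y)
    Yhat = np.asarray(Yhat)
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Yhat.shape}")
    return Y.astype(bool), Yhat.astype(bool)


def acc_example(Y, Yhat) -> float:
    """Mean per-sample Jaccard index between true and predicted label sets."""
    Y, Yhat = _check_label_pair(Y, Yhat)
    inter = (Y & Yhat).sum(axis=1).astype(float)
    union = (Y | Yhat).sum(axis=1).astype(float)
    ratio = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return float(ratio.mean())


def _binary_f1(y, yhat) -> float:
    tp = int(np.sum(y & yhat))
    fp = int(np.sum(~y & yhat))
    fn = int(np.sum(y & ~yhat))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def f1_label(Y, Yhat) -> float:
    """Macro-F1: unweighted mean of per-function binary F1 (0 on empty)."""
    Y, Yhat = _check_label_pair(Y, Yhat)
    return float(np.mean([_binary_f1(Y[:, c], Yhat[:, c])
                          for c in range(Y.shape[1])]))


def binary_metrics(y, scores, threshold: float = 0.5) -> dict[str, float | None]:
    """One-vs-all binary metrics for a single function.

    AUC uses the rank (Mann-Whitney, half-credit ties) method and is
    ``None`` when only one class is present; the rest come from the
    thresholded confusion counts with zero-division conventions of 0.
    """
    y = np.asarray(y).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError("length mismatch between labels and scores")
    yhat = scores > threshold
    tp = int(np.sum(y & yhat))
    tn = int(np.sum(~y & ~yhat))
    fp = int(np.sum(~y & yhat))
    fn = int(np.sum(y & ~yhat))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    auc = float(roc_auc_score(y, scores)) if 0 < y.sum() < len(y) else None
    return {"auc": auc, "mcc": float(mcc), "f1": float(f1),
            "precision": float(precision), "recall": float(recall)}


def rkcc(confusion: np.ndarray) -> float:
    """Gorodkin's K-category correlation coefficient R_K from a K x K
    confusion matrix (true classes on rows). Equals MCC for K = 2; returns
    0 for degenerate matrices where either marginal is concentrated."""
    M = np.asarray(confusion, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (M < 0).any() or M.sum() <= 0:
        raise ValueError("confusion matrix needs non-negative counts, total > 0")
    s = M.sum()
    c = np.trace(M)
    t = M.sum(axis=1)   # true-class totals
    p = M.sum(axis=0)   # predicted-class totals
    cov = c * s - float(t @ p)
    d1 = s * s - float(p @ p)
    d2 = s * s - float(t @ t)
    if d1 <= 0 or d2 <= 0:
        return 0.0
    return float(cov / np.sqrt(d1 * d2))


# -- shot groups ---------------------------------------------------------

def assign_shot_groups(train_Y: np.ndarray, vocab: FunctionVocabulary,
                       thresholds: tuple[int, int] = DEFAULT_SHOT_THRESHOLDS
                       ) -> dict[str, str]:
    """Bin each function by its training-set positive count.

    ``thresholds = (many_min, few_max)``: many-shot above ``many_min``,
    few-shot below ``few_max``, medium-shot in between.
    """
    many_min, few_max = thresholds
    counts = np.asarray(train_Y).sum(axis=0)
    out = {}
    for name, n in zip(vocab, counts):
        out[name] = "many" if n > many_min else ("few" if n < few_max else "medium")
    return out


def group_report(Y, Yhat, vocab: FunctionVocabulary,
                 groups: dict[str, str]) -> dict[str, float | None]:
    """Macro-F1 within each shot group's function subset (None when empty)."""
    Y, Yhat = _check_label_pair(Y, Yhat)
    missing = [n for n in vocab if n not in groups]
    if missing:
        raise ValueError(f"functions without a shot group: {missing}")
    out: dict[str, float | None] = {}
    for g in ("many", "medium", "few"):
        cols = [i for i, n in enumerate(vocab) if groups[n] == g]
        out[g] = f1_label(Y[:, cols], Yhat[:, cols]) if cols else None
    return out


# -- correlation matrices ------------------------------------------------

@dataclass
class CorrelationMatrix:
    values: np.ndarray            # (C, C) symmetric
    kind: str                     # "label_cooccurrence" | "representation"
    undefined: np.ndarray | None = None   # bool flags where variance was 0


def _pearson_with_flags(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson matrix; zero-variance rows give 0 entries, flagged."""
    C = rows.shape[0]
    sd = rows.std(axis=1)
    ok = sd > 0
    out = np.zeros((C, C))
    if ok.any():
        sub = np.corrcoef(rows[ok])
        out[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(out, np.where(ok, 1.0, 0.0))
    flags = ~(ok[:, None] & ok[None, :])
    return np.clip(out, -1.0, 1.0), flags


def label_cooccurrence_pearson(Y: np.ndarray) -> CorrelationMatrix:
    """Pearson correlation between label columns of the binary matrix."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    values, flags = _pearson_with_flags(Y.T)
    return CorrelationMatrix(values=values, kind="label_cooccurrence",
                             undefined=flags)


def representation_pearson(Z_per_sample: list[np.ndarray] | np.ndarray
                           ) -> CorrelationMatrix:
    """Mean over samples of the pairwise Pearson correlation between the
    per-function representation rows z_i of each sample's Z matrix."""
    Zs = np.asarray(Z_per_sample, dtype=float)
    if Zs.ndim == 2:
        Zs = Zs[None]
    if len(Zs) < 1 or Zs.shape[-1] < 2:
        raise ValueError("need >= 1 sample and representation width >= 2")
    acc = np.zeros((Zs.shape[1], Zs.shape[1]))
    any_flag = np.zeros_like(acc, dtype=bool)
    for Z in Zs:
        v, f = _pearson_with_flags(Z)
        acc += v
        any_flag |= f
    return CorrelationMatrix(values=acc / len(Zs), kind="representation",
                             undefined=any_flag)


# -- attention summaries -------------------------------------------------

def attention_summaries(records: list[AttentionRecord]
                        ) -> dict[str, np.ndarray]:
    """Received-attention profiles from the last decoder layer.

    For each function: the mean attention mass directed *at* it, averaged
    over samples, heads and query functions (column means of the
    function-function matrices). For each residue position: the analogous
    column means of the function-residue matrices. The per-function vector
    sums to 1 because every attention row is a probability vector.
    """
    if not records:
        raise ValueError("no attention records given")
    ff = np.concatenate([r.function_function[-1] for r in records], axis=0)
    fr = np.concatenate([r.function_residue[-1] for r in records], axis=0)
    return {
        "function_received": ff.mean(axis=(0, 1, 2)),
        "residue_received": fr.mean(axis=(0, 1, 2)),
    }


# -- report assembly -----------------------------------------------------

@dataclass
class MetricsReport:
    acc_example: float
    f1_label: float
    per_function: dict[str, dict[str, float | None]]
    per_group: dict[str, float | None] = field(default_factory=dict)
    per_function_rkcc: dict[str, float] = field(default_factory=dict)
    empty_intersection_flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "acc_example": self.acc_example,
            "f1_label": self.f1_label,
            "per_function": self.per_function,
            "per_group": self.per_group,
            "per_function_rkcc": self.per_function_rkcc,
            "empty_intersection_flagged": self.empty_intersection_flagged,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tfunction\tvalue\n")
            fh.write(f"acc_example\t-\t{self.acc_example:.6f}\n")
            fh.write(f"f1_label\t-\t{self.f1_label:.6f}\n")
            for g, v in self.per_group.items():
                fh.write(f"f1_label_{g}\t-\t{'' if v is None else f'{v:.6f}'}\n")
            for fn, vals in self.per_function.items():
                for m, v in vals.items():
                    fh.write(f"{m}\t{fn}\t{'' if v is None else f'{v:.6f}'}\n")


def compute_report(Y: np.ndarray, probs: np.ndarray,
                   vocab: FunctionVocabulary, threshold: float = 0.5,
                   groups: dict[str, str] | None = None) -> MetricsReport:
    """Full evaluation from ground truth and per-function probabilities."""
    Y = np.asarray(Y)
    probs = np.asarray(probs, dtype=float)
    if Y.shape != probs.shape:
        raise ValueError("label and probability matrices disagree in shape")
    Yhat = probs > threshold
    per_function = {}
    per_rkcc = {}
    for c, name in enumerate(vocab):
        per_function[name] = binary_metrics(Y[:, c], probs[:, c], threshold)
        conf = np.array([
            [np.sum((Y[:, c] == 0) & ~Yhat[:, c]), np.sum((Y[:, c] == 0) & Yhat[:, c])],
            [np.sum((Y[:, c] == 1) & ~Yhat[:, c]), np.sum((Y[:, c] == 1) & Yhat[:, c])],
        ])
        per_rkcc[name] = rkcc(conf) if conf.sum() else 0.0
    both_empty = bool(np.any((Y.sum(axis=1) == 0) & (Yhat.sum(axis=1) == 0)))
    return MetricsReport(
        acc_example=acc_example(Y, Yhat),
        f1_label=f1_label(Y, Yhat),
        per_function=per_function,
        per_group=(group_report(Y, Yhat, vocab, groups) if groups else {}),
        per_function_rkcc=per_rkcc,
        empty_intersection_flagged=both_empty,
    )


def average_reports(reports: list[MetricsReport]) -> dict:
    """Arithmetic mean of the scalar fields across seeds (per-seed values
    are retained by the caller)."""
    def nanmean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    out = {
        "acc_example": nanmean([r.acc_example for r in reports]),
        "f1_label": nanmean([r.f1_label for r in reports]),
        "per_function": {},
        "per_group": {},
    }
    if reports and reports[0].per_group:
        for g in reports[0].per_group:
            out["per_group"][g] = nanmean([r.per_group.get(g) for r in reports])
    for name in reports[0].per_function:
        out["per_function"][name] = {
            m: nanmean([r.per_function[name][m] for r in reports])
            for m in reports[0].per_function[name]}
    return out
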