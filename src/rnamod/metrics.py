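"""Evaluation metrics and rank-based empirical significance.

AUC here is always the Mann-Whitney pairwise probability
``P(score_pos > score_neg) + 0.5 * P(tie)`` — i.e. the area under the ROC
curve computed over the finite set of observed thresholds with no
interpolation. Two variants are reported: AUC_b against same-base negatives
only (comparable to the binary-classifier literature) and AUC_m against a
widened pool containing all other labels and all unmodifiable nucleotides.
Classification thresholds are chosen by maximising the G-mean
``sqrt(Sn * Sp)`` over ROC operating points, and point metrics (Sn, Sp, Acc,
MCC) follow the standard confusion-matrix formulas.

The significance of a single predicted probability is an upper bound on its
p-value obtained from its rank among background scores of negative sites of
the same base: a site exceeded by only 1% of a large background gets a bound
of 0.01. The add-one correction keeps the bound valid (and nonzero) for
finite backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .labels import LABEL_NAMES, ORIGINAL_BASE

__all__ = [
    "auc_b",
    "auc_m",
    "gmean_threshold",
    "ConfusionCounts",
    "confusion_metrics",
    "BackgroundScoreTable",
    "empirical_pvalue_bound",
    "multilabel_report",
    "evaluation_report",
]


def _mann_whitney_auc(pos, neg) -> float:
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))  # midranks handle ties
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_b(pos_scores, neg_scores) -> float:
    """AUC against the modification's own-base negatives (binary scenario)."""
    return _mann_whitney_auc(pos_scores, neg_scores)


def auc_m(pos_scores, all_other_scores) -> float:
    """AUC against all other labels and all unmodifiable nucleotides."""
    return _mann_whitney_auc(pos_scores, all_other_scores)


def gmean_threshold(pos_scores, neg_scores) -> tuple[float, float]:
    """Threshold maximising sqrt(Sn * Sp) over ROC operating points.

    Ties are broken toward higher specificity (lower false-positive rate).
    Returns ``(threshold, gmean)``; a score is called positive when it is
    >= the threshold.
    """
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    gmean = np.sqrt(tpr * (1.0 - fpr))
    # lexicographic: best gmean first, then lowest fpr (highest Sp)
    best = np.lexsort((fpr, -gmean))[0]
    return float(thr[best]), float(gmean[best])


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_scores(cls, pos, neg, threshold: float) -> "ConfusionCounts":
        pos = np.asarray(pos)
        neg = np.asarray(neg)
        return cls(
            TP=int((pos >= threshold).sum()),
            FN=int((pos < threshold).sum()),
            TN=int((neg < threshold).sum()),
            FP=int((neg >= threshold).sum()),
        )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sn, Sp, Acc and MCC from confusion counts.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total, and
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    A zero MCC denominator yields MCC = 0 with ``mcc_undefined`` flagged.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    total = tp + tn + fp + fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / total if total else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    undefined = denom == 0
    mcc = 0.0 if undefined else (tp * tn - fp * fn) / np.sqrt(denom)
    return {
        "Sn": float(sn), "Sp": float(sp), "Acc": float(acc),
        "MCC": float(mcc), "mcc_undefined": bool(undefined),
    }


class BackgroundScoreTable:
    """Sorted negative-site score samples, one pool per (base, label).

    Built from held-out negative sites so that prediction-time significance
    is reproducible; persists alongside a checkpoint as TSV.
    """

    def __init__(self, pools: dict[str, np.ndarray]):
        self.pools = {
            label: np.sort(np.asarray(scores, dtype=np.float64))
            for label, scores in pools.items()
        }
        for label in self.pools:
            if label not in ORIGINAL_BASE:
                raise KeyError(f"unknown label {label!r} in background table")

    @classmethod
    def from_predictions(
        cls, probs: np.ndarray, y: np.ndarray, mask: np.ndarray
    ) -> "BackgroundScoreTable":
        """Pool the scores of supervised negatives, per label."""
        pools = {}
        unmodified = y.sum(axis=1) == 0
        for j, name in enumerate(LABEL_NAMES):
            sel = (mask[:, j] == 1) & unmodified
            if sel.any():
                pools[name] = probs[sel, j]
        return cls(pools)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tscores\n")
            for label, scores in sorted(self.pools.items()):
                fh.write(label + "\t" + ",".join(f"{s:.8g}" for s in scores) + "\n")

    @classmethod
    def load(cls, path) -> "BackgroundScoreTable":
        pools = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                label, scores = line.rstrip("\n").split("\t")
                pools[label] = np.fromstring(scores, sep=",")
        return cls(pools)


def empirical_pvalue_bound(
    score: float, background: BackgroundScoreTable, label: str
) -> float:
    """Upper bound on the p-value of a predicted probability.

    ``(#background scores > score + 1) / (N + 1)`` — the rank-based bound
    with an add-one correction so it is a valid bound (never zero) for a
    finite background. A score exceeded by exactly 1% of a large background
    receives a bound of 0.01.
    """
    pool = background.pools.get(label)
    if pool is None or pool.size == 0:
        raise KeyError(f"no background scores for label {label!r}")
    exceed = pool.size - np.searchsorted(pool, score, side="right")
    return float((exceed + 1) / (pool.size + 1))


def multilabel_report(
    probs: np.ndarray, y: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Optional multi-label-scheme summary (hamming loss, micro/macro F1,
    subset accuracy) at a common threshold."""
    from sklearn.metrics import accuracy_score, f1_score, hamming_loss

    pred = (np.asarray(probs) >= threshold).astype(int)
    y = np.asarray(y).astype(int)
    return {
        "hamming_loss": float(hamming_loss(y, pred)),
        "micro_f1": float(f1_score(y, pred, average="micro", zero_division=0)),
        "macro_f1": float(f1_score(y, pred, average="macro", zero_division=0)),
        "subset_accuracy": float(accuracy_score(y, pred)),
    }


def evaluation_report(
    probs: np.ndarray, y: np.ndarray, mask: np.ndarray
):
    """Per-label table of AUC_b, AUC_m, G-mean threshold, Sn/Sp/Acc/MCC.

    ``probs``/``y``/``mask`` are aligned (N, 12) arrays over a balanced test
    set. AUC_b compares each label's positives with its supervised (same
    base) negatives; AUC_m widens the negative pool to every other sample,
    including positives of other labels and windows of other bases. Mean and
    median rows summarise the per-label columns.
    """
    import pandas as pd

    rows = []
    unmodified = y.sum(axis=1) == 0
    for j, name in enumerate(LABEL_NAMES):
        pos = probs[(y[:, j] == 1), j]
        # binary scenario: the label's own unmodified-base negatives
        neg_b = probs[(mask[:, j] == 1) & unmodified, j]
        # multi-label scenario: all other labels and all unmodifiable bases
        neg_m = probs[(y[:, j] == 0), j]
        if pos.size == 0 or neg_b.size == 0:
            continue
        thr, gm = gmean_threshold(pos, neg_b)
        cm = confusion_metrics(ConfusionCounts.from_scores(pos, neg_b, thr))
        rows.append({
            "label": name, "Sn": cm["Sn"], "Sp": cm["Sp"], "Acc": cm["Acc"],
            "MCC": cm["MCC"], "AUC_b": auc_b(pos, neg_b),
            "AUC_m": auc_m(pos, neg_m), "threshold": thr, "gmean": gm,
            "n_pos": int(pos.size), "n_neg": int(neg_b.size),
        })
    df = pd.DataFrame(rows)
    if len(df):
        numeric = df.drop(columns=["label"])
        df = pd.concat([
            df,
            pd.DataFrame([
                {"label": "Mean", **numeric.mean().to_dict()},
                {"label": "Median", **numeric.median().to_dict()},
            ]),
        ], ignore_index=True)
    return df
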