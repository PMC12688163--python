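"""Classifier evaluation: ROC/PR areas, confusion metrics, association tests.

ROC AUC equals the Mann-Whitney statistic P(score+ > score-) + 0.5 P(tie).
PR AUC uses step-wise integration over the achievable operating points
(sum over thresholds of (recall_k - recall_{k-1}) * precision_k), whose
baseline for uninformative scores is the prevalence P/(P+N).

Fisher association tests use the two-sided exact (hypergeometric) p-value;
the reported odds ratio is the cross-product (a*d)/(b*c), with 0.5 added to
every cell when any cell is zero (Haldane correction) — a closed-form
convention that differs from conditional-MLE odds ratios reported by some
statistical packages.  Multiplicity is handled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError

log = logging.getLogger(__name__)

POSITIVE, NEGATIVE, UNKNOWN = "positive", "negative", "unknown"


def _binary_truth(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OU":
        return y == POSITIVE
    return y.astype(bool)


def roc_auc(probabilities, labels) -> float:
    """Area under the ROC curve (Mann-Whitney convention for ties)."""
    y = _binary_truth(labels)
    if y.all() or (~y).all():
        raise ValidationError("both classes required for ROC AUC")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def pr_auc(probabilities, labels) -> float:
    """Area under the precision-recall curve, step-wise integration."""
    y = _binary_truth(labels)
    if y.all() or (~y).all():
        raise ValidationError("both classes required for PR AUC")
    return float(average_precision_score(y, np.asarray(probabilities, dtype=float)))


@dataclasses.dataclass
class EvaluationReport:
    tp: int
    fn: int
    fp: int
    tn: int
    unknown_called_positive: int = 0
    unknown_called_negative: int = 0
    auc: float | None = None
    aucpr: float | None = None

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def mcc(self) -> float:
        tp, fn, fp, tn = (float(v) for v in (self.tp, self.fn, self.fp, self.tn))
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        if denom == 0:
            return float("nan")
        return (tp * tn - fp * fn) / denom

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FN": self.fn, "FP": self.fp, "TN": self.tn,
            "unknown_called_positive": self.unknown_called_positive,
            "unknown_called_negative": self.unknown_called_negative,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "mcc": self.mcc,
            "auc": self.auc, "aucpr": self.aucpr,
        }


def confusion_metrics(calls, labels, probabilities=None) -> EvaluationReport:
    """Confusion counts + derived metrics for labelled samples.

    ``calls`` and ``labels`` are aligned sequences of 'positive'/'negative'
    (labels may include 'unknown', tallied separately).
    """
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    if calls.shape != labels.shape:
        raise ValidationError("calls and labels are misaligned")
    known = labels != UNKNOWN
    pos_call = calls == POSITIVE
    pos_lab = labels == POSITIVE
    rep = EvaluationReport(
        tp=int((pos_call & pos_lab & known).sum()),
        fn=int((~pos_call & pos_lab & known).sum()),
        fp=int((pos_call & ~pos_lab & known).sum()),
        tn=int((~pos_call & ~pos_lab & known).sum()),
        unknown_called_positive=int((pos_call & ~known).sum()),
        unknown_called_negative=int((~pos_call & ~known).sum()),
    )
    if probabilities is not None:
        p = np.asarray(probabilities, dtype=float)
        rep.auc = roc_auc(p[known], labels[known])
        rep.aucpr = pr_auc(p[known], labels[known])
    return rep


def fisher_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Haldane-corrected cross-product odds ratio."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (v + 0.5 for v in (a, b, c, d))
    return (a * d) / (b * c)


def fisher_association(events: pd.DataFrame, calls: pd.Series) -> pd.DataFrame:
    """Per-event Fisher exact association with predicted HRD status.

    ``events``: samples x binary events (0/1).  ``calls``: 'positive' /
    'negative' per sample.  Returns odds_ratio, p, BH-adjusted q per event.
    """
    calls = calls.reindex(events.index)
    pos = (calls == POSITIVE).to_numpy()
    rows = {}
    for event in events.columns:
        e = events[event]
        if not e.isin([0, 1, True, False]).all():
            raise ValidationError(f"event {event!r} is not binary")
        e = e.astype(bool).to_numpy()
        a = int((e & pos).sum())       # event present, HRD+
        b = int((e & ~pos).sum())
        c = int((~e & pos).sum())
        d = int((~e & ~pos).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows[event] = {"odds_ratio": fisher_odds_ratio(a, b, c, d),
                       "p": float(p), "a": a, "b": b, "c": c, "d": d}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def cn_state_events(gene_cn: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Loss-vs-neutral and gain-vs-neutral binary contrasts from CN states.

    ``gene_cn``: samples x genes coded −1 (loss, CN<2), 0 (neutral, CN=2),
    1 (gain, CN>2).  Non-contrast samples are dropped per gene by NA masking.
    """
    if not gene_cn.isin([-1, 0, 1]).all().all():
        raise ValidationError("CN states must be coded -1/0/1")
    loss = gene_cn.where(gene_cn <= 0).replace({-1: 1})   # loss=1, neutral=0
    gain = gene_cn.where(gene_cn >= 0)                    # gain=1, neutral=0
    return {"loss_vs_neutral": loss, "gain_vs_neutral": gain}


def variant_type_summary(mutations: pd.DataFrame,
                         probabilities: pd.Series) -> pd.DataFrame:
    """Per-gene, per-variant-class summary of predicted HRD probabilities.

    ``mutations`` needs columns sample_id, gene, variant_class.  Samples
    without a probability are skipped; empty groups are omitted.
    """
    merged = mutations.merge(probabilities.rename("p_hrd"),
                             left_on="sample_id", right_index=True, how="inner")
    if merged.empty:
        log.info("variant_type_summary: no mutation has a probability; "
                 "empty summary")
        return pd.DataFrame(columns=["gene", "variant_class", "n", "median",
                                     "q1", "q3"])
    rows = []
    for (gene, vclass), sub in merged.groupby(["gene", "variant_class"]):
        p = sub["p_hrd"].to_numpy()
        rows.append({"gene": gene, "variant_class": vclass, "n": len(p),
                     "median": float(np.median(p)),
                     "q1": float(np.quantile(p, 0.25)),
                     "q3": float(np.quantile(p, 0.75))})
    return pd.DataFrame(rows)
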