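"""Thematic-map accuracy assessment and classifier screening.

Conventions, fixed once and documented because the literature is loose
about them:

* Confusion matrices are oriented rows = predicted, columns = reference.
* The accuracy unit is the validation *pixel*.
* Producer's accuracy of class j is ``counts[j][j] / colsum_j`` — the
  fraction of reference pixels of j recovered (1 − omission error).
  User's accuracy of class i is ``counts[i][i] / rowsum_i`` — the fraction
  of pixels mapped as i that truly are i (1 − commission error).
* Undefined quantities (zero marginal, chance agreement of 1) are reported
  as NaN, never silently as 0.

McNemar's test compares two classifiers on the same validation pixels via
the discordant counts b (A correct, B wrong) and c (A wrong, B correct):
``chi2 = (|b-c| - 1)^2 / (b+c)`` with continuity correction (the default),
or without the ``-1``; p-values come from the chi-squared distribution with
one degree of freedom. Screening for ensemble membership excludes an
algorithm iff some other algorithm is significantly different from it *and*
has higher overall accuracy — so the top-accuracy algorithm can never be
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2

from .raster import HabitatMap
from .sampling import LabeledSamples


@dataclass
class ConfusionMatrix:
    """K x K predicted-vs-reference pixel counts."""

    counts: np.ndarray
    class_ids: list[int]
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_ids)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K legend classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        names = [self.legend.get(c, str(c)) for c in self.class_ids]
        return pd.DataFrame(self.counts, index=names, columns=names)


@dataclass
class AccuracyReport:
    overall_accuracy: float
    kappa: float
    producers_accuracy: dict[int, float]  # NaN where undefined
    users_accuracy: dict[int, float]


@dataclass
class McNemarResult:
    b: int
    c: int
    statistic: float
    p_value: float
    continuity: bool


def confusion_matrix(pred: HabitatMap | np.ndarray,
                     samples: LabeledSamples) -> ConfusionMatrix:
    """Confusion matrix of a predicted map over the validation samples.

    ``pred`` may be a HabitatMap (indexed at the samples' pixel coordinates)
    or a 1-D label array aligned with the validation samples.
    """
    val = samples.subset("validation")
    if len(val) == 0:
        raise ValueError("validation set is empty")
    if isinstance(pred, HabitatMap):
        y_pred = pred.labels[val.rows, val.cols]
        legend = dict(pred.legend)
    else:
        y_pred = np.asarray(pred)
        if len(y_pred) != len(val):
            raise ValueError("prediction length does not match validation set")
        legend = dict(val.legend)
    class_ids = sorted(set(legend) | set(int(v) for v in np.unique(val.y)))
    for v in np.unique(val.y):
        if int(v) not in legend:
            legend[int(v)] = str(int(v))
    bad = [int(v) for v in np.unique(y_pred) if int(v) not in class_ids]
    if bad:
        raise ValueError(f"predicted labels {bad} outside the legend")
    return confusion_from_labels(y_pred, val.y, class_ids, legend)


def confusion_from_labels(y_pred: Sequence[int], y_ref: Sequence[int],
                          class_ids: Sequence[int],
                          legend: Mapping[int, str] | None = None,
                          ) -> ConfusionMatrix:
    """Tally a confusion matrix from aligned label vectors."""
    y_pred = np.asarray(y_pred)
    y_ref = np.asarray(y_ref)
    if y_pred.shape != y_ref.shape:
        raise ValueError("label vectors must have equal length")
    class_ids = [int(c) for c in class_ids]
    for v in np.unique(y_ref):
        if int(v) not in class_ids:
            raise ValueError(f"reference label {int(v)} outside the legend")
    index = {c: i for i, c in enumerate(class_ids)}
    k = len(class_ids)
    counts = np.zeros((k, k), dtype=np.int64)
    pi = np.vectorize(index.__getitem__)(y_pred)
    ri = np.vectorize(index.__getitem__)(y_ref)
    np.add.at(counts, (pi, ri), 1)
    legend = dict(legend) if legend else {c: str(c) for c in class_ids}
    return ConfusionMatrix(counts, class_ids, legend)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of validation pixels on the diagonal (trace / total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement (NaN if p_e = 1)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    p_e = float(rows @ cols) / (n * n)
    if p_e == 1.0:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def class_accuracies(cm: ConfusionMatrix) -> tuple[dict[int, float], dict[int, float]]:
    """(producer's, user's) accuracy per class; NaN on zero marginals."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    diag = np.diag(cm.counts)
    producers = {}
    users = {}
    for i, cid in enumerate(cm.class_ids):
        producers[cid] = float(diag[i] / cols[i]) if cols[i] > 0 else float("nan")
        users[cid] = float(diag[i] / rows[i]) if rows[i] > 0 else float("nan")
    return producers, users


def accuracy_report(cm: ConfusionMatrix) -> AccuracyReport:
    pra, ura = class_accuracies(cm)
    return AccuracyReport(overall_accuracy(cm), kappa(cm), pra, ura)


def mcnemar(pred_a: Sequence[int], pred_b: Sequence[int],
            reference: Sequence[int], continuity: bool = True) -> McNemarResult:
    """McNemar's test on two classifiers' correctness over one reference.

    Depends only on the per-pixel correctness indicators, so it is
    invariant under any relabelling of the classes. ``b + c = 0`` yields
    statistic 0 and p = 1.
    """
    a = np.asarray(pred_a)
    bv = np.asarray(pred_b)
    ref = np.asarray(reference)
    if not (len(a) == len(bv) == len(ref)) or len(ref) == 0:
        raise ValueError("prediction/reference vectors must share a length >= 1")
    ok_a = a == ref
    ok_b = bv == ref
    b = int(np.count_nonzero(ok_a & ~ok_b))
    c = int(np.count_nonzero(~ok_a & ok_b))
    if b + c == 0:
        return McNemarResult(b, c, 0.0, 1.0, continuity)
    diff = abs(b - c) - (1 if continuity else 0)
    stat = diff * diff / (b + c)
    p = float(_chi2.sf(stat, df=1))
    return McNemarResult(b, c, float(stat), p, continuity)


def pairwise_mcnemar(predictions: Mapping[str, Sequence[int]],
                     reference: Sequence[int],
                     continuity: bool = True) -> pd.DataFrame:
    """Symmetric matrix of pairwise McNemar p-values (unit diagonal)."""
    ids = list(predictions)
    p = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for bname in ids[i + 1:]:
            res = mcnemar(predictions[a], predictions[bname], reference,
                          continuity)
            p.loc[a, bname] = p.loc[bname, a] = res.p_value
    return p


def screen_classifiers(reports: Mapping[str, "AccuracyReport | float"],
                       pvals: pd.DataFrame, alpha: float = 0.05,
                       adjust: str | None = None) -> list[str]:
    """Retain algorithms for the ensemble; drop significantly worse ones.

    Algorithm i is excluded iff some j has ``p[i, j] < alpha`` and higher
    overall accuracy than i. ``adjust`` optionally applies a Bonferroni or
    Holm correction to the off-diagonal p-values first (off by default).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    ids = list(reports)
    pm = pvals.loc[ids, ids].to_numpy(dtype=float)
    if not np.allclose(pm, pm.T):
        raise ValueError("p-value matrix must be symmetric")
    if not np.allclose(np.diag(pm), 1.0):
        raise ValueError("p-value matrix must have a unit diagonal")
    if adjust is not None:
        pm = _adjust_pvalues(pm, adjust)
    oa = {k: (r.overall_accuracy if isinstance(r, AccuracyReport) else float(r))
          for k, r in reports.items()}
    retained = []
    for i, a in enumerate(ids):
        worse = any(pm[i, j] < alpha and oa[a] < oa[bid]
                    for j, bid in enumerate(ids) if j != i)
        if not worse:
            retained.append(a)
    return retained


def _adjust_pvalues(pm: np.ndarray, method: str) -> np.ndarray:
    iu = np.triu_indices_from(pm, k=1)
    p = pm[iu]
    m = len(p)
    if method == "bonferroni":
        adj = np.minimum(p * m, 1.0)
    elif method == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min((m - rank) * p[idx], 1.0))
            adj[idx] = running
    else:
        raise ValueError(f"unknown adjustment {method!r}")
    out = pm.copy()
    out[iu] = adj
    out.T[iu] = adj
    return out
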