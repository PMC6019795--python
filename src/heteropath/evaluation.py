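"""ROC/AUC evaluation protocol.

Ground truth is consensus-derived from the two comparator methods: a
(set, tissue) test is a positive when its q-value clears a strict cut in
both comparators, a negative when both q-values are large, and excluded
otherwise.  The heterogeneity score is then evaluated as a classifier of
that ground truth via ROC curves and trapezoidal AUC (equivalently the
Mann-Whitney statistic with half-credit for ties), at several fold-change
thresholds, with a label-permutation test for AUC significance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .core import heterogeneity_scores, tissue_t_statistics
from .io import ExpressionMatrix, GeneSetCollection, TissueDesign

__all__ = [
    "GroundTruth",
    "RocResult",
    "consensus_ground_truth",
    "roc_auc",
    "auc_permutation_test",
    "evaluate_protocol",
]


@dataclass
class GroundTruth:
    positives: list
    negatives: list
    ambiguous: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives overlap")


@dataclass
class RocResult:
    fc_threshold: float | None
    points: np.ndarray  # (k, 2) of (FPR, TPR)
    auc: float
    auc_p: float | None = None


def consensus_ground_truth(
    gsea_q: pd.Series,
    pgsea_q: pd.Series,
    pos_cut: float = 0.01,
    neg_cut: float = 0.2,
    rule: str = "both",
) -> GroundTruth:
    """Positive / negative / ambiguous labels from two comparator q-tables.

    Under the default ``rule="both"`` a test is positive iff q < pos_cut in
    both methods and negative iff q > neg_cut in both; ``rule="any"``
    requires only one method.  Everything else is ambiguous and excluded
    from ROC analysis.  Both tables must cover the same tests.
    """
    if set(gsea_q.index) != set(pgsea_q.index):
        raise ValueError("the two q-value tables must cover the same tests")
    pgsea_q = pgsea_q.reindex(gsea_q.index)
    if rule == "both":
        pos = (gsea_q < pos_cut) & (pgsea_q < pos_cut)
        neg = (gsea_q > neg_cut) & (pgsea_q > neg_cut)
    elif rule == "any":
        pos = (gsea_q < pos_cut) | (pgsea_q < pos_cut)
        neg = ((gsea_q > neg_cut) | (pgsea_q > neg_cut)) & ~pos
    else:
        raise ValueError("rule must be 'both' or 'any'")
    idx = gsea_q.index
    return GroundTruth(
        positives=list(idx[pos]),
        negatives=list(idx[neg]),
        ambiguous=list(idx[~pos & ~neg]),
    )


def _mann_whitney_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney statistic (ties get half credit);
    identical to the trapezoidal integral of the ROC curve."""
    both = np.concatenate([pos_scores, neg_scores])
    ranks = rankdata(both)
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: pd.Series, truth: GroundTruth, fc_threshold: float | None = None) -> RocResult:
    """ROC curve and AUC of ``scores`` (higher = more positive) against the
    consensus ground truth; ambiguous tests are dropped."""
    if not truth.positives or not truth.negatives:
        raise ValueError("ROC undefined: need at least one positive and one negative")
    keys = list(truth.positives) + list(truth.negatives)
    missing = [k for k in keys if k not in scores.index]
    if missing:
        raise ValueError(f"scores missing for labelled tests: {missing[:5]}")
    y = np.concatenate(
        [np.ones(len(truth.positives), dtype=int), np.zeros(len(truth.negatives), dtype=int)]
    )
    s = scores.loc[keys].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        warnings.warn("all scores identical; AUC = 0.5 by convention", stacklevel=2)
    fpr, tpr, _ = roc_curve(y, s)
    auc = _mann_whitney_auc(s[y == 1], s[y == 0])
    return RocResult(fc_threshold=fc_threshold, points=np.column_stack([fpr, tpr]), auc=auc)


def auc_permutation_test(
    scores: pd.Series,
    truth: GroundTruth,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive_cap: int = 10_000,
) -> float:
    """p-value for the observed AUC by permuting the positive/negative
    labels over the scored tests.

    p is the fraction of permuted AUCs >= the observed AUC, floored at
    1/n_perm; designs with at most ``exhaustive_cap`` distinct label
    arrangements are enumerated exactly.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse p-value", stacklevel=2)
    keys = list(truth.positives) + list(truth.negatives)
    s = scores.loc[keys].to_numpy(dtype=float)
    n_pos = len(truth.positives)
    n = len(keys)
    auc_obs = _mann_whitney_auc(s[:n_pos], s[n_pos:])

    n_arr = math.comb(n, n_pos)
    if n_arr <= exhaustive_cap:
        count = 0
        for chosen in combinations(range(n), n_pos):
            mask = np.zeros(n, dtype=bool)
            mask[list(chosen)] = True
            if _mann_whitney_auc(s[mask], s[~mask]) >= auc_obs - 1e-12:
                count += 1
        return count / n_arr
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_pos, replace=False)] = True
        if _mann_whitney_auc(s[mask], s[~mask]) >= auc_obs - 1e-12:
            count += 1
    return max(count, 1) / n_perm


def evaluate_protocol(
    expr: ExpressionMatrix,
    design: TissueDesign | None,
    sets: GeneSetCollection,
    gsea_q: pd.Series,
    pgsea_q: pd.Series,
    fc_thresholds: tuple[float, ...] = (1.5, 2.0, 3.0),
    n_perm: int = 1000,
    seed: int = 0,
    rule: str = "both",
) -> list[RocResult]:
    """Full protocol: consensus truth, then one ROC per fold-change threshold
    with the heterogeneity score as the classifier, pooled over tissues.

    ``gsea_q``/``pgsea_q`` are indexed by (set, tissue) tuples.
    """
    design = design or expr.design()
    truth = consensus_ground_truth(gsea_q, pgsea_q, rule=rule)
    results = []
    for fc in fc_thresholds:
        stats = tissue_t_statistics(expr, design, fc_threshold=fc)
        hs, _ = heterogeneity_scores(stats, sets)
        scores = hs.stack()
        scores.index = [(s, t) for s, t in scores.index]
        res = roc_auc(scores, truth, fc_threshold=fc)
        res.auc_p = auc_permutation_test(scores, truth, n_perm=n_perm, seed=seed)
        results.append(res)
    return results
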