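"""Comparator enrichment scores: a parametric average-fold-change test
("pgsea-like") and a weighted Kolmogorov-Smirnov running-sum enrichment
score ("gsea-like").

These are self-contained minimal re-derivations of the two classical
approaches, sufficient to contrast with the heterogeneity score: both are
mean/rank based and therefore blind to a set whose members shift up and
down in equal measure.  They are labelled "pgsea-like"/"gsea-like" in
output; exact parity with the published R packages is a non-goal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import _group_columns, _membership_matrix
from .io import ExpressionMatrix, GeneSetCollection, TissueDesign

__all__ = [
    "ComparatorResult",
    "pgsea_scores",
    "gsea_enrichment",
    "enrichment_score",
]

_SD_EPS = 1e-12
_P_FLOOR = 1e-15


@dataclass
class ComparatorResult:
    """Scores from one comparator method.

    ``sample_scores`` is sets x samples (NaN where undefined); ``scores``
    and ``p`` are sets x tissues.
    """

    method: str
    sample_scores: pd.DataFrame
    scores: pd.DataFrame
    p: pd.DataFrame


# ---------------------------------------------------------------------------
# pgsea-like: one-sample t of a set's fold changes vs zero
# ---------------------------------------------------------------------------


def pgsea_scores(
    expr: ExpressionMatrix,
    design: TissueDesign | None = None,
    sets: GeneSetCollection | None = None,
) -> ComparatorResult:
    """Average-fold-change test per sample, aggregated per tissue.

    Per sample, each gene's fold change is its value minus the gene's median
    over all samples (log2 space).  A set's score in a sample is the
    one-sample t-statistic of its members' fold changes against zero; the
    per-tissue score is the mean over the tissue's samples and its p-value
    is two-sided from the t distribution with (n_set - 1) df.  Sets with
    fewer than two measured genes are emitted as NaN with a warning.
    """
    if sets is None:
        raise ValueError("a gene set collection is required")
    design = design or expr.design()
    values = expr.data[design.sample_ids].to_numpy(dtype=float)
    fc = values - np.median(values, axis=1, keepdims=True)
    member = _membership_matrix(sets, expr.gene_ids)
    n_samples = values.shape[1]

    sample_scores = np.full((len(sets), n_samples), np.nan)
    dfree = np.full(len(sets), np.nan)
    for si in range(len(sets)):
        idx = np.flatnonzero(member[si])
        if len(idx) < 2:
            warnings.warn(
                f"set {sets.names[si]!r} has < 2 measured genes; score undefined",
                stacklevel=2,
            )
            continue
        sub = fc[idx]  # (n_set, n_samples)
        n = len(idx)
        mean = sub.mean(axis=0)
        sd = np.maximum(sub.std(axis=0, ddof=1), _SD_EPS)
        sample_scores[si] = mean / (sd / np.sqrt(n))
        dfree[si] = n - 1

    groups = _group_columns(design, design.sample_ids)
    tissue_scores = np.column_stack([sample_scores[:, g].mean(axis=1) for g in groups])
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.t.sf(np.abs(tissue_scores), dfree[:, None])
    p = np.clip(p, _P_FLOOR, 1.0)
    p[np.isnan(tissue_scores)] = np.nan

    idx = pd.Index(sets.names, name="set")
    return ComparatorResult(
        method="pgsea-like",
        sample_scores=pd.DataFrame(sample_scores, index=idx, columns=design.sample_ids),
        scores=pd.DataFrame(tissue_scores, index=idx, columns=list(design.tissues)),
        p=pd.DataFrame(p, index=idx, columns=list(design.tissues)),
    )


# ---------------------------------------------------------------------------
# gsea-like: weighted KS running sum on a ranked gene list
# ---------------------------------------------------------------------------


def enrichment_score(metric: np.ndarray, in_set: np.ndarray, weight: float = 1.0) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    Genes are sorted by ``metric`` descending.  Hits increment the running
    sum by |metric|^weight normalised over the set; misses decrement by
    1/(N - n_set).  When the set covers the whole universe the miss step is
    zero.  If every member's metric is zero, hits fall back to equal weight.
    """
    metric = np.asarray(metric, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    n = metric.size
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit > n:
        raise ValueError("set must be a non-empty subset of the gene universe")
    order = np.argsort(-metric, kind="stable")
    hit = in_set[order]
    w = np.abs(metric[order]) ** weight
    w[~hit] = 0.0
    total = w.sum()
    if total < _SD_EPS:
        w = hit / n_hit
    else:
        w = w / total
    miss_step = 0.0 if n == n_hit else 1.0 / (n - n_hit)
    steps = np.where(hit, w, -miss_step)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def _es_for_groups(
    values: np.ndarray, groups: list[np.ndarray], member: np.ndarray, weight: float
) -> np.ndarray:
    """ES per (set, tissue) for an assignment of columns to tissues, using
    the two-sample pooled-variance t against the remaining samples as the
    ranking metric."""
    n_sets = member.shape[0]
    n_total = values.shape[1]
    es = np.zeros((n_sets, len(groups)))
    for j, cols in enumerate(groups):
        rest = np.setdiff1d(np.arange(n_total), cols)
        a, b = values[:, cols], values[:, rest]
        n1, n0 = a.shape[1], b.shape[1]
        var_a = a.var(axis=1, ddof=1)
        var_b = b.var(axis=1, ddof=1)
        sp = np.sqrt(((n1 - 1) * var_a + (n0 - 1) * var_b) / (n1 + n0 - 2))
        metric = (a.mean(axis=1) - b.mean(axis=1)) / (
            np.maximum(sp, _SD_EPS) * np.sqrt(1.0 / n1 + 1.0 / n0)
        )
        for si in range(n_sets):
            es[si, j] = enrichment_score(metric, member[si], weight)
    return es


def gsea_enrichment(
    expr: ExpressionMatrix,
    design: TissueDesign | None = None,
    sets: GeneSetCollection | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> ComparatorResult:
    """Weighted-KS enrichment per tissue with phenotype-permutation p-values.

    The ranking metric for tissue T is the per-gene two-sample t-statistic
    of T's replicates against all other samples (pooled variance).
    Significance: sample labels are permuted, the metric and ES recomputed,
    and p = (1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm).
    """
    if sets is None:
        raise ValueError("a gene set collection is required")
    design = design or expr.design()
    values = expr.data[design.sample_ids].to_numpy(dtype=float)
    member = _membership_matrix(sets, expr.gene_ids)
    if member.sum(axis=1).min() == 0:
        bad = [sets.names[i] for i in np.flatnonzero(~member.any(axis=1))]
        raise ValueError(f"sets with no measured genes cannot be ranked: {bad}")
    groups = _group_columns(design, design.sample_ids)
    sizes = [len(g) for g in groups]

    es_obs = _es_for_groups(values, groups, member, weight)
    obs_comp = [frozenset(g.tolist()) for g in groups]
    exceed = np.zeros_like(es_obs)
    denom = np.zeros(len(groups))
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        order = rng.permutation(values.shape[1])
        assignment, start = [], 0
        for k in sizes:
            assignment.append(order[start : start + k])
            start += k
        es_perm = _es_for_groups(values, assignment, member, weight)
        for j in range(len(sizes)):
            # draws re-assigning the observed sample multiset to tissue j
            # reproduce ES exactly and are not distinct relabelings of that
            # test (same convention as the heterogeneity-score permutation)
            if frozenset(assignment[j].tolist()) == obs_comp[j]:
                continue
            exceed[:, j] += np.abs(es_perm[:, j]) >= np.abs(es_obs[:, j])
            denom[j] += 1
    p = (1.0 + exceed) / (1.0 + denom[None, :])

    # per-sample ES (single-sample fold-change ranking) for score matrices
    fc = values - np.median(values, axis=1, keepdims=True)
    sample_es = np.zeros((len(sets), values.shape[1]))
    for j in range(values.shape[1]):
        for si in range(len(sets)):
            sample_es[si, j] = enrichment_score(fc[:, j], member[si], weight)

    idx = pd.Index(sets.names, name="set")
    return ComparatorResult(
        method="gsea-like",
        sample_scores=pd.DataFrame(sample_es, index=idx, columns=design.sample_ids),
        scores=pd.DataFrame(es_obs, index=idx, columns=list(design.tissues)),
        p=pd.DataFrame(p, index=idx, columns=list(design.tissues)),
    )
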