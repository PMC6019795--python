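"""The heterogeneity-score algorithm.

Each tissue is compared against a "virtual median cell": the per-gene median
across all samples of all tissues.  For gene *i* and tissue *T*,

    t_i = (M1(i) - M2(i)) / s(i)

where M1 is the gene's median over T's replicates, M2 its median over all
samples, and s the pooled standard deviation of the two groups (the tissue's
replicates vs all samples).  Genes whose |M1 - M2| falls below log2 of the
fold-change threshold are filtered out, and the heterogeneity score of a
gene set S in tissue T is

    HS(S, T) = sum over filter-passing members of |t_i|.

Because the score sums magnitudes, a set whose members split into an
upregulated and a downregulated half scores highly even though its mean
shift is zero — the signature invisible to mean-based enrichment statistics.
Inference is by phenotype-label permutation (exhaustive when the number of
distinct label arrangements is small, Monte Carlo otherwise) with
Benjamini-Hochberg FDR control across all (set, tissue) tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection, TissueDesign

__all__ = [
    "GeneTissueStats",
    "PathwayResult",
    "HeteroPathParams",
    "tissue_t_statistics",
    "heterogeneity_scores",
    "permutation_pvalues",
    "fdr_adjust",
    "tissue_specificity",
    "pathway_zscore",
    "run_heteropath",
]

_VAR_EPS = 1e-8


@dataclass
class GeneTissueStats:
    """Per-gene, per-tissue moderated statistics and the filter mask."""

    gene_ids: list[str]
    tissues: list[str]
    t: np.ndarray  # (genes, tissues)
    m1: np.ndarray  # (genes, tissues) per-tissue medians
    m2: np.ndarray  # (genes,) all-sample medians
    s: np.ndarray  # (genes, tissues) pooled standard deviations
    pass_fc: np.ndarray  # (genes, tissues) bool
    fc_threshold: float


@dataclass
class PathwayResult:
    set_name: str
    tissue: str
    hs: float
    n_contributing: int
    p: float
    q: float
    z: float
    specific_tissue: str | None


@dataclass
class HeteroPathParams:
    fc_threshold: float = 2.0
    n_perm: int = 1000
    seed: int = 0
    alpha: float = 0.05
    exhaustive_cap: int = 10_000
    specificity_threshold: float = 0.60
    group2: Literal["all", "rest"] = "all"


# ---------------------------------------------------------------------------
# step 1-2: per-gene tissue statistics and the fold-change filter
# ---------------------------------------------------------------------------


def _group_columns(design: TissueDesign, sample_ids: list[str]) -> list[np.ndarray]:
    pos = {s: j for j, s in enumerate(sample_ids)}
    return [np.array([pos[s] for s in design.replicates[t]]) for t in design.tissues]


def _stats_for_groups(
    values: np.ndarray,
    groups: list[np.ndarray],
    m2: np.ndarray,
    var_all: np.ndarray,
    fc_log2: float,
    group2: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """t, m1, s, pass_fc for an arbitrary assignment of columns to tissues.

    ``m2`` and ``var_all`` (all-sample median and ddof-1 variance) are
    invariant under column permutation and are precomputed by the caller.
    """
    n_total = values.shape[1]
    n_genes = values.shape[0]
    k = len(groups)
    t = np.zeros((n_genes, k))
    m1 = np.zeros((n_genes, k))
    s = np.zeros((n_genes, k))
    pass_fc = np.zeros((n_genes, k), dtype=bool)

    for j, cols in enumerate(groups):
        sub = values[:, cols]
        n1 = len(cols)
        m1_j = np.median(sub, axis=1)
        var1 = sub.var(axis=1, ddof=1)
        if group2 == "all":
            n2, var2 = n_total, var_all
        else:  # the complement: every sample not in this tissue
            rest = np.setdiff1d(np.arange(n_total), cols)
            n2 = len(rest)
            var2 = values[:, rest].var(axis=1, ddof=1)
        pooled = np.sqrt(((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2))
        num = m1_j - m2
        with np.errstate(invalid="ignore"):
            t_j = num / (pooled + _VAR_EPS)
        # constant genes: both group variances ~0 -> t forced to 0
        degenerate = (var1 < _VAR_EPS) & (var2 < _VAR_EPS)
        t_j[degenerate] = 0.0
        t[:, j] = t_j
        m1[:, j] = m1_j
        s[:, j] = pooled
        pass_fc[:, j] = np.abs(num) >= fc_log2
    return t, m1, s, pass_fc


def tissue_t_statistics(
    expr: ExpressionMatrix,
    design: TissueDesign | None = None,
    fc_threshold: float = 2.0,
    group2: Literal["all", "rest"] = "all",
) -> GeneTissueStats:
    """Per-gene t-statistics of each tissue against the virtual median cell.

    ``group2`` selects the second group of the pooled standard deviation:
    ``"all"`` (default) uses every sample, ``"rest"`` only the samples
    outside the tissue under test.  Every tissue needs >= 2 replicates.
    """
    design = design or expr.design()
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    values = expr.data[design.sample_ids].to_numpy(dtype=float)
    groups = _group_columns(design, design.sample_ids)
    m2 = np.median(values, axis=1)
    var_all = values.var(axis=1, ddof=1)
    t, m1, s, pass_fc = _stats_for_groups(
        values, groups, m2, var_all, math.log2(fc_threshold), group2
    )
    return GeneTissueStats(
        gene_ids=expr.gene_ids,
        tissues=list(design.tissues),
        t=t,
        m1=m1,
        m2=m2,
        s=s,
        pass_fc=pass_fc,
        fc_threshold=fc_threshold,
    )


# ---------------------------------------------------------------------------
# step 3: heterogeneity scores
# ---------------------------------------------------------------------------


def _membership_matrix(sets: GeneSetCollection, gene_ids: list[str]) -> np.ndarray:
    """(n_sets, n_genes) boolean membership restricted to measured genes."""
    pos = {g: i for i, g in enumerate(gene_ids)}
    mat = np.zeros((len(sets), len(gene_ids)), dtype=bool)
    for si, name in enumerate(sets.names):
        idx = [pos[g] for g in sets.genes(name) if g in pos]
        mat[si, idx] = True
    return mat


def heterogeneity_scores(
    stats: GeneTissueStats, sets: GeneSetCollection
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """HS and contributing-gene counts per (set, tissue).

    HS(S, T) sums |t| over the set's measured members that pass the
    fold-change filter in T; a set with no measured or no passing members
    scores 0 (never fatal).  Returns (hs, n_contributing) DataFrames indexed
    by set name with one column per tissue.
    """
    member = _membership_matrix(sets, stats.gene_ids)
    empty = ~member.any(axis=1)
    if empty.any():
        missing = [sets.names[i] for i in np.flatnonzero(empty)]
        warnings.warn(f"gene sets with no measured genes score 0: {missing}", stacklevel=2)
    contrib = np.abs(stats.t) * stats.pass_fc
    hs = member.astype(float) @ contrib
    n_contributing = member.astype(int) @ stats.pass_fc.astype(int)
    idx = pd.Index(sets.names, name="set")
    return (
        pd.DataFrame(hs, index=idx, columns=stats.tissues),
        pd.DataFrame(n_contributing, index=idx, columns=stats.tissues),
    )


def _hs_for_groups(
    values: np.ndarray,
    groups: list[np.ndarray],
    m2: np.ndarray,
    var_all: np.ndarray,
    member: np.ndarray,
    fc_log2: float,
    group2: str,
) -> np.ndarray:
    t, _, _, pass_fc = _stats_for_groups(values, groups, m2, var_all, fc_log2, group2)
    return member.astype(float) @ (np.abs(t) * pass_fc)


# ---------------------------------------------------------------------------
# steps 4-5: permutation inference
# ---------------------------------------------------------------------------


def _n_arrangements(sizes: list[int]) -> int:
    total = sum(sizes)
    n = math.factorial(total)
    for k in sizes:
        n //= math.factorial(k)
    return n


def permutation_pvalues(
    expr: ExpressionMatrix,
    design: TissueDesign | None = None,
    sets: GeneSetCollection | None = None,
    fc_threshold: float = 2.0,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive_cap: int = 10_000,
    group2: Literal["all", "rest"] = "all",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Empirical p-values for HS by permuting the sample->tissue labels.

    Steps 1-3 (t-statistics, fold-change filter, HS) are recomputed for every
    permuted labelling.  For the test of set S in tissue T, arrangements that
    assign the *same* sample multiset to T as the observed labelling are not
    distinct relabelings of that test and are excluded from its null; among
    the remaining arrangements ties count as exceedances, and the add-one
    estimator keeps p > 0:

        p(S, T) = (1 + #{HS_perm >= HS_obs}) / (1 + N_distinct)

    When the total number of distinct label arrangements is at most
    ``exhaustive_cap`` the null is enumerated exactly (HS in tissue T depends
    only on which samples form T's group, so enumeration runs over group
    compositions with arrangement multiplicities as weights); otherwise
    ``n_perm`` Monte Carlo permutations are drawn.  A constant observed HS
    of 0 still yields p = 1, since permuted HSs of 0 tie and are counted.

    Returns (p, hs_observed) DataFrames indexed by set with tissue columns.
    """
    if sets is None:
        raise ValueError("a gene set collection is required")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    design = design or expr.design()
    values = expr.data[design.sample_ids].to_numpy(dtype=float)
    groups = _group_columns(design, design.sample_ids)
    sizes = [len(g) for g in groups]
    n_samples = values.shape[1]
    m2 = np.median(values, axis=1)
    var_all = values.var(axis=1, ddof=1)
    member = _membership_matrix(sets, expr.gene_ids)
    fc_log2 = math.log2(fc_threshold)

    hs_obs = _hs_for_groups(values, groups, m2, var_all, member, fc_log2, group2)
    obs_comp = [frozenset(g.tolist()) for g in groups]
    exceed = np.zeros_like(hs_obs)
    denom = np.zeros(len(groups))

    n_arr = _n_arrangements(sizes)
    if n_arr <= exhaustive_cap:
        # HS(:, T) depends only on T's group composition; enumerate the
        # compositions once per distinct group size and weight each by the
        # number of full arrangements it appears in.
        hs_by_size: dict[int, dict[frozenset, np.ndarray]] = {}
        for k in sorted(set(sizes)):
            hs_by_size[k] = {}
            for comb in combinations(range(n_samples), k):
                cols = np.array(comb)
                hs_col = _hs_for_groups(
                    values, [cols], m2, var_all, member, fc_log2, group2
                )[:, 0]
                hs_by_size[k][frozenset(comb)] = hs_col
        for j, k in enumerate(sizes):
            rest = sizes[:j] + sizes[j + 1 :]
            weight = _n_arrangements(rest) if rest else 1
            for comp, hs_col in hs_by_size[k].items():
                if comp == obs_comp[j]:
                    continue
                exceed[:, j] += weight * (hs_col >= hs_obs[:, j])
                denom[j] += weight
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            order = rng.permutation(n_samples)
            assignment, start = [], 0
            for k in sizes:
                assignment.append(order[start : start + k])
                start += k
            hs_perm = _hs_for_groups(values, assignment, m2, var_all, member, fc_log2, group2)
            for j in range(len(sizes)):
                if frozenset(assignment[j].tolist()) == obs_comp[j]:
                    continue
                exceed[:, j] += hs_perm[:, j] >= hs_obs[:, j]
                denom[j] += 1

    p = (1.0 + exceed) / (1.0 + denom[None, :])
    idx = pd.Index(sets.names, name="set")
    return (
        pd.DataFrame(p, index=idx, columns=list(design.tissues)),
        pd.DataFrame(hs_obs, index=idx, columns=list(design.tissues)),
    )


# ---------------------------------------------------------------------------
# step 6: FDR
# ---------------------------------------------------------------------------


def fdr_adjust(p_table: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg step-up applied jointly across all (set, tissue)
    tests in the table."""
    flat = p_table.to_numpy(dtype=float).ravel()
    _, q, _, _ = multipletests(flat, method="fdr_bh")
    return pd.DataFrame(
        q.reshape(p_table.shape), index=p_table.index, columns=p_table.columns
    )


# ---------------------------------------------------------------------------
# tissue specificity (the 60% rule)
# ---------------------------------------------------------------------------


def tissue_specificity(
    stats: GeneTissueStats, sets: GeneSetCollection, threshold: float = 0.60
) -> pd.Series:
    """Assign each set to a tissue where >= threshold of its heterogeneous
    elements are uniquely perturbed.

    A heterogeneous element is a measured member gene passing the fold-change
    filter in at least one tissue; it is *unique* to tissue T when it passes
    in T and in no other tissue.  Sets with no heterogeneous elements, or
    where no tissue reaches the threshold, get None.
    """
    member = _membership_matrix(sets, stats.gene_ids)
    n_pass = stats.pass_fc.sum(axis=1)  # per gene: tissues passed
    hetero = n_pass >= 1
    unique = stats.pass_fc & (n_pass == 1)[:, None]  # (genes, tissues)

    calls: dict[str, str | None] = {}
    for si, name in enumerate(sets.names):
        genes = member[si]
        total = int((genes & hetero).sum())
        if total == 0:
            calls[name] = None
            continue
        uniq_counts = unique[genes].sum(axis=0)
        best = int(np.argmax(uniq_counts))
        if uniq_counts[best] >= threshold * total:
            calls[name] = stats.tissues[best]
        else:
            calls[name] = None
    return pd.Series(calls, name="specific_tissue")


# ---------------------------------------------------------------------------
# pathway Z-score (heatmap statistic)
# ---------------------------------------------------------------------------


def pathway_zscore(
    expr: ExpressionMatrix,
    design: TissueDesign | None = None,
    sets: GeneSetCollection | None = None,
) -> pd.DataFrame:
    """Z = (x_p - mu) * sqrt(p) / sigma per (set, tissue).

    Per-gene fold change in tissue T is M1 - M2 in log2 space; mu and sigma
    are the mean and (ddof-1) standard deviation of all genes' fold changes
    in T; x_p is the mean fold change over the set's measured genes and p
    their count.  Sets with no measured genes yield NaN.
    """
    if sets is None:
        raise ValueError("a gene set collection is required")
    design = design or expr.design()
    values = expr.data[design.sample_ids].to_numpy(dtype=float)
    groups = _group_columns(design, design.sample_ids)
    m2 = np.median(values, axis=1)
    member = _membership_matrix(sets, expr.gene_ids)
    sizes = member.sum(axis=1).astype(float)

    z = np.full((len(sets), len(groups)), np.nan)
    for j, cols in enumerate(groups):
        fc = np.median(values[:, cols], axis=1) - m2
        mu, sigma = fc.mean(), fc.std(ddof=1)
        if sigma == 0:
            raise ValueError("degenerate input: all fold changes identical")
        with np.errstate(invalid="ignore"):
            x_p = (member @ fc) / sizes
        z[:, j] = (x_p - mu) * np.sqrt(sizes) / sigma
    return pd.DataFrame(z, index=pd.Index(sets.names, name="set"), columns=list(design.tissues))


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


def run_heteropath(
    expr: ExpressionMatrix,
    design: TissueDesign | None = None,
    sets: GeneSetCollection | None = None,
    params: HeteroPathParams | None = None,
) -> pd.DataFrame:
    """Run the full pipeline and return one row per (set, tissue).

    Columns: set, tissue, hs, n_contributing, p, q, z, specific_tissue;
    sorted by HS descending within tissue.  An empty collection returns an
    empty frame with a warning.
    """
    params = params or HeteroPathParams()
    design = design or expr.design()
    if sets is None or len(sets) == 0:
        warnings.warn("empty gene set collection; nothing to score", stacklevel=2)
        return pd.DataFrame(
            columns=["set", "tissue", "hs", "n_contributing", "p", "q", "z", "specific_tissue"]
        )

    stats = tissue_t_statistics(expr, design, params.fc_threshold, params.group2)
    hs, n_contrib = heterogeneity_scores(stats, sets)
    p, _ = permutation_pvalues(
        expr,
        design,
        sets,
        fc_threshold=params.fc_threshold,
        n_perm=params.n_perm,
        seed=params.seed,
        exhaustive_cap=params.exhaustive_cap,
        group2=params.group2,
    )
    q = fdr_adjust(p)
    z = pathway_zscore(expr, design, sets)
    specific = tissue_specificity(stats, sets, params.specificity_threshold)

    rows = []
    for tissue in design.tissues:
        for name in sets.names:
            rows.append(
                {
                    "set": name,
                    "tissue": tissue,
                    "hs": hs.loc[name, tissue],
                    "n_contributing": int(n_contrib.loc[name, tissue]),
                    "p": p.loc[name, tissue],
                    "q": q.loc[name, tissue],
                    "z": z.loc[name, tissue],
                    "specific_tissue": specific[name],
                }
            )
    out = pd.DataFrame(rows)
    out = (
        out.sort_values(["tissue", "hs"], ascending=[True, False])
        .reset_index(drop=True)
    )
    return out


def to_pathway_results(table: pd.DataFrame) -> list[PathwayResult]:
    return [
        PathwayResult(
            set_name=r["set"],
            tissue=r["tissue"],
            hs=float(r["hs"]),
            n_contributing=int(r["n_contributing"]),
            p=float(r["p"]),
            q=float(r["q"]),
            z=float(r["z"]),
            specific_tissue=r["specific_tissue"],
        )
        for _, r in table.iterrows()
    ]
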