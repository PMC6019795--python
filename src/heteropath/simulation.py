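"""Linear additive microarray simulator and the power / type-I-error study.

Data are generated as y_ij = alpha_i + beta_ij + eps_ij: alpha_i ~ N(0, 1)
is a gene-specific (probe) effect, eps_ij ~ N(0, 1) is noise, and beta_ij is
a sample effect drawn per gene and sample from N(mu_g, sigma_g) where g is
the sample's group (three groups standing in for three tissues).  Only the
truly shifted members of the differentially expressed (DE) set receive a
non-null group-1 effect: (mu_1, sigma_1) = (0.5, 0.5) for the weak setting
or (1.0, 0.5) for the strong one; every other gene-group combination uses
(0, 1).  A size-matched non-DE set serves as the negative control.

Each enrichment method turns a dataset into one score per sample per set;
a one-way ANOVA across the three groups at level alpha then yields, over
replicate datasets, the power (rejection rate on the DE set) and the
empirical type-I error (rejection rate on the non-DE set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .comparators import enrichment_score

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "score_matrix",
    "power_study",
    "METHODS",
]

METHODS = ("heteropath", "pgsea", "gsea")
_EPS = 1e-12

_EFFECTS = {"weak": (0.5, 0.5), "strong": (1.0, 0.5), "none": (0.0, 1.0)}


@dataclass(frozen=True)
class SimulationConfig:
    m: int = 5000
    n: int = 20  # samples, split into 3 near-equal groups
    de_set_size: int = 50
    de_fraction: float = 0.5
    effect: str = "strong"
    n_reps: int = 500
    alpha: float = 0.05
    seed: int = 0
    fc_threshold: float = 2.0  # filter for the per-sample heterogeneity score

    def __post_init__(self) -> None:
        if self.n < 6:
            raise ValueError("need at least 6 samples (2 per group)")
        if not (0 < self.de_fraction <= 1):
            raise ValueError("de_fraction must be in (0, 1]")
        if self.effect not in _EFFECTS:
            raise ValueError(f"effect must be one of {sorted(_EFFECTS)}")
        if 2 * self.de_set_size > self.m:
            raise ValueError("m too small to host the DE and the matched non-DE set")


@dataclass
class SimulatedDataset:
    values: np.ndarray  # (m, n)
    gene_ids: list[str]
    sample_ids: list[str]
    group_of: np.ndarray  # (n,) int in {0, 1, 2}
    de_set: list[str]
    null_set: list[str]
    truly_shifted: list[str]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def simulate_dataset(config: SimulationConfig, rep_index: int = 0) -> SimulatedDataset:
    """One replicate dataset; fully determined by (config.seed, rep_index)."""
    rng = np.random.default_rng([config.seed, rep_index])
    m, n = config.m, config.n
    sizes = [len(a) for a in np.array_split(np.arange(n), 3)]
    group_of = np.repeat(np.arange(3), sizes)

    alpha = rng.normal(0.0, 1.0, size=m)
    beta = rng.normal(0.0, 1.0, size=(m, n))
    eps = rng.normal(0.0, 1.0, size=(m, n))

    n_shift = _round_half_up(config.de_fraction * config.de_set_size)
    shifted = np.arange(n_shift)
    mu1, sigma1 = _EFFECTS[config.effect]
    g1_cols = np.flatnonzero(group_of == 0)
    beta[np.ix_(shifted, g1_cols)] = rng.normal(mu1, sigma1, size=(n_shift, len(g1_cols)))

    values = alpha[:, None] + beta + eps
    gene_ids = [f"g{i:05d}" for i in range(m)]
    sample_ids = [f"s{j:03d}_g{group_of[j] + 1}" for j in range(n)]
    de = gene_ids[: config.de_set_size]
    null = gene_ids[config.de_set_size : 2 * config.de_set_size]
    return SimulatedDataset(
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        group_of=group_of,
        de_set=de,
        null_set=null,
        truly_shifted=gene_ids[:n_shift],
    )


# ---------------------------------------------------------------------------
# per-sample enrichment scores
# ---------------------------------------------------------------------------


def _per_sample_scores(
    values: np.ndarray, idx: np.ndarray, method: str, fc_threshold: float
) -> np.ndarray:
    """Scores of one gene set (row indices ``idx``) for every sample.

    heteropath: single-sample analogue of the heterogeneity score — the sum
    of signed standardised deviations (x_ij - M2(i)) / s2(i) over the set's
    genes whose |x_ij - M2(i)| clears the fold-change threshold, with M2/s2
    the all-sample median and sd.  The filter keeps the score driven by
    strongly perturbed genes in either direction; the sign is kept because a
    per-sample absolute deviation carries no information about a mean shift
    whose variance also changes.
    pgsea: one-sample t of the set's per-sample fold changes against zero.
    gsea: weighted-KS enrichment score on the per-sample fold-change ranking.
    """
    med = np.median(values, axis=1, keepdims=True)
    fc = values - med
    if method == "heteropath":
        s2 = np.maximum(values.std(axis=1, ddof=1), _EPS)
        dev = fc[idx] / s2[idx, None]
        passing = np.abs(fc[idx]) >= math.log2(fc_threshold)
        return (dev * passing).sum(axis=0)
    if method == "pgsea":
        sub = fc[idx]
        n = len(idx)
        sd = np.maximum(sub.std(axis=0, ddof=1), _EPS)
        return sub.mean(axis=0) / (sd / np.sqrt(n))
    if method == "gsea":
        member = np.zeros(values.shape[0], dtype=bool)
        member[idx] = True
        return np.array(
            [enrichment_score(fc[:, j], member) for j in range(values.shape[1])]
        )
    raise ValueError(f"unknown method {method!r}")


def score_matrix(dataset: SimulatedDataset, method: str, fc_threshold: float = 2.0) -> pd.DataFrame:
    """Per-sample scores for the DE set and the matched non-DE set."""
    pos = {g: i for i, g in enumerate(dataset.gene_ids)}
    rows = {}
    for label, genes in (("de_set", dataset.de_set), ("null_set", dataset.null_set)):
        idx = np.array([pos[g] for g in genes])
        rows[label] = _per_sample_scores(dataset.values, idx, method, fc_threshold)
    return pd.DataFrame(rows, index=dataset.sample_ids).T


# ---------------------------------------------------------------------------
# the study harness
# ---------------------------------------------------------------------------


def _anova_rejects(scores: np.ndarray, group_of: np.ndarray, alpha: float) -> bool:
    groups = [scores[group_of == g] for g in range(3)]
    _, p = sps.f_oneway(*groups)
    return bool(p < alpha)


def power_study(
    config_grid: list[SimulationConfig],
    methods: tuple[str, ...] = METHODS,
) -> pd.DataFrame:
    """Estimate power and type-I error over a grid of simulation settings.

    For every config, ``n_reps`` independent datasets are generated; each
    method's score matrix is tested by one-way ANOVA for a mean difference
    among the three groups at level alpha.  Power is the rejection rate on
    the DE set, type-I error the rejection rate on the non-DE set; both come
    with 95% Wilson intervals.
    """
    records = []
    for config in config_grid:
        rej_de = {m: 0 for m in methods}
        rej_null = {m: 0 for m in methods}
        for rep in range(config.n_reps):
            ds = simulate_dataset(config, rep)
            for method in methods:
                sm = score_matrix(ds, method, config.fc_threshold)
                if _anova_rejects(sm.loc["de_set"].to_numpy(), ds.group_of, config.alpha):
                    rej_de[method] += 1
                if _anova_rejects(sm.loc["null_set"].to_numpy(), ds.group_of, config.alpha):
                    rej_null[method] += 1
        for method in methods:
            p_lo, p_hi = proportion_confint(rej_de[method], config.n_reps, method="wilson")
            t_lo, t_hi = proportion_confint(rej_null[method], config.n_reps, method="wilson")
            records.append(
                {
                    "method": method,
                    "n": config.n,
                    "set_size": config.de_set_size,
                    "fraction": config.de_fraction,
                    "effect": config.effect,
                    "n_reps": config.n_reps,
                    "power": rej_de[method] / config.n_reps,
                    "power_lo": p_lo,
                    "power_hi": p_hi,
                    "type1": rej_null[method] / config.n_reps,
                    "type1_lo": t_lo,
                    "type1_hi": t_hi,
                }
            )
    return pd.DataFrame(records)


def default_grid(
    n_values: tuple[int, ...] = (10, 20, 40, 60),
    set_sizes: tuple[int, ...] = (50, 150),
    fractions: tuple[float, ...] = (0.25, 0.5, 0.8),
    effects: tuple[str, ...] = ("weak", "strong"),
    n_reps: int = 500,
    seed: int = 0,
    m: int = 5000,
) -> list[SimulationConfig]:
    """The full factorial study grid."""
    base = SimulationConfig(m=m, n_reps=n_reps, seed=seed)
    return [
        replace(base, n=n, de_set_size=s, de_fraction=f, effect=e)
        for n in n_values
        for s in set_sizes
        for f in fractions
        for e in effects
    ]
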