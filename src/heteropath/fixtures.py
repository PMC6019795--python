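"""Synthetic fixtures with planted structure.

``generate_fixture`` emulates an RMA-normalised multi-tissue microarray
study: per-gene baseline intensities on the log2 scale with Gaussian
replicate noise, and selected gene sets receiving a mean-zero bidirectional
(or directional) log2 shift in one target tissue.  It does not emulate
probe-level effects, inter-gene correlation or array batch effects.

``generate_promoter_fixture`` builds target and background promoter sets
with a motif planted in a chosen fraction of the targets, for exercising the
promoter-scanning and enrichment machinery.

All generators use ``numpy.random.default_rng`` (PCG64) so a given
config + seed reproduces bit-identical output across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BASES, ExpressionMatrix, GeneSetCollection, PromoterSet, PWM

__all__ = [
    "PlantedPathway",
    "FixtureConfig",
    "FixtureTruth",
    "generate_fixture",
    "PromoterFixtureConfig",
    "generate_promoter_fixture",
]


@dataclass
class PlantedPathway:
    """A gene set perturbed in one tissue.

    ``fraction_up``/``fraction_down`` give the fraction of members shifted by
    +effect / -effect log2 units in ``target_tissue``; the remainder are left
    at baseline.  fraction_up = fraction_down = 0.5 plants the mean-zero
    bidirectional signature that mean-based enrichment scores cannot see.
    """

    name: str
    size: int
    fraction_up: float
    fraction_down: float
    effect: float
    target_tissue: str

    def __post_init__(self) -> None:
        if self.fraction_up + self.fraction_down > 1 + 1e-12:
            raise ValueError(f"planted set {self.name!r}: fraction up + down > 1")


@dataclass
class FixtureConfig:
    n_genes: int = 2000
    tissues: tuple[str, ...] = ("brain", "lung", "heart")
    replicates: int = 3
    planted: list[PlantedPathway] = field(default_factory=list)
    n_decoy_sets: int = 20
    decoy_set_size: int = 50
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0


@dataclass
class FixtureTruth:
    """Ground truth of a generated fixture: which sets are planted where,
    and which member genes were shifted in which direction."""

    planted_sets: dict[str, str]  # set name -> target tissue
    up_genes: dict[str, list[str]]
    down_genes: dict[str, list[str]]


def generate_fixture(
    config: FixtureConfig, seed: int
) -> tuple[ExpressionMatrix, GeneSetCollection, FixtureTruth]:
    """Generate an expression matrix, gene sets, and the planted truth.

    Baseline expression for gene g, sample j is N(mu_g, noise_sd) with
    mu_g ~ N(baseline_mean, baseline_sd).  Planted shifts are added only to
    the target tissue's replicates.  Decoy sets are disjoint from planted
    sets and from each other.
    """
    rng = np.random.default_rng(seed)
    n_planted_genes = sum(p.size for p in config.planted)
    n_needed = n_planted_genes + config.n_decoy_sets * config.decoy_set_size
    if n_needed > config.n_genes:
        raise ValueError(
            f"{config.n_genes} genes cannot host {n_needed} planted + decoy members"
        )

    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"{t}_{r + 1}" for t in config.tissues for r in range(config.replicates)]
    tissue_of = {s: s.rsplit("_", 1)[0] for s in sample_ids}

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(sample_ids)))

    pool = rng.permutation(config.n_genes)
    cursor = 0
    sets: dict[str, tuple[str, list[str]]] = {}
    truth = FixtureTruth(planted_sets={}, up_genes={}, down_genes={})

    for p in config.planted:
        if p.target_tissue not in config.tissues:
            raise ValueError(f"unknown target tissue {p.target_tissue!r}")
        members = pool[cursor : cursor + p.size]
        cursor += p.size
        n_up = int(round(p.fraction_up * p.size))
        n_down = int(round(p.fraction_down * p.size))
        up, down = members[:n_up], members[n_up : n_up + n_down]
        cols = [j for j, s in enumerate(sample_ids) if tissue_of[s] == p.target_tissue]
        values[np.ix_(up, cols)] += p.effect
        values[np.ix_(down, cols)] -= p.effect
        sets[p.name] = (f"planted:{p.target_tissue}", [gene_ids[i] for i in members])
        truth.planted_sets[p.name] = p.target_tissue
        truth.up_genes[p.name] = [gene_ids[i] for i in up]
        truth.down_genes[p.name] = [gene_ids[i] for i in down]

    for d in range(config.n_decoy_sets):
        members = pool[cursor : cursor + config.decoy_set_size]
        cursor += config.decoy_set_size
        sets[f"decoy{d:03d}"] = ("decoy", [gene_ids[i] for i in members])

    expr = ExpressionMatrix(
        data=pd.DataFrame(values, index=gene_ids, columns=sample_ids), tissue_of=tissue_of
    )
    return expr, GeneSetCollection(sets=sets), truth


# ---------------------------------------------------------------------------
# promoter fixture
# ---------------------------------------------------------------------------


@dataclass
class PromoterFixtureConfig:
    seq_length: int = 300
    n_targets: int = 50
    n_background: int = 500
    motif_consensus: str = "TGACGTCATAGC"
    consensus_weight: float = 0.95  # pre-pseudocount frequency of the consensus base
    fraction_with_motif: float = 0.8
    pseudocount: float = 0.01


def _pwm_from_consensus(consensus: str, weight: float, pseudocount: float) -> PWM:
    idx = {b: i for i, b in enumerate(BASES)}
    counts = np.full((len(consensus), 4), (1 - weight) / 3 * 100.0)
    for i, b in enumerate(consensus.upper()):
        counts[i] = (1 - weight) / 3 * 100.0
        counts[i, idx[b]] = weight * 100.0
    return PWM.from_counts("planted_motif", counts, pseudocount=pseudocount)


def generate_promoter_fixture(
    config: PromoterFixtureConfig, seed: int
) -> tuple[PromoterSet, PromoterSet, PWM]:
    """Generate target and background promoters plus the planted PWM.

    Background sequences are i.i.d. uniform over {A,C,G,T}; targets are the
    same except that a motif instance sampled from the PWM is embedded at a
    uniform random position in ``fraction_with_motif`` of them.
    """
    if len(config.motif_consensus) > config.seq_length:
        raise ValueError("motif longer than the promoter sequences")
    rng = np.random.default_rng(seed)
    pwm = _pwm_from_consensus(config.motif_consensus, config.consensus_weight, config.pseudocount)
    L = len(pwm)

    def random_seqs(n: int) -> list[str]:
        draws = rng.integers(0, 4, size=(n, config.seq_length))
        return ["".join(BASES[b] for b in row) for row in draws]

    targets = random_seqs(config.n_targets)
    background = random_seqs(config.n_background)

    n_with = int(round(config.fraction_with_motif * config.n_targets))
    chosen = rng.choice(config.n_targets, size=n_with, replace=False)
    for i in chosen:
        instance = "".join(
            BASES[rng.choice(4, p=pwm.matrix[pos])] for pos in range(L)
        )
        start = int(rng.integers(0, config.seq_length - L + 1))
        targets[i] = targets[i][:start] + instance + targets[i][start + L :]

    tgt = PromoterSet(records={f"tgt{i:04d}": s for i, s in enumerate(targets)})
    bg = PromoterSet(records={f"bg{i:04d}": s for i, s in enumerate(background)})
    return tgt, bg, pwm
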