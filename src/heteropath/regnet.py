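"""Promoter motif scanning, over-representation testing, and construction
of tissue-specific TF -> gene regulatory edge lists.

Scanning follows the MATCH scoring scheme: each motif position i carries an
information weight I(i) = sum_b f(i,b) ln(4 f(i,b)); a window scores

    Current = sum_i I(i) f(i, b_i)
    MSS     = (Current - Min) / (Max - Min)

where Min/Max substitute the per-position minimal/maximal frequencies, so
MSS is 1.0 exactly on the consensus window and 0.0 on the anti-consensus.
The core similarity score (CSS) applies the same formula to the five
consecutive positions of highest total information.  A hit requires both
MSS and CSS to clear the cutoff (0.7 by default); windows containing N
never match.  Both strands are scanned; positions are 1-based starts on the
forward sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import tissue_t_statistics
from .io import BASES, ExpressionMatrix, GeneSetCollection, PromoterSet, PWM, TissueDesign

__all__ = [
    "MotifHit",
    "EnrichmentResult",
    "NetworkEdge",
    "scan_promoter",
    "scan_promoters",
    "motif_enrichment",
    "minsum_cutoff",
    "build_network",
]

_EPS = 1e-12
_CORE_LEN = 5
_ENCODE = {b: i for i, b in enumerate(BASES)}
_ENCODE["N"] = 4


@dataclass
class MotifHit:
    gene_id: str
    motif_id: str
    position: int  # 1-based start on the forward sequence
    strand: str  # '+' or '-'
    mss: float
    css: float


@dataclass
class EnrichmentResult:
    motif_id: str
    observed_hits: int  # target promoters with >= 1 passing hit
    background_mean: float  # mean of the statistic over random background draws
    p: float


@dataclass
class NetworkEdge:
    tf_gene_id: str
    target_gene_id: str
    tissue: str
    set_name: str
    motif_id: str
    evidence: str  # 'annotated' | 'putative'
    tf_expressed: bool = True


# ---------------------------------------------------------------------------
# MATCH-style scanning
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from exc


def _core_start(info: np.ndarray) -> int:
    """Start of the CORE_LEN consecutive positions of maximal total
    information (the whole motif when shorter than CORE_LEN)."""
    L = len(info)
    if L <= _CORE_LEN:
        return 0
    sums = np.convolve(info, np.ones(_CORE_LEN), mode="valid")
    return int(np.argmax(sums))


def _window_scores(codes: np.ndarray, freq: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mss, css, valid) for every window of one strand.

    ``freq`` is the (L, 4) frequency matrix oriented for this strand;
    windows containing N are flagged invalid.
    """
    L = freq.shape[0]
    info = np.sum(freq * np.log(4.0 * freq), axis=1)
    weighted = info[:, None] * freq  # (L, 4)
    lo, hi = weighted.min(axis=1), weighted.max(axis=1)
    cs = _core_start(info)

    windows = np.lib.stride_tricks.sliding_window_view(codes, L)  # (W, L)
    valid = ~(windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)

    pos_idx = np.arange(L)
    current_all = weighted[pos_idx, safe].sum(axis=1)
    span = slice(cs, min(cs + _CORE_LEN, L))
    core_idx = pos_idx[span]
    current_core = weighted[core_idx, safe[:, span]].sum(axis=1)

    def normalise(cur: np.ndarray, idx: np.ndarray) -> np.ndarray:
        mn, mx = lo[idx].sum(), hi[idx].sum()
        if mx - mn < _EPS:
            return np.ones_like(cur)
        return (cur - mn) / (mx - mn)

    return normalise(current_all, pos_idx), normalise(current_core, core_idx), valid


def _revcomp_matrix(freq: np.ndarray) -> np.ndarray:
    return freq[::-1, ::-1]


def scan_promoter(seq: str, pwm: PWM, cutoff: float = 0.7, gene_id: str = "") -> list[MotifHit]:
    """All passing hits of one PWM on both strands of one sequence.

    Returns hits (1-based forward-strand start positions) where both MSS and
    CSS reach ``cutoff``.  A sequence shorter than the motif yields an empty
    list.
    """
    if not (0 <= cutoff <= 1):
        raise ValueError("cutoff must be in [0, 1]")
    L = len(pwm)
    if len(seq) < L:
        return []
    codes = _encode(seq.upper())
    hits: list[MotifHit] = []
    for strand, freq in (("+", pwm.matrix), ("-", _revcomp_matrix(pwm.matrix))):
        mss, css, valid = _window_scores(codes, freq)
        passing = valid & (mss >= cutoff) & (css >= cutoff)
        for w in np.flatnonzero(passing):
            hits.append(
                MotifHit(
                    gene_id=gene_id,
                    motif_id=pwm.motif_id,
                    position=int(w) + 1,
                    strand=strand,
                    mss=float(mss[w]),
                    css=float(css[w]),
                )
            )
    return hits


def scan_promoters(promoters: PromoterSet, pwm: PWM, cutoff: float = 0.7) -> list[MotifHit]:
    """Hits of one PWM over a promoter set."""
    hits: list[MotifHit] = []
    for gid, seq in promoters.records.items():
        hits.extend(scan_promoter(seq, pwm, cutoff, gene_id=gid))
    return hits


def _has_hit(promoters: PromoterSet, pwm: PWM, cutoff: float) -> np.ndarray:
    """Boolean per promoter: carries at least one passing hit."""
    out = np.zeros(len(promoters), dtype=bool)
    for i, seq in enumerate(promoters.records.values()):
        if len(seq) < len(pwm):
            continue
        codes = _encode(seq)
        for freq in (pwm.matrix, _revcomp_matrix(pwm.matrix)):
            mss, css, valid = _window_scores(codes, freq)
            if np.any(valid & (mss >= cutoff) & (css >= cutoff)):
                out[i] = True
                break
    return out


# ---------------------------------------------------------------------------
# over-representation against a background
# ---------------------------------------------------------------------------


def motif_enrichment(
    targets: PromoterSet,
    background: PromoterSet,
    pwm: PWM,
    cutoff: float = 0.7,
    n_draws: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Empirical over-representation p-value of a motif in target promoters.

    The statistic is the number of target promoters carrying at least one
    passing hit; the null resamples |targets| promoters (without
    replacement) from the background ``n_draws`` times and
    p = (1 + #{null >= observed}) / (1 + n_draws).
    """
    if len(background) < len(targets):
        raise ValueError("background must be at least as large as the target set")
    observed = int(_has_hit(targets, pwm, cutoff).sum())
    bg_hit = _has_hit(background, pwm, cutoff)
    rng = np.random.default_rng(seed)
    draws = np.array(
        [bg_hit[rng.choice(len(background), size=len(targets), replace=False)].sum()
         for _ in range(n_draws)]
    )
    p = (1.0 + np.sum(draws >= observed)) / (1.0 + n_draws)
    return EnrichmentResult(
        motif_id=pwm.motif_id,
        observed_hits=observed,
        background_mean=float(draws.mean()),
        p=float(p),
    )


def minsum_cutoff(
    pwm: PWM,
    background: PromoterSet,
    n_positive_samples: int = 1000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> float:
    """Score cutoff minimising false-negative% + false-positive%.

    Positives are motif-length sequences sampled from the PWM's column
    distributions; FN% is the fraction scoring (MSS) below a candidate
    cutoff, FP% the per-window background match rate, both in percent.  The
    grid runs 0.50..1.00 in steps of 0.01; ties take the larger cutoff.
    """
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    if grid is None:
        grid = np.round(np.arange(0.50, 1.0 + 1e-9, 0.01), 2)
    rng = np.random.default_rng(seed)
    L = len(pwm)
    # MSS of sampled positives: score each sampled L-mer as its own window
    samples = np.stack(
        [rng.choice(4, size=n_positive_samples, p=pwm.matrix[i]) for i in range(L)], axis=1
    )
    info = np.sum(pwm.matrix * np.log(4.0 * pwm.matrix), axis=1)
    weighted = info[:, None] * pwm.matrix
    lo, hi = weighted.min(axis=1).sum(), weighted.max(axis=1).sum()
    current = weighted[np.arange(L), samples].sum(axis=1)
    pos_scores = np.ones(n_positive_samples) if hi - lo < _EPS else (current - lo) / (hi - lo)

    bg_scores: list[np.ndarray] = []
    for seq in background.records.values():
        if len(seq) < L:
            continue
        codes = _encode(seq)
        for freq in (pwm.matrix, _revcomp_matrix(pwm.matrix)):
            mss, _, valid = _window_scores(codes, freq)
            bg_scores.append(mss[valid])
    all_bg = np.concatenate(bg_scores) if bg_scores else np.array([])

    best_cut, best_sum = grid[0], np.inf
    for cut in grid:
        fn = 100.0 * np.mean(pos_scores < cut)
        fp = 100.0 * np.mean(all_bg >= cut) if all_bg.size else 0.0
        if fn + fp <= best_sum:  # <= keeps the larger cutoff on ties
            best_sum, best_cut = fn + fp, cut
    return float(best_cut)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def build_network(
    results: pd.DataFrame,
    tf_motif_map: pd.DataFrame,
    enrichments: list[EnrichmentResult],
    hits: list[MotifHit],
    expr: ExpressionMatrix,
    design: TissueDesign | None = None,
    sets: GeneSetCollection | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    enrichment_alpha: float = 0.05,
) -> pd.DataFrame:
    """TF -> gene edges for significant heterogeneous pathways.

    For every (set, tissue) in ``results`` with q < alpha, edges run from
    each TF whose motif is over-represented (enrichment p < enrichment_alpha)
    AND which is itself upregulated in that tissue (t > 0 and passing the
    fold-change filter) to each heterogeneous member gene whose promoter
    carries a passing hit of that motif.  ``tf_motif_map`` needs columns
    tf_gene_id and motif_id plus an optional evidence column
    ('annotated'/'putative'; default 'putative').
    """
    if tf_motif_map is None or len(tf_motif_map) == 0:
        raise ValueError(
            "empty tf_motif_map: supply a TSV with columns tf_gene_id, motif_id "
            "(e.g. exported from a curated TF-motif resource)"
        )
    if sets is None:
        raise ValueError("the gene set collection is required to resolve member genes")
    design = design or expr.design()
    stats = tissue_t_statistics(expr, design, fc_threshold=fc_threshold)
    gene_pos = {g: i for i, g in enumerate(stats.gene_ids)}
    tissue_pos = {t: j for j, t in enumerate(stats.tissues)}

    enriched = {e.motif_id for e in enrichments if e.p < enrichment_alpha}
    hit_genes: dict[str, set[str]] = {}
    for h in hits:
        hit_genes.setdefault(h.motif_id, set()).add(h.gene_id)

    if "evidence" not in tf_motif_map.columns:
        tf_motif_map = tf_motif_map.assign(evidence="putative")

    edges: list[NetworkEdge] = []
    seen: set[tuple] = set()
    significant = results[results["q"] < alpha]
    for _, row in significant.iterrows():
        tissue = row["tissue"]
        tj = tissue_pos[tissue]
        members = [g for g in sets.genes(row["set"]) if g in gene_pos]
        hetero = [g for g in members if stats.pass_fc[gene_pos[g], tj]]
        for _, tfrow in tf_motif_map.iterrows():
            tf, motif = tfrow["tf_gene_id"], tfrow["motif_id"]
            if motif not in enriched:
                continue
            gi = gene_pos.get(tf)
            if gi is None:
                continue
            upregulated = stats.t[gi, tj] > 0 and stats.pass_fc[gi, tj]
            if not upregulated:
                continue
            for target in hetero:
                if target not in hit_genes.get(motif, ()):
                    continue
                key = (tf, target, tissue, row["set"], motif)
                if key in seen:
                    continue
                seen.add(key)
                edges.append(
                    NetworkEdge(
                        tf_gene_id=tf,
                        target_gene_id=target,
                        tissue=tissue,
                        set_name=row["set"],
                        motif_id=motif,
                        evidence=tfrow["evidence"],
                    )
                )
    if not edges:
        warnings.warn("no edges passed the enrichment and expression gates", stacklevel=2)
    return pd.DataFrame(
        [
            {
                "tf": e.tf_gene_id,
                "target": e.target_gene_id,
                "tissue": e.tissue,
                "set": e.set_name,
                "motif": e.motif_id,
                "evidence": e.evidence,
                "tf_expressed": e.tf_expressed,
            }
            for e in edges
        ],
        columns=["tf", "target", "tissue", "set", "motif", "evidence", "tf_expressed"],
    )
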