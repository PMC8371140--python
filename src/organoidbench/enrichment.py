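"""Gene-set enrichment: weighted running-sum ES and directional z-scores.

The enrichment score walks down a ranked gene list, incrementing a running
sum on gene-set hits by the hit's weighted statistic share and decrementing
on misses by 1/(misses in the list); the ES is the signed maximum absolute
deviation of the walk — the classic weighted Kolmogorov–Smirnov-like
statistic. Significance comes from a gene-label permutation null (random
sets of the same size) with a plus-one-corrected p-value and BH adjustment
across sets.

The directional z-score summary scales each gene across samples, multiplies
by the gene's declared direction (+1 up-regulated, −1 down-regulated), and
averages over the set per sample, reporting per-group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import bh_adjust
from .io import GeneSet, SampleSheet

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "gsea",
    "zscore_signature",
]


@dataclass
class RankedList:
    """Gene IDs ordered by a ranking statistic, descending, ties broken by ID."""

    genes: list
    stats: np.ndarray

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate gene IDs")
        if not np.isfinite(self.stats).all():
            raise ValueError("ranking statistics must be finite")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(deg: pd.DataFrame, by: str = "stat") -> RankedList:
    """Rank a DEG table by its Wald statistic, descending.

    Untested genes (NaN statistic) are excluded; ties are broken by gene ID
    lexicographically so the order is deterministic.
    """
    if deg.empty:
        raise ValueError("cannot rank an empty DEG table")
    table = deg[np.isfinite(deg[by])]
    if table.empty:
        raise ValueError("no gene has a finite ranking statistic")
    order = sorted(zip(table.index, table[by]), key=lambda kv: (-kv[1], kv[0]))
    genes = [g for g, _ in order]
    return RankedList(genes=genes, stats=np.array([v for _, v in order]))


def _es_from_hits(
    hit_pos: np.ndarray, hit_weights: np.ndarray, n_total: int
) -> float:
    """ES from sorted hit positions without materializing the full walk.

    The walk's extrema can only occur at a hit (positive candidates) or
    just before a hit / at the list end (negative candidates).
    """
    m = len(hit_pos)
    wsum = hit_weights.sum()
    if wsum == 0:
        hit_cum = np.arange(1, m + 1) / m
    else:
        hit_cum = np.cumsum(hit_weights) / wsum
    miss_step = 1.0 / (n_total - m)
    i = np.arange(m)
    at_hit = hit_cum - (hit_pos + 1 - (i + 1)) * miss_step
    before_hit = np.concatenate([[0.0], hit_cum[:-1]]) - (hit_pos - i) * miss_step
    candidates = np.concatenate([at_hit, before_hit])
    best = candidates[np.argmax(np.abs(candidates))]
    return float(best)


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_exponent: float = 1.0
):
    """Weighted running-sum enrichment score and the full walk.

    Hits increment by |r|^weight_exponent normalized over hit weights;
    misses decrement by 1/(list size − set size). The ES is the walk value
    of maximum absolute deviation from zero (signed); with
    ``weight_exponent = 0`` this is the classic Kolmogorov–Smirnov
    statistic of the hit positions.

    Returns ``(es, running_sum)``.
    """
    members = set(gene_set.genes)
    hits = np.array([g in members for g in ranked.genes])
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the ranked list")
    if n_hits == len(ranked):
        raise ValueError(f"gene set {gene_set.name!r} covers the whole ranked list")
    weights = np.abs(ranked.stats) ** weight_exponent
    hit_w = np.where(hits, weights, 0.0)
    wsum = hit_w.sum()
    if wsum == 0:  # all hit statistics are zero: fall back to equal weights
        hit_w = hits.astype(float)
        wsum = hit_w.sum()
    step = hit_w / wsum - (~hits) / (len(ranked) - n_hits)
    running = np.cumsum(step)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


@dataclass
class EnrichmentResult:
    name: str
    es: float
    pvalue: float
    padj: float
    leading_edge: list
    size: int


def _leading_edge(ranked: RankedList, gene_set: GeneSet, running: np.ndarray) -> list:
    members = set(gene_set.genes)
    peak = int(np.argmax(np.abs(running)))
    if running[peak] >= 0:
        span = range(0, peak + 1)
    else:
        span = range(peak + 1, len(ranked))
    return [ranked.genes[i] for i in span if ranked.genes[i] in members]


def gsea(
    ranked: RankedList,
    sets: list[GeneSet],
    n_permutations: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Permutation GSEA over a list of gene sets.

    The null redraws |S| random genes from the ranked universe
    ``n_permutations`` times; p = (1 + #{|ES_null| >= |ES_obs|}) /
    (n_permutations + 1), so p is never 0; BH adjustment across sets.
    Deterministic given the seed.
    """
    import warnings

    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value grid")
    rng = np.random.default_rng(seed)
    n = len(ranked)
    weights = np.abs(ranked.stats) ** weight_exponent
    results = []
    for gs in sets:
        es, running = enrichment_score(ranked, gs, weight_exponent)
        m = len([g for g in gs.genes if g in set(ranked.genes)])
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            pos = np.sort(rng.choice(n, size=m, replace=False))
            null[i] = _es_from_hits(pos, weights[pos], n)
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_permutations + 1.0)
        results.append(
            EnrichmentResult(
                name=gs.name,
                es=es,
                pvalue=float(p),
                padj=np.nan,
                leading_edge=_leading_edge(ranked, gs, running),
                size=m,
            )
        )
    table = pd.DataFrame(
        {
            "es": [r.es for r in results],
            "pvalue": [r.pvalue for r in results],
            "size": [r.size for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        },
        index=pd.Index([r.name for r in results], name="gene_set"),
    )
    table["padj"] = bh_adjust(table["pvalue"].to_numpy())
    return table[["es", "pvalue", "padj", "size", "leading_edge"]]


def zscore_signature(
    normalized: pd.DataFrame,
    gene_set: GeneSet,
    sheet: SampleSheet,
    group_factor: str = "sample_type",
) -> pd.Series:
    """Per-group mean directional z-score of a gene set.

    Each set gene is centered and scaled across samples, multiplied by its
    declared direction (+1/−1), averaged over set genes per sample, then
    averaged within each level of ``group_factor``. Zero-variance genes are
    excluded with a warning; genes absent from the matrix are an error.
    """
    import warnings

    if gene_set.directions is None:
        raise ValueError(f"gene set {gene_set.name!r} has no directions")
    if list(normalized.columns) != sheet.sample_ids:
        raise ValueError("normalized matrix columns do not match the sample sheet")
    missing = [g for g in gene_set.genes if g not in normalized.index]
    if missing:
        raise ValueError(f"set genes absent from the matrix: {missing[:5]}")
    block = normalized.loc[list(gene_set.genes)]
    sd = block.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} zero-variance gene(s) from "
            f"{gene_set.name!r}"
        )
    block = block.loc[usable]
    if block.empty:
        raise ValueError("no gene with nonzero variance in the set")
    z = block.sub(block.mean(axis=1), axis=0).div(sd[usable], axis=0)
    direction = pd.Series({g: gene_set.directions[g] for g in block.index})
    per_sample = z.mul(direction, axis=0).mean(axis=0)
    groups = sheet.frame.set_index("sample_id")[group_factor]
    return per_sample.groupby(groups).mean()
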