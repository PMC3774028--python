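"""Hub prioritization (step 5): GeneRank and degree ranking.

GeneRank is a PageRank variant whose stationary score is pulled toward
genes with large differential expression: it solves

    r = (1 - d) e + d W r

where ``e`` is the (normalized) differential-expression magnitude, ``W``
the column-degree-normalized adjacency, and ``d`` the damping/controlling
parameter (0.5 here, weighting connectivity and expression equally).
Hubs are also ranked by their differential-network degree, and the two
top-k lists are intersected to form the candidate signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DifferentialNetwork, GeneNetwork


@dataclass
class GeneRankConfig:
    damping: float = 0.5
    tolerance: float = 1e-10
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not 0 <= self.damping < 1:
            raise ValueError("damping must be in [0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class RankedGeneList:
    """Genes with GeneRank score, differential degree, and per-method ranks
    (1 = best).  ``gene_ids`` is ordered by the list's primary ranking."""

    gene_ids: list[str]
    generank_score: np.ndarray
    degree: np.ndarray
    generank_rank: np.ndarray
    degree_rank: np.ndarray

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "generank_score": self.generank_score,
                "degree": self.degree,
                "generank_rank": self.generank_rank,
                "degree_rank": self.degree_rank,
            }
        )


def _adjacency_of(network: GeneNetwork | DifferentialNetwork) -> tuple[list[str], np.ndarray]:
    if isinstance(network, GeneNetwork):
        return network.gene_ids, network.adjacency.astype(float)
    genes = network.gene_ids
    index = {g: i for i, g in enumerate(genes)}
    adj = np.zeros((len(genes), len(genes)))
    for a, b in network.edges:
        i, j = index[a], index[b]
        adj[i, j] = adj[j, i] = 1.0
    return genes, adj


def generank(
    network: GeneNetwork | DifferentialNetwork,
    expression_change: Sequence[float],
    config: GeneRankConfig | None = None,
) -> np.ndarray:
    """GeneRank scores by fixed-point iteration.

    ``expression_change`` must be nonnegative, aligned with the network's
    genes, and not all zero; it is normalized to sum to 1.  Columns of
    isolated genes are replaced by the expression vector (the standard
    dangling-node fix), so the scores themselves sum to 1.
    """
    config = config or GeneRankConfig()
    genes, adj = _adjacency_of(network)
    e = np.asarray(expression_change, dtype=float)
    if e.shape != (len(genes),):
        raise ValueError("expression_change must align with the network genes")
    if np.any(e < 0):
        raise ValueError("expression_change entries must be >= 0")
    total = e.sum()
    if total == 0:
        raise ValueError("expression_change must not be all zero")
    e = e / total

    deg = adj.sum(axis=0)
    dangling = deg == 0
    w = np.divide(adj, np.where(dangling, 1.0, deg)[None, :])
    d = config.damping

    r = e.copy()
    for _ in range(config.max_iter):
        r_new = (1.0 - d) * e + d * (w @ r + e * r[dangling].sum())
        if np.abs(r_new - r).sum() < config.tolerance:
            return r_new
        r = r_new
    raise RuntimeError(f"GeneRank did not converge in {config.max_iter} iterations")


def generank_ranking(
    network: GeneNetwork | DifferentialNetwork,
    expression_change: Sequence[float],
    config: GeneRankConfig | None = None,
    restrict_to: Sequence[str] | None = None,
) -> RankedGeneList:
    """Full ranked list ordered by decreasing GeneRank score.

    ``restrict_to`` reads the ranking off for a gene subset (e.g. the hubs)
    while the scores are computed on the whole network.
    """
    genes, _ = _adjacency_of(network)
    scores = generank(network, expression_change, config)
    degrees = (
        network.degrees()
        if isinstance(network, (GeneNetwork, DifferentialNetwork))
        else {}
    )
    keep = list(restrict_to) if restrict_to is not None else list(genes)
    idx = {g: i for i, g in enumerate(genes)}
    rows = sorted(keep, key=lambda g: (-scores[idx[g]], g))
    score_arr = np.array([scores[idx[g]] for g in rows])
    deg_arr = np.array([degrees.get(g, 0) for g in rows])
    gr_rank = np.arange(1, len(rows) + 1)
    deg_order = sorted(range(len(rows)), key=lambda i: (-deg_arr[i], rows[i]))
    deg_rank = np.empty(len(rows), dtype=int)
    deg_rank[deg_order] = np.arange(1, len(rows) + 1)
    return RankedGeneList(rows, score_arr, deg_arr, gr_rank, deg_rank)


def degree_ranking(diff: DifferentialNetwork,
                   restrict_to: Sequence[str] | None = None) -> RankedGeneList:
    """Ranked list ordered by decreasing differential degree, ties broken by
    gene ID."""
    degrees = diff.degrees()
    keep = list(restrict_to) if restrict_to is not None else list(diff.gene_ids)
    if not keep:
        raise ValueError("degree_ranking needs at least one gene")
    rows = sorted(keep, key=lambda g: (-degrees[g], g))
    deg_arr = np.array([degrees[g] for g in rows])
    deg_rank = np.arange(1, len(rows) + 1)
    zeros = np.zeros(len(rows))
    return RankedGeneList(rows, zeros, deg_arr, deg_rank.copy(), deg_rank)


def intersect_top_k(
    ranking1: RankedGeneList | Sequence[str],
    ranking2: RankedGeneList | Sequence[str],
    k: int = 10,
) -> list[str]:
    """Genes in the top-k of both rankings, ordered by ranking1 position."""
    if k < 1:
        raise ValueError("k must be >= 1")

    def _top(ranking: RankedGeneList | Sequence[str]) -> list[str]:
        if isinstance(ranking, RankedGeneList):
            return ranking.top(k)
        return list(ranking)[:k]

    top1 = _top(ranking1)
    top2 = set(_top(ranking2))
    return [g for g in top1 if g in top2]
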