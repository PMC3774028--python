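"""Differential-network construction and hub detection (steps 3-4).

The differential network is the symmetric difference of the case and
control networks: edges present in only one condition.  Case-specific edges
are tagged ``positive`` (inducible), control-specific edges ``negative``
(suppressive).  Hubs are differential-network genes with high degree and a
significant upstream differential-expression p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import NEGATIVE, POSITIVE, DifferentialNetwork, GeneNetwork, _canonical_edge
from .preprocess import DEResult


@dataclass
class HubCriteria:
    """Thresholds for differential-network hubs: degree >= min_degree and
    differential-expression p-value <= max_p (both inclusive)."""

    min_degree: int = 5
    max_p: float = 0.01

    def __post_init__(self) -> None:
        if self.min_degree < 1:
            raise ValueError("min_degree must be >= 1")
        if not 0 < self.max_p <= 1:
            raise ValueError("max_p must be in (0, 1]")


def subtract_networks(
    case_net: GeneNetwork, control_net: GeneNetwork
) -> DifferentialNetwork:
    """Symmetric difference of two condition networks with sign tags.

    Edges present only in the case network are ``positive``; edges present
    only in the control network are ``negative``.  Shared (trivial) edges
    cancel out.
    """
    if case_net.gene_ids != control_net.gene_ids:
        raise ValueError("case and control networks must share the same "
                         "gene universe in the same order")
    genes = case_net.gene_ids
    diff = case_net.adjacency.astype(np.int8) - control_net.adjacency.astype(np.int8)
    edges: dict[tuple[str, str], str] = {}
    ii, jj = np.nonzero(np.triu(diff, k=1))
    for i, j in zip(ii, jj):
        sign = POSITIVE if diff[i, j] > 0 else NEGATIVE
        edges[_canonical_edge(genes[i], genes[j])] = sign
    return DifferentialNetwork(genes, edges)


def classify_interactions(diff: DifferentialNetwork) -> tuple[int, int, int]:
    """Counts ``(n_total, n_positive, n_negative)`` over differential edges."""
    n_pos = sum(1 for s in diff.edges.values() if s == POSITIVE)
    n_neg = diff.n_edges - n_pos
    return (diff.n_edges, n_pos, n_neg)


def identify_hubs(
    diff: DifferentialNetwork, de: DEResult, criteria: HubCriteria | None = None
) -> list[str]:
    """Hub genes of the differential network.

    A hub has differential degree >= ``criteria.min_degree`` and
    differential-expression p-value <= ``criteria.max_p``.  Returned sorted
    by decreasing degree, ties broken by gene ID.
    """
    criteria = criteria or HubCriteria()
    degrees = diff.degrees()
    known = set(de.gene_ids)
    missing = sorted(g for g, d in degrees.items() if d > 0 and g not in known)
    if missing:
        raise KeyError(f"gene(s) missing from DE results: {missing[:5]}")
    hubs = []
    for gene, deg in degrees.items():
        if deg < criteria.min_degree:
            continue
        if de.p_value_for(gene) <= criteria.max_p:
            hubs.append((gene, deg))
    hubs.sort(key=lambda item: (-item[1], item[0]))
    return [g for g, _ in hubs]
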