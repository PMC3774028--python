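"""Synthetic benchmark generator with known ground truth.

Emulates SynTReN-style microarray benchmarks: a scale-free (preferential
attachment) gene network, linear-Gaussian expression data sampled along an
acyclic orientation of the network, and case/control dataset pairs in which
a fraction of edges is rewired (the true differential edges) and a subset
of genes receives a mean shift (the true differentially expressed genes).
Defaults match the benchmark regime of 200 genes, 100 samples, ~500 edges,
and additive noise sigma = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    CASE,
    CONTROL,
    DifferentialNetwork,
    ExpressionMatrix,
    GeneNetwork,
    NEGATIVE,
    POSITIVE,
    SampleLabels,
    _canonical_edge,
)


@dataclass
class SimulationConfig:
    """Benchmark parameters.

    ``noise_sigma`` is the standard deviation of the additive Gaussian noise
    on each non-root gene; ``de_shift`` the planted case-group mean shift in
    log2 units; ``rewire_fraction`` the fraction of base edges replaced in
    the case topology (removed edges become control-specific truth, added
    ones case-specific).
    """

    n_genes: int = 200
    n_samples: int = 100
    target_edges: int = 500
    noise_sigma: float = 0.5
    rewire_fraction: float = 0.1
    n_de_genes: int = 20
    de_shift: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        max_edges = self.n_genes * (self.n_genes - 1) // 2
        if not 1 <= self.target_edges <= max_edges:
            raise ValueError(f"target_edges must be in [1, {max_edges}]")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if not 0 <= self.rewire_fraction <= 1:
            raise ValueError("rewire_fraction must be in [0, 1]")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ValueError("n_de_genes must be in [0, n_genes]")


@dataclass
class GroundTruth:
    """Everything the generator knows: topologies, differential edges,
    planted DE genes, and the linear-model edge weights."""

    true_network: GeneNetwork  # base/control topology
    case_network: GeneNetwork
    true_differential: DifferentialNetwork
    true_de_genes: list[str]
    coefficients: dict[tuple[str, str], float] = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_topology(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> GeneNetwork:
    """Scale-free topology by preferential attachment with an exact edge
    budget.

    Growth starts from a small seed clique; each subsequent node attaches a
    near-constant number of edges to existing nodes chosen with probability
    proportional to their current degree, and any residual budget is filled
    with degree-weighted extra edges.  Deterministic given ``config.seed``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p, target = config.n_genes, config.target_edges
    per_node = target / max(p - 1, 1)
    s = min(p, max(2, int(np.ceil(per_node)) + 1))
    adj = np.zeros((p, p), dtype=np.int8)
    for i in range(s):
        for j in range(i + 1, s):
            adj[i, j] = adj[j, i] = 1
    n_edges = s * (s - 1) // 2

    if p > s and target > n_edges:
        remaining_nodes = p - s
        budget = target - n_edges
        base_m = budget // remaining_nodes
        extra = budget % remaining_nodes
        bonus_nodes = set(rng.choice(remaining_nodes, size=extra, replace=False)
                          ) if extra else set()
        deg = adj.sum(axis=0).astype(float)
        for t in range(s, p):
            m = base_m + (1 if (t - s) in bonus_nodes else 0)
            m = min(m, t)
            if m == 0:
                continue
            probs = deg[:t] / deg[:t].sum()
            targets = rng.choice(t, size=m, replace=False, p=probs)
            for j in targets:
                adj[t, j] = adj[j, t] = 1
                deg[j] += 1
                deg[t] += 1
                n_edges += 1

    # Fill any shortfall (clamped attachments) with degree-weighted extras.
    deg = adj.sum(axis=0).astype(float)
    attempts = 0
    while n_edges < target and attempts < 100 * target:
        attempts += 1
        probs = (deg + 1) / (deg + 1).sum()
        i, j = rng.choice(p, size=2, replace=False, p=probs)
        if adj[i, j] == 0:
            adj[i, j] = adj[j, i] = 1
            deg[i] += 1
            deg[j] += 1
            n_edges += 1
    if abs(n_edges - target) > 0.05 * target:
        raise RuntimeError(
            f"could not realize {target} edges (got {n_edges}); "
            "check target_edges against n_genes"
        )
    return GeneNetwork(_gene_ids(p), adj)


def _draw_weights(
    rng: np.random.Generator, edges: list[tuple[int, int]]
) -> dict[tuple[int, int], float]:
    """Nonzero edge weights with magnitude U[0.3, 0.9] and random sign."""
    mags = rng.uniform(0.3, 0.9, size=len(edges))
    signs = rng.choice((-1.0, 1.0), size=len(edges))
    return {e: float(m * s) for e, m, s in zip(edges, mags, signs)}


def _sample_linear_gaussian(
    n_genes: int,
    weights: dict[tuple[int, int], float],
    n_samples: int,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample from the linear-Gaussian system induced by orienting each edge
    from its lower-index endpoint (the older, hub-prone node) to the higher.

    Root genes are N(0, 1).  Each child is its weighted parent sum rescaled
    to unit empirical variance, plus N(0, sigma^2) — the rescaling keeps
    sigma interpretable as noise relative to a unit-variance regulatory
    signal at every depth of the cascade (SNR = 1/sigma^2)."""
    parents: list[list[tuple[int, float]]] = [[] for _ in range(n_genes)]
    for (i, j), w in weights.items():
        a, b = (i, j) if i < j else (j, i)
        parents[b].append((a, w))
    x = np.empty((n_genes, n_samples))
    for g in range(n_genes):
        if not parents[g]:
            x[g] = rng.normal(0.0, 1.0, size=n_samples)
        else:
            signal = np.zeros(n_samples)
            for parent, w in parents[g]:
                signal += w * x[parent]
            scale = signal.std()
            if scale > 0:
                signal = signal / scale
            x[g] = signal + rng.normal(0.0, sigma, size=n_samples)
    return x


def generate_expression(
    network: GeneNetwork,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Linear-Gaussian expression data for a fixed topology.

    Values are treated as log2-scale intensities (``log_scale=True``), the
    scale on which the downstream pipeline operates."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    index_edges = [
        (network.gene_ids.index(a), network.gene_ids.index(b))
        for a, b in network.edges()
    ]
    weights = _draw_weights(rng, index_edges)
    x = _sample_linear_gaussian(
        network.adjacency.shape[0], weights, config.n_samples,
        config.noise_sigma, rng,
    )
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    return ExpressionMatrix(network.gene_ids, samples, x, log_scale=True)


def generate_case_control(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """A case/control benchmark pair with full ground truth.

    The control condition uses the base scale-free topology.  The case
    topology removes ``round(rewire_fraction * n_edges)`` random edges and
    adds the same number of random non-edges; removed edges are the
    control-specific (negative) truth, added edges the case-specific
    (positive) truth.  ``n_de_genes`` random genes additionally get a
    ``de_shift`` mean increase in the case samples.  Edge weights are shared
    between conditions for edges common to both.
    """
    rng = np.random.default_rng(config.seed)
    base = generate_topology(config, rng)
    genes = base.gene_ids
    p = len(genes)
    base_edges = [
        (genes.index(a), genes.index(b)) for a, b in base.edges()
    ]
    n_rewire = int(round(config.rewire_fraction * len(base_edges)))
    if config.rewire_fraction > 0 and n_rewire == 0:
        raise ValueError(
            "rewire_fraction yields zero rewired edges; use a larger network "
            "or a larger rewire_fraction"
        )

    case_adj = base.adjacency.copy()
    removed: list[tuple[int, int]] = []
    added: list[tuple[int, int]] = []
    if n_rewire:
        pick = rng.choice(len(base_edges), size=n_rewire, replace=False)
        for k in pick:
            i, j = base_edges[k]
            case_adj[i, j] = case_adj[j, i] = 0
            removed.append((i, j))
        existing = set(map(frozenset, base_edges))
        while len(added) < n_rewire:
            i, j = rng.choice(p, size=2, replace=False)
            key = frozenset((int(i), int(j)))
            if key in existing or case_adj[i, j]:
                continue
            case_adj[i, j] = case_adj[j, i] = 1
            added.append((int(i), int(j)))
    case_net = GeneNetwork(genes, case_adj)

    union_edges = sorted(
        {tuple(sorted(e)) for e in base_edges} | {tuple(sorted(e)) for e in added}
    )
    weights = _draw_weights(rng, union_edges)
    control_w = {e: w for e, w in weights.items() if base.adjacency[e[0], e[1]]}
    case_w = {e: w for e, w in weights.items() if case_adj[e[0], e[1]]}

    x_control = _sample_linear_gaussian(
        p, control_w, config.n_samples, config.noise_sigma, rng
    )
    x_case = _sample_linear_gaussian(
        p, case_w, config.n_samples, config.noise_sigma, rng
    )
    de_idx = (
        sorted(rng.choice(p, size=config.n_de_genes, replace=False).tolist())
        if config.n_de_genes
        else []
    )
    x_case[de_idx, :] += config.de_shift

    control = ExpressionMatrix(
        genes, [f"ctrl{i:04d}" for i in range(config.n_samples)],
        x_control, log_scale=True,
    )
    case = ExpressionMatrix(
        genes, [f"case{i:04d}" for i in range(config.n_samples)],
        x_case, log_scale=True,
    )
    diff_edges = {
        _canonical_edge(genes[i], genes[j]): NEGATIVE for i, j in removed
    }
    diff_edges.update(
        {_canonical_edge(genes[i], genes[j]): POSITIVE for i, j in added}
    )
    truth = GroundTruth(
        true_network=base,
        case_network=case_net,
        true_differential=DifferentialNetwork(genes, diff_edges),
        true_de_genes=[genes[i] for i in de_idx],
        coefficients={
            _canonical_edge(genes[i], genes[j]): w
            for (i, j), w in weights.items()
        },
    )
    return case, control, truth


def combine_case_control(
    case: ExpressionMatrix, control: ExpressionMatrix
) -> tuple[ExpressionMatrix, SampleLabels]:
    """Concatenate a case and a control matrix into one labeled dataset."""
    if case.gene_ids != control.gene_ids:
        raise ValueError("case and control matrices must share gene IDs")
    values = np.hstack([case.values, control.values])
    samples = list(case.sample_ids) + list(control.sample_ids)
    expr = ExpressionMatrix(case.gene_ids, samples, values,
                            case.log_scale and control.log_scale)
    labels = SampleLabels(
        samples, [CASE] * case.n_samples + [CONTROL] * control.n_samples
    )
    return expr, labels
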