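"""End-to-end differential-network analysis.

Chains the five pipeline stages: differential-expression screening,
per-condition network inference by posterior-scored boosting, network
subtraction, hub detection, and GeneRank/degree prioritization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import diffnet, inference, prioritize
from .io import CASE, CONTROL, DifferentialNetwork, ExpressionMatrix, GeneNetwork, SampleLabels
from .preprocess import DEResult, differential_expression, filter_de_genes


@dataclass
class NetsamResult:
    de: DEResult
    de_genes: list[str]
    case_network: GeneNetwork
    control_network: GeneNetwork
    differential: DifferentialNetwork
    hubs: list[str]
    generank_list: prioritize.RankedGeneList | None
    degree_list: prioritize.RankedGeneList | None
    signature: list[str]


def run_netsam(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    boost_config: inference.BoostingConfig | None = None,
    hub_criteria: diffnet.HubCriteria | None = None,
    generank_config: prioritize.GeneRankConfig | None = None,
    top_k: int = 10,
    skip_de_filter: bool = False,
) -> NetsamResult:
    """Run the full differential-network pipeline on one labeled dataset.

    ``skip_de_filter`` keeps every gene in the inference panel (useful on
    benchmarks where the topology over all genes is the evaluation target);
    the DE statistics are computed either way, since hub detection and
    GeneRank consume them.
    """
    de = differential_expression(expr, labels, fc_threshold, p_threshold)
    de_genes = filter_de_genes(de, fc_threshold, p_threshold)
    panel = list(expr.gene_ids) if skip_de_filter else de_genes
    if len(panel) < 2:
        raise ValueError(
            f"only {len(panel)} gene(s) pass the DE filter; cannot infer a "
            "network — relax the thresholds or check the input data"
        )
    sub = expr.subset_genes(panel)
    case_expr = sub.subset_samples(labels.ids_for(CASE))
    control_expr = sub.subset_samples(labels.ids_for(CONTROL))

    case_net, _ = inference.infer_network(case_expr, boost_config)
    control_net, _ = inference.infer_network(control_expr, boost_config)
    # standardize() may drop zero-variance genes per condition; align universes
    common = [g for g in panel
              if g in set(case_net.gene_ids) and g in set(control_net.gene_ids)]
    case_net = _restrict(case_net, common)
    control_net = _restrict(control_net, common)

    diff = diffnet.subtract_networks(case_net, control_net)
    hubs = diffnet.identify_hubs(diff, de, hub_criteria)

    generank_list = degree_list = None
    signature: list[str] = []
    if hubs and diff.n_edges:
        idx = {g: i for i, g in enumerate(de.gene_ids)}
        change = de.abs_log2_fold_change()
        expr_change = np.array([change[idx[g]] for g in diff.gene_ids])
        if expr_change.sum() > 0:
            generank_list = prioritize.generank_ranking(
                diff, expr_change, generank_config, restrict_to=hubs
            )
            degree_list = prioritize.degree_ranking(diff, restrict_to=hubs)
            signature = prioritize.intersect_top_k(generank_list, degree_list, top_k)
    return NetsamResult(
        de=de,
        de_genes=de_genes,
        case_network=case_net,
        control_network=control_net,
        differential=diff,
        hubs=hubs,
        generank_list=generank_list,
        degree_list=degree_list,
        signature=signature,
    )


def _restrict(net: GeneNetwork, genes: list[str]) -> GeneNetwork:
    idx = [net.gene_ids.index(g) for g in genes]
    return GeneNetwork(genes, net.adjacency[np.ix_(idx, idx)])
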