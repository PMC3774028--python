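"""Benchmark metrics and gene-based comparison baselines.

Edge recovery is scored against the known topology via ROC/AUC, PPV
(precision) and FDR curves.  Gene-based baselines (|t| and lasso) are
lifted to the edge metric by scoring each gene pair with the weaker of its
two endpoint scores.  The module also provides the robustness-vs-noise
sweep and the overlap-ratio concordance measure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.linear_model import Lasso

from .inference import BoostingConfig, boosting_fit, edge_confidence, standardize
from .io import CASE, DifferentialNetwork, ExpressionMatrix, GeneNetwork, SampleLabels
from .preprocess import differential_expression
from .simulate import SimulationConfig, generate_case_control


@dataclass
class EvaluationResult:
    """Edge-recovery metrics: ROC points, AUC, and precision/FDR curves
    indexed by recall."""

    roc_points: list[tuple[float, float]]
    auc: float
    ppv_curve: list[tuple[float, float]]
    fdr_curve: list[tuple[float, float]]
    overlap_ratio: float | None = None


def _upper_triangle(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def edge_recovery_metrics(
    predicted_scores: np.ndarray | Sequence[float],
    truth: GeneNetwork,
) -> EvaluationResult:
    """Score a per-pair edge ranking against a known network.

    ``predicted_scores`` is either a symmetric p x p score matrix aligned
    with ``truth.gene_ids`` or a flat vector over the upper-triangle pairs
    (row-major).  Thresholds sweep the distinct score values, grouping ties;
    AUC is the trapezoidal area under the ROC.
    """
    y_true = _upper_triangle(truth.adjacency).astype(int)
    scores = np.asarray(predicted_scores, dtype=float)
    if scores.ndim == 2:
        if scores.shape != truth.adjacency.shape:
            raise ValueError("score matrix must match the truth adjacency shape")
        scores = _upper_triangle(scores)
    if scores.shape != y_true.shape:
        raise ValueError("need one score per unordered gene pair")
    n_pos = int(y_true.sum())
    if n_pos == 0 or n_pos == y_true.size:
        raise ValueError("truth must contain both edges and non-edges")

    fpr, tpr, _ = skmetrics.roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    hits = np.cumsum(y_true[order])
    k = np.arange(1, scores.size + 1)
    # evaluate at the last index of each distinct score (tie groups together)
    cut = np.nonzero(np.diff(sorted_scores, append=-np.inf))[0]
    ppv = hits[cut] / k[cut]
    recall = hits[cut] / n_pos
    ppv_curve = list(zip(recall.tolist(), ppv.tolist()))
    fdr_curve = [(r, 1.0 - v) for r, v in ppv_curve]
    return EvaluationResult(
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        ppv_curve=ppv_curve,
        fdr_curve=fdr_curve,
    )


def overlap_ratio(identified: Sequence[str], reference: Iterable[str]) -> float:
    """|identified ∩ reference| / |identified|."""
    identified = list(identified)
    if not identified:
        raise ValueError("identified gene list must be non-empty")
    ref = set(reference)
    return sum(1 for g in identified if g in ref) / len(identified)


# ---------------------------------------------------------------------------
# Gene-based baselines
# ---------------------------------------------------------------------------

def pair_scores_from_gene_scores(gene_scores: np.ndarray) -> np.ndarray:
    """Lift per-gene scores to per-pair scores: a pair is as credible as its
    weaker endpoint, ``min(s_i, s_j)``."""
    s = np.asarray(gene_scores, dtype=float)
    pair = np.minimum.outer(s, s)
    np.fill_diagonal(pair, 0.0)
    return pair


def baseline_ttest_rank(
    expr: ExpressionMatrix, labels: SampleLabels
) -> np.ndarray:
    """Per-gene |t| scores from the case/control Student t-test."""
    de = differential_expression(expr, labels)
    t = np.abs(de.t_statistic)
    # infinite t (zero pooled variance, unequal means) still ranks first
    finite_max = np.nanmax(np.where(np.isfinite(t), t, 0.0))
    return np.where(np.isfinite(t), t, finite_max + 1.0)


def baseline_lasso_rank(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    regularization: float = 0.01,
) -> np.ndarray:
    """Per-gene |coefficient| from the lasso regression of the +/-1 group
    label on z-scored gene expression.

    ``regularization`` is the L1 penalty in the objective
    ``1/(2n) ||y - Xb||^2 + regularization * ||b||_1``.  A zero penalty
    falls back to the least-squares solution.
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    lab = dict(zip(labels.sample_ids, labels.group))
    y = np.array([1.0 if lab[s] == CASE else -1.0 for s in expr.sample_ids])
    x = expr.values.T  # samples x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    if regularization == 0:
        coef, *_ = np.linalg.lstsq(x, y - y.mean(), rcond=None)
    else:
        model = Lasso(alpha=regularization, fit_intercept=True, max_iter=50000)
        model.fit(x, y)
        coef = model.coef_
    return np.abs(coef)


# ---------------------------------------------------------------------------
# Benchmark drivers
# ---------------------------------------------------------------------------

def netsam_edge_scores(
    expr: ExpressionMatrix, config: BoostingConfig | None = None
) -> np.ndarray:
    """Edge-confidence matrix of the boosting inference on one dataset."""
    std = standardize(expr)
    beta = boosting_fit(std, config)
    return edge_confidence(beta)


def benchmark_replicate(
    sim_config: SimulationConfig,
    boost_config: BoostingConfig | None = None,
    lasso_regularization: float = 0.01,
) -> dict[str, float]:
    """One benchmark replicate: simulate a case/control pair and score all
    three methods against the control-condition topology.

    The network method infers from the control samples; the gene-based
    baselines see the combined labeled dataset and are lifted to pair
    scores by the min-of-endpoints rule.
    """
    from .simulate import combine_case_control

    case, control, truth = generate_case_control(sim_config)
    net_scores = netsam_edge_scores(control, boost_config)
    combined, labels = combine_case_control(case, control)
    t_scores = pair_scores_from_gene_scores(baseline_ttest_rank(combined, labels))
    l_scores = pair_scores_from_gene_scores(
        baseline_lasso_rank(combined, labels, lasso_regularization)
    )
    return {
        "netsam": edge_recovery_metrics(net_scores, truth.true_network).auc,
        "ttest": edge_recovery_metrics(t_scores, truth.true_network).auc,
        "lasso": edge_recovery_metrics(l_scores, truth.true_network).auc,
    }


def benchmark(
    n_replicates: int = 10,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
    boost_config: BoostingConfig | None = None,
    lasso_regularization: float = 0.01,
) -> dict[str, list[float]]:
    """Edge-recovery AUC of netSAM and both baselines over seeded
    replicates.  Replicate r uses simulation seed ``seed + r``."""
    sim_config = sim_config or SimulationConfig()
    out: dict[str, list[float]] = {"netsam": [], "ttest": [], "lasso": []}
    for r in range(n_replicates):
        rep = benchmark_replicate(
            replace(sim_config, seed=seed + r), boost_config, lasso_regularization
        )
        for k, v in rep.items():
            out[k].append(v)
    return out


def robustness_curve(
    configs: Sequence[SimulationConfig],
    n_replicates: int = 3,
    boost_config: BoostingConfig | None = None,
) -> list[tuple[float, float, float]]:
    """AUC vs signal-to-noise ratio across noise levels.

    For each config, ``n_replicates`` independent simulations are inferred
    and scored; SNR is the mean per-gene signal variance (total variance
    minus the noise floor) divided by ``noise_sigma**2``.  Returns
    ``(snr, mean_auc, sd_auc)`` per config.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    out = []
    for cfg in configs:
        aucs = []
        snrs = []
        for r in range(n_replicates):
            c = replace(cfg, seed=cfg.seed + r)
            _, control, truth = generate_case_control(c)
            scores = netsam_edge_scores(control, boost_config)
            aucs.append(edge_recovery_metrics(scores, truth.true_network).auc)
            total_var = control.values.var(axis=1).mean()
            signal_var = max(total_var - c.noise_sigma**2, 0.0)
            snrs.append(signal_var / c.noise_sigma**2)
        out.append(
            (float(np.mean(snrs)), float(np.mean(aucs)), float(np.std(aucs, ddof=1)))
        )
    return out


def differential_edge_recall(
    predicted: DifferentialNetwork, truth: DifferentialNetwork
) -> float:
    """Fraction of true differential edges present in the prediction."""
    if truth.n_edges == 0:
        raise ValueError("truth has no differential edges")
    hit = sum(1 for e in truth.edges if e in predicted.edges)
    return hit / truth.n_edges


def degree_matched_random_recall(
    predicted: DifferentialNetwork,
    truth: DifferentialNetwork,
    seed: int = 0,
    n_draws: int = 50,
) -> float:
    """Mean recall of random edge sets matched in size and degree profile.

    Each draw samples ``predicted.n_edges`` distinct pairs with endpoint
    probabilities proportional to the predicted network's degrees (plus
    one), giving a null with the same hub structure but no signal.
    """
    rng = np.random.default_rng(seed)
    genes = predicted.gene_ids
    p = len(genes)
    deg = np.array([predicted.degrees()[g] for g in genes], dtype=float) + 1.0
    probs = deg / deg.sum()
    truth_edges = set(truth.edges)
    n_edges = predicted.n_edges
    if n_edges == 0:
        return 0.0
    recalls = []
    for _ in range(n_draws):
        chosen: set[tuple[str, str]] = set()
        guard = 0
        while len(chosen) < n_edges and guard < 100 * n_edges:
            guard += 1
            i, j = rng.choice(p, size=2, replace=False, p=probs)
            a, b = sorted((genes[i], genes[j]))
            chosen.add((a, b))
        recalls.append(sum(1 for e in truth_edges if e in chosen) / len(truth_edges))
    return float(np.mean(recalls))
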