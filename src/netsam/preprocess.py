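"""Differential-expression screening (pipeline step 1).

Genes are screened by two criteria computed between case and control
samples on log2-scale data: linear-scale fold change ``2**|mean_case -
mean_control|`` and the two-sided Student's t-test p-value.  A gene is
retained when fold change exceeds ``fc_threshold`` (default 2) and p falls
below ``p_threshold`` (default 0.01), both strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CASE, CONTROL, ExpressionMatrix, SampleLabels

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-gene differential-expression statistics (log2-scale input)."""

    gene_ids: list[str]
    mean_case: np.ndarray
    mean_control: np.ndarray
    fold_change: np.ndarray  # linear scale, >= 1 by symmetric definition
    t_statistic: np.ndarray
    p_value: np.ndarray
    pass_filter: np.ndarray  # at the thresholds given to differential_expression

    def p_value_for(self, gene_id: str) -> float:
        try:
            return float(self.p_value[self.gene_ids.index(gene_id)])
        except ValueError as exc:
            raise KeyError(f"gene {gene_id!r} missing from DE results") from exc

    def abs_log2_fold_change(self) -> np.ndarray:
        """|log2 fold change| per gene (the GeneRank expression-change input)."""
        return np.abs(self.mean_case - self.mean_control)


def differential_expression(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    welch: bool = False,
) -> DEResult:
    """Two-sample t-test and fold change per gene, case vs control.

    Uses the equal-variance (Student) t-test by default; set ``welch`` for
    the unequal-variance variant.  Fold change is symmetric,
    ``2**|delta log2 mean|``, so down-regulated genes are captured too.
    Degenerate genes whose pooled variance is zero get ``p = 1`` when the
    group means agree and ``p = 0`` (infinite t) otherwise; the latter is
    logged.
    """
    if not expr.log_scale:
        raise ValueError("differential_expression requires log2-scale data")
    labels.validate_against(expr, min_per_group=2)
    lab = dict(zip(labels.sample_ids, labels.group))
    case_idx = [i for i, s in enumerate(expr.sample_ids) if lab[s] == CASE]
    ctrl_idx = [i for i, s in enumerate(expr.sample_ids) if lab[s] == CONTROL]
    xc = expr.values[:, case_idx]
    xk = expr.values[:, ctrl_idx]

    mean_case = xc.mean(axis=1)
    mean_control = xk.mean(axis=1)
    delta = mean_case - mean_control
    fold_change = 2.0 ** np.abs(delta)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_val = stats.ttest_ind(xc, xk, axis=1, equal_var=not welch)
    t_stat = np.asarray(t_stat, dtype=float)
    p_val = np.asarray(p_val, dtype=float)

    # Zero pooled variance: the t statistic is 0/0 (NaN).  Equal means are a
    # perfect null (p=1); unequal means separate the groups perfectly (p=0).
    degenerate = ~np.isfinite(t_stat)
    if degenerate.any():
        equal = degenerate & np.isclose(delta, 0.0)
        sep = degenerate & ~np.isclose(delta, 0.0)
        t_stat[equal] = 0.0
        p_val[equal] = 1.0
        t_stat[sep] = np.sign(delta[sep]) * np.inf
        p_val[sep] = 0.0
        if sep.any():
            genes = [expr.gene_ids[i] for i in np.nonzero(sep)[0][:5]]
            logger.warning(
                "%d gene(s) with zero pooled variance but unequal means "
                "(p set to 0), e.g. %s", int(sep.sum()), genes
            )

    pass_filter = (fold_change > fc_threshold) & (p_val < p_threshold)
    return DEResult(
        gene_ids=list(expr.gene_ids),
        mean_case=mean_case,
        mean_control=mean_control,
        fold_change=fold_change,
        t_statistic=t_stat,
        p_value=p_val,
        pass_filter=pass_filter,
    )


def filter_de_genes(
    de: DEResult, fc_threshold: float = 2.0, p_threshold: float = 0.01
) -> list[str]:
    """Genes with fold change strictly above ``fc_threshold`` and p strictly
    below ``p_threshold``, in input gene order."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    keep = (de.fold_change > fc_threshold) & (de.p_value < p_threshold)
    return [g for g, k in zip(de.gene_ids, keep) if k]
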