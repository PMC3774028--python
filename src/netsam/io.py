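"""Core domain types and plain-text readers/writers.

Expression matrices are genes-by-samples TSV tables (first column gene IDs,
header row sample IDs).  Networks are written as SIF-compatible 2- or
3-column edge lists.  All formats round-trip bit-exactly through
``repr``-precision floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

POSITIVE = "positive"  # case-specific edge (inducible)
NEGATIVE = "negative"  # control-specific edge (suppressive)

CASE = "case"
CONTROL = "control"


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued expression matrix.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row of ``values``.
    sample_ids
        Unique sample identifiers, one per column of ``values``.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))``; must be
        finite.
    log_scale
        True when values are on the log2 scale (required by the
        differential-expression step).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        p, n = self.values.shape
        if p != len(self.gene_ids) or n != len(self.sample_ids):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene IDs must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample IDs must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/Inf)")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return the sub-matrix restricted to ``gene_ids`` (in that order)."""
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), self.sample_ids, self.values[idx], self.log_scale
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.gene_ids, list(sample_ids), self.values[:, idx], self.log_scale
        )


@dataclass
class SampleLabels:
    """Case/control assignment for the samples of an expression matrix."""

    sample_ids: list[str]
    group: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.group = list(self.group)
        if len(self.sample_ids) != len(self.group):
            raise ValueError("sample_ids and group must have equal length")
        bad = sorted({g for g in self.group} - {CASE, CONTROL})
        if bad:
            raise ValueError(f"labels must be '{CASE}' or '{CONTROL}', got {bad}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample IDs must be unique")

    def ids_for(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group) if g == group]

    def validate_against(self, expr: ExpressionMatrix, min_per_group: int = 1) -> None:
        missing = set(expr.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"unlabeled samples: {sorted(missing)[:5]}")
        for grp in (CASE, CONTROL):
            n = sum(1 for s, g in zip(self.sample_ids, self.group)
                    if g == grp and s in set(expr.sample_ids))
            if n < min_per_group:
                raise ValueError(
                    f"group '{grp}' has {n} labeled samples; need >= {min_per_group}"
                )


@dataclass
class GeneNetwork:
    """Undirected, unweighted gene network as a binary adjacency matrix."""

    gene_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.adjacency = np.asarray(self.adjacency)
        p = len(self.gene_ids)
        if self.adjacency.shape != (p, p):
            raise ValueError("adjacency must be p x p")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = self.adjacency.astype(np.int8)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[str, str]]:
        """Undirected edges with endpoints in lexicographic order."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        out = []
        for i, j in zip(ii, jj):
            a, b = sorted((self.gene_ids[i], self.gene_ids[j]))
            out.append((a, b))
        return sorted(out)

    def degrees(self) -> dict[str, int]:
        deg = self.adjacency.sum(axis=0)
        return {g: int(d) for g, d in zip(self.gene_ids, deg)}


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-edge on gene {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class DifferentialNetwork:
    """Edges present in exactly one of two condition-specific networks.

    Each edge carries a sign: ``positive`` for case-specific (inducible)
    interactions, ``negative`` for control-specific (suppressive) ones.
    """

    gene_ids: list[str]
    edges: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        universe = set(self.gene_ids)
        canon: dict[tuple[str, str], str] = {}
        for (a, b), sign in self.edges.items():
            if sign not in (POSITIVE, NEGATIVE):
                raise ValueError(f"edge sign must be positive/negative, got {sign!r}")
            if a not in universe or b not in universe:
                raise ValueError(f"edge ({a}, {b}) outside the gene universe")
            canon[_canonical_edge(a, b)] = sign
        self.edges = canon

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.gene_ids}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def signed_edges(self) -> list[tuple[str, str, str]]:
        return sorted((a, b, s) for (a, b), s in self.edges.items())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, log_transform: bool = False) -> ExpressionMatrix:
    """Load a genes x samples TSV table.

    The first column holds gene IDs, the header row sample IDs.  With
    ``log_transform`` the (strictly positive) intensities are replaced by
    their log2 and the matrix is flagged ``log_scale``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise LoadError(f"{path}: cannot parse expression table: {exc}") from exc
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise LoadError(f"{path}: duplicate gene IDs: {dups[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise LoadError(f"{path}: non-numeric expression value: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise LoadError(f"{path}: expression values must be finite")
    if log_transform:
        if np.any(values <= 0):
            raise LoadError(
                f"{path}: log2 transform requires strictly positive values"
            )
        values = np.log2(values)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
        log_scale=log_transform,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")  # bit-exact round trip


def read_labels(path: str | Path) -> SampleLabels:
    """Load a 2-column TSV (sample_id, group) with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise LoadError(f"{path}: label file needs 2 columns (sample_id, group)")
    return SampleLabels(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "group": labels.group}).to_csv(
        path, sep="\t", index=False
    )


def write_edge_list(
    network: GeneNetwork | DifferentialNetwork, path: str | Path
) -> None:
    """Write one line per undirected edge, endpoints in lexicographic order.

    ``GeneNetwork`` -> 2 columns; ``DifferentialNetwork`` -> 3 columns with
    the sign tag.  A header line is always written.
    """
    path = Path(path)
    with path.open("w") as fh:
        if isinstance(network, DifferentialNetwork):
            fh.write("gene_a\tgene_b\tsign\n")
            for a, b, sign in network.signed_edges():
                fh.write(f"{a}\t{b}\t{sign}\n")
        else:
            fh.write("gene_a\tgene_b\n")
            for a, b in network.edges():
                fh.write(f"{a}\t{b}\n")


def read_network(path: str | Path, gene_ids: Sequence[str] | None = None) -> GeneNetwork:
    """Read a 2-column edge list back into a :class:`GeneNetwork`.

    When ``gene_ids`` is omitted the gene universe is the sorted set of
    endpoints appearing in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
    if gene_ids is None:
        gene_ids = sorted({g for pair in pairs for g in pair})
    gene_ids = list(gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    adj = np.zeros((len(gene_ids), len(gene_ids)), dtype=np.int8)
    for a, b in pairs:
        i, j = index[a], index[b]
        adj[i, j] = adj[j, i] = 1
    return GeneNetwork(gene_ids, adj)


def read_differential_network(
    path: str | Path, gene_ids: Sequence[str] | None = None
) -> DifferentialNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise LoadError(f"{path}: differential edge list needs a sign column")
    edges = {
        _canonical_edge(str(a), str(b)): str(s)
        for a, b, s in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
    }
    if gene_ids is None:
        gene_ids = sorted({g for pair in edges for g in pair})
    return DifferentialNetwork(list(gene_ids), edges)


def write_ranked_genes(table: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked-gene table (gene, generank_score, degree, rank...)."""
    table.to_csv(path, sep="\t", index=False)
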