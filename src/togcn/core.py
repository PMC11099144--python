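"""TO-GCN construction: PCC matrix, empirical cutoff, BFS time-ordering.

The time-ordered co-expression network is built in three steps: compute
Pearson correlations between all TF gene pairs, threshold them at an
empirically determined cutoff (right tail of the pairwise PCC
distribution), and stratify the resulting graph into levels by
breadth-first search from a seed TF assumed to be the first up-regulated.
The seed and its direct neighbors form level 1; nodes at graph distance k
from the seed form level k.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix

__all__ = [
    "PCCMatrix",
    "CoexpressionNetwork",
    "TOGCN",
    "LevelGeneSets",
    "compute_pcc_matrix",
    "determine_cutoff",
    "build_gcn",
    "assign_levels_bfs",
    "assign_level_gene_sets",
    "mean_zscore_profile",
]


@dataclass(frozen=True)
class PCCMatrix:
    """Symmetric Pearson-correlation matrix over non-constant genes."""

    gene_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    constant_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("PCC matrix shape does not match gene list")
        if n and not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("PCC matrix is not symmetric")
        if n and not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("PCC matrix diagonal is not 1")

    def pairwise_values(self) -> np.ndarray:
        """Strictly upper-triangular PCC values as a flat array."""
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return self.values[iu]

    def get(self, a: str, b: str) -> float:
        i = self.gene_ids.index(a)
        j = self.gene_ids.index(b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class CoexpressionNetwork:
    """Undirected co-expression graph; edges are PCC >= cutoff pairs."""

    graph: nx.Graph = field(repr=False)
    cutoff: float = 0.9

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def isolated_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.degree(n) == 0]


@dataclass(frozen=True)
class TOGCN:
    """A leveled co-expression network: node -> 1-based BFS level."""

    network: CoexpressionNetwork
    seed: str
    levels: dict[str, int]
    unreached: frozenset[str]

    @property
    def n_levels(self) -> int:
        return max(self.levels.values()) if self.levels else 0

    def genes_at_level(self, level: int) -> list[str]:
        return sorted(g for g, lv in self.levels.items() if lv == level)

    def level_table(self) -> pd.DataFrame:
        rows = sorted(self.levels.items())
        return pd.DataFrame(rows, columns=["gene", "level"])


#: level -> set of co-expressed gene IDs (a gene may appear at many levels)
LevelGeneSets = dict[int, set[str]]


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale rows to zero mean, unit population SD; flag constants."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    constant = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    sd[sd == 0] = 1.0
    return (x - mu) / sd, constant


def compute_pcc_matrix(
    m: ExpressionMatrix, genes: Iterable[str] | None = None
) -> PCCMatrix:
    """Pearson correlations between all pairs of the requested genes.

    Genes with constant profiles (zero variance) are excluded from the
    matrix and reported in ``constant_genes``. Requires >= 3 columns.
    """
    if m.shape[1] < 3:
        raise ValueError(f"need >= 3 samples to compute PCC, got {m.shape[1]}")
    if genes is None:
        genes = m.gene_ids
    genes = list(genes)
    missing = [g for g in genes if g not in m.data.index]
    if missing:
        raise KeyError(f"gene not in matrix: {missing[0]!r}")
    x = m.data.loc[genes].to_numpy(dtype=float)
    z, constant = _standardize_rows(x)
    kept = [g for g, c in zip(genes, constant) if not c]
    dropped = tuple(g for g, c in zip(genes, constant) if c)
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} constant-profile gene(s) from PCC",
            stacklevel=2,
        )
    zk = z[~constant]
    r = (zk @ zk.T) / x.shape[1]
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return PCCMatrix(tuple(kept), r, dropped)


def determine_cutoff(p: PCCMatrix, alpha: float = 0.05) -> float:
    """Empirical co-expression cutoff from the pairwise PCC distribution.

    Returns the nearest-rank ``1 - alpha`` quantile of the strictly
    upper-triangular PCC values: the ascending order statistic at rank
    ``ceil((1 - alpha) * n_pairs)``. The returned value is always a
    realized pairwise PCC, and the fraction of pairs strictly above it is
    at most ``alpha`` (right-tail p < alpha, with equality only when
    ``(1 - alpha) * n_pairs`` is an exact integer and there are no ties).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if len(p.gene_ids) < 2:
        raise ValueError("need >= 2 genes to determine a cutoff")
    pairs = np.sort(p.pairwise_values())
    rank = math.ceil((1.0 - alpha) * pairs.size)
    return float(pairs[rank - 1])


def build_gcn(p: PCCMatrix, cutoff: float) -> CoexpressionNetwork:
    """Threshold the PCC matrix into an undirected co-expression graph.

    All genes are kept as nodes; pairs with PCC >= cutoff become edges
    (closed threshold). Isolated nodes are allowed.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    g = nx.Graph()
    g.add_nodes_from(p.gene_ids)
    ids = p.gene_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    sel = p.values[iu, ju] >= cutoff
    g.add_weighted_edges_from(
        (ids[i], ids[j], float(p.values[i, j])) for i, j in zip(iu[sel], ju[sel])
    )
    return CoexpressionNetwork(g, cutoff)


def assign_levels_bfs(g: CoexpressionNetwork, seed: str) -> TOGCN:
    """Assign time-order levels by breadth-first search from ``seed``.

    The seed and its direct neighbors are level 1; nodes at shortest-path
    distance k >= 2 from the seed are level k (level = max(1, distance)).
    Nodes unreachable from the seed are reported in ``unreached`` and
    carry no level.
    """
    graph = g.graph
    if seed not in graph:
        raise KeyError(f"seed {seed!r} is not a node of the network")
    dist = {seed: 0}
    queue = deque([seed])
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    levels = {node: max(1, d) for node, d in dist.items()}
    unreached = frozenset(graph.nodes) - levels.keys()
    if graph.degree(seed) == 0:
        warnings.warn(f"seed {seed!r} is isolated; only the seed is leveled", stacklevel=2)
    return TOGCN(g, seed, levels, unreached)


def assign_level_gene_sets(
    m: ExpressionMatrix,
    t: TOGCN,
    cutoff: float,
    candidates: Iterable[str],
) -> LevelGeneSets:
    """Attach co-expressed candidate genes to each TO-GCN level.

    A candidate joins level L iff its PCC with at least one TF leveled L
    is >= cutoff. A gene may belong to several levels, so neighboring
    level sets can overlap.
    """
    candidates = list(candidates)
    result: LevelGeneSets = {lv: set() for lv in range(1, t.n_levels + 1)}
    if not candidates:
        warnings.warn("empty candidate set; all level gene sets empty", stacklevel=2)
        return result
    tfs = [g for g in t.levels if g in m.data.index]
    missing = [g for g in candidates if g not in m.data.index]
    if missing:
        raise KeyError(f"candidate gene not in matrix: {missing[0]!r}")
    n = m.shape[1]
    zc, const_c = _standardize_rows(m.data.loc[candidates].to_numpy(dtype=float))
    zt, const_t = _standardize_rows(m.data.loc[tfs].to_numpy(dtype=float))
    r = (zc @ zt.T) / n  # candidates x TFs
    r[const_c, :] = -np.inf
    r[:, const_t] = -np.inf
    passing = r >= cutoff
    tf_levels = np.array([t.levels[g] for g in tfs])
    for ci, gene in enumerate(candidates):
        for lv in np.unique(tf_levels[passing[ci]]):
            result[int(lv)].add(gene)
    return result


def mean_zscore_profile(m: ExpressionMatrix, t: TOGCN) -> pd.DataFrame:
    """Per-level mean z-score profile across ordered conditions.

    Each leveled TF's profile is standardized to zero mean and unit
    population SD across the matrix columns (expected to be ordered
    condition means); the level profile is the arithmetic mean of its
    members' z-vectors. Constant-profile TFs are excluded with a warning.
    """
    rows: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for gene, level in t.levels.items():
        if gene not in m.data.index:
            raise KeyError(f"leveled TF {gene!r} not in matrix")
        x = m.data.loc[gene].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            warnings.warn(f"constant-profile TF {gene!r} excluded from z-scores", stacklevel=2)
            continue
        z = (x - x.mean()) / sd
        rows[level] = rows.get(level, 0) + z
        counts[level] = counts.get(level, 0) + 1
    profile = {lv: rows[lv] / counts[lv] for lv in rows}
    out = pd.DataFrame.from_dict(profile, orient="index", columns=m.sample_ids)
    return out.sort_index()


def write_edge_list(g: CoexpressionNetwork, path) -> None:
    rows = sorted((min(a, b), max(a, b), g.graph[a][b]["weight"]) for a, b in g.edges)
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc"]).to_csv(path, sep="\t", index=False)


def write_levels(t: TOGCN, path) -> None:
    t.level_table().to_csv(path, sep="\t", index=False)


def read_levels(path) -> dict[str, int]:
    t = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return dict(zip(t["gene"], t["level"].astype(int)))


def write_level_sets(sets: LevelGeneSets, path) -> None:
    rows = [(lv, g) for lv in sorted(sets) for g in sorted(sets[lv])]
    pd.DataFrame(rows, columns=["level", "gene"]).to_csv(path, sep="\t", index=False)


def read_level_sets(path) -> LevelGeneSets:
    t = pd.read_csv(path, sep="\t", dtype={"gene": str})
    out: LevelGeneSets = {}
    for lv, grp in t.groupby("level"):
        out[int(lv)] = set(grp["gene"])
    return out
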