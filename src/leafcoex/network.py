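"""Rank-based coexpression network construction.

The network is built from an RPKM matrix in three steps:

1. Pearson product-moment correlation ``cc`` between every pair of gene
   profiles.  A zero-variance profile has no defined correlation; such
   entries are carried as an explicit "undefined" marker (NaN), never as 0.
2. Per-gene neighbour ranking: each gene sorts all other genes by descending
   ``cc`` (ties broken by ascending gene_id); ``rank(g, h)`` is the 1-based
   position of *h* in *g*'s list and is generally asymmetric.
3. Edge selection under two parameters: an edge (g, h) exists iff
   ``cc(g, h) > min_cc`` (default 0.95, strict) and the rank condition holds
   — by default *either* ``rank(g, h) <= max_rank`` *or*
   ``rank(h, g) <= max_rank`` (default 50); a stricter both-directions mode
   (mutual rank) is available.

The high correlation floor keeps only strongly mutually coexpressed genes,
while the generous rank cap keeps, for each gene, the largest subset of its
most correlated partners.  With only four gradient zones per profile the
null distribution of ``cc`` is wide (uniform on [-1, 1] for independent
profiles), which is why the floor is stringent.

:class:`CoexpressionNetwork` is the estimator form (``fit`` on a genes x
zones matrix, fitted graph in ``graph_``); :func:`build_network` is the
functional wrapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .catalog_io import ExpressionTable
from .errors import DimensionError, DuplicateGeneError, ParameterError

__all__ = [
    "NetworkParams",
    "CoexpressionNetwork",
    "pearson_cc",
    "correlation_matrix",
    "rank_neighbors",
    "build_network",
    "graph_stats",
    "write_sif",
    "write_graphml",
    "write_edgelist",
]

RANK_MODES = ("either_direction", "both_directions")


@dataclass(frozen=True)
class NetworkParams:
    """Edge-selection parameters of the rank-based construction."""

    min_cc: float = 0.95
    max_rank: int = 50
    rank_mode: str = "either_direction"

    def __post_init__(self) -> None:
        if not -1.0 <= self.min_cc <= 1.0:
            raise ParameterError(f"min_cc must be in [-1, 1], got {self.min_cc}")
        if self.max_rank < 0 or int(self.max_rank) != self.max_rank:
            raise ParameterError(
                f"max_rank must be a non-negative integer, got {self.max_rank}"
            )
        if self.rank_mode not in RANK_MODES:
            raise ParameterError(
                f"rank_mode must be one of {RANK_MODES}, got {self.rank_mode!r}"
            )


def pearson_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two profiles.

    Returns NaN ("undefined") when either profile has zero variance — a
    constant profile carries no pattern to correlate.  Raises
    :class:`DimensionError` on length mismatch or fewer than two samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise DimensionError(f"profiles must be equal-length 1-D, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise DimensionError(f"profiles need length >= 2, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / math.sqrt(sx * sy), -1.0, 1.0))


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionTable):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise DimensionError("expression matrix must be 2-D")
    return pd.DataFrame(arr, index=[f"G{i}" for i in range(arr.shape[0])])


def correlation_matrix(matrix) -> pd.DataFrame:
    """All-pairs Pearson correlation of gene profiles (genes x genes).

    Symmetric with unit diagonal for defined rows; rows/columns involving a
    zero-variance profile are NaN (undefined), including their diagonal.
    """
    df = _as_frame(matrix)
    if df.shape[1] < 2:
        raise DimensionError("need at least 2 zones to correlate profiles")
    arr = df.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=1, keepdims=True)
    ss = (centered * centered).sum(axis=1)
    defined = ss > 0.0
    norm = np.sqrt(np.where(defined, ss, 1.0))
    unit = centered / norm[:, None]
    cc = np.clip(unit @ unit.T, -1.0, 1.0)
    cc[~defined, :] = np.nan
    cc[:, ~defined] = np.nan
    np.fill_diagonal(cc, np.where(defined, 1.0, np.nan))
    return pd.DataFrame(cc, index=df.index, columns=df.index)


def rank_neighbors(corr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene neighbour ranks from a correlation matrix.

    ``ranks.loc[g, h]`` is the 1-based position of *h* in *g*'s list of all
    other genes sorted by descending correlation; ties break by ascending
    gene_id so the ranking is deterministic.  Entries with undefined
    correlation (and the diagonal) are NaN; a gene undefined against
    everything has an empty list (all-NaN row).
    """
    genes = list(corr.index)
    n = len(genes)
    ranks = np.full((n, n), np.nan)
    cc = corr.to_numpy(dtype=float)
    order_key = np.array(genes)
    for i in range(n):
        neighbors = [j for j in range(n) if j != i and not np.isnan(cc[i, j])]
        neighbors.sort(key=lambda j: (-cc[i, j], order_key[j]))
        for pos, j in enumerate(neighbors, start=1):
            ranks[i, j] = pos
    return pd.DataFrame(ranks, index=corr.index, columns=corr.index)


class CoexpressionNetwork(BaseEstimator):
    """Rank-based coexpression network estimator.

    Parameters
    ----------
    min_cc : float, default 0.95
        Strict lower bound on Pearson correlation for an edge.
    max_rank : int, default 50
        Cap on a neighbour's 1-based rank in a gene's correlation-sorted
        list.
    rank_mode : {"either_direction", "both_directions"}, default "either_direction"
        Whether the rank cap must hold in at least one direction or in both.

    Attributes (after ``fit``)
    --------------------------
    gene_ids_ : list of str
    correlation_ : DataFrame, genes x genes Pearson matrix (NaN = undefined)
    ranks_ : DataFrame, asymmetric neighbour ranks (NaN = undefined)
    graph_ : networkx.Graph with edge attributes ``cc``, ``rank_ab``,
        ``rank_ba`` (ranks in the lexicographically sorted pair order) and
        the parameters stored in ``graph_.graph["params"]``.
    """

    def __init__(
        self,
        min_cc: float = 0.95,
        max_rank: int = 50,
        rank_mode: str = "either_direction",
    ):
        self.min_cc = min_cc
        self.max_rank = max_rank
        self.rank_mode = rank_mode

    @property
    def params_(self) -> NetworkParams:
        return NetworkParams(self.min_cc, self.max_rank, self.rank_mode)

    def fit(self, X, y=None):
        """Build the network from a genes x zones matrix.

        ``X`` may be an :class:`ExpressionTable`, a DataFrame indexed by
        gene_id, or a plain 2-D array (genes auto-named G0..Gn-1).
        """
        params = self.params_  # validates parameters
        df = _as_frame(X)
        if len(df) < 2:
            raise DimensionError("need at least 2 genes to build a network")
        if df.index.duplicated().any():
            raise DuplicateGeneError(
                "expression matrix has duplicate gene_ids; run "
                "collapse_duplicates before building a network"
            )
        self.gene_ids_ = [str(g) for g in df.index]
        self.correlation_ = correlation_matrix(df)
        self.ranks_ = rank_neighbors(self.correlation_)
        self.graph_ = self._select_edges(params)
        return self

    def _select_edges(self, params: NetworkParams) -> nx.Graph:
        genes = self.gene_ids_
        cc = self.correlation_.to_numpy(dtype=float)
        rk = self.ranks_.to_numpy(dtype=float)
        g = nx.Graph(params=params)
        g.add_nodes_from(genes)
        n = len(genes)
        for i in range(n):
            for j in range(i + 1, n):
                c = cc[i, j]
                if np.isnan(c) or not c > params.min_cc:
                    continue
                fwd_ok = rk[i, j] <= params.max_rank
                bwd_ok = rk[j, i] <= params.max_rank
                ok = (
                    (fwd_ok or bwd_ok)
                    if params.rank_mode == "either_direction"
                    else (fwd_ok and bwd_ok)
                )
                if not ok:
                    continue
                a, b = sorted((genes[i], genes[j]))
                ia, ib = (i, j) if a == genes[i] else (j, i)
                g.add_edge(
                    a,
                    b,
                    cc=float(c),
                    rank_ab=int(rk[ia, ib]),
                    rank_ba=int(rk[ib, ia]),
                )
        return g


def build_network(matrix, params: NetworkParams | None = None, **overrides) -> nx.Graph:
    """Functional wrapper over :class:`CoexpressionNetwork`.

    ``params`` (or keyword overrides ``min_cc``/``max_rank``/``rank_mode``)
    select the edge criteria; returns the networkx graph.
    """
    if params is None:
        params = NetworkParams(**overrides)
    elif overrides:
        raise ParameterError("pass either params or keyword overrides, not both")
    est = CoexpressionNetwork(params.min_cc, params.max_rank, params.rank_mode)
    return est.fit(matrix).graph_


def graph_stats(net: nx.Graph) -> dict:
    """Standard unweighted topology summary of a coexpression network.

    Reports node/edge counts, the degree distribution, mean clustering
    coefficient, the number of non-singleton connected components and of
    singletons, and per-component diameter and mean shortest-path length.
    An empty network yields zeros.
    """
    n = net.number_of_nodes()
    if n == 0:
        return {
            "n_nodes": 0,
            "n_edges": 0,
            "degree_distribution": {},
            "mean_clustering": 0.0,
            "n_components": 0,
            "n_singletons": 0,
            "components": [],
        }
    degrees = [d for _, d in net.degree()]
    dist: dict[int, int] = {}
    for d in degrees:
        dist[d] = dist.get(d, 0) + 1
    comps = [sorted(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    comp_stats = []
    n_singletons = 0
    for members in comps:
        if len(members) == 1:
            n_singletons += 1
            continue
        sub = net.subgraph(members)
        comp_stats.append(
            {
                "size": len(members),
                "diameter": int(nx.diameter(sub)),
                "mean_path_length": float(nx.average_shortest_path_length(sub)),
                "members": members,
            }
        )
    return {
        "n_nodes": n,
        "n_edges": net.number_of_edges(),
        "degree_distribution": dict(sorted(dist.items())),
        "mean_clustering": float(nx.average_clustering(net)) if n else 0.0,
        "n_components": len(comp_stats),
        "n_singletons": n_singletons,
        "components": comp_stats,
    }


def _sorted_edges(net: nx.Graph):
    return sorted((tuple(sorted((u, v))), d) for u, v, d in net.edges(data=True))


def write_sif(net: nx.Graph, path: str | Path) -> None:
    """Cytoscape SIF export: ``geneA<TAB>cc<TAB>geneB``, cc to 4 decimals."""
    lines = [f"{a}\t{d['cc']:.4f}\t{b}" for (a, b), d in _sorted_edges(net)]
    lines += sorted(n for n in net.nodes if net.degree(n) == 0)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    """GraphML export with cc/rank edge attributes (Cytoscape-readable)."""
    out = nx.Graph()
    out.add_nodes_from(net.nodes)
    for (a, b), d in _sorted_edges(net):
        out.add_edge(a, b, **d)
    params = net.graph.get("params")
    if params is not None:
        out.graph.update(
            min_cc=params.min_cc, max_rank=params.max_rank, rank_mode=params.rank_mode
        )
    nx.write_graphml(out, str(path))


def write_edgelist(net: nx.Graph, path: str | Path) -> None:
    """Edge-list TSV: source, target, cc, rank_ab, rank_ba."""
    lines = ["source\ttarget\tcc\trank_ab\trank_ba"]
    for (a, b), d in _sorted_edges(net):
        lines.append(f"{a}\t{b}\t{d['cc']:.6f}\t{d['rank_ab']}\t{d['rank_ba']}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
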