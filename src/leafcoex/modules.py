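"""Module partitioning and gradient-profile labelling.

With the stringent correlation floor (min_cc = 0.95) the thresholded network
is sparse and its connected components are the natural, assumption-free
reading of "modules": maximal groups of genes linked by strong positive
coexpression.  :func:`partition_modules` returns those components (size >=
``min_module_size``); smaller components are reported as leftovers, never
silently dropped.  An average-linkage hierarchical alternative (cut at k
clusters on correlation distance) is available for exploratory use.

Each module is labelled by where its members peak on the gradient:
``early`` when a strict majority peaks in the younger half of the zones
(basal/transitional), ``late`` for the older half (maturing/mature),
``mixed`` otherwise.

:class:`ModuleDetector` is the clusterer form: ``fit`` on a genes x zones
matrix yields integer ``labels_`` (-1 for leftover genes), composing with
sklearn model selection; :func:`partition_modules` stays the functional
surface over an already-built graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .catalog_io import ExpressionTable
from .errors import GeneLookupError, ParameterError
from .network import CoexpressionNetwork, _as_frame, correlation_matrix

__all__ = ["Module", "ModuleDetector", "partition_modules", "label_module",
           "module_mean_profile", "write_module_report"]

PROFILE_LABELS = ("early", "late", "mixed")


@dataclass
class Module:
    """A connected gene set with its gradient profile class."""

    members: tuple[str, ...]
    profile_label: str | None = None
    mean_profile: np.ndarray | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def partition_modules(
    net: nx.Graph, min_module_size: int = 2
) -> tuple[list[Module], list[str]]:
    """Split a network into connected-component modules plus leftovers.

    Modules are components with at least ``min_module_size`` members,
    ordered by descending size then lexicographically smallest member;
    every other node lands in the leftover list (sorted), so the result is
    a partition of all nodes.
    """
    if min_module_size < 1:
        raise ParameterError("min_module_size must be >= 1")
    comps = [tuple(sorted(c)) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    modules = [Module(c) for c in comps if len(c) >= min_module_size]
    leftovers = sorted(
        g for c in comps if len(c) < min_module_size for g in c
    )
    return modules, leftovers


def label_module(module: Module | tuple[str, ...], matrix) -> str:
    """Label a module early/late/mixed from its members' peak zones.

    ``early`` if a strict majority of members peak in the younger half of
    the gradient, ``late`` for a strict majority in the older half,
    otherwise ``mixed``.  Members absent from the matrix raise a lookup
    error.
    """
    members = module.members if isinstance(module, Module) else tuple(module)
    df = _as_frame(matrix)
    half = df.shape[1] // 2
    early = late = 0
    for g in members:
        if g not in df.index:
            raise GeneLookupError(f"module member {g!r} not in expression matrix")
        peak = int(np.argmax(df.loc[g].to_numpy(dtype=float)))
        if peak < half:
            early += 1
        else:
            late += 1
    if early * 2 > len(members):
        return "early"
    if late * 2 > len(members):
        return "late"
    return "mixed"


def module_mean_profile(module: Module | tuple[str, ...], matrix) -> np.ndarray:
    """Per-zone mean of z-scored member profiles (flat members contribute 0)."""
    members = module.members if isinstance(module, Module) else tuple(module)
    df = _as_frame(matrix)
    profiles = []
    for g in members:
        if g not in df.index:
            raise GeneLookupError(f"module member {g!r} not in expression matrix")
        v = df.loc[g].to_numpy(dtype=float)
        sd = v.std()
        profiles.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
    return np.mean(profiles, axis=0)


class ModuleDetector(ClusterMixin, BaseEstimator):
    """Partition genes into coexpression modules (sklearn clusterer API).

    Parameters
    ----------
    min_cc, max_rank, rank_mode
        Edge criteria of the underlying rank-based network (see
        :class:`~leafcoex.network.CoexpressionNetwork`).
    min_module_size : int, default 2
        Components smaller than this become leftovers (label -1).
    method : {"components", "hierarchical"}, default "components"
        "components" partitions the thresholded network into connected
        components; "hierarchical" is the exploratory alternative —
        average-linkage on correlation distance (1 - cc), cut at
        ``n_modules`` clusters, with the same size filter applied.
    n_modules : int, default 2
        Number of clusters for the hierarchical cut (ignored otherwise).

    Attributes (after ``fit``)
    --------------------------
    labels_ : ndarray of int, module index per gene, -1 for leftovers
    modules_ : list of :class:`Module` with labels and mean profiles
    leftovers_ : list of gene_ids not in any module
    network_ : fitted :class:`CoexpressionNetwork` (components method only)
    """

    def __init__(
        self,
        min_cc: float = 0.95,
        max_rank: int = 50,
        rank_mode: str = "either_direction",
        min_module_size: int = 2,
        method: str = "components",
        n_modules: int = 2,
    ):
        self.min_cc = min_cc
        self.max_rank = max_rank
        self.rank_mode = rank_mode
        self.min_module_size = min_module_size
        self.method = method
        self.n_modules = n_modules

    def fit(self, X, y=None):
        if self.method not in ("components", "hierarchical"):
            raise ParameterError(f"unknown method {self.method!r}")
        df = _as_frame(X)
        if self.method == "components":
            self.network_ = CoexpressionNetwork(
                self.min_cc, self.max_rank, self.rank_mode
            ).fit(df)
            modules, leftovers = partition_modules(
                self.network_.graph_, self.min_module_size
            )
        else:
            modules, leftovers = self._hierarchical(df)
        for m in modules:
            m.profile_label = label_module(m, df)
            m.mean_profile = module_mean_profile(m, df)
        self.modules_ = modules
        self.leftovers_ = leftovers
        index = {g: i for i, m in enumerate(modules) for g in m.members}
        self.labels_ = np.array(
            [index.get(str(g), -1) for g in df.index], dtype=int
        )
        return self

    def _hierarchical(self, df: pd.DataFrame):
        corr = correlation_matrix(df).to_numpy(dtype=float)
        # undefined correlations sit at maximal distance so flat profiles
        # cannot glue clusters together
        dist = 1.0 - np.nan_to_num(corr, nan=-1.0)
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        flat = fcluster(z, t=self.n_modules, criterion="maxclust")
        groups: dict[int, list[str]] = {}
        for g, k in zip(df.index, flat):
            groups.setdefault(int(k), []).append(str(g))
        comps = [tuple(sorted(v)) for v in groups.values()]
        comps.sort(key=lambda c: (-len(c), c[0]))
        modules = [Module(c) for c in comps if len(c) >= self.min_module_size]
        leftovers = sorted(
            g for c in comps if len(c) < self.min_module_size for g in c
        )
        return modules, leftovers


def write_module_report(
    modules: list[Module],
    leftovers: list[str],
    path,
    table: ExpressionTable | None = None,
) -> pd.DataFrame:
    """Module report TSV: module_id, profile_label, size, members, names."""
    rows = []
    for i, m in enumerate(modules):
        names = (
            ",".join(table.name_of(g) for g in m.members) if table is not None else ""
        )
        rows.append(
            {
                "module_id": i,
                "profile_label": m.profile_label or "",
                "size": m.size,
                "members": ",".join(m.members),
                "names": names,
            }
        )
    if leftovers:
        names = (
            ",".join(table.name_of(g) for g in leftovers) if table is not None else ""
        )
        rows.append(
            {
                "module_id": -1,
                "profile_label": "leftover",
                "size": len(leftovers),
                "members": ",".join(leftovers),
                "names": names,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
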