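"""Cross-family association mining: aquaporins vs transmembrane transporters.

"Exhibits the same expression pattern" is operationalized as the network
edge criterion itself: a query (aquaporin) and a target (transporter) are
associated iff their profiles satisfy ``cc > min_cc`` plus the rank
condition, with ranks computed over the *full* supplied matrix — query and
target families together with any other genes present — matching the
genome-wide framing of the analysis.  No additional filter is applied.

The result is an :class:`AssociationTable` of passing records with the
supporting statistics (cc and both directional ranks), viewable per query
or per target; the shared-target report surfaces transporters that track
several aquaporins at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .catalog_io import Catalogue, ExpressionTable
from .errors import InputSetError
from .network import CoexpressionNetwork, NetworkParams, _as_frame

__all__ = [
    "AssociationRecord",
    "AssociationTable",
    "AssociationMiner",
    "associate",
    "shared_target_report",
    "write_association_table",
]


@dataclass(frozen=True)
class AssociationRecord:
    """One passing aquaporin-transporter coexpression link."""

    query_id: str
    query_name: str
    target_id: str
    target_name: str
    cc: float
    rank_qt: int  # rank of target among query's neighbours
    rank_tq: int  # rank of query among target's neighbours
    passes: bool = True


class AssociationTable:
    """Passing association records with per-query and per-target views."""

    def __init__(self, records: Iterable[AssociationRecord]):
        self.records: list[AssociationRecord] = sorted(
            records, key=lambda r: (r.query_id, r.target_id)
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_query(self) -> dict[str, list[AssociationRecord]]:
        out: dict[str, list[AssociationRecord]] = {}
        for r in self.records:
            out.setdefault(r.query_id, []).append(r)
        return out

    def by_target(self) -> dict[str, list[AssociationRecord]]:
        out: dict[str, list[AssociationRecord]] = {}
        for r in self.records:
            out.setdefault(r.target_id, []).append(r)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query_id": r.query_id,
                    "query_name": r.query_name,
                    "target_id": r.target_id,
                    "target_name": r.target_name,
                    "cc": r.cc,
                    "rank_qt": r.rank_qt,
                    "rank_tq": r.rank_tq,
                }
                for r in self.records
            ],
            columns=[
                "query_id",
                "query_name",
                "target_id",
                "target_name",
                "cc",
                "rank_qt",
                "rank_tq",
            ],
        )


class AssociationMiner(BaseEstimator):
    """Estimator form: fit the network once, then mine any query/target split.

    Parameters are the network edge criteria; ``fit`` accepts the full
    genes x zones matrix (queries, targets and any background genes
    together), after which :meth:`associate` evaluates cross-set pairs
    against the fitted correlations and ranks.
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

    def fit(self, X, y=None):
        self.network_ = CoexpressionNetwork(
            self.min_cc, self.max_rank, self.rank_mode
        ).fit(X)
        return self

    def associate(
        self,
        query_ids: Sequence[str],
        target_ids: Sequence[str],
        names: dict[str, str] | None = None,
    ) -> AssociationTable:
        net = self.network_
        known = set(net.gene_ids_)
        queries = [str(q) for q in query_ids]
        targets = [str(t) for t in target_ids]
        missing = [g for g in (*queries, *targets) if g not in known]
        if missing:
            raise InputSetError(
                f"gene ids not in the fitted matrix: {sorted(set(missing))}"
            )
        overlap = sorted(set(queries) & set(targets))
        if overlap:
            raise InputSetError(
                f"query and target sets must be disjoint; overlap: {overlap}"
            )
        names = names or {}
        graph = net.graph_
        rk = net.ranks_
        records = []
        for q in queries:
            for t in targets:
                if not graph.has_edge(q, t):
                    continue
                records.append(
                    AssociationRecord(
                        query_id=q,
                        query_name=names.get(q, q),
                        target_id=t,
                        target_name=names.get(t, t),
                        cc=float(graph.edges[q, t]["cc"]),
                        rank_qt=int(rk.loc[q, t]),
                        rank_tq=int(rk.loc[t, q]),
                    )
                )
        return AssociationTable(records)


def associate(
    matrix,
    query_ids: Sequence[str],
    target_ids: Sequence[str],
    params: NetworkParams | None = None,
    catalogue: Catalogue | None = None,
) -> AssociationTable:
    """Mine aquaporin-transporter associations on the full matrix.

    Every cross-set pair is evaluated against the network edge criteria
    (correlations and ranks computed over *all* genes in ``matrix``).
    Query/target sets must be disjoint and resolve in the matrix.
    """
    params = params or NetworkParams()
    miner = AssociationMiner(params.min_cc, params.max_rank, params.rank_mode)
    miner.fit(matrix)
    names: dict[str, str] = {}
    if isinstance(matrix, ExpressionTable):
        names = {
            str(g): nm for g, nm in zip(matrix.values.index, matrix.names) if nm
        }
    if catalogue is not None:
        for rec in catalogue:
            names.setdefault(rec.gene_id, rec.display_name)
    return miner.associate(query_ids, target_ids, names)


def shared_target_report(table: AssociationTable) -> pd.DataFrame:
    """Per-target list of associated queries, multi-query targets first.

    Ordered by descending query count then target_id, so transporters that
    track several aquaporins surface at the top.  Deterministic.
    """
    rows = []
    for target_id, recs in table.by_target().items():
        rows.append(
            {
                "target_id": target_id,
                "target_name": recs[0].target_name,
                "n_queries": len(recs),
                "queries": ",".join(sorted(r.query_id for r in recs)),
                "query_names": ",".join(
                    r.query_name for r in sorted(recs, key=lambda r: r.query_id)
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["target_id", "target_name", "n_queries", "queries", "query_names"],
    )
    if len(df):
        df = df.sort_values(
            ["n_queries", "target_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def write_association_table(
    table: AssociationTable, path: str | Path, catalogue: Catalogue | None = None
) -> pd.DataFrame:
    """Association TSV with optional GO-term metadata from the catalogue."""
    df = table.to_frame()
    go = []
    for r in table.records:
        rec = catalogue.get(r.target_id) if catalogue is not None else None
        go.append(",".join(sorted(rec.go_terms)) if rec is not None else "")
    df["target_go_terms"] = go
    df.to_csv(path, sep="\t", index=False)
    return df
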