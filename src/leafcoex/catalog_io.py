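"""Gene catalogues and RPKM expression tables.

The study design is a four-zone maize leaf developmental gradient — basal,
transitional, maturing, mature, ordered from youngest to oldest tissue — with
one RPKM value per gene model per zone.  This module reads and writes the two
tabular artefacts everything else consumes:

* an expression table: ``gene_id<TAB>name<TAB><zone columns...>`` with RPKM
  values, where a cell printed as ``0*`` means "below detection" and is stored
  as 0.0 with a per-cell flag;
* a gene catalogue: ``gene_id name accession gene_class go_terms``, mapping
  gene models to isoform names and to aquaporin subfamilies (PIP1, PIP2, TIP,
  NIP, SIP) or to the transmembrane-transporter class.

Gene identity is the gene model (``gene_id``), not the isoform symbol: two
isoform names may share one gene model (ZmPIP1;3 / ZmPIP1;4 both map to
GRMZM2G392975 with identical RPKM rows), and :func:`collapse_duplicates`
merges such rows explicitly rather than silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    DuplicateConflictError,
    DuplicateGeneError,
    ExpressionFormatError,
    GeneLookupError,
)

#: Canonical zone labels of the leaf developmental gradient, young to old.
ZONES: tuple[str, ...] = ("basal", "transitional", "maturing", "mature")

#: Marker used in printed tables for "hardly any or no expression".
BELOW_DETECTION_MARKER = "0*"

#: Aquaporin subfamilies plus the two non-aquaporin classes.
GENE_CLASSES = ("PIP1", "PIP2", "TIP", "NIP", "SIP", "transporter", "other")

_SUBFAMILY_RE = re.compile(r"^Zm(PIP1|PIP2|TIP|NIP|SIP)", re.IGNORECASE)

#: Prefix marking a synthesized placeholder gene_id (family member known to
#: exist but never printed with an identifier).
PLACEHOLDER_PREFIX = "PLACEHOLDER_"


def classify_by_name(name: str) -> str:
    """Return the aquaporin subfamily encoded in a gene symbol.

    Symbols beginning ``ZmPIP1``/``ZmPIP2``/``ZmTIP``/``ZmNIP``/``ZmSIP``
    map to the corresponding subfamily; anything else (including bare gene
    model IDs such as ``GRMZM2G455124``) maps to ``"other"``.  Total function:
    never raises.
    """
    m = _SUBFAMILY_RE.match(str(name))
    return m.group(1).upper() if m else "other"


@dataclass(frozen=True)
class GeneRecord:
    """Identity and annotation of one gene model.

    ``names`` holds every isoform symbol reported for the gene model (usually
    one; two for merged isoforms).  ``gene_class`` is an aquaporin subfamily,
    ``"transporter"`` (GO:0055085 transmembrane transport), or ``"other"``.
    """

    gene_id: str
    names: tuple[str, ...] = ()
    accession: str = ""
    gene_class: str = "other"
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene_class {self.gene_class!r}")
        for name in self.names:
            derived = classify_by_name(name)
            if derived != "other" and derived != self.gene_class:
                raise ValueError(
                    f"gene_class {self.gene_class!r} contradicts symbol "
                    f"{name!r} (prefix-derived subfamily {derived!r})"
                )

    @property
    def placeholder(self) -> bool:
        """True for synthesized IDs standing in for never-printed gene models."""
        return self.gene_id.startswith(PLACEHOLDER_PREFIX)

    @property
    def display_name(self) -> str:
        return "/".join(self.names) if self.names else self.gene_id


class Catalogue:
    """A set of :class:`GeneRecord` keyed by gene_id.

    gene_ids are unique; isoform symbols need not be (a record may carry
    several names).  ``len(catalogue)`` counts records; :attr:`n_names`
    counts isoform names, which is how the literature tallies family sizes.
    """

    def __init__(self, records: Iterable[GeneRecord] = ()):
        self._records: dict[str, GeneRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: GeneRecord) -> None:
        existing = self._records.get(rec.gene_id)
        if existing is None:
            self._records[rec.gene_id] = rec
            return
        if existing.gene_class != rec.gene_class:
            raise DuplicateConflictError(
                f"gene_id {rec.gene_id!r} listed with conflicting classes "
                f"{existing.gene_class!r} and {rec.gene_class!r}"
            )
        merged_names = existing.names + tuple(
            n for n in rec.names if n not in existing.names
        )
        self._records[rec.gene_id] = replace(
            existing,
            names=merged_names,
            accession=existing.accession or rec.accession,
            go_terms=existing.go_terms | rec.go_terms,
        )

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        try:
            return self._records[gene_id]
        except KeyError:
            raise GeneLookupError(f"gene_id {gene_id!r} not in catalogue") from None

    def get(self, gene_id: str, default: GeneRecord | None = None) -> GeneRecord | None:
        return self._records.get(gene_id, default)

    @property
    def names(self) -> tuple[str, ...]:
        """All isoform names in record order."""
        return tuple(n for rec in self for n in rec.names)

    @property
    def n_names(self) -> int:
        return len(self.names)

    def class_of(self, gene_id: str) -> str:
        rec = self._records.get(gene_id)
        return rec.gene_class if rec is not None else "other"

    def subfamily_counts(self, by_name: bool = True) -> dict[str, int]:
        """Tally gene classes, counting isoform names by default."""
        counts: dict[str, int] = {}
        for rec in self:
            k = len(rec.names) or 1
            counts[rec.gene_class] = counts.get(rec.gene_class, 0) + (
                k if by_name else 1
            )
        return counts

    def ids_of_class(self, *classes: str) -> list[str]:
        return [rec.gene_id for rec in self if rec.gene_class in classes]

    def ids_with_go(self, go_term: str) -> list[str]:
        return [rec.gene_id for rec in self if go_term in rec.go_terms]

    def record_merge(self, gene_id: str, names: Sequence[str]) -> None:
        """Attach additional isoform names to an existing record."""
        rec = self[gene_id]
        merged = rec.names + tuple(n for n in names if n not in rec.names)
        self._records[gene_id] = replace(rec, names=merged)


@dataclass
class ExpressionTable:
    """RPKM values for a set of gene models across ordered gradient zones.

    ``values`` is a genes x zones DataFrame indexed by gene_id (duplicate
    indices are legal before :func:`collapse_duplicates`); ``names`` is the
    per-row isoform symbol (or None); ``below_detection`` flags cells that the
    source table marked as below the detection limit (stored as 0.0).
    """

    values: pd.DataFrame
    names: list[str | None] = field(default_factory=list)
    below_detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.names:
            self.names = [None] * len(self.values)
        if self.below_detection is None:
            self.below_detection = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df = self.values
        if df.shape[1] < 2:
            raise DimensionError(
                f"expression table needs at least 2 zone columns, got {df.shape[1]}"
            )
        if len(self.names) != len(df):
            raise DimensionError("names must align with rows")
        if self.below_detection.shape != df.shape:
            raise DimensionError("below_detection must align with values")
        if any(not g for g in df.index):
            raise ExpressionFormatError("empty gene_id in expression table")
        arr = df.to_numpy(dtype=float)
        bad = ~np.isfinite(arr)
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ExpressionFormatError(
                f"non-finite RPKM at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        neg = arr < 0
        if neg.any():
            r, c = map(int, np.argwhere(neg)[0])
            raise ExpressionFormatError(
                f"negative RPKM at row {df.index[r]!r}, column {df.columns[c]!r}"
            )

    # -- basic accessors ----------------------------------------------------
    @property
    def zones(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def n_genes(self) -> int:
        return len(self.values)

    def name_of(self, gene_id: str) -> str:
        for gid, nm in zip(self.values.index, self.names):
            if gid == gene_id and nm:
                return nm
        return gene_id

    def row(self, gene_id: str) -> np.ndarray:
        """RPKM vector of a gene model (first row when the id is duplicated)."""
        if gene_id not in self.values.index:
            raise GeneLookupError(f"gene_id {gene_id!r} not in expression table")
        sub = self.values.loc[[gene_id]] if self.has_duplicates else None
        if sub is not None:
            return sub.to_numpy(dtype=float)[0]
        return self.values.loc[gene_id].to_numpy(dtype=float)

    @property
    def has_duplicates(self) -> bool:
        return bool(self.values.index.duplicated().any())

    def copy(self) -> "ExpressionTable":
        return ExpressionTable(
            self.values.copy(), list(self.names), self.below_detection.copy()
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, names: Sequence[str | None] | None = None
    ) -> "ExpressionTable":
        return cls(df.astype(float), list(names) if names is not None else [])


@dataclass(frozen=True)
class MergeRecord:
    """One duplicate-row collapse: which names folded into which gene model."""

    gene_id: str
    names: tuple[str, ...]
    n_rows: int


def read_expression_table(
    path: str | Path,
    *,
    sep: str = "\t",
    on_duplicate: str = "keep",
) -> ExpressionTable:
    """Read a delimited RPKM table into an :class:`ExpressionTable`.

    Expected layout: header row, first column ``gene_id``, optional second
    column ``name``, remaining columns one per zone (at least two).  Cells
    equal to ``0*`` are parsed as 0.0 and flagged below-detection.  Input row
    order is preserved.

    ``on_duplicate`` controls duplicate gene_id rows: ``"keep"`` (default)
    keeps them when their RPKM vectors are identical — the same gene model
    reported under two isoform names — and raises only when they conflict;
    ``"raise"`` refuses any duplicate and points at
    :func:`collapse_duplicates`.
    """
    if on_duplicate not in ("keep", "raise"):
        raise ValueError("on_duplicate must be 'keep' or 'raise'")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ExpressionFormatError(f"{path}: empty expression table")
    header = lines[0].split(sep)
    if not header or header[0].strip().lower() != "gene_id":
        raise ExpressionFormatError(
            f"{path}: missing header (first column must be 'gene_id', "
            f"got {header[0]!r})" if header else f"{path}: missing header"
        )
    has_names = len(header) > 1 and header[1].strip().lower() == "name"
    zone_cols = [h.strip() for h in header[(2 if has_names else 1):]]
    if len(zone_cols) < 2:
        raise DimensionError(
            f"{path}: need at least 2 zone columns, found {len(zone_cols)}"
        )

    gene_ids: list[str] = []
    names: list[str | None] = []
    rows: list[list[float]] = []
    flags: list[list[bool]] = []
    ncol = len(header)
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(sep)
        if len(fields) != ncol:
            raise ExpressionFormatError(
                f"{path}:{lineno}: expected {ncol} fields, got {len(fields)}"
            )
        gid = fields[0].strip()
        if not gid:
            raise ExpressionFormatError(f"{path}:{lineno}: empty gene_id")
        gene_ids.append(gid)
        names.append(fields[1].strip() or None if has_names else None)
        row: list[float] = []
        flag: list[bool] = []
        for col, cell in zip(zone_cols, fields[(2 if has_names else 1):]):
            cell = cell.strip()
            if cell == BELOW_DETECTION_MARKER:
                row.append(0.0)
                flag.append(True)
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ExpressionFormatError(
                    f"{path}: non-numeric RPKM {cell!r} at row {gid!r}, "
                    f"column {col!r}"
                ) from None
            if v < 0:
                raise ExpressionFormatError(
                    f"{path}: negative RPKM {v} at row {gid!r}, column {col!r}"
                )
            row.append(v)
            flag.append(False)
        rows.append(row)
        flags.append(flag)

    values = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"),
                          columns=zone_cols, dtype=float)
    below = pd.DataFrame(flags, index=values.index, columns=zone_cols)
    _check_duplicates(values, on_duplicate)
    return ExpressionTable(values, names, below)


def _check_duplicates(values: pd.DataFrame, on_duplicate: str) -> None:
    dup_ids = values.index[values.index.duplicated()].unique()
    if len(dup_ids) == 0:
        return
    if on_duplicate == "raise":
        raise DuplicateGeneError(
            f"duplicate gene_id rows {list(map(str, dup_ids))}; "
            "use collapse_duplicates to merge identical rows"
        )
    for gid in dup_ids:
        block = values.loc[[gid]].to_numpy(dtype=float)
        if not (block == block[0]).all():
            raise DuplicateConflictError(
                f"rows sharing gene_id {gid!r} have differing RPKM vectors; "
                "refusing to merge or average"
            )


def write_expression_table(
    table: ExpressionTable, path: str | Path, *, sep: str = "\t"
) -> None:
    """Write a table in the same dialect :func:`read_expression_table` reads.

    Floats are rendered with ``repr``-style shortest text, so a write/read
    round trip reproduces every value bit-exactly; below-detection cells are
    written back as ``0*``.
    """
    path = Path(path)
    cols = ["gene_id", "name", *table.zones]
    lines = [sep.join(cols)]
    flags = table.below_detection.to_numpy()
    for i, (gid, nm) in enumerate(zip(table.values.index, table.names)):
        cells = [str(gid), nm or ""]
        for j, z in enumerate(table.zones):
            v = table.values.iat[i, j]
            cells.append(BELOW_DETECTION_MARKER if flags[i, j] else _fmt(v))
        lines.append(sep.join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _fmt(v: float) -> str:
    s = repr(float(v))
    return s[:-2] if s.endswith(".0") else s


def collapse_duplicates(
    table: ExpressionTable, catalogue: Catalogue | None = None
) -> tuple[ExpressionTable, list[MergeRecord]]:
    """Merge rows that share a gene_id into one row per gene model.

    Rows sharing a gene_id must have identical RPKM vectors (same gene model
    reported under several isoform names); differing vectors raise
    :class:`DuplicateConflictError` — values are never averaged.  Merged
    isoform names are joined with ``/`` on the surviving row and, when a
    catalogue is supplied, recorded on its :class:`GeneRecord`.  Idempotent.
    """
    values, names = table.values, table.names
    if not table.has_duplicates:
        return table.copy(), []
    _check_duplicates(values, "keep")  # raises on conflicting vectors
    report: list[MergeRecord] = []
    keep_rows: list[int] = []
    seen: dict[str, int] = {}
    merged_names: dict[str, list[str]] = {}
    for i, gid in enumerate(values.index):
        if gid not in seen:
            seen[gid] = i
            keep_rows.append(i)
            merged_names[gid] = [names[i]] if names[i] else []
        else:
            if names[i] and names[i] not in merged_names[gid]:
                merged_names[gid].append(names[i])
    for gid, nms in merged_names.items():
        n_rows = int((values.index == gid).sum())
        if n_rows > 1:
            report.append(MergeRecord(gid, tuple(nms), n_rows))
            if catalogue is not None and gid in catalogue:
                catalogue.record_merge(gid, nms)
    new_values = values.iloc[keep_rows]
    new_names = [
        "/".join(merged_names[gid]) or None for gid in new_values.index
    ]
    new_below = table.below_detection.iloc[keep_rows]
    return ExpressionTable(new_values, new_names, new_below), report


def read_catalogue(path: str | Path, *, sep: str = "\t") -> Catalogue:
    """Read a gene catalogue TSV: gene_id name accession gene_class go_terms.

    ``go_terms`` is comma-separated and may be absent/empty.  Rows sharing a
    gene_id merge into a single multi-name record.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"gene_id", "name", "gene_class"}
    missing = required - set(df.columns)
    if missing:
        raise ExpressionFormatError(
            f"{path}: catalogue missing columns {sorted(missing)}"
        )
    cat = Catalogue()
    for _, row in df.iterrows():
        go = frozenset(
            t.strip() for t in str(row.get("go_terms", "")).split(",") if t.strip()
        )
        cat.add(
            GeneRecord(
                gene_id=row["gene_id"],
                names=(row["name"],) if row["name"] else (),
                accession=str(row.get("accession", "")),
                gene_class=row["gene_class"],
                go_terms=go,
            )
        )
    return cat


def write_catalogue(cat: Catalogue, path: str | Path, *, sep: str = "\t") -> None:
    lines = [sep.join(["gene_id", "name", "accession", "gene_class", "go_terms"])]
    for rec in cat:
        for name in rec.names or (rec.gene_id,):
            lines.append(
                sep.join(
                    [
                        rec.gene_id,
                        name if rec.names else "",
                        rec.accession,
                        rec.gene_class,
                        ",".join(sorted(rec.go_terms)),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
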