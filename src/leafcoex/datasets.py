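"""Packaged fixtures: the printed aquaporin RPKM table and family catalogue.

``load_table1`` returns the 24 detected aquaporin isoform rows over the four
leaf gradient zones, digit-for-digit as printed (cells marked below detection
are 0.0 with the flag set).  ``load_aquaporin_catalogue`` returns the full
maize aquaporin family — 33 isoform names over 32 gene models (ZmPIP1;3 and
ZmPIP1;4 share GRMZM2G392975): 6 PIP1 + 7 PIP2 + 11 TIP + 6 NIP + 3 SIP.
ZmPIP1;2 was never published with a gene-model identifier and carries a
flagged placeholder id.
"""

from __future__ import annotations

from importlib import resources

from .catalog_io import Catalogue, ExpressionTable, read_catalogue, read_expression_table

__all__ = ["load_table1", "load_aquaporin_catalogue"]


def _data_path(filename: str):
    return resources.files("leafcoex.data").joinpath(filename)


def load_table1() -> ExpressionTable:
    """The 24-row detected-aquaporin RPKM matrix (4 gradient zones)."""
    with resources.as_file(_data_path("table1.tsv")) as p:
        return read_expression_table(p)


def load_aquaporin_catalogue() -> Catalogue:
    """The 33-name maize aquaporin family catalogue."""
    with resources.as_file(_data_path("aquaporins.tsv")) as p:
        return read_catalogue(p)
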