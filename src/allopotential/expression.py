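"""Gene-by-tissue expression join for presented peptides.

A presented peptide is only a plausible in vivo minor antigen in tissues that
actually express its source gene. This module loads a relative-expression-unit
(REU) table (genes x tissues) and counts, per tissue, the distinct genes that
both contribute a presented peptide and exceed an expression threshold
(strictly > 10 REU by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Set, Tuple

import pandas as pd

from .errors import InputFormatError


@dataclass
class ExpressionTable:
    """REU values indexed by (gene, tissue); wraps a genes x tissues frame."""

    data: pd.DataFrame  # index: gene, columns: tissues

    def __post_init__(self) -> None:
        self.data.index.name = "gene"
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise InputFormatError(f"duplicate gene identifier {dup!r} in expression table")
        if (self.data.to_numpy() < 0).any():
            raise InputFormatError("expression values must be non-negative")

    @property
    def genes(self) -> Set[str]:
        return set(self.data.index)

    @property
    def tissues(self) -> List[str]:
        return list(self.data.columns)

    def value(self, gene: str, tissue: str) -> float:
        return float(self.data.at[gene, tissue])


def load_expression_table(path: str | Path) -> ExpressionTable:
    """Load a CSV with a leading ``gene`` column and one column per tissue."""
    df = pd.read_csv(path)
    if df.columns[0] != "gene":
        raise InputFormatError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    df = df.set_index("gene")
    return ExpressionTable(df.astype(float))


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="gene")


def count_expressed_antigen_genes(
    presented_records: Iterable,
    table: ExpressionTable,
    threshold: float = 10.0,
) -> Tuple[Dict[str, int], Set[str]]:
    """Per-tissue count of distinct antigen-source genes expressed above
    ``threshold`` (strict >).

    ``presented_records`` are BindingRecords already classified presented
    (<500 nM); each must carry a ``gene`` provenance entry. Returns the
    per-tissue counts and the set of source genes missing from the table
    (reported, never silently dropped).
    """
    genes: Set[str] = set()
    unmapped: Set[str] = set()
    for r in presented_records:
        gene = r.provenance_dict().get("gene") if hasattr(r, "provenance_dict") else r
        if gene is None:
            continue
        if gene in table.genes:
            genes.add(gene)
        else:
            unmapped.add(gene)
    counts: Dict[str, int] = {}
    for tissue in table.tissues:
        col = table.data[tissue]
        counts[tissue] = int(sum(1 for g in genes if col.at[g] > threshold))
    return counts, unmapped


def write_tissue_counts(counts: Dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tissue,n_genes\n")
        for tissue in counts:
            fh.write(f"{tissue},{counts[tissue]}\n")
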