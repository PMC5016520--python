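"""Normalisation, locus gene ordering, and synthesis tables.

The synthesis table puts side by side, for every gene in locus order,
its usage in both sets normalised to 10,000 clonotypes (or sequences),
the difference in proportions with its confidence interval, and which
adjustment procedures call the difference significant — the tabular
counterpart of a normalised bar graph annotated with significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .proptests import PROCEDURES, PropTestRow
from .repertoire import GeneCountTable

__all__ = [
    "normalize_per_10000",
    "GeneOrdering",
    "load_gene_ordering",
    "synthesis_table",
]


def normalize_per_10000(count: float, total: float) -> float:
    """Rescale a count to a total of 10,000."""
    if total <= 0:
        raise ValueError("total must be positive")
    return count / total * 10_000


def load_gene_ordering(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Read a locus ordering file: (group, gene) pairs in locus position order.

    Without a path, the bundled human IGH ordering is used (an
    approximation of the curated locus order; supply a file to override).
    """
    if path is None:
        source = resources.files("clonostat.data").joinpath("igh_gene_order.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    pairs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        group, gene = line.split("\t")
        pairs.append((group, gene))
    return pairs


@dataclass
class GeneOrdering:
    """Gene display order for one locus; unknown genes sort after known."""

    genes: list[str]
    source: str = "bundled"

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ordering contains duplicate gene names")

    def sort_key(self, name: str):
        try:
            return (0, self.genes.index(name))
        except ValueError:
            return (1, name)

    def order(self, names: Sequence[str], warn: bool = True) -> list[str]:
        unknown = [n for n in names if n not in self.genes]
        if unknown and warn:
            warnings.warn(
                f"genes not in the ordering file, appended in name order: {unknown}",
                stacklevel=2,
            )
        return sorted(names, key=self.sort_key)

    @classmethod
    def for_locus(cls, group_prefix: str, path: str | Path | None = None) -> "GeneOrdering":
        pairs = load_gene_ordering(path)
        genes = [g for grp, g in pairs if grp.startswith(group_prefix)]
        return cls(genes, source="user-file" if path else "bundled")


def synthesis_table(
    rows: Sequence[PropTestRow],
    table: GeneCountTable,
    ordering: GeneOrdering | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Normalised usage + significance flags per item, in display order.

    Genes are ordered by locus position (unknown ones appended in name
    order); alleles ascending by name.  ``norm1``/``norm2`` are per
    10,000 for the table's mode; one boolean column per adjustment
    procedure flags adjusted p < alpha.
    """
    by_item = {r.item: r for r in rows if r.item in table.rows}
    names = list(table.rows)
    if table.level == "allele" or ordering is None:
        names = sorted(names)
    else:
        names = ordering.order(names)

    n1, n2 = table.totals
    data = []
    for name in names:
        x1, x2 = table.rows[name]
        row = by_item.get(name)
        entry = {
            "item": name,
            "norm1": normalize_per_10000(x1, n1),
            "norm2": normalize_per_10000(x2, n2),
            "diff": row.diff if row else (x1 / n1 - x2 / n2),
            "ci_low": row.ci_low if row else float("nan"),
            "ci_high": row.ci_high if row else float("nan"),
        }
        for proc in PROCEDURES:
            entry[f"sig_{proc}"] = bool(row and row.adj[proc] < alpha)
        data.append(entry)
    return pd.DataFrame(data)
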