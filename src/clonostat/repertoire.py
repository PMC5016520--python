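"""Repertoire sets: CDR3-length filtering and gene/allele count tables.

A :class:`RepertoireSet` is a filtered clonotype collection with its two
totals: *diversity* (number of distinct clonotypes, the ``n`` of the
proportion tests) and *expression* (number of sequences assigned to those
clonotypes).  :func:`count_by_gene` tabulates, for a pair of sets, how
many clonotypes (or sequences) use each single V, D or J gene or allele;
ambiguous multi-gene calls accumulate separately so that counts always
conserve the set totals.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .io import ClonotypeRecord, GeneCall

__all__ = [
    "RepertoireSet",
    "GeneCountTable",
    "filter_cdr3_range",
    "count_by_gene",
    "write_set_summary",
]

GeneType = Literal["V", "D", "J"]
Level = Literal["gene", "allele"]
Mode = Literal["diversity", "expression"]

DEFAULT_CDR3_MIN = 4
DEFAULT_CDR3_MAX = 45

#: key for records whose allele-level category cannot be resolved
NO_ALLELE = "(no allele)"


@dataclass(frozen=True)
class RepertoireSet:
    """A filtered clonotype set with its diversity and expression totals."""

    label: str
    records: tuple[ClonotypeRecord, ...]
    outliers: tuple[ClonotypeRecord, ...]
    cdr3_min: int
    cdr3_max: int

    @property
    def n_clonotypes(self) -> int:
        """Diversity total: number of kept clonotypes."""
        return len(self.records)

    @property
    def n_sequences_total(self) -> int:
        """Expression total: sequences assigned to kept clonotypes."""
        return sum(r.n_sequences for r in self.records)

    @property
    def n_one_copy(self) -> int:
        return sum(1 for r in self.records if r.n_sequences == 1)

    @property
    def n_more_than_one(self) -> int:
        return sum(1 for r in self.records if r.n_sequences > 1)

    def total(self, mode: Mode) -> int:
        return self.n_clonotypes if mode == "diversity" else self.n_sequences_total


def filter_cdr3_range(
    records: Iterable[ClonotypeRecord],
    min_len: int = DEFAULT_CDR3_MIN,
    max_len: int = DEFAULT_CDR3_MAX,
    label: str = "set",
) -> RepertoireSet:
    """Partition records by the inclusive CDR3 length range.

    Clonotypes outside ``[min_len, max_len]`` are length outliers,
    excluded from every downstream analysis but retained for reporting.
    """
    if min_len < 1 or max_len < min_len:
        raise ValueError(f"invalid CDR3 length range [{min_len}, {max_len}]")
    kept, out = [], []
    for rec in records:
        (kept if min_len <= rec.cdr3_length <= max_len else out).append(rec)
    return RepertoireSet(label, tuple(kept), tuple(out), min_len, max_len)


def _category(call: GeneCall | None, level: Level) -> tuple[str | None, bool]:
    """Resolve a call to its counting category at the requested level.

    Returns ``(name, is_several)``.  ``name`` is None for an absent call,
    :data:`NO_ALLELE` for a gene-only call at allele level.  A call
    listing several alleles of one gene is a single category at gene
    level but ambiguous at allele level.
    """
    if call is None:
        return None, False
    if level == "gene":
        if call.is_several:
            genes = {g for g, _ in call.members}
            if len(genes) == 1:
                return genes.pop(), False
            return call.canonical(), True
        return call.gene, False
    # allele level
    if call.is_several:
        return call.canonical(), True
    if call.allele is None:
        return NO_ALLELE, False
    return f"{call.gene}*{call.allele}", False


@dataclass
class GeneCountTable:
    """Per-item counts for both sets at one (gene_type, level, mode)."""

    gene_type: GeneType
    level: Level
    mode: Mode
    rows: dict[str, tuple[int, int]]
    several_items: dict[str, tuple[int, int]]
    no_allele: tuple[int, int] = (0, 0)
    no_call: tuple[int, int] = (0, 0)
    totals: tuple[int, int] = (0, 0)
    labels: tuple[str, str] = ("set1", "set2")

    def items(self) -> list[str]:
        return list(self.rows)


def _call_of(rec: ClonotypeRecord, gene_type: GeneType) -> GeneCall | None:
    return {"V": rec.v_call, "D": rec.d_call, "J": rec.j_call}[gene_type]


def count_by_gene(
    set1: RepertoireSet,
    set2: RepertoireSet,
    gene_type: GeneType,
    level: Level = "gene",
    mode: Mode = "diversity",
) -> GeneCountTable:
    """Tabulate per-gene (or per-allele) counts for two sets.

    Every distinct single item observed in either set gets a row (zero
    count where absent).  Multi-gene/multi-allele calls go to
    ``several_items``; gene-only calls at allele level go to the
    ``no_allele`` remainder, records lacking the call entirely to the
    ``no_call`` remainder.  Totals are the set-wide totals (the test
    denominators n1, n2); single + several + no-allele + no-call counts
    conserve them exactly.
    """
    if (set1.cdr3_min, set1.cdr3_max) != (set2.cdr3_min, set2.cdr3_max):
        raise ValueError("both sets must be filtered with identical CDR3 bounds")

    rows: dict[str, list[int]] = {}
    several: dict[str, list[int]] = {}
    no_allele = [0, 0]
    no_call = [0, 0]
    any_call = False
    for idx, rset in enumerate((set1, set2)):
        for rec in rset.records:
            call = _call_of(rec, gene_type)
            weight = 1 if mode == "diversity" else rec.n_sequences
            if call is None:
                no_call[idx] += weight
                continue
            any_call = True
            name, is_several = _category(call, level)
            if name == NO_ALLELE:
                no_allele[idx] += weight
            elif is_several:
                several.setdefault(name, [0, 0])[idx] += weight
            else:
                rows.setdefault(name, [0, 0])[idx] += weight
    if gene_type == "D" and not any_call:
        warnings.warn("no D calls in either set; empty table", stacklevel=2)

    totals = (set1.total(mode), set2.total(mode))
    return GeneCountTable(
        gene_type=gene_type,
        level=level,
        mode=mode,
        rows={k: tuple(v) for k, v in sorted(rows.items())},
        several_items={k: tuple(v) for k, v in sorted(several.items())},
        no_allele=tuple(no_allele),
        no_call=tuple(no_call),
        totals=totals,
        labels=(set1.label, set2.label),
    )


def write_set_summary(rset: RepertoireSet, path: str | Path) -> Path:
    """Per-set summary CSV: totals, one-copy split, and the outlier list."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["quantity", "value"])
        w.writerow(["label", rset.label])
        w.writerow(["cdr3_min", rset.cdr3_min])
        w.writerow(["cdr3_max", rset.cdr3_max])
        w.writerow(["n_clonotypes", rset.n_clonotypes])
        w.writerow(["n_sequences_total", rset.n_sequences_total])
        w.writerow(["n_one_copy", rset.n_one_copy])
        w.writerow(["n_more_than_one", rset.n_more_than_one])
        w.writerow(["n_outliers", len(rset.outliers)])
        w.writerow([])
        w.writerow(["outlier_clonotype_id", "cdr3_aa", "cdr3_length"])
        for rec in rset.outliers:
            w.writerow([rec.clonotype_id, rec.cdr3_aa, rec.cdr3_length])
    return path
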