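"""Model/Results surface for a pairwise repertoire comparison.

:class:`RepertoireComparison` is the model: two filtered clonotype sets
plus the comparison settings (level, counting mode, alpha).  Its
:meth:`~RepertoireComparison.fit` runs the whole testing procedure —
count tables per gene type, z or Fisher per item, the seven p-value
adjustments over the joint family — and returns a
:class:`ComparisonResults` carrying the per-item estimates, confidence
intervals, adjusted p-values and diagnostics.  Rejection curves, scatter
tables, synthesis tables, the allele-level follow-up and plots all hang
off the results object.

    >>> set1 = filter_cdr3_range(records1, label="S1")
    >>> set2 = filter_cdr3_range(records2, label="S2")
    >>> res = RepertoireComparison(set1, set2).fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import proptests
from .io import StatsDialect, CANONICAL_DIALECT, read_stats_file
from .proptests import PROCEDURES, PropTestRow, RejectionCurve
from .repertoire import (
    DEFAULT_CDR3_MAX,
    DEFAULT_CDR3_MIN,
    GeneCountTable,
    RepertoireSet,
    count_by_gene,
    filter_cdr3_range,
)
from .report import GeneOrdering, synthesis_table

__all__ = ["RepertoireComparison", "ComparisonResults"]


class RepertoireComparison:
    """Pairwise per-gene comparison of two clonotype sets.

    Parameters
    ----------
    set1, set2
        Filtered repertoire sets (identical CDR3 bounds).
    gene_types
        Which groups to test jointly; the adjustment family spans all of
        them, so a V+D+J run of a human IGH pair tests one family of
        ~72 gene hypotheses.
    level
        ``"gene"`` or ``"allele"``.
    mode
        ``"diversity"`` (clonotype counts) or ``"expression"``
        (assigned-sequence counts).
    alpha
        Type I error rate used for confidence intervals and for the
        significance flags in summaries.
    """

    def __init__(
        self,
        set1: RepertoireSet,
        set2: RepertoireSet,
        gene_types: Sequence[str] = ("V", "D", "J"),
        level: str = "gene",
        mode: str = "diversity",
        alpha: float = 0.05,
    ):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.set1 = set1
        self.set2 = set2
        self.gene_types = tuple(gene_types)
        self.level = level
        self.mode = mode
        self.alpha = alpha

    @classmethod
    def from_files(
        cls,
        path1: str | Path,
        path2: str | Path,
        dialect: StatsDialect = CANONICAL_DIALECT,
        cdr3_min: int = DEFAULT_CDR3_MIN,
        cdr3_max: int = DEFAULT_CDR3_MAX,
        labels: tuple[str, str] = ("set1", "set2"),
        **kwargs,
    ) -> "RepertoireComparison":
        """Build the model straight from two stats tables on disk."""
        recs1, _ = read_stats_file(path1, dialect)
        recs2, _ = read_stats_file(path2, dialect)
        set1 = filter_cdr3_range(recs1, cdr3_min, cdr3_max, label=labels[0])
        set2 = filter_cdr3_range(recs2, cdr3_min, cdr3_max, label=labels[1])
        return cls(set1, set2, **kwargs)

    def count_tables(self) -> dict[str, GeneCountTable]:
        return {
            gt: count_by_gene(self.set1, self.set2, gt, self.level, self.mode)
            for gt in self.gene_types
        }

    def fit(self) -> "ComparisonResults":
        """Run the tests and adjustments; returns the results object."""
        tables = self.count_tables()
        rows = proptests.run_comparison(list(tables.values()), alpha=self.alpha)
        return ComparisonResults(model=self, tables=tables, rows=rows)


@dataclass
class ComparisonResults:
    """Fitted per-item results of a :class:`RepertoireComparison`."""

    model: RepertoireComparison
    tables: dict[str, GeneCountTable]
    rows: list[PropTestRow]

    # -- frames -----------------------------------------------------------
    def frame(self) -> pd.DataFrame:
        """The full results table (one row per gene or allele)."""
        data = []
        for r in self.rows:
            entry = {
                "Gene_Name": r.item,
                "Gene_Type": r.gene_type,
                "Level": r.level,
                "x1": r.x1, "n1": r.n1, "x2": r.x2, "n2": r.n2,
                "p1": r.p1, "p2": r.p2, "diff": r.diff,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "z": r.z if r.z is not None else np.nan,
                "method": r.method,
                "rawp": r.rawp,
            }
            for proc in PROCEDURES:
                entry[f"adj_{proc}"] = r.adj[proc]
            entry["Test_interpretation"] = r.interpretation
            data.append(entry)
        return pd.DataFrame(data)

    @property
    def alpha(self) -> float:
        return self.model.alpha

    @property
    def n_hypotheses(self) -> int:
        return len(self.rows)

    def hypotheses_by_group(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rows:
            out[r.gene_type] = out.get(r.gene_type, 0) + 1
        return out

    def n_significant(self, procedure: str = "rawp") -> int:
        """Rejections at this fit's alpha under raw or one adjusted family."""
        if procedure == "rawp":
            return sum(1 for r in self.rows if r.rawp < self.alpha)
        return sum(1 for r in self.rows if r.adj[procedure] < self.alpha)

    def significant_items(self, procedure: str = "rawp") -> list[str]:
        if procedure == "rawp":
            return [r.item for r in self.rows if r.rawp < self.alpha]
        return [r.item for r in self.rows if r.adj[procedure] < self.alpha]

    def validated_by_all(self) -> list[str]:
        """Items significant under every adjustment procedure."""
        return [
            r.item
            for r in self.rows
            if all(r.adj[p] < self.alpha for p in PROCEDURES)
        ]

    def small_occurrence_items(self) -> list[str]:
        """Items routed to Fisher's exact test by the small-count guard."""
        return [r.item for r in self.rows if r.method == "fisher"]

    def signed_significant(self) -> tuple[int, int]:
        """(negative, positive) raw-significant differences in proportions."""
        neg = sum(1 for r in self.rows if r.rawp < self.alpha and r.diff < 0)
        pos = sum(1 for r in self.rows if r.rawp < self.alpha and r.diff > 0)
        return neg, pos

    # -- downstream products ---------------------------------------------
    def rejection_curves(
        self,
        procedures: Sequence[str] = PROCEDURES,
        alpha_grid: np.ndarray | None = None,
    ) -> list[RejectionCurve]:
        return proptests.rejection_curves(self.rows, procedures, alpha_grid)

    def scatter_table(self) -> pd.DataFrame:
        return proptests.scatter_table(self.rows, alpha=self.alpha)

    def synthesis(self, gene_type: str, ordering: GeneOrdering | None = None) -> pd.DataFrame:
        if ordering is None and self.model.level == "gene":
            names = list(self.tables[gene_type].rows)
            group = names[0][:4] if names else "IGHV"
            try:
                ordering = GeneOrdering.for_locus(group)
            except Exception:
                ordering = None
        return synthesis_table(
            self.rows, self.tables[gene_type], ordering, alpha=self.alpha
        )

    def allele_followup(self, restrict: bool = True) -> "ComparisonResults":
        """Allele-level comparison for genes validated by all procedures.

        The allele family contains every single allele of the qualifying
        genes across the tested groups (all observed alleles when
        ``restrict`` is False); adjustment uses that family size.
        """
        if self.model.level != "gene":
            raise ValueError("allele follow-up starts from a gene-level fit")
        qualifying = set(self.validated_by_all()) if restrict else None
        allele_model = RepertoireComparison(
            self.model.set1,
            self.model.set2,
            gene_types=self.model.gene_types,
            level="allele",
            mode=self.model.mode,
            alpha=self.model.alpha,
        )
        tables = allele_model.count_tables()
        if qualifying is not None:
            for gt, table in tables.items():
                table.rows = {
                    name: counts
                    for name, counts in table.rows.items()
                    if name.split("*")[0] in qualifying
                }
        rows = proptests.run_comparison(list(tables.values()), alpha=self.alpha)
        return ComparisonResults(model=allele_model, tables=tables, rows=rows)

    # -- presentation -----------------------------------------------------
    def summary(self, max_rows: int | None = 25) -> str:
        """Text summary: set totals, family sizes, rejection counts, top items."""
        m = self.model
        by_group = self.hypotheses_by_group()
        lines = [
            "Pairwise repertoire comparison",
            "=" * 62,
            f"level: {m.level}   mode: {m.mode}   alpha: {m.alpha}",
            f"{m.set1.label}: {m.set1.n_clonotypes} clonotypes, "
            f"{m.set1.n_sequences_total} sequences, {len(m.set1.outliers)} outliers",
            f"{m.set2.label}: {m.set2.n_clonotypes} clonotypes, "
            f"{m.set2.n_sequences_total} sequences, {len(m.set2.outliers)} outliers",
            f"hypotheses: {self.n_hypotheses} "
            f"({', '.join(f'{v} {k}' for k, v in sorted(by_group.items()))})",
            f"significant before adjustment: {self.n_significant('rawp')} "
            f"(neg {self.signed_significant()[0]}, pos {self.signed_significant()[1]})",
        ]
        for proc in PROCEDURES:
            lines.append(f"  {proc:>10}: {self.n_significant(proc)} rejected")
        lines.append(
            f"validated by all procedures: {len(self.validated_by_all())}"
        )
        fisher = self.small_occurrence_items()
        lines.append(f"small-occurrence (Fisher) items: {len(fisher)}")
        df = self.frame().sort_values("rawp")
        if max_rows is not None:
            df = df.head(max_rows)
        cols = ["Gene_Name", "x1", "x2", "diff", "z", "rawp", "adj_BH", "Test_interpretation"]
        with pd.option_context("display.float_format", lambda v: f"{v:.4g}"):
            lines.append("")
            lines.append(df[cols].to_string(index=False))
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame().to_csv(path, index=False)
        return path

    # -- plots -------------------------------------------------------------
    def plot_rejection_curves(self, ax=None):
        from . import plotting

        return plotting.plot_rejection_curves(self.rejection_curves(), ax=ax)

    def plot_scatter(self, ax=None):
        from . import plotting

        return plotting.plot_scatter(self.scatter_table(), alpha=self.alpha, ax=ax)

    def plot_synthesis(self, gene_type: str, ax=None, ordering=None):
        from . import plotting

        return plotting.plot_synthesis(
            self.synthesis(gene_type, ordering), self.model, ax=ax
        )
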