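"""V-J, V-D and D-J gene-association contingency tables with Ward clustering.

A cell (g_row, g_col) counts the kept clonotypes whose two calls are the
single genes g_row and g_col; ambiguous (multi-gene) calls are excluded
and reported.  Optional double hierarchical clustering orders rows and
columns independently by the Ward minimum-variance criterion on
Euclidean distances (the Ward.D2 update on raw Euclidean input), so a
heatmap of the reordered matrix groups genes with similar association
profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .repertoire import GeneType, RepertoireSet, _call_of, _category

__all__ = ["AssociationMatrix", "association_matrix", "ward_cluster", "tree_to_newick"]

_PAIRS = {"VJ": ("V", "J"), "VD": ("V", "D"), "DJ": ("D", "J")}


@dataclass
class AssociationMatrix:
    """Gene-pair contingency table, optionally Ward-ordered."""

    pair: str
    table: pd.DataFrame            # rows x cols, counts or per-10,000
    normalized: bool
    n_excluded: int                # clonotypes with ambiguous/absent calls
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    @property
    def total(self) -> float:
        return float(self.table.to_numpy().sum())

    def reordered(self) -> pd.DataFrame:
        """The table with clustered row/column order applied (if any)."""
        t = self.table
        if self.row_order:
            t = t.loc[self.row_order]
        if self.col_order:
            t = t[self.col_order]
        return t


def association_matrix(
    rset: RepertoireSet,
    pair: str = "VJ",
    normalized: bool = False,
    mode: str = "diversity",
) -> AssociationMatrix:
    """Contingency table of single-gene co-occurrences for one set.

    Clonotypes whose call for either gene type is absent or lists
    several genes are excluded (counted in ``n_excluded``).  Diversity
    mode counts clonotypes, expression mode their assigned sequences.
    With ``normalized`` the cells are rescaled to sum to 10,000.
    """
    if pair not in _PAIRS:
        raise ValueError(f"pair must be one of {sorted(_PAIRS)}")
    row_type, col_type = _PAIRS[pair]
    cells: dict[tuple[str, str], int] = {}
    excluded = 0
    for rec in rset.records:
        rc = _call_of(rec, row_type)
        cc = _call_of(rec, col_type)
        if rc is None or cc is None:
            excluded += 1
            continue
        rname, rsev = _category(rc, "gene")
        cname, csev = _category(cc, "gene")
        if rsev or csev:
            excluded += 1
            continue
        w = 1 if mode == "diversity" else rec.n_sequences
        cells[(rname, cname)] = cells.get((rname, cname), 0) + w
    if not cells:
        warnings.warn(f"{rset.label}: no clonotype with single {pair} calls", stacklevel=2)
        return AssociationMatrix(pair, pd.DataFrame(), normalized, excluded)

    rows = sorted({r for r, _ in cells})
    cols = sorted({c for _, c in cells})
    table = pd.DataFrame(0.0, index=rows, columns=cols)
    for (r, c), n in cells.items():
        table.loc[r, c] = n
    if normalized:
        table = table / table.to_numpy().sum() * 10_000
    return AssociationMatrix(pair, table, normalized, excluded)


def _leaf_order(linkage: np.ndarray, labels: list[str]) -> list[str]:
    return [labels[i] for i in hierarchy.leaves_list(linkage)]


def ward_cluster(matrix: AssociationMatrix) -> AssociationMatrix:
    """Double Ward clustering: rows on row vectors, columns on column vectors.

    Merge heights are monotone non-decreasing (Ward admits no
    inversions); ties break deterministically by scipy's lowest-index
    convention.  A matrix with a single row (or column) keeps identity
    order and no tree on that axis.
    """
    t = matrix.table
    if t.empty:
        return matrix
    row_link = col_link = None
    row_order = list(t.index)
    col_order = list(t.columns)
    if len(t.index) >= 2:
        row_link = hierarchy.linkage(pdist(t.to_numpy()), method="ward")
        row_order = _leaf_order(row_link, list(t.index))
    if len(t.columns) >= 2:
        col_link = hierarchy.linkage(pdist(t.to_numpy().T), method="ward")
        col_order = _leaf_order(col_link, list(t.columns))
    return AssociationMatrix(
        pair=matrix.pair,
        table=t,
        normalized=matrix.normalized,
        n_excluded=matrix.n_excluded,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
    )


def tree_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a merge history as a newick string with merge heights."""
    tree = hierarchy.to_tree(linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - (0.0 if node.left.is_leaf() else node.left.dist)
        dr = node.dist - (0.0 if node.right.is_leaf() else node.right.dist)
        return f"({left}:{dl:g},{right}:{dr:g})"

    return walk(tree) + ";"
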